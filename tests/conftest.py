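import numpy as np
import pandas as pd
import pytest

from sqimap.samples import SampleTable


@pytest.fixture(scope="session")
def study_matrices():
    from sqimap.ahp import default_matrices

    return default_matrices()


@pytest.fixture
def small_survey():
    """Deterministic 12-point two-parameter survey for plumbing tests."""
    rng = np.random.default_rng(42)
    n = 12
    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "x": rng.uniform(0, 1000, n),
            "y": rng.uniform(0, 1000, n),
            "OM": rng.uniform(0.6, 3.5, n),
            "pH": rng.uniform(7.1, 9.0, n),
        }
    )
    return SampleTable(df)


def make_table(x, y, values, name="v"):
    return SampleTable(
        pd.DataFrame(
            {"id": np.arange(len(x)), "x": x, "y": y, name: values}
        )
    )
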