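"""Analytic hierarchy process: pairwise-comparison weighting and consistency.

Criterion weights for the soil-quality index come from reciprocal
pairwise-comparison matrices on the Saaty 1-9 scale, one matrix per level of
the hierarchy (main criteria groups, then the indicators inside each group).
Weights are the normalized principal right eigenvector of the matrix (the
classical AHP prioritisation); the column-normalized row-mean approximation
is available as an alternative.  Consistency of a judgement matrix is
certified by the consistency ratio CR = CI / RI with
CI = (lambda_max - n) / (n - 1), acceptable when CR <= 0.10.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairwiseMatrix",
    "WeightVector",
    "ConsistencyReport",
    "PairwiseMatrixError",
    "SAATY_SCALE",
    "RANDOM_INDEX",
    "validate_pairwise",
    "derive_weights",
    "lambda_max",
    "random_index",
    "consistency",
    "global_weights",
    "read_pairwise_csv",
    "consistency_table",
    "default_matrices",
    "default_hierarchy_weights",
]

#: Admissible entries in strict Saaty mode: 1/9 ... 1/2, 1, 2 ... 9.
SAATY_SCALE = tuple(1.0 / k for k in range(9, 1, -1)) + tuple(
    float(k) for k in range(1, 10)
)

#: Random consistency index by matrix order n = 1..15 (Saaty's simulation table).
RANDOM_INDEX = (
    0.00, 0.00, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41,
    1.45, 1.49, 1.51, 1.48, 1.56, 1.57, 1.59,
)

_RECIPROCITY_RTOL = 1e-6
_SAATY_RTOL = 1e-6


class PairwiseMatrixError(ValueError):
    """A pairwise-comparison matrix violates a structural invariant."""


@dataclass(frozen=True)
class PairwiseMatrix:
    """Square reciprocal matrix of importance ratios for one hierarchy level.

    Parameters
    ----------
    labels
        Ordered criterion names, one per row/column.
    values
        ``(n, n)`` array of positive ratios; ``values[i, j]`` is how strongly
        criterion *i* is preferred over *j*.
    level
        Free tag naming the hierarchy level (``"main"``, ``"physical"``, ...).
    """

    labels: tuple[str, ...]
    values: np.ndarray
    level: str = "custom"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class WeightVector:
    """Normalized criterion weights in the order of the source matrix labels."""

    labels: tuple[str, ...]
    weights: np.ndarray
    method: str = "eigenvector"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or len(w) != len(self.labels):
            raise ValueError("weights must be 1-D and match labels")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", tuple(self.labels))

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.labels), name=self.method)

    def __getitem__(self, label: str) -> float:
        return float(self.weights[self.labels.index(label)])


@dataclass(frozen=True)
class ConsistencyReport:
    """lambda_max / CI / RI / CR summary for one judgement matrix."""

    lambda_max: float
    n: int
    ci: float
    ri: float
    cr: float
    acceptable: bool
    level: str = "custom"


def _check_square_positive(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise PairwiseMatrixError(f"matrix must be square, got shape {arr.shape}")
    if arr.shape[0] < 2:
        raise PairwiseMatrixError("pairwise matrix needs at least 2 criteria")
    bad = np.argwhere(~np.isfinite(arr) | (arr <= 0))
    if bad.size:
        i, j = bad[0]
        raise PairwiseMatrixError(
            f"entry ({i}, {j}) = {arr[i, j]!r} is not a positive finite ratio"
        )
    return arr


def validate_pairwise(
    matrix: PairwiseMatrix, strict_saaty: bool = True
) -> PairwiseMatrix:
    """Check the structural invariants of a pairwise-comparison matrix.

    Verifies squareness, positivity, unit diagonal, reciprocity
    (``a_ij * a_ji == 1`` to relative tolerance 1e-6) and, when
    ``strict_saaty`` is on, membership of every off-diagonal entry in the
    Saaty scale {1/9..1/2, 1, 2..9}.  Returns the matrix unchanged if all
    hold; raises :class:`PairwiseMatrixError` naming the offending indices
    otherwise.
    """
    arr = _check_square_positive(matrix.values)
    n = arr.shape[0]
    if len(matrix.labels) != n:
        raise PairwiseMatrixError(
            f"{len(matrix.labels)} labels for a {n}x{n} matrix"
        )
    diag = np.diag(arr)
    if not np.allclose(diag, 1.0, rtol=_RECIPROCITY_RTOL):
        i = int(np.argmax(np.abs(diag - 1.0)))
        raise PairwiseMatrixError(f"diagonal entry ({i}, {i}) = {diag[i]!r} != 1")
    prod = arr * arr.T
    bad = np.argwhere(np.abs(prod - 1.0) > _RECIPROCITY_RTOL)
    if bad.size:
        i, j = bad[0]
        raise PairwiseMatrixError(
            f"reciprocity broken at ({i}, {j}): "
            f"{arr[i, j]!r} * {arr[j, i]!r} = {prod[i, j]!r} != 1"
        )
    if strict_saaty:
        scale = np.asarray(SAATY_SCALE)
        off = ~np.eye(n, dtype=bool)
        rel = np.abs(arr[..., None] - scale) / scale
        on_scale = (rel < _SAATY_RTOL).any(axis=-1)
        bad = np.argwhere(off & ~on_scale)
        if bad.size:
            i, j = bad[0]
            raise PairwiseMatrixError(
                f"entry ({i}, {j}) = {arr[i, j]!r} is not on the Saaty "
                "1/9..9 scale (strict mode)"
            )
    return matrix


def derive_weights(matrix: PairwiseMatrix, method: str = "eigenvector") -> WeightVector:
    """Derive criterion weights from a validated pairwise matrix.

    ``method="eigenvector"`` (default) returns the normalized principal right
    eigenvector, obtained by power iteration from the uniform vector until the
    relative change drops below 1e-10 (at most 10,000 sweeps).
    ``method="column_normalized_row_mean"`` divides each column by its sum and
    averages the rows — the textbook hand approximation.
    """
    arr = _check_square_positive(matrix.values)
    n = arr.shape[0]
    if method == "eigenvector":
        w = np.full(n, 1.0 / n)
        for _ in range(10_000):
            w_next = arr @ w
            w_next /= w_next.sum()
            if np.max(np.abs(w_next - w) / np.maximum(w, 1e-300)) < 1e-10:
                w = w_next
                break
            w = w_next
        else:
            raise ArithmeticError(
                "power iteration did not converge in 10,000 iterations "
                "(degenerate matrix?)"
            )
        w /= w.sum()
    elif method == "column_normalized_row_mean":
        w = (arr / arr.sum(axis=0)).mean(axis=1)
        w /= w.sum()
    else:
        raise ValueError(f"unknown weight method {method!r}")
    return WeightVector(matrix.labels, w, method=method)


def lambda_max(matrix: PairwiseMatrix, weights: WeightVector) -> float:
    """Principal-eigenvalue estimate: mean over i of ``(A w)_i / w_i``.

    Exact when ``weights`` is the principal eigenvector; for a reciprocal
    matrix the result is >= n.
    """
    arr = _check_square_positive(matrix.values)
    w = np.asarray(weights.weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("lambda_max requires strictly positive weights")
    return float(np.mean((arr @ w) / w))


def random_index(n: int) -> float:
    """Tabulated random consistency index RI for matrix order ``n`` (1..15)."""
    if not 1 <= n <= len(RANDOM_INDEX):
        raise ValueError(f"random index tabulated for n in 1..15, got {n}")
    return RANDOM_INDEX[n - 1]


def consistency(matrix: PairwiseMatrix, weights: WeightVector) -> ConsistencyReport:
    """Consistency report: CI = (lambda_max - n)/(n - 1), CR = CI/RI.

    A matrix is acceptable when CR <= 0.10.  For n <= 2 a reciprocal matrix
    is always consistent and RI = 0 would make CR undefined; CR is defined
    as 0 there.
    """
    n = matrix.n
    lam = lambda_max(matrix, weights)
    if n <= 2:
        ci = 0.0
        ri = random_index(n)
        cr = 0.0
    else:
        ci = (lam - n) / (n - 1)
        ri = random_index(n)
        cr = ci / ri
    return ConsistencyReport(
        lambda_max=lam, n=n, ci=ci, ri=ri, cr=cr,
        acceptable=bool(cr <= 0.10), level=matrix.level,
    )


def global_weights(
    main: WeightVector, groups: Mapping[str, WeightVector]
) -> WeightVector:
    """Flatten a two-level hierarchy into global indicator weights.

    Each sub-criterion's global weight is the product of its group's main
    weight and its within-group weight; the result sums to 1 because each
    level does.
    """
    missing = [g for g in main.labels if g not in groups]
    if missing:
        raise KeyError(f"no group weight vector for main criteria: {missing}")
    labels: list[str] = []
    weights: list[float] = []
    for g in main.labels:
        gv = groups[g]
        for lab, w in zip(gv.labels, gv.weights):
            if lab in labels:
                raise ValueError(f"sub-criterion label {lab!r} appears in two groups")
            labels.append(lab)
            weights.append(main[g] * float(w))
    return WeightVector(tuple(labels), np.asarray(weights), method=main.method)


# ---------------------------------------------------------------------------
# I/O


def _parse_ratio(cell: str | float) -> float:
    """Parse a matrix cell: decimal or a fraction string like ``1/3``."""
    if isinstance(cell, str) and "/" in cell:
        return float(Fraction(cell.strip()))
    return float(cell)


def read_pairwise_csv(source, level: str = "custom") -> PairwiseMatrix:
    """Read a pairwise matrix from CSV: header row and first column are labels,
    cells are decimals or fraction strings such as ``1/3``."""
    df = pd.read_csv(source, index_col=0, dtype=str)
    labels = tuple(str(c).strip() for c in df.columns)
    row_labels = tuple(str(r).strip() for r in df.index)
    if labels != row_labels:
        raise PairwiseMatrixError(
            f"row labels {row_labels} do not match column labels {labels}"
        )
    values = np.array(
        [[_parse_ratio(df.iat[i, j]) for j in range(len(labels))]
         for i in range(len(labels))]
    )
    return PairwiseMatrix(labels, values, level=level)


def consistency_table(reports: Sequence[ConsistencyReport]) -> pd.DataFrame:
    """Flat table of lambda_max/CI/RI/CR, one column per hierarchy level."""
    return pd.DataFrame(
        {
            r.level: [r.lambda_max, r.ci, r.ri, r.cr]
            for r in reports
        },
        index=["lambda_max", "CI", "RI", "CR"],
    )


# ---------------------------------------------------------------------------
# Built-in wheat-barley study matrices
#
# Expert judgement matrices for wheat-barley land suitability: 8 physical,
# 6 chemical and 10 productivity (fertility) indicators, plus the 3x3 main
# matrix ranking the groups.  Entries include 0.5, hence strict Saaty mode
# is off when validating these.

_PHYSICAL_CSV = """\
,Clay,Silt,Sand,HC,BD,AWC,Slope,Depth
Clay,1,3,3,2,2,1/2,1/3,1/2
Silt,1/3,1,1/3,1/5,1/5,1/5,1/3,1/3
Sand,1/3,3,1,1/3,1/3,1/3,1/3,1/3
HC,1/2,5,3,1,1/3,1/5,1/2,1/3
BD,1/2,5,3,3,1,1/3,1/3,1/2
AWC,2,5,3,5,3,1,1/2,1/2
Slope,3,3,3,2,3,2,1,3
Depth,2,3,3,3,2,2,1/3,1
"""

_CHEMICAL_CSV = """\
,pH,EC,OM,CaCO3,CEC,ESP
pH,1,3,1/2,3,1/3,3
EC,1/3,1,1/3,1/3,1/3,1/3
OM,2,3,1,3,2,3
CaCO3,1/3,3,1/3,1,1/3,1/3
CEC,3,3,1/2,3,1,3
ESP,1/3,3,1/3,3,1/3,1
"""

_PRODUCTIVITY_CSV = """\
,N,P,K,Ca,Mg,Na,Fe,Cu,Zn,Mn
N,1,2,3,3,5,7,5,5,3,5
P,1/2,1,3,5,7,7,3,3,3,5
K,1/3,1/3,1,3,3,7,3,3,3,5
Ca,1/3,1/5,1/3,1,2,3,1/5,1/3,1/5,1/3
Mg,1/5,1/7,1/3,1/2,1,3,1/5,1/3,1/5,1/3
Na,1/7,1/7,1/7,1/3,1/3,1,1/5,1/3,1/3,1/3
Fe,1/5,1/3,1/3,5,5,5,1,3,3,3
Cu,1/5,1/3,1/3,3,3,3,1/3,1,1/3,3
Zn,1/3,1/3,1/3,5,5,3,1/3,3,1,3
Mn,1/5,1/5,1/5,3,3,3,1/3,1/3,1/3,1
"""

_MAIN_CSV = """\
,physical,chemical,productivity
physical,1,2,2
chemical,1/2,1,2
productivity,1/2,1/2,1
"""


def default_matrices() -> dict[str, PairwiseMatrix]:
    """The built-in wheat-barley judgement matrices, keyed by hierarchy level
    (``main``, ``physical``, ``chemical``, ``productivity``)."""
    out = {
        "main": read_pairwise_csv(_io.StringIO(_MAIN_CSV), level="main"),
        "physical": read_pairwise_csv(_io.StringIO(_PHYSICAL_CSV), level="physical"),
        "chemical": read_pairwise_csv(_io.StringIO(_CHEMICAL_CSV), level="chemical"),
        "productivity": read_pairwise_csv(
            _io.StringIO(_PRODUCTIVITY_CSV), level="productivity"
        ),
    }
    for m in out.values():
        validate_pairwise(m, strict_saaty=False)
    return out


def default_hierarchy_weights(
    method: str = "eigenvector",
) -> tuple[WeightVector, dict[str, ConsistencyReport]]:
    """Global indicator weights and consistency reports for the built-in
    wheat-barley hierarchy."""
    mats = default_matrices()
    main_w = derive_weights(mats["main"], method)
    groups = {
        level: derive_weights(mats[level], method)
        for level in ("physical", "chemical", "productivity")
    }
    reports = {
        level: consistency(mats[level], derive_weights(mats[level], method))
        for level in mats
    }
    return global_weights(main_w, groups), reports
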