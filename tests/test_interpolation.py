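"""Interpolators, LOOCV selection and rasterisation against hand oracles."""

import numpy as np
import pandas as pd
import pytest

from sqimap.interpolation import (
    CVResult,
    InterpolationError,
    InterpolatorSpec,
    candidate_specs,
    fit_variogram,
    loocv_rmse,
    predict,
    rasterize,
    select_best,
)
from sqimap.samples import SampleTable

from conftest import make_table

UNIT_SQUARE = make_table([0, 1, 0, 1], [0, 0, 1, 1], [0.0, 0.0, 1.0, 1.0])

EXACT_SPECS = [
    InterpolatorSpec("IDW", "power1"),
    InterpolatorSpec("IDW", "power2"),
    InterpolatorSpec("IDW", "power3"),
    InterpolatorSpec("RBF", "TPS"),
    InterpolatorSpec("RBF", "CRS"),
    InterpolatorSpec("RBF", "ST"),
]


@pytest.fixture(scope="module")
def smooth_points():
    rng = np.random.default_rng(3)
    x, y = rng.uniform(0, 4000, 30), rng.uniform(0, 4000, 30)
    v = np.sin(x / 900.0) * np.cos(y / 900.0) + 2.0
    return make_table(x, y, v)


class TestSpecs:
    def test_fifteen_candidates_in_fixed_order(self):
        specs = candidate_specs()
        assert len(specs) == 15
        assert [s.label for s in specs[:6]] == [
            "IDW-power1", "IDW-power2", "IDW-power3",
            "RBF-TPS", "RBF-CRS", "RBF-ST",
        ]
        assert specs[6].label == "Kriging-ordinary_gaussian"
        assert specs[-1].label == "Kriging-universal_exponential"

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            InterpolatorSpec("IDW", "power4")


class TestPredict:
    def test_single_sample_idw_constant(self):
        t = make_table([5.0], [5.0], [3.25])
        out = predict(InterpolatorSpec("IDW", "power2"), t, "v",
                      [[0, 0], [100, 50]])
        np.testing.assert_allclose(out, 3.25)

    @pytest.mark.parametrize("spec", EXACT_SPECS, ids=lambda s: s.label)
    def test_exactness_at_data_points(self, spec, smooth_points):
        out = predict(spec, smooth_points, "v", smooth_points.coords)
        np.testing.assert_allclose(out, smooth_points.values("v"), atol=1e-8)

    @pytest.mark.parametrize("variant", [
        "ordinary_gaussian", "ordinary_spherical", "ordinary_exponential",
        "simple_spherical", "universal_exponential",
    ])
    def test_kriging_exactness_at_data_points(self, variant, smooth_points):
        spec = InterpolatorSpec("Kriging", variant)
        out = predict(spec, smooth_points, "v", smooth_points.coords)
        np.testing.assert_allclose(out, smooth_points.values("v"), atol=1e-6)

    def test_idw_centre_of_square_is_mean(self):
        # equal distances force the arithmetic mean of the 4 corner values
        out = predict(InterpolatorSpec("IDW", "power2"), UNIT_SQUARE, "v",
                      [[0.5, 0.5]])
        assert out[0] == pytest.approx(0.5)

    def test_idw_bounded_by_sample_range(self, smooth_points):
        rng = np.random.default_rng(0)
        q = rng.uniform(-500, 4500, size=(200, 2))
        v = smooth_points.values("v")
        for p in (1, 2, 3):
            out = predict(InterpolatorSpec("IDW", f"power{p}"),
                          smooth_points, "v", q)
            assert np.all(out >= v.min() - 1e-12)
            assert np.all(out <= v.max() + 1e-12)

    def test_translation_invariance(self, smooth_points):
        q = np.array([[1234.0, 2345.0], [10.0, 3900.0]])
        shift = np.array([1.7e6, -3.3e5])
        shifted = make_table(
            smooth_points.coords[:, 0] + shift[0],
            smooth_points.coords[:, 1] + shift[1],
            smooth_points.values("v"),
        )
        for spec in EXACT_SPECS + [InterpolatorSpec("Kriging",
                                                    "ordinary_spherical")]:
            a = predict(spec, smooth_points, "v", q)
            b = predict(spec, shifted, "v", q + shift)
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_duplicate_points_reported(self):
        t = make_table([0, 0, 1], [0, 0, 1], [1.0, 2.0, 3.0])
        with pytest.raises(InterpolationError, match="rows 0 and 1"):
            predict(InterpolatorSpec("RBF", "TPS"), t, "v", [[0.5, 0.5]])

    def test_kriging_needs_ten_points(self):
        t = make_table([0, 1, 2], [0, 1, 0], [1.0, 2.0, 3.0])
        with pytest.raises(InterpolationError, match="10 points"):
            predict(InterpolatorSpec("Kriging", "ordinary_spherical"), t,
                    "v", [[0.5, 0.5]])


class TestLOOCV:
    def test_constant_values_rmse_zero(self):
        t = make_table([0, 1, 2, 3], [0, 1, 0, 1], [7.0] * 4)
        for spec in EXACT_SPECS:
            assert loocv_rmse(spec, t, "v").rmse == pytest.approx(0.0, abs=1e-9)

    def test_three_collinear_points_hand_enumeration(self):
        # points (0,0,0), (1,0,1), (2,0,2); IDW power 1.
        # fold 0: w=(1, 1/2) -> (1 + 2/2)/(3/2) = 4/3, residual  4/3
        # fold 1: w=(1, 1)   -> (0 + 2)/2      = 1,   residual  0
        # fold 2: w=(1/2, 1) -> (0/2 + 1)/(3/2) = 2/3, residual -4/3
        t = make_table([0, 1, 2], [0, 0, 0], [0.0, 1.0, 2.0])
        res = loocv_rmse(InterpolatorSpec("IDW", "power1"), t, "v")
        expected = np.sqrt((16 / 9 + 0 + 16 / 9) / 3)
        assert res.rmse == pytest.approx(expected, abs=1e-9)
        np.testing.assert_allclose(res.residuals, [4 / 3, 0.0, -4 / 3],
                                   atol=1e-9)

    def test_rmse_identity(self, smooth_points):
        res = loocv_rmse(InterpolatorSpec("IDW", "power2"), smooth_points, "v")
        assert res.rmse**2 * res.n == pytest.approx(
            np.sum(res.residuals**2), rel=1e-12
        )

    def test_brute_force_oracle_small_configurations(self):
        rng = np.random.default_rng(11)
        for n in (3, 4, 5):
            x, y = rng.uniform(0, 10, n), rng.uniform(0, 10, n)
            v = rng.uniform(0, 5, n)
            t = make_table(x, y, v)
            for p in (1, 2, 3):
                spec = InterpolatorSpec("IDW", f"power{p}")
                res = loocv_rmse(spec, t, "v")
                # independent enumeration of the folds
                sq = []
                for i in range(n):
                    d = np.hypot(x - x[i], y - y[i])
                    w = np.delete(d, i) ** (-float(p))
                    pred = np.sum(w * np.delete(v, i)) / np.sum(w)
                    sq.append((pred - v[i]) ** 2)
                assert res.rmse == pytest.approx(
                    np.sqrt(np.mean(sq)), abs=1e-9
                )

    def test_duplicated_table_leaves_idw_rmse_unchanged(self):
        rng = np.random.default_rng(5)
        x, y = rng.uniform(0, 10, 5), rng.uniform(0, 10, 5)
        v = rng.uniform(0, 1, 5)
        base = loocv_rmse(InterpolatorSpec("IDW", "power2"),
                          make_table(x, y, v), "v")
        # duplicates perturbed by 1e-6 m so systems stay non-singular;
        # each held-out point still has its twin -> exact prediction
        x2 = np.concatenate([x, x + 1e-6])
        y2 = np.concatenate([y, y + 1e-6])
        v2 = np.concatenate([v, v])
        dup = loocv_rmse(InterpolatorSpec("IDW", "power2"),
                         make_table(x2, y2, v2), "v")
        assert dup.rmse == pytest.approx(0.0, abs=1e-5)
        assert base.rmse > 0.01

    def test_too_few_points(self):
        t = make_table([0, 1], [0, 1], [0.0, 1.0])
        with pytest.raises(InterpolationError, match=">= 3"):
            loocv_rmse(InterpolatorSpec("IDW", "power1"), t, "v")


class TestSelectBest:
    def test_first_minimum_tie_break(self):
        specs = [InterpolatorSpec("IDW", f"power{p}") for p in (1, 2, 3)]
        results = [
            CVResult(specs[0], 2.0, 3, np.zeros(3)),
            CVResult(specs[1], 1.5, 3, np.zeros(3)),
            CVResult(specs[2], 1.5, 3, np.zeros(3)),
        ]
        best = min(results, key=lambda r: r.rmse)
        assert best.spec is specs[1]

    def test_single_candidate_returns_itself(self, smooth_points):
        spec = InterpolatorSpec("IDW", "power2")
        best, results = select_best(smooth_points, "v", [spec])
        assert best == spec and len(results) == 1

    def test_smooth_field_prefers_structure_aware_methods(self):
        rng = np.random.default_rng(21)
        x, y = rng.uniform(0, 4000, 50), rng.uniform(0, 4000, 50)
        v = np.sin(x / 800.0) * np.cos(y / 800.0)
        best, results = select_best(make_table(x, y, v), "v")
        rmse = {r.spec.label: r.rmse for r in results}
        structured = min(
            r for l, r in rmse.items() if not l.startswith("IDW")
        )
        assert structured < rmse["IDW-power3"]
        assert not best.label.startswith("IDW")


class TestVariogram:
    def test_fit_recovers_sill_scale(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 2000, size=(120, 2))
        v = np.sin(coords[:, 0] / 400) + 0.5 * rng.standard_normal(120)
        vg = fit_variogram(coords, v, "exponential")
        assert vg.nugget >= 0
        assert vg.psill > 0
        # the sill should be on the order of the data variance
        assert 0.1 * np.var(v) < vg.nugget + vg.psill < 10 * np.var(v)

    def test_gamma_zero_at_origin_when_no_nugget(self):
        from sqimap.interpolation import Variogram

        for model in ("gaussian", "spherical", "exponential"):
            vg = Variogram(model, 0.0, 2.0, 500.0)
            assert vg.gamma(np.array([0.0]))[0] == pytest.approx(0.0)
            # practical range reaches ~ the sill
            assert vg.gamma(np.array([500.0]))[0] >= 0.95 * 2.0 * 0.95


class TestRasterize:
    def test_single_cell_grid(self):
        t = make_table([0, 10, 0, 10], [0, 0, 10, 10], [1.0, 2.0, 3.0, 4.0])
        grid = rasterize(InterpolatorSpec("IDW", "power2"), t, "v",
                         (0, 0, 10, 10), 10.0, hull_buffer=100.0)
        assert grid.values.shape == (1, 1)
        assert grid.values[0, 0] == pytest.approx(2.5)  # centre of the square

    def test_constant_samples_constant_raster(self):
        t = make_table([0, 10, 0, 10], [0, 0, 10, 10], [5.0] * 4)
        grid = rasterize(InterpolatorSpec("RBF", "TPS"), t, "v",
                         (0, 0, 10, 10), 2.0, hull_buffer=100.0)
        np.testing.assert_allclose(grid.values, 5.0, atol=1e-9)

    def test_sample_aligned_cells_reproduce_values(self):
        # samples at (5, 5), (15, 5), ... coincide with 10 m cell centres
        xs, ys = np.meshgrid(np.arange(5, 40, 10.0), np.arange(5, 40, 10.0))
        v = (xs + ys).ravel()
        t = make_table(xs.ravel(), ys.ravel(), v)
        grid = rasterize(InterpolatorSpec("IDW", "power2"), t, "v",
                         (0, 0, 40, 40), 10.0, hull_buffer=100.0)
        np.testing.assert_allclose(np.flipud(grid.values).ravel(), v,
                                   atol=1e-9)

    def test_hull_masking(self):
        t = make_table([0, 10, 0, 10], [0, 0, 10, 10], [1.0] * 4)
        grid = rasterize(InterpolatorSpec("IDW", "power1"), t, "v",
                         (-50, -50, 60, 60), 10.0, hull_buffer=1.0)
        assert (~grid.mask()).any()  # far cells are no-data
        assert grid.mask().any()

    def test_cell_cap_guard(self):
        t = make_table([0, 1, 2], [0, 1, 0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="cap"):
            rasterize(InterpolatorSpec("IDW", "power1"), t, "v",
                      (0, 0, 1e6, 1e6), 1.0)
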