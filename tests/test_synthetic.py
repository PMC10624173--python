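"""Synthetic survey generator: determinism, marginals, sampling, yields."""

import numpy as np
import pytest
from scipy import stats

from sqimap.synthetic import (
    FieldSpec,
    MarginalSpec,
    default_marginals,
    default_yield_params,
    effective_sample_sizes,
    generate_field,
    generate_survey,
    population_kurtosis,
    sample_grid,
    simulate_yield,
    transform_gaussian,
)

SMALL = FieldSpec(extent=(2000.0, 2000.0), cellsize=100.0, seed=5)


class TestMarginals:
    def test_catalog_reference_rows(self):
        m = {s.name: s for s in default_marginals()}
        clay = m["Clay"]
        assert (clay.mean, clay.sd) == (28.62, 7.44)
        assert (clay.vmin, clay.vmax) == (10.53, 60.83)
        assert m["pH"].mean == 8.27 and m["pH"].sd == 0.38
        assert (m["Depth"].vmin, m["Depth"].vmax, m["Depth"].mean) == (
            20.0, 120.0, 74.46)
        assert len(m) == 24

    def test_invalid_marginals_rejected(self):
        with pytest.raises(ValueError):
            MarginalSpec("x", 1.0, -1.0, 0.0, 0.0, 2.0)
        with pytest.raises(ValueError):
            MarginalSpec("x", 5.0, 1.0, 0.0, 0.0, 2.0)  # mean outside range

    def test_transform_matches_moments_exactly_in_population(self):
        # the transform is moment-matched: huge-n draws must agree closely
        rng = np.random.default_rng(0)
        z = rng.standard_normal(400_000)
        for skew in (0.0, 0.41, 1.5, 3.8, -0.87, -2.0):
            m = MarginalSpec("x", 10.0, 3.0, skew, -1e9, 1e9)
            y = transform_gaussian(z, m)
            assert np.mean(y) == pytest.approx(10.0, abs=0.05)
            assert np.std(y) == pytest.approx(3.0, rel=0.03)
            if abs(skew) >= 0.5:
                assert np.sign(stats.skew(y)) == np.sign(skew)
                assert stats.skew(y) == pytest.approx(skew, rel=0.25)

    def test_kurtosis_of_affine_branch_is_normal(self):
        m = MarginalSpec("x", 0.0, 1.0, 0.2, -10, 10)
        assert population_kurtosis(m) == 3.0
        heavy = MarginalSpec("x", 0.0, 1.0, 3.0, -100, 100)
        assert population_kurtosis(heavy) > 3.0


class TestGenerateField:
    def test_determinism(self):
        a = generate_field(SMALL, "Clay")
        b = generate_field(SMALL, "Clay")
        np.testing.assert_array_equal(a.values, b.values)

    def test_different_parameters_differ(self):
        a = generate_field(SMALL, "Clay")
        b = generate_field(SMALL, "Silt")
        assert not np.allclose(a.values, b.values)

    def test_clip_respects_bounds(self):
        m = {s.name: s for s in default_marginals()}["Slope"]
        g = generate_field(SMALL, "Slope")
        assert g.values.min() >= m.vmin - 1e-12
        assert g.values.max() <= m.vmax + 1e-12

    def test_long_correlation_length_gives_flat_field(self):
        spec = FieldSpec(extent=(2000.0, 2000.0), cellsize=100.0, seed=5,
                         correlation_length=1e9)
        g = generate_field(spec, "Clay", clip=False)
        assert np.std(g.values) < 0.05 * 7.44  # essentially constant in space

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            generate_field(SMALL, "Uranium")

    def test_cross_correlation_couples_fields(self):
        spec = FieldSpec(extent=(4000.0, 4000.0), cellsize=100.0, seed=5,
                         cross_correlation={"Clay": 0.9, "CEC": 0.9})
        a = generate_field(spec, "Clay", clip=False).values.ravel()
        b = generate_field(spec, "CEC", clip=False).values.ravel()
        assert np.corrcoef(a, b)[0, 1] > 0.5

    def test_marginal_moments_within_three_se(self):
        # mean and SD of the raw (pre-clip) transform, against the catalog,
        # per parameter in >= 18 of 20 seeds; n_eff accounts for the
        # spatial autocorrelation, SE(sd) for the marginal kurtosis
        spec0 = FieldSpec(extent=(6800.0, 6800.0), cellsize=200.0)
        n_rows, n_cols = spec0.shape
        neff_mean, neff_var = effective_sample_sizes(
            n_rows, n_cols, spec0.cellsize, spec0.correlation_length
        )
        assert n_rows * n_cols >= 1000
        marginals = {s.name: s for s in spec0.marginals}
        for name in ("Clay", "pH", "Slope", "Depth", "Sand", "EC"):
            m = marginals[name]
            kurt = population_kurtosis(m)
            se_mean = m.sd / np.sqrt(neff_mean)
            se_sd = m.sd * np.sqrt(max(kurt - 1.0, 0.1) / (4 * neff_var))
            passes = 0
            for seed in range(20):
                spec = FieldSpec(extent=spec0.extent, cellsize=spec0.cellsize,
                                 seed=seed)
                g = generate_field(spec, name, clip=False)
                ok_mean = abs(g.values.mean() - m.mean) <= 3 * se_mean
                ok_sd = abs(g.values.std() - m.sd) <= 3 * se_sd
                ok_skew = (abs(m.skewness) < 0.5 or
                           np.sign(stats.skew(g.values.ravel()))
                           == np.sign(m.skewness))
                passes += ok_mean and ok_sd and ok_skew
            assert passes >= 18, (name, passes)


class TestSampleGrid:
    def test_point_count_geometry(self):
        fields = {"Clay": generate_field(SMALL, "Clay")}
        t = sample_grid(fields, spacing=500.0)
        assert t.n == 16  # 4 x 4 over 2 km
        t1 = sample_grid(fields, spacing=2000.0)
        assert t1.n == 1

    def test_default_survey_approximates_260_points(self):
        fields, samples, manifest = generate_survey(FieldSpec(seed=1))
        assert samples.n == 256  # 16 x 16 nodes at 400 m over 6.48 km
        assert manifest["n_points"] == 256
        assert set(samples.parameters) == {m.name for m in default_marginals()}

    def test_determinism_with_jitter(self):
        fields = {"Clay": generate_field(SMALL, "Clay")}
        a = sample_grid(fields, spacing=400.0, jitter=30.0, seed=3)
        b = sample_grid(fields, spacing=400.0, jitter=30.0, seed=3)
        assert a.data.equals(b.data)
        c = sample_grid(fields, spacing=400.0, jitter=30.0, seed=4)
        assert not a.data.equals(c.data)

    def test_spacing_larger_than_extent_rejected(self):
        fields = {"Clay": generate_field(SMALL, "Clay")}
        with pytest.raises(ValueError, match="spacing"):
            sample_grid(fields, spacing=5000.0)

    def test_mismatched_geometry_rejected(self):
        other = FieldSpec(extent=(1000.0, 1000.0), cellsize=100.0, seed=5)
        fields = {
            "Clay": generate_field(SMALL, "Clay"),
            "Silt": generate_field(other, "Silt"),
        }
        with pytest.raises(ValueError, match="geometry"):
            sample_grid(fields)

    def test_values_consistent_with_positions(self):
        # bilinear reads: a sample taken exactly at a cell centre must equal
        # that cell's value
        g = generate_field(SMALL, "Clay")
        t = sample_grid({"Clay": g}, spacing=100.0)  # nodes on cell centres
        xs, ys = t.coords[:, 0], t.coords[:, 1]
        cols = (xs / 100).astype(int)
        rows = g.n_rows - 1 - (ys / 100).astype(int)
        np.testing.assert_allclose(t.values("Clay"), g.values[rows, cols])


class TestSimulateYield:
    SQI = np.random.default_rng(1).uniform(0.3, 0.8, 64)

    def test_zero_noise_perfect_r2(self):
        from sqimap.validation import validate
        import pandas as pd

        y = simulate_yield(self.SQI, noise_sd=0.0, seed=2)
        rep = validate(pd.DataFrame({"yield_kg_ha": y, "sqi": self.SQI}))
        assert rep.r2 == pytest.approx(1.0)

    def test_zero_gain_no_association(self):
        from sqimap.validation import validate
        import pandas as pd

        r2s = []
        for seed in range(20):
            y = simulate_yield(self.SQI, gain=0.0, base=1600.0,
                               noise_sd=350.0, seed=seed)
            rep = validate(pd.DataFrame({"yield_kg_ha": y, "sqi": self.SQI}))
            r2s.append(rep.r2)
        assert np.median(r2s) < 0.1

    def test_default_params_solve_variance_decomposition(self):
        base, gain, noise_sd = default_yield_params(self.SQI)
        var_signal = gain**2 * np.var(self.SQI)
        r2_pop = var_signal / (var_signal + noise_sd**2)
        assert r2_pop == pytest.approx(0.67, abs=1e-9)
        mean_y = base + gain * self.SQI.mean()
        assert mean_y == pytest.approx(1600.0)

    def test_median_realized_r2_near_target(self):
        from sqimap.validation import validate
        import pandas as pd

        r2s = []
        for seed in range(50):
            y = simulate_yield(self.SQI, seed=seed)
            rep = validate(pd.DataFrame({"yield_kg_ha": y, "sqi": self.SQI}))
            r2s.append(rep.r2)
        assert abs(np.median(r2s) - 0.67) <= 0.1

    def test_determinism(self):
        a = simulate_yield(self.SQI, seed=11)
        b = simulate_yield(self.SQI, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_yield(self.SQI, noise_sd=-1.0)
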