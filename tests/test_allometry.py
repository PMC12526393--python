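"""Tree-level allometry: fitting, weighting, diagnostics, prediction."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beechbiomass import (
    GenerativeParams,
    TreeBiomassModel,
    breusch_pagan,
    compute_weights,
    estimate_variance_exponent,
    generate_sample_trees,
    variance_profile,
)
from beechbiomass.allometry import (
    CollinearityWarning,
    ConvergenceError,
    PowerPredictor,
    VarianceProfile,
)


class TestVarianceProfile:
    def test_111_points_give_four_groups_with_merged_tail(self):
        rng = np.random.default_rng(0)
        prof = variance_profile(rng.normal(size=111), rng.uniform(4, 70, 111))
        assert len(prof) == 4
        assert list(prof.size) == [25, 25, 25, 36]
        assert np.all(np.diff(prof.mean_predictor) > 0)

    def test_half_group_tail_is_kept(self):
        rng = np.random.default_rng(1)
        prof = variance_profile(rng.normal(size=63), rng.uniform(4, 70, 63))
        assert list(prof.size) == [25, 25, 13]

    def test_rejects_fewer_than_two_groups(self):
        with pytest.raises(ValueError, match="at least 50"):
            variance_profile(np.zeros(49), np.arange(49) + 1.0)

    def test_constant_residuals_give_zero_variances(self):
        prof = variance_profile(np.ones(50), np.arange(50) + 1.0)
        assert np.allclose(prof.variance, 0.0)
        with pytest.raises(ValueError, match="zero group variance"):
            estimate_variance_exponent(prof)

    def test_quadratic_variance_growth_recovered(self):
        """Residuals with Var proportional to d0^2 give ln-ln slope ~2."""
        rng = np.random.default_rng(42)
        d0 = rng.uniform(4, 70, 2000)
        resid = rng.normal(0, 1, 2000) * d0
        prof = variance_profile(resid, d0)
        _, lam = estimate_variance_exponent(prof)
        assert abs(lam - 2.0) < 0.3


class TestVarianceExponent:
    def test_two_point_exact_solution(self):
        prof = VarianceProfile(
            np.array([10.0, 20.0]), np.array([4.0, 16.0]), np.array([25, 25])
        )
        alpha, lam = estimate_variance_exponent(prof)
        assert lam == pytest.approx(2.0, abs=1e-12)
        assert alpha == pytest.approx(0.04, rel=1e-10)

    def test_homoscedastic_residuals_give_near_zero_exponent(self):
        rng = np.random.default_rng(3)
        d0 = rng.uniform(4, 70, 2000)
        prof = variance_profile(rng.normal(0, 5, 2000), d0)
        _, lam = estimate_variance_exponent(prof)
        assert abs(lam) < 0.3


class TestWeights:
    def test_zero_exponent_gives_unit_weights(self):
        np.testing.assert_array_equal(compute_weights(np.array([3.0, 9.0]), 0.0), 1.0)

    def test_arithmetic(self):
        assert compute_weights(np.array([10.0]), 2.0)[0] == pytest.approx(0.01)
        assert compute_weights(np.array([60.0]), 1.821)[0] == pytest.approx(
            60.0**-1.821, rel=1e-12
        )

    def test_rejects_nonpositive_predictor(self):
        with pytest.raises(ValueError, match="positive"):
            compute_weights(np.array([10.0, 0.0]), 1.0)


class TestFitting:
    def test_noise_free_fit_recovers_generative_coefficients(self):
        p = GenerativeParams(b0_fol=0.01, b1_fol=2.5, alpha_var=0.0, seed=11)
        trees = generate_sample_trees(p, 80)
        res = TreeBiomassModel(trees, "foliage", "d0").fit_unweighted()
        assert res.params[0] == pytest.approx(0.01, rel=1e-6)
        assert res.params[1] == pytest.approx(2.5, rel=1e-6)
        assert np.allclose(res.resid, 0.0, atol=1e-8)

    def test_large_sample_recovers_foliage_exponent(self, trees500):
        res = TreeBiomassModel(trees500, "foliage", "d0").fit_unweighted()
        assert abs(res.params[1] - 2.63892) < 0.1

    def test_unit_weights_reproduce_unweighted_fit(self, trees500):
        model = TreeBiomassModel(trees500, "woody", "d0")
        a = model.fit_unweighted()
        b = model.fit_weighted(np.ones(len(trees500)))
        np.testing.assert_allclose(a.params, b.params, rtol=1e-8)

    def test_weighted_fit_exact_on_noise_free_data(self, noisefree_trees):
        model = TreeBiomassModel(noisefree_trees, "woody", "d0")
        w = compute_weights(noisefree_trees["d0_mm"].to_numpy(), 1.5)
        res = model.fit_weighted(w)
        assert np.allclose(res.resid, 0.0, atol=1e-7)

    def test_collinear_predictors_flagged(self):
        """h an exact power of d0 makes the combined form unidentifiable."""
        p = GenerativeParams(seed=21)
        trees = generate_sample_trees(p, 200).copy()
        trees["h_m"] = 0.05 * trees["d0_mm"] ** 1.0
        with pytest.warns(CollinearityWarning):
            TreeBiomassModel(trees, "woody", "d0h").fit_unweighted()

    def test_weighting_shrinks_exponent_standard_errors(self):
        """Under heteroscedastic noise the weighted fit is more efficient:
        its b1 standard error is smaller than the unweighted one on
        average over replicates."""
        diffs = []
        for seed in range(30):
            p = GenerativeParams(lambda_var=1.9, seed=1000 + seed)
            trees = generate_sample_trees(p, 300)
            model = TreeBiomassModel(trees, "foliage", "d0")
            unw = model.fit_unweighted()
            w = compute_weights(trees["d0_mm"].to_numpy(), 1.9)
            wtd = model.fit_weighted(w)
            diffs.append(unw.bse[1] - wtd.bse[1])
        assert np.mean(diffs) > 0


class TestProcedure:
    def test_two_pass_fit_carries_diagnostics(self, trees500):
        res = TreeBiomassModel(trees500, "foliage", "d0").fit()
        assert res.n_used + res.n_outliers_removed == len(trees500)
        assert np.all(res.weights > 0)
        assert res.lambda_ > 0.5
        assert np.isfinite(res.bp_pvalue)
        # weighted-scale metric consistency
        p = len(res.params)
        assert res.mse == pytest.approx(res.rse**2 * (res.n_used - p) / res.n_used)

    def test_noise_free_data_degrade_to_unweighted_with_warning(self, noisefree_trees):
        with pytest.warns(UserWarning, match="unweighted"):
            res = TreeBiomassModel(noisefree_trees, "foliage", "d0").fit()
        assert res.lambda_ == 0.0
        assert np.allclose(res.weights, 1.0)

    def test_outlier_rule_removes_points_above_99th_percentile(self, monkeypatch):
        p = GenerativeParams(seed=31)
        trees = generate_sample_trees(p, 200).copy()
        trees.loc[0, "foliage_g"] = 10 * trees["foliage_g"].max()
        y = trees["foliage_g"].to_numpy()
        expected_removed = int((y > np.percentile(y, 99)).sum())

        model = TreeBiomassModel(trees, "foliage", "d0")
        original = model._run_two_pass
        calls = {"n": 0}

        def fail_first(data):
            calls["n"] += 1
            if calls["n"] == 1:
                raise ConvergenceError("forced for the outlier rule")
            return original(data)

        monkeypatch.setattr(model, "_run_two_pass", fail_first)
        res = model.fit()
        assert res.n_outliers_removed == expected_removed
        assert res.n_used == len(trees) - expected_removed


class TestBreuschPagan:
    def test_constant_residuals_boundary_case(self):
        chi2, p = breusch_pagan(np.full(100, 2.0), np.linspace(1, 10, 100))
        assert chi2 == 0.0
        assert p == 1.0

    def test_detects_strong_heteroscedasticity(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            d0 = rng.uniform(4, 70, 500)
            resid = rng.normal(0, 1, 500) * d0  # variance ~ d0^2
            _, p = breusch_pagan(resid, d0)
            hits += p < 0.05
        assert hits >= 19

    def test_null_distribution_is_calibrated(self):
        """Homoscedastic residuals should rarely trigger the test."""
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            d0 = rng.uniform(4, 70, 200)
            _, p = breusch_pagan(rng.normal(0, 3, 200), d0)
            rejections += p < 0.05
        assert rejections <= 12  # ~5% nominal


class TestPrediction:
    def test_published_d0_models_reproduce_worked_example(self):
        """The d0-based parameter sets give ~432 g foliage and ~2936 g
        woody mass for a 60 mm tree -- the 'around 400 g / nearly 3000 g'
        illustration."""
        fol = PowerPredictor("foliage", "d0", np.array([0.00878, 2.63892]))
        wood = PowerPredictor("woody", "d0", np.array([0.01762, 2.93664]))
        assert fol.predict(d0=60.0) == pytest.approx(432.4, abs=0.5)
        assert wood.predict(d0=60.0) == pytest.approx(2936.3, abs=0.5)

    def test_small_trees_vanish(self, trees500):
        res = TreeBiomassModel(trees500, "foliage", "d0").fit()
        assert res.predict(d0=1e-6) < 1e-10

    def test_missing_predictor_raises(self, trees500):
        res = TreeBiomassModel(trees500, "foliage", "d0h").fit()
        with pytest.raises(ValueError, match="requires h"):
            res.predict(d0=30.0)

    @settings(max_examples=30, deadline=None)
    @given(
        d0_pair=st.tuples(
            st.floats(min_value=1.0, max_value=100.0),
            st.floats(min_value=1.0, max_value=100.0),
        )
    )
    def test_prediction_monotone_in_diameter(self, fitted_foliage_d0, d0_pair):
        lo, hi = sorted(d0_pair)
        if lo == hi:
            return
        assert fitted_foliage_d0.predict(d0=lo) <= fitted_foliage_d0.predict(d0=hi)


@pytest.fixture(scope="module")
def fitted_foliage_d0(trees500):
    return TreeBiomassModel(trees500, "foliage", "d0").fit()


class TestPredictInterval:
    def test_zero_covariance_collapses_to_point(self, fitted_foliage_d0):
        res = fitted_foliage_d0
        saved = res.cov_params
        try:
            res.cov_params = np.zeros_like(saved)
            lo, hi = res.predict_interval(d0=30.0, n_draws=200, seed=0)
            point = res.predict(d0=30.0)
            assert lo == pytest.approx(point)
            assert hi == pytest.approx(point)
        finally:
            res.cov_params = saved

    def test_interval_narrows_with_sample_size(self):
        widths = {}
        for n in (500, 5000):
            p = GenerativeParams(seed=55)
            trees = generate_sample_trees(p, n)
            res = TreeBiomassModel(trees, "foliage", "d0").fit()
            lo, hi = res.predict_interval(d0=30.0, n_draws=2000, seed=1)
            widths[n] = hi - lo
        assert widths[5000] < widths[500]

    def test_band_covers_the_true_curve(self):
        """The 95% Monte-Carlo band contains the generative curve at
        d0 = 30 mm in roughly 95% of replicates."""
        p0 = GenerativeParams()
        truth = p0.b0_fol * 30.0**p0.b1_fol
        covered = 0
        n_rep = 60
        for seed in range(n_rep):
            p = GenerativeParams(seed=20_000 + seed)
            trees = generate_sample_trees(p, 200)
            res = TreeBiomassModel(trees, "foliage", "d0").fit()
            lo, hi = res.predict_interval(d0=30.0, n_draws=1000, seed=seed)
            covered += lo <= truth <= hi
        assert covered / n_rep >= 0.85

    def test_nonfinite_covariance_rejected(self, fitted_foliage_d0):
        res = fitted_foliage_d0
        saved = res.cov_params
        try:
            res.cov_params = np.full_like(saved, np.nan)
            with pytest.raises(ValueError, match="covariance"):
                res.predict_interval(d0=30.0)
        finally:
            res.cov_params = saved


class TestReporting:
    def test_summary_and_json_round_trip(self, tmp_path, fitted_foliage_d0):
        res = fitted_foliage_d0
        text = res.summary()
        assert "Breusch-Pagan" in text and "RSE" in text
        path = tmp_path / "model.json"
        res.to_json(path)
        loaded = PowerPredictor.from_json(path)
        assert loaded.predict(d0=42.0) == pytest.approx(res.predict(d0=42.0))
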