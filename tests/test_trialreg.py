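"""Pairwise differences, z-scoring, robust regression and the
subject-level covariation analysis."""

import numpy as np
import pytest

from ssralpha import (AnalysisConfig, SimParams, pairwise_condition_differences,
                      robust_fit, simulate_cohort, subject_level_regression,
                      zscore)
from ssralpha.pipeline import decompose_subject


class TestPairwiseDifferences:
    def test_count_and_order(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([10.0, 20.0, 30.0, 40.0])
        d = pairwise_condition_differences(a, b)
        assert d.shape == (12,)
        assert d[0] == 1.0 - 10.0
        assert d[3] == 1.0 - 40.0          # a-index major ordering

    def test_constant_inputs_give_zeros(self):
        a = np.full(3, 5.0)
        assert np.allclose(pairwise_condition_differences(a, a), 0.0)

    def test_mean_linearity(self, rng):
        a = rng.standard_normal(6)
        b = rng.standard_normal(9)
        d = pairwise_condition_differences(a, b)
        assert d.mean() == pytest.approx(a.mean() - b.mean())

    def test_2d_channel_alignment(self, rng):
        a = rng.standard_normal((3, 4))
        b = rng.standard_normal((5, 4))
        d = pairwise_condition_differences(a, b)
        assert d.shape == (15, 4)
        assert np.allclose(d[:, 2],
                           pairwise_condition_differences(a[:, 2], b[:, 2]))


class TestZscore:
    def test_standardization(self, rng):
        v = rng.standard_normal(50) * 3 + 7
        z = zscore(v)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        v = rng.standard_normal(30)
        assert np.allclose(zscore(4.0 * v + 2.0), zscore(v))
        assert np.allclose(zscore(-4.0 * v), -zscore(v))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            zscore(np.ones(10))


class TestRobustFit:
    def test_exact_recovery_on_noiseless_line(self, rng):
        x = rng.standard_normal(40)
        y = 2.5 * x - 1.25
        slope, inter, conv = robust_fit(x, y)
        assert conv
        assert slope == pytest.approx(2.5, abs=1e-10)
        assert inter == pytest.approx(-1.25, abs=1e-10)

    def test_constant_y_zero_slope(self, rng):
        x = rng.standard_normal(20)
        slope, inter, conv = robust_fit(x, np.full(20, 3.0))
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert inter == pytest.approx(3.0)

    def test_outlier_resistance_beats_ols(self, rng):
        """With gross outliers, the bisquare fit stays closer to the true
        slope than ordinary least squares."""
        wins = 0
        for _ in range(50):
            x = rng.standard_normal(33)
            y = x + 0.1 * rng.standard_normal(33)
            y[:3] += rng.choice([-1, 1], 3) * rng.uniform(8, 15, 3)
            slope, _, _ = robust_fit(x, y)
            ols = np.polyfit(x, y, 1)[0]
            wins += abs(slope - 1.0) < abs(ols - 1.0)
        assert wins >= 45

    def test_matches_reference_irls_implementation(self, rng):
        """Cross-check against statsmodels RLM with the same bisquare
        tuning constant and MAD scale."""
        import statsmodels.api as sm
        x = rng.standard_normal(60)
        y = 1.7 * x + 0.4 + rng.standard_normal(60)
        y[:5] += 10
        slope, inter, _ = robust_fit(x, y)
        X = sm.add_constant(x)
        rlm = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(4.685)).fit()
        assert slope == pytest.approx(rlm.params[1], abs=0.02)
        assert inter == pytest.approx(rlm.params[0], abs=0.05)

    def test_multi_column_matches_single(self, rng):
        x = rng.standard_normal(25)
        Y = np.column_stack([x * 2 + rng.standard_normal(25),
                             -x + 5 + rng.standard_normal(25)])
        slopes, inters, conv = robust_fit(x, Y)
        for k in range(2):
            s1, i1, _ = robust_fit(x, Y[:, k])
            assert slopes[k] == pytest.approx(s1, abs=1e-6)
            assert inters[k] == pytest.approx(i1, abs=1e-6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            robust_fit(np.arange(4.0), np.arange(4.0))


@pytest.fixture(scope="module")
def small_cohort_spectra():
    """Compact cohort for regression tests: trial-coupled SSR/alpha."""
    cfg = AnalysisConfig(
        sim=SimParams(n_trials_per_condition=16, n_channels=24,
                      trial_coupling=0.8),
        n_subjects=6, scd_enabled=False, seed=0)
    subjects, montage, _ = simulate_cohort(
        cfg.n_subjects, cfg.sim, master_seed=77)
    spectra = [decompose_subject(e, montage, cfg) for e in subjects]
    return spectra, montage


class TestSubjectLevelRegression:
    def test_coupled_effects_give_positive_slopes(self, small_cohort_spectra):
        """When the generator couples trial-wise SSR amplitude to alpha
        lateralization, regression slopes at SSR channels are positive."""
        spectra, montage = small_cohort_spectra
        res = subject_level_regression(spectra, montage, "evopow", 10.0,
                                       n_perm=300, seed=1, compute_bf=False)
        assert res.beta.shape == (6, 24)
        assert np.all(np.isfinite(res.beta))
        # slope map should be positive where the 10 Hz SSR projects
        from ssralpha.synth import spatial_profile, _SSR_SEED_RIGHT
        prof = spatial_profile(montage.positions, _SSR_SEED_RIGHT, 0.6)
        top = np.argsort(-prof)[:3]
        assert res.beta[:, top].mean() > 0.05

    def test_replication_invariance(self, small_cohort_spectra):
        """Duplicating every subject leaves the per-subject slopes
        unchanged."""
        spectra, montage = small_cohort_spectra
        r1 = subject_level_regression(spectra, montage, "itcz", 12.0,
                                      n_perm=200, seed=2, compute_bf=False)
        r2 = subject_level_regression(spectra + spectra, montage, "itcz", 12.0,
                                      n_perm=200, seed=2, compute_bf=False)
        assert np.allclose(r2.beta[:6], r1.beta)
        assert np.allclose(r2.beta[6:], r1.beta)

    def test_channel_count_and_bf_map(self, small_cohort_spectra):
        spectra, montage = small_cohort_spectra
        res = subject_level_regression(spectra, montage, "evopow", 12.0,
                                       n_perm=200, seed=3)
        assert len(res.bf_map) == montage.n_channels
        assert all(b.bf10 > 0 for b in res.bf_map)

    def test_too_few_subjects_rejected(self, small_cohort_spectra):
        spectra, montage = small_cohort_spectra
        with pytest.raises(ValueError):
            subject_level_regression(spectra[:2], montage, "evopow", 10.0)
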