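import numpy as np
import pytest

from irivsca import (IrivConfig, IrivError, SpectrumSet, backward_eliminate,
                     classify_variable, generate_design_matrix, run_iriv,
                     score_variables)
from irivsca._pls import make_folds
from irivsca.iriv import (INTERFERING, STRONG, UNINFORMATIVE, WEAK,
                          _mannwhitney_p)


class TestDesignMatrix:
    def test_columns_balanced(self):
        A = generate_design_matrix(4, 6, seed=1)
        np.testing.assert_array_equal(A.sum(axis=0), [3, 3, 3, 3])

    def test_deterministic(self):
        a = generate_design_matrix(5, 10, seed=3)
        b = generate_design_matrix(5, 10, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_complement_stays_balanced(self):
        A = generate_design_matrix(4, 8, seed=0)
        B = 1 - A
        np.testing.assert_array_equal(B.sum(axis=0), [4, 4, 4, 4])

    def test_odd_rows_rejected(self):
        with pytest.raises(ValueError):
            generate_design_matrix(3, 5, seed=0)


class TestClassification:
    @pytest.mark.parametrize("dmean,p,expected", [
        (-0.3, 0.01, STRONG),
        (-0.3, 0.50, WEAK),
        (+0.2, 0.50, UNINFORMATIVE),
        (+0.2, 0.01, INTERFERING),
        (0.0, 0.01, UNINFORMATIVE),  # no evidence of benefit
        (-0.3, 0.05, WEAK),          # p == alpha is not significant
    ])
    def test_four_quadrant_rule(self, dmean, p, expected):
        assert classify_variable(dmean, p) == expected

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            classify_variable(0.1, 1.5)

    def test_exhaustive_quadrants_match_rule(self, rng):
        dm = rng.normal(size=500)
        pv = rng.uniform(size=500)
        for d, p in zip(dm, pv):
            got = classify_variable(d, p, alpha=0.05)
            want = {(True, True): STRONG, (True, False): WEAK,
                    (False, False): UNINFORMATIVE, (False, True): INTERFERING}[
                        (d < 0, p < 0.05)]
            assert got == want


class TestScoreVariables:
    def test_identical_distributions_give_p_one(self, rng):
        a = rng.normal(size=20)
        assert _mannwhitney_p(a, a.copy()) == pytest.approx(1.0)
        assert _mannwhitney_p(np.full(10, 2.0), np.full(12, 2.0)) == 1.0

    def test_sole_predictor_scores_negative_dmean(self, rng):
        """Inclusion of the only informative variable must lower RMSECV;
        cross-checked against a brute-force pooling of the row scores."""
        n, p = 30, 3
        X = rng.normal(size=(n, p))
        y = 2.0 * X[:, 0] + 0.05 * rng.normal(size=n)
        cfg = IrivConfig(n_rows=20, seed=5)
        A = generate_design_matrix(p, cfg.n_rows, seed=11)
        folds = make_folds(n, cfg.cv_folds, np.random.default_rng(cfg.seed))
        dmean, pvals = score_variables(X, y, A, cfg, folds)
        assert dmean[0] < 0 and pvals[0] < 0.05

        # brute-force oracle: recompute phi pools with plain loops
        from irivsca._pls import cv_rmse
        B = 1 - A
        ra = np.array([cv_rmse(X[:, A[k] == 1], y, folds, 10) for k in range(cfg.n_rows)])
        rb = np.array([cv_rmse(X[:, B[k] == 1], y, folds, 10) for k in range(cfg.n_rows)])
        for i in range(p):
            phi0, phii = [], []
            for k in range(cfg.n_rows):
                if np.isfinite(ra[k]):
                    (phi0 if A[k, i] == 1 else phii).append(ra[k])
                if np.isfinite(rb[k]):
                    (phi0 if B[k, i] == 1 else phii).append(rb[k])
            assert dmean[i] == pytest.approx(np.mean(phi0) - np.mean(phii), abs=1e-12)

    def test_noise_variable_rarely_significant(self):
        """A pure-noise variable among several strong predictors barely moves
        any sub-model's RMSECV, so its inclusion/exclusion distributions
        should look alike (p > alpha) in most seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 6))
            y = X[:, 0] + 0.8 * X[:, 1] + 0.6 * X[:, 2] + 0.5 * rng.normal(size=40)
            cfg = IrivConfig(n_rows=30, seed=seed)
            A = generate_design_matrix(6, cfg.n_rows, seed=seed + 100)
            dmean, pvals = score_variables(X, y, A, cfg)
            if pvals[5] > 0.05:
                hits += 1
        assert hits >= 6  # noise variable non-significant in most seeds


class TestBackwardElimination:
    def test_duplicate_column_removed(self, rng):
        x = rng.normal(size=(40, 1))
        X = np.column_stack([x, x, rng.normal(size=40)])
        y = 2 * x[:, 0] + 0.1 * rng.normal(size=40)
        survivors, _, _ = backward_eliminate(X, y, [0, 1, 2], IrivConfig(seed=0))
        assert not {0, 1} <= set(survivors)  # at most one of the duplicates

    def test_single_perfect_predictor_unchanged(self, rng):
        x = rng.normal(size=(30, 1))
        y = 3 * x[:, 0]
        survivors, theta, trace = backward_eliminate(x, y, [0], IrivConfig(seed=0))
        assert survivors == [0] and theta <= 1e-8 and trace == ()

    def test_deterministic(self, rng):
        X = rng.normal(size=(30, 5))
        y = X @ [1, 0.5, 0, 0, 0] + 0.2 * rng.normal(size=30)
        cfg = IrivConfig(seed=9)
        a = backward_eliminate(X, y, list(range(5)), cfg)
        b = backward_eliminate(X, y, list(range(5)), cfg)
        assert a[0] == b[0] and a[1] == b[1]


def _tiny_planted_set(seed, n_bands=40, planted=(5, 14, 26, 33), noise=0.006):
    from irivsca.synthetic import SimConfig, simulate
    grid = np.arange(400.0, 400.0 + 50.0 * n_bands, 50.0)
    bands = {float(grid[i]): e for i, e in zip(planted, (0.012, 0.014, 0.011, 0.013))}
    cfg = SimConfig(grid=grid, planted_bands=bands, feature_width_nm=20.0,
                    noise_sd=noise, baseline_offset_sd=0.0015, scatter_sd=0.002,
                    seed=seed)
    return simulate(cfg), bands


class TestRunIriv:
    def test_retained_counts_non_increasing_and_recovery(self):
        ss, bands = _tiny_planted_set(seed=21)
        res = run_iriv(ss, IrivConfig(n_rows=200, seed=2))
        counts = [r.n_retained for r in res.rounds]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        planted = np.array(sorted(bands))
        found = sum(np.min(np.abs(res.final_wavelengths - b)) <= 50.0 for b in planted)
        assert found >= 3  # recovers at least 3 of the 4 planted bands

    def test_early_rounds_shrink_fast(self):
        ss, _ = _tiny_planted_set(seed=22)
        res = run_iriv(ss, IrivConfig(n_rows=200, seed=3))
        if len(res.rounds) >= 3:
            assert res.rounds[2].n_retained < 0.5 * len(res.rounds[0].wavelengths)

    def test_full_run_deterministic(self):
        ss, _ = _tiny_planted_set(seed=23)
        cfg = IrivConfig(n_rows=200, seed=4)
        a, b = run_iriv(ss, cfg), run_iriv(ss, cfg)
        np.testing.assert_array_equal(a.final_wavelengths, b.final_wavelengths)
        assert a.final_rmsecv == b.final_rmsecv
        for ra, rb in zip(a.rounds, rb_rounds := b.rounds):
            np.testing.assert_array_equal(ra.dmean, rb.dmean)
            np.testing.assert_array_equal(ra.pvalues, rb.pvalues)

    def test_final_bands_subset_of_last_round(self):
        ss, _ = _tiny_planted_set(seed=24)
        res = run_iriv(ss, IrivConfig(n_rows=200, seed=5))
        assert set(res.final_wavelengths) <= set(res.rounds[-1].retained_wavelengths)

    def test_requires_target(self):
        ss, _ = _tiny_planted_set(seed=25)
        bare = SpectrumSet(ss.wavelengths, ss.reflectance, ss.sample_ids)
        with pytest.raises(IrivError, match="target"):
            run_iriv(bare, IrivConfig(seed=0))


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(n_rows=3), dict(n_rows=0), dict(cv_folds=1),
        dict(max_pls_factors=0), dict(alpha=0.0), dict(alpha=1.0),
        dict(max_rounds=0),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            IrivConfig(**kwargs)
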