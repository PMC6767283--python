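import numpy as np
import pytest
from scipy import stats

from irivsca import (FIXTURES, IrivConfig, SimConfig, SyntheticError,
                     field_grid, lab_grid, make_fixture, planted_recovery,
                     run_iriv, simulate, simulate_spectra, simulate_targets)


class TestGrids:
    def test_lab_grid_has_2151_one_nm_bands(self):
        wl = lab_grid()
        assert wl.size == 2151 and wl[0] == 350 and wl[-1] == 2500
        np.testing.assert_allclose(np.diff(wl), 1.0)

    def test_field_grid_has_990_bands_with_regional_spacing(self):
        wl = field_grid()
        assert wl.size == 990
        assert wl[0] == 350 and wl[-1] <= 2500
        d = np.diff(wl)
        assert np.all(d > 0)
        # regional sampling never exceeds the nominal interval of its region
        assert d[wl[:-1] < 1000].max() <= 1.5 + 1e-9
        assert d[(wl[:-1] >= 1000) & (wl[:-1] < 1900)].max() <= 3.8 + 1e-9
        assert d[wl[:-1] >= 1900].max() <= 2.5 + 1e-9


class TestTargets:
    def test_moments_converge_to_configured_values(self):
        cfg = SimConfig(seed=1)
        t = simulate_targets(cfg, n=100_000)
        assert t.mean() == pytest.approx(9.28, abs=0.02)
        assert t.std() == pytest.approx(1.11, abs=0.02)
        assert stats.skew(t) == pytest.approx(0.58, abs=0.05)

    def test_zero_skewness_symmetric(self):
        cfg = SimConfig(target_skewness=0.0, seed=2)
        t = simulate_targets(cfg, n=100_000)
        assert abs(stats.skew(t)) < 0.05

    def test_deterministic(self):
        cfg = SimConfig(seed=3)
        np.testing.assert_array_equal(simulate_targets(cfg), simulate_targets(cfg))

    def test_unattainable_skewness_errors(self):
        with pytest.raises(SyntheticError):
            simulate_targets(SimConfig(target_skewness=1.2, seed=0))


class TestSpectra:
    def test_reflectance_within_unit_interval(self):
        for name in FIXTURES:
            ss, _ = make_fixture(name)
            assert ss.reflectance.min() > 0 and ss.reflectance.max() < 1

    def test_noise_free_planted_band_perfectly_antitone(self):
        grid = np.arange(400.0, 900.0, 10.0)
        cfg = SimConfig(grid=grid, planted_bands={600.0: 0.02}, noise_sd=0.0,
                        baseline_offset_sd=0.0, scatter_sd=0.0, seed=4)
        ss = simulate(cfg)
        j = int(np.flatnonzero(grid == 600.0)[0])
        r = stats.spearmanr(ss.reflectance[:, j], ss.target).statistic
        assert r == pytest.approx(-1.0)

    def test_null_simulation_band_correlations_stay_low(self):
        """With zero planted effects, band-target correlations are pure
        chance; the frozen null quantile over 100 seeds keeps max|r| < 0.4
        in at least 90% of seeds at n = 63."""
        grid = np.arange(400.0, 1400.0, 10.0)
        frac = []
        for seed in range(100):
            ss = simulate(SimConfig(grid=grid, planted_bands={}, seed=seed))
            r = stats.spearmanr(ss.reflectance, ss.target).statistic[-1, :-1]
            frac.append(np.abs(r).max() < 0.4)
        assert np.mean(frac) >= 0.9

    def test_off_grid_planted_band_rejected(self):
        with pytest.raises(SyntheticError):
            SimConfig(grid=np.arange(400.0, 500.0, 10.0),
                      planted_bands={405.0: 0.01}, seed=0)


class TestFixtures:
    def test_pinned_fixture_bit_identical(self):
        a, _ = make_fixture("lab-small")
        b, _ = make_fixture("lab-small")
        np.testing.assert_array_equal(a.reflectance, b.reflectance)
        np.testing.assert_array_equal(a.target, b.target)

    def test_lab_small_shape_and_documented_planted_bands(self, lab_small):
        ss, truth = lab_small
        assert ss.n_samples == 63 and ss.n_bands == 200
        assert sorted(truth["planted_bands"]) == [520.0, 850.0, 1190.0, 1870.0, 2210.0]

    def test_lab_full_band_count(self):
        ss, _ = make_fixture("lab-full")
        assert ss.n_bands == 2151

    def test_unknown_fixture(self):
        with pytest.raises(SyntheticError):
            make_fixture("nope")


class TestRecoveryMetric:
    def test_exact_and_windowed_hits(self):
        grid = np.arange(400.0, 500.0, 10.0)
        recall, fp = planted_recovery([420.0, 480.0], [420.0, 460.0], grid)
        assert recall == 0.5 and fp == 1
        recall, fp = planted_recovery([450.0], [460.0], grid, window_steps=1)
        assert recall == 1.0 and fp == 0

    def test_empty_selection(self):
        grid = np.arange(400.0, 500.0, 10.0)
        recall, fp = planted_recovery([], [420.0], grid)
        assert recall == 0.0 and fp == 0


class TestNoiseDegradesRecovery:
    def test_mean_recall_non_increasing_in_noise(self):
        grid = np.arange(400.0, 2400.0, 50.0)  # 40 bands
        planted = {500.0: 0.012, 1100.0: 0.014, 1700.0: 0.011, 2200.0: 0.013}
        means = []
        for noise in (0.002, 0.02, 0.06):
            recs = []
            for seed in range(8):
                cfg = SimConfig(grid=grid, planted_bands=planted,
                                feature_width_nm=20.0, noise_sd=noise,
                                baseline_offset_sd=0.0015, scatter_sd=0.002,
                                seed=300 + seed)
                ss = simulate(cfg)
                res = run_iriv(ss, IrivConfig(n_rows=200, seed=seed))
                rec, _ = planted_recovery(res.final_wavelengths, planted, grid)
                recs.append(rec)
            means.append(np.mean(recs))
        assert means[0] >= means[1] - 1e-9 >= means[2] - 1e-9
        assert means[0] > means[2]

    def test_zero_noise_single_planted_band_always_found(self):
        grid = np.arange(400.0, 2400.0, 50.0)
        planted = {1100.0: 0.02}
        for seed in range(5):
            cfg = SimConfig(grid=grid, planted_bands=planted, noise_sd=0.0,
                            baseline_offset_sd=0.0, scatter_sd=0.0,
                            feature_width_nm=20.0, seed=seed)
            ss = simulate(cfg)
            res = run_iriv(ss, IrivConfig(n_rows=200, seed=seed))
            assert np.min(np.abs(res.final_wavelengths - 1100.0)) == 0.0
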