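"""Simulator correctness: dwell laws, increment statistics, MSD scaling."""

import numpy as np
import pytest
from scipy import integrate, stats

from pwdiff.sim_models import (
    ATTMConfig,
    PiecewiseConfig,
    add_localization_noise,
    compose_trajectory,
    fractional_gaussian_noise,
    generate_dataset,
    sample_attm_D,
    sample_dwell_times,
    simulate_anomalous_segment,
    simulate_attm,
    simulate_fbm,
    simulate_piecewise_bm,
    simulate_sbm,
    SegmentSpec,
    truncexp_rate,
)
from pwdiff.baselines import ensemble_msd, tamsd


def _msd_slope(trajs, lag_lo, lag_hi):
    msd = ensemble_msd(trajs)
    lags = np.arange(lag_lo, lag_hi + 1)
    return np.polyfit(np.log(lags), np.log(msd[lags]), 1)[0]


class TestDwellTimes:
    def test_mean_matches_target(self, rng):
        d = sample_dwell_times(10 ** 6, (10, 190), 57, rng)
        assert abs(d.mean() - 57) < 0.2

    def test_truncation_bounds(self, rng):
        d = sample_dwell_times(10 ** 4, (10, 190), 57, rng)
        assert d.min() >= 10 and d.max() <= 190
        assert d.dtype.kind == "i"

    def test_rate_solves_closed_form_mean(self):
        """The calibrated rate reproduces the mean under numerical integration."""
        rate = truncexp_rate((10, 190), 57)
        num, _ = integrate.quad(lambda t: t * rate * np.exp(-rate * t), 10, 190)
        den, _ = integrate.quad(lambda t: rate * np.exp(-rate * t), 10, 190)
        assert num / den == pytest.approx(57, abs=1e-8)

    def test_infeasible_mean_rejected(self):
        with pytest.raises(ValueError):
            sample_dwell_times(10, (10, 190), 100.5)  # above midpoint
        with pytest.raises(ValueError):
            sample_dwell_times(10, (10, 190), 9.0)


class TestPiecewiseBM:
    def test_zero_D_is_static(self, rng):
        traj = simulate_piecewise_bm(np.zeros(50), rng=rng)
        assert np.allclose(traj.positions, traj.positions[0])

    def test_constant_D_increment_variance(self, rng):
        n = 10 ** 5
        traj = simulate_piecewise_bm(np.ones(n), dt=1.0, rng=rng)
        v = traj.displacements().var(axis=0)
        se = 2.0 * np.sqrt(2.0 / (n - 1))  # SD of a variance estimate
        assert np.all(np.abs(v - 2.0) < 3 * se)

    def test_split_profile_variances_chi2(self, rng):
        """Each half's increment variance lies in its chi-square 99% CI."""
        D = np.concatenate([np.full(100, 1e-3), np.full(100, 1e3)])
        traj = simulate_piecewise_bm(D, rng=rng)
        d = traj.displacements()
        for sl, Dval in ((slice(0, 99), 1e-3), (slice(99, 199), 1e3)):
            x = d[sl].ravel()
            k = x.size
            stat = np.sum(x ** 2) / (2 * Dval)
            lo, hi = stats.chi2.ppf([0.005, 0.995], k)
            assert lo < stat < hi

    def test_negative_D_rejected(self):
        with pytest.raises(ValueError):
            simulate_piecewise_bm(np.array([1.0, -1.0]))


class TestFBM:
    def test_alpha_one_is_uncorrelated(self, rng):
        traj = simulate_fbm(5000, 1.0, rng=rng)
        d = traj.displacements()[:, 0]
        r = np.corrcoef(d[:-1], d[1:])[0, 1]
        assert abs(r) < 3 / np.sqrt(d.size)

    def test_lag1_autocorrelation_alpha_half(self, rng):
        """fGn lag-1 correlation equals (2^(2H) - 2)/2 = -0.293 at H=0.25."""
        x = fractional_gaussian_noise(300, 0.25, rng, size=600)
        r1 = np.mean(x[:, :-1] * x[:, 1:]) / np.mean(x * x)
        expected = (2 ** 0.5 - 2) / 2
        assert r1 == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("alpha", [0.4, 1.0, 1.6])
    def test_fgn_autocovariance_closed_form(self, alpha, rng):
        H = alpha / 2
        n, reps = 256, 800
        x = fractional_gaussian_noise(n, H, rng, size=reps)
        k = np.arange(6, dtype=float)
        expected = 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))
        for lag in range(6):
            prod = x[:, : n - lag] * x[:, lag:] if lag else x * x
            est = prod.mean()
            se = prod.std() / np.sqrt(prod.size / max(1, 2 * n * H))  # conservative
            se = max(se, prod.std() / np.sqrt(reps))
            assert abs(est - expected[lag]) < 3 * se + 0.01

    def test_ensemble_msd_exponent(self, rng):
        trajs = [simulate_fbm(100, 0.3, rng=rng) for _ in range(3000)]
        assert _msd_slope(trajs, 1, 99) == pytest.approx(0.30, abs=0.05)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            simulate_fbm(50, 2.0)


class TestSBM:
    def test_alpha_one_matches_bm_variance(self, rng):
        traj = simulate_sbm(20000, 1.0, D0=1.0, rng=rng)
        v = traj.displacements().var()
        assert v == pytest.approx(2.0, rel=0.05)

    def test_per_step_variance_scaling(self, rng):
        """log per-step ensemble variance vs log t has slope alpha - 1."""
        n, reps = 200, 4000
        steps = np.stack([simulate_sbm(n, 0.5, rng=rng).displacements() for _ in range(reps)])
        var_t = steps.var(axis=(0, 2))
        t = np.arange(1, n)
        sel = t >= 5
        slope = np.polyfit(np.log(t[sel]), np.log(var_t[sel]), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.03)

    def test_ensemble_msd_exponent_strongly_subdiffusive(self, rng):
        trajs = [simulate_sbm(100, 0.1, rng=rng) for _ in range(3000)]
        assert _msd_slope(trajs, 1, 99) == pytest.approx(0.1, abs=0.05)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            simulate_sbm(50, 0.0)


class TestATTM:
    def test_sampled_D_matches_inverse_cdf_law(self, rng):
        sigma, bounds = 0.3, (10 ** -6.7, 1.0)
        x = sample_attm_D(sigma, bounds, rng, size=10 ** 5)
        lo, hi = bounds
        cdf = lambda v: (v ** sigma - lo ** sigma) / (hi ** sigma - lo ** sigma)
        assert stats.kstest(x, cdf).pvalue > 0.01

    def test_mean_segment_count(self, rng):
        counts = [
            len(simulate_attm(ATTMConfig(), rng)[1].changepoints) + 1
            for _ in range(1500)
        ]
        assert 16 <= np.mean(counts) <= 20

    def test_fresh_ensemble_msd_exponent(self, rng):
        trajs = [
            simulate_attm(ATTMConfig(), rng, stationary=False)[0] for _ in range(2000)
        ]
        slope = _msd_slope(trajs, 10, 100)
        assert 0.70 <= slope <= 0.80

    def test_normal_regime_warns(self):
        with pytest.warns(UserWarning):
            ATTMConfig(sigma=0.8, gamma=0.4)


class TestAnomalousSegments:
    @pytest.mark.parametrize("model,alpha,lo,hi", [
        ("CTRW", 0.5, 10, 199),
        ("LW", 1.5, 10, 199),
    ])
    def test_ensemble_msd_exponent(self, model, alpha, lo, hi, rng):
        trajs = [
            simulate_anomalous_segment(model, 200, alpha, rng=rng) for _ in range(2000)
        ]
        assert _msd_slope(trajs, lo, hi) == pytest.approx(alpha, abs=0.05)

    @pytest.mark.parametrize("model,alpha", [("LW", 0.5), ("CTRW", 1.5), ("ATTM", 1.2)])
    def test_inadmissible_pairs_rejected(self, model, alpha):
        with pytest.raises(ValueError, match="only"):
            simulate_anomalous_segment(model, 100, alpha)


class TestComposition:
    def test_single_segment(self, rng):
        traj, truth = compose_trajectory([SegmentSpec("BM", 120, 1.0, 2.0)], 100, rng)
        assert truth.changepoints.size == 0
        assert np.all(truth.D_true == 2.0)
        assert traj.n == 100

    def test_two_segments_boundary(self, rng):
        specs = [SegmentSpec("BM", 100, 1.0, 1.0), SegmentSpec("fBm", 100, 0.5, 1.0)]
        traj, truth = compose_trajectory(specs, 200, rng)
        assert list(truth.changepoints) == [100]
        assert truth.model_tag[99] == "BM" and truth.model_tag[100] == "fBm"
        # position continuity: boundary step comparable to interior steps
        step = np.linalg.norm(traj.displacements(), axis=1)
        assert step[99] <= step.max()

    def test_labels_roundtrip_changepoints(self, rng):
        cfg = PiecewiseConfig(n_steps=150, target="alpha", model_set=("fBm", "SBM"))
        for traj, truth in generate_dataset(cfg, 5, rng):
            rebuilt = np.zeros(truth.n)
            for a, b in truth.segment_bounds():
                rebuilt[a:b] = truth.alpha_true[a]
            assert np.array_equal(rebuilt, truth.alpha_true)

    def test_no_positional_jumps_at_boundaries(self, rng):
        """Boundary steps are not distributionally larger than interior ones."""
        boundary, interior = [], []
        for _ in range(200):
            specs = [SegmentSpec("BM", 50, 1.0, 1.0), SegmentSpec("BM", 50, 1.0, 1.0)]
            traj, truth = compose_trajectory(specs, 100, rng)
            step = np.linalg.norm(traj.displacements(), axis=1)
            boundary.append(step[49])
            interior.extend(step[10:40])
        assert np.mean(boundary) == pytest.approx(np.mean(interior), rel=0.1)


class TestLocalizationNoise:
    def test_zero_sigma_identity(self, rng):
        traj = simulate_piecewise_bm(np.ones(50), rng=rng)
        noisy = add_localization_noise(traj, 0.0, rng)
        assert np.array_equal(noisy.positions, traj.positions)

    def test_negative_sigma_rejected(self, rng):
        traj = simulate_piecewise_bm(np.ones(50), rng=rng)
        with pytest.raises(ValueError):
            add_localization_noise(traj, -0.1, rng)

    def test_tamsd_offset(self, rng):
        """Noise adds 4 sigma^2 to the ensemble TA-MSD at every lag >= 1."""
        sigma = 0.5
        base, noisy = [], []
        for _ in range(400):
            traj = simulate_piecewise_bm(np.full(200, 0.1), rng=rng)
            base.append(tamsd(traj, 5).msd)
            noisy.append(tamsd(add_localization_noise(traj, sigma, rng), 5).msd)
        offset = np.mean(noisy, axis=0) - np.mean(base, axis=0)
        assert np.allclose(offset, 4 * sigma ** 2, atol=0.05)

    def test_negative_lag1_displacement_correlation(self, rng):
        """Static noise anticorrelates consecutive displacements."""
        corrs = []
        for _ in range(100):
            traj = simulate_piecewise_bm(np.full(500, 0.05), rng=rng)
            noisy = add_localization_noise(traj, 0.5, rng)
            d = noisy.displacements()[:, 0]
            corrs.append(np.corrcoef(d[:-1], d[1:])[0, 1])
        assert np.mean(corrs) < -0.2


class TestDatasetGeneration:
    def test_reproducible_under_seed(self):
        cfg = PiecewiseConfig(n_steps=80, seed=42, noise_sigma=(0.0, 0.5))
        a = generate_dataset(cfg, 5)
        b = generate_dataset(cfg, 5)
        for (ta, _), (tb, _) in zip(a, b):
            assert np.array_equal(ta.positions, tb.positions)

    def test_labels_within_configured_ranges(self, rng):
        cfg = PiecewiseConfig(n_steps=120, target="alpha",
                              model_set=("fBm", "SBM", "CTRW", "LW"))
        for _, truth in generate_dataset(cfg, 20, rng):
            assert np.all((truth.alpha_true >= 0.05) & (truth.alpha_true <= 2.0))
        cfg = PiecewiseConfig(n_steps=120, target="D")
        for _, truth in generate_dataset(cfg, 20, rng):
            assert np.all((truth.D_true >= 1e-3) & (truth.D_true <= 1e3))

    def test_dwell_distribution_in_dataset(self, rng):
        """Observed dwells respect the truncation bounds and sit near the
        target mean.  Interior segments are selected by fitting inside the
        200-step window, which biases their mean below the sampler's 57
        (the sampler itself is checked exactly in TestDwellTimes)."""
        cfg = PiecewiseConfig(n_steps=200, target="D")
        lengths = []
        for _, truth in generate_dataset(cfg, 300, rng):
            bounds = truth.segment_bounds()
            lengths.extend(b - a for a, b in bounds[1:-1])
        assert max(lengths) <= 190
        assert 40 < np.mean(lengths) < 60
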