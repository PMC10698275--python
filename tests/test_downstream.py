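"""Segment-level analysis: power laws, dwell coupling, states, geometry."""

import numpy as np
import pandas as pd
import pytest

from pwdiff.downstream import (
    cluster_segments,
    confinement_radius,
    dwell_vs_D,
    fit_powerlaw_tail,
    synthetic_multistate_segment_table,
    turning_angles,
)
from pwdiff.sim_models import ATTMConfig, sample_attm_D, simulate_attm, simulate_piecewise_bm
from pwdiff.trajectory import Trajectory


class TestPowerlawTail:
    def test_recovers_exponent_from_exact_samples(self, rng):
        x = sample_attm_D(0.3, (10 ** -6.7, 1.0), rng, size=10 ** 5)
        assert fit_powerlaw_tail(x, (10 ** -6.7, 1.0)) == pytest.approx(0.30, abs=0.01)

    def test_rescaling_invariance(self, rng):
        x = sample_attm_D(0.4, (1e-4, 1.0), rng, size=5000)
        a = fit_powerlaw_tail(x, (1e-4, 1.0))
        b = fit_powerlaw_tail(x * 37.0, (37e-4, 37.0))
        assert a == pytest.approx(b, rel=1e-9)

    def test_too_few_points(self, rng):
        with pytest.raises(ValueError):
            fit_powerlaw_tail(np.full(10, 0.5), (0.1, 1.0))

    def test_degenerate_constant_data(self):
        with pytest.raises(ValueError):
            fit_powerlaw_tail(np.full(100, 0.5), (0.1, 1.0))


class TestDwellVsD:
    def test_exact_powerlaw(self, rng):
        D = 10 ** rng.uniform(-5, 0, 500)
        tab = pd.DataFrame({"mean_D": D, "tau": D ** -0.4})
        assert dwell_vs_D(tab) == pytest.approx(0.400, abs=1e-6)

    def test_constant_tau_gives_zero(self, rng):
        D = 10 ** rng.uniform(-5, 0, 500)
        tab = pd.DataFrame({"mean_D": D, "tau": np.full(500, 7.0)})
        assert dwell_vs_D(tab) == pytest.approx(0.0, abs=1e-9)

    def test_ground_truth_attm_recovery(self, rng):
        rows = []
        for _ in range(400):
            _, g = simulate_attm(ATTMConfig(), rng)
            for a, b in g.segment_bounds():
                rows.append({"mean_D": g.D_true[a], "tau": float(b - a)})
        gamma = dwell_vs_D(pd.DataFrame(rows))
        assert 0.35 <= gamma <= 0.45

    def test_input_validation(self):
        with pytest.raises(ValueError):
            dwell_vs_D(pd.DataFrame({"mean_D": [1.0] * 5, "tau": [1.0] * 5}))
        bad = pd.DataFrame({"mean_D": np.ones(30), "tau": np.zeros(30)})
        with pytest.raises(ValueError):
            dwell_vs_D(bad)


class TestClustering:
    def test_two_separated_blobs(self, rng):
        f1 = np.column_stack([rng.normal(-4, 0.1, 60), rng.normal(0.3, 0.02, 60)])
        f2 = np.column_stack([rng.normal(0, 0.1, 60), rng.normal(1.5, 0.02, 60)])
        tab = pd.DataFrame({
            "mean_D": 10.0 ** np.concatenate([f1[:, 0], f2[:, 0]]),
            "mean_alpha": np.concatenate([f1[:, 1], f2[:, 1]]),
            "tau": np.ones(120),
        })
        sc = cluster_segments(tab, k_candidates=(1, 2, 3, 4), rng=0)
        assert sc.k == 2
        labels = sc.labels
        assert len(set(labels[:60])) == 1 and len(set(labels[60:])) == 1
        assert labels[0] != labels[-1]

    def test_four_state_mixture(self):
        tab, states = synthetic_multistate_segment_table(400, rng=1)
        sc = cluster_segments(tab, rng=2)
        assert sc.k == 4
        true_occ = np.array([
            tab["tau"][states == s].sum() for s in range(4)
        ]) / tab["tau"].sum()
        assert np.allclose(np.sort(sc.occupancy), np.sort(true_occ), atol=0.05)

    def test_occupancy_sums_to_one_and_order_invariant(self):
        tab, _ = synthetic_multistate_segment_table(300, rng=3)
        sc1 = cluster_segments(tab, rng=4)
        shuffled = tab.sample(frac=1, random_state=0).reset_index(drop=True)
        sc2 = cluster_segments(shuffled, rng=4)
        assert sc1.occupancy.sum() == pytest.approx(1.0)
        assert np.allclose(np.sort(sc1.occupancy), np.sort(sc2.occupancy), atol=1e-9)

    def test_fixed_seed_reproducible(self):
        tab, _ = synthetic_multistate_segment_table(200, rng=5)
        a = cluster_segments(tab, rng=6)
        b = cluster_segments(tab, rng=6)
        assert np.array_equal(a.labels, b.labels)


class TestTurningAngles:
    def test_straight_line_zero(self):
        traj = Trajectory(np.column_stack([np.arange(10.0), np.zeros(10)]))
        assert np.allclose(turning_angles(traj), 0.0)

    def test_zigzag_reversals(self):
        x = np.array([0, 1, 0, 1, 0, 1.0])
        traj = Trajectory(np.column_stack([x, np.zeros(6)]))
        assert np.allclose(turning_angles(traj), 180.0)

    def test_bm_angles_uniform(self, rng):
        from scipy.stats import chisquare

        angles = np.concatenate([
            turning_angles(simulate_piecewise_bm(np.ones(2000), rng=rng))
            for _ in range(50)
        ])
        hist, _ = np.histogram(angles, bins=18, range=(0, 180))
        assert chisquare(hist).pvalue > 0.01

    def test_mirror_invariance(self, rng):
        traj = simulate_piecewise_bm(np.ones(100), rng=rng)
        mirrored = Trajectory(traj.positions * [-1.0, 1.0])
        assert np.allclose(turning_angles(traj), turning_angles(mirrored))

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            turning_angles(Trajectory(np.zeros((2, 2))))


class TestConfinementRadius:
    def test_identical_points_zero(self):
        assert confinement_radius(np.ones((5, 2))) == 0.0

    def test_circle_radius(self):
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pos = np.column_stack([3.0 * np.cos(theta), 3.0 * np.sin(theta)])
        assert confinement_radius(pos) == pytest.approx(3.0, rel=1e-9)

    def test_reflected_bm_scales_with_disc_radius(self, rng):
        """For BM reflected in a disc the radius-of-gyration estimate is
        proportional to the disc radius (constant fixed by simulation)."""

        def reflected_bm(R, n=4000):
            pos = np.zeros((n, 2))
            for i in range(1, n):
                step = rng.normal(scale=0.2 * R, size=2)
                cand = pos[i - 1] + step
                r = np.hypot(*cand)
                if r > R:
                    cand *= (2 * R - r) / r  # radial reflection
                pos[i] = cand
            return pos

        ratios = [confinement_radius(reflected_bm(R)) / R for R in (1.0, 2.0)]
        assert ratios[0] == pytest.approx(ratios[1], rel=0.1)
        assert 0.5 < ratios[0] < 1.0  # between uniform-disc RMS and boundary

    def test_too_short(self):
        with pytest.raises(ValueError):
            confinement_radius(np.zeros((2, 2)))
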