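"""Simulators for heterogeneous diffusion in 2D.

This module generates labeled synthetic trajectories for every scenario used
to train and benchmark the pointwise regressor:

* piecewise Brownian motion with abrupt changes of the diffusion coefficient
  ``D`` (log-uniform in ``[1e-3, 1e3]`` by default);
* segments of anomalous diffusion (fBm, SBM, CTRW, LW, ATTM) with anomalous
  exponent ``alpha`` in ``[0.05, 2]``;
* scaled Brownian motion (SBM) with a continuously varying diffusivity
  ``D(t) ~ t^(alpha-1)``;
* the annealed transient-time model (ATTM): Brownian motion whose ``D`` is
  redrawn from a power-law density ``~ D^(sigma-1)`` with dwell time
  ``tau = D^(-gamma)``, giving ensemble MSD exponent ``alpha = sigma/gamma``.

Dwell times between abrupt changes follow an exponential distribution
truncated to ``[10, 190]`` steps with mean 57; the rate is calibrated by
root-finding on the closed-form truncated-exponential mean.

Fractional Gaussian noise is synthesized exactly (Davies-Harte circulant
embedding), with a Cholesky fallback when the embedding is not nonnegative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .trajectory import GroundTruthProfile, Trajectory

__all__ = [
    "PiecewiseConfig",
    "ATTMConfig",
    "truncexp_rate",
    "sample_dwell_times",
    "simulate_piecewise_bm",
    "fractional_gaussian_noise",
    "simulate_fbm",
    "simulate_sbm",
    "simulate_ctrw",
    "simulate_lw",
    "sample_attm_D",
    "simulate_attm",
    "simulate_anomalous_segment",
    "compose_trajectory",
    "add_localization_noise",
    "generate_dataset",
]

#: models admissible for each side of alpha = 1
SUBDIFFUSIVE_ONLY = {"CTRW", "ATTM"}
SUPERDIFFUSIVE_ONLY = {"LW"}
ALL_MODELS = ("BM", "fBm", "SBM", "CTRW", "LW", "ATTM")


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class PiecewiseConfig:
    """Configuration of the piecewise heterogeneous-diffusion generator."""

    n_steps: int = 200
    D_range: tuple[float, float] = (1e-3, 1e3)
    alpha_range: tuple[float, float] = (0.05, 2.0)
    dwell_bounds: tuple[float, float] = (10.0, 190.0)
    dwell_mean: float = 57.0
    #: scalar -> fixed localization SD; pair -> uniform range per trajectory
    noise_sigma: object = 0.0
    model_set: tuple[str, ...] = ("BM",)
    target: str = "D"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.dwell_bounds[0] < self.dwell_mean < self.dwell_bounds[1]):
            raise ValueError("dwell_mean must lie strictly inside dwell_bounds")
        if self.D_range[0] >= self.D_range[1] or self.alpha_range[0] >= self.alpha_range[1]:
            raise ValueError("empty parameter range")
        unknown = set(self.model_set) - set(ALL_MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")


@dataclass
class ATTMConfig:
    """Parameters of the annealed transient-time model.

    ``sigma`` is the tail exponent of the D distribution (density ~
    ``D^(sigma-1)``), ``gamma`` couples the dwell time to D through
    ``tau = D^(-gamma)`` (unit proportionality constant, step units).
    The anomalous regime requires ``sigma/gamma < 1``.
    """

    sigma: float = 0.3
    gamma: float = 0.4
    D_bounds: tuple[float, float] = (10 ** -6.7, 1.0)
    n_steps: int = 200

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.gamma <= 0:
            raise ValueError("sigma and gamma must be positive")
        if self.D_bounds[0] >= self.D_bounds[1]:
            raise ValueError("D_bounds must satisfy D_min < D_max")
        if self.sigma / self.gamma >= 1:
            warnings.warn(
                "sigma/gamma >= 1: outside the anomalous (subdiffusive) regime",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# dwell times
# ---------------------------------------------------------------------------

def _truncexp_mean(rate: float, lo: float, hi: float) -> float:
    # closed-form mean of an exponential truncated to [lo, hi]
    ea, eb = np.exp(-rate * lo), np.exp(-rate * hi)
    return 1.0 / rate + (lo * ea - hi * eb) / (ea - eb)


def truncexp_rate(dwell_bounds: tuple[float, float], dwell_mean: float) -> float:
    """Rate of the truncated exponential whose mean equals ``dwell_mean``.

    Solved by 1-D root finding on the closed-form truncated-exponential mean;
    the mean decreases monotonically from ``(lo+hi)/2`` (rate -> 0) to ``lo``
    (rate -> inf), so the root is unique when it exists.
    """
    lo, hi = dwell_bounds
    if not (lo < dwell_mean < (lo + hi) / 2):
        raise ValueError(
            f"mean {dwell_mean} infeasible for truncation [{lo}, {hi}]; "
            f"must lie in ({lo}, {(lo + hi) / 2})"
        )
    return brentq(lambda r: _truncexp_mean(r, lo, hi) - dwell_mean, 1e-9, 10.0)


def sample_dwell_times(
    count: int,
    dwell_bounds: tuple[float, float] = (10.0, 190.0),
    dwell_mean: float = 57.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Integer dwell times from a truncated exponential with the given mean."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(rng)
    lo, hi = dwell_bounds
    rate = truncexp_rate(dwell_bounds, dwell_mean)
    u = rng.uniform(size=count)
    ea, eb = np.exp(-rate * lo), np.exp(-rate * hi)
    t = -np.log(ea - u * (ea - eb)) / rate
    return np.clip(np.rint(t), np.ceil(lo), np.floor(hi)).astype(int)


# ---------------------------------------------------------------------------
# elementary processes
# ---------------------------------------------------------------------------

def simulate_piecewise_bm(
    D_profile: np.ndarray,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Brownian motion with a per-step diffusion coefficient.

    The displacement arriving at position ``i`` (from ``i-1`` to ``i``) has
    per-axis variance ``2 * D_profile[i] * dt``, so a changepoint at step
    ``k`` affects displacements from index ``k`` on.  ``D_profile[0]`` labels
    the starting position and generates no displacement.
    """
    rng = np.random.default_rng(rng)
    D = np.asarray(D_profile, dtype=float)
    if np.any(D < 0):
        raise ValueError("D_profile must be nonnegative")
    sd = np.sqrt(2.0 * D[1:] * dt)
    steps = rng.normal(size=(D.size - 1, 2)) * sd[:, None]
    pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    return Trajectory(pos, dt=dt)


def fractional_gaussian_noise(
    n: int,
    hurst: float,
    rng: np.random.Generator | None = None,
    size: int = 1,
) -> np.ndarray:
    """Exact unit-variance fGn, shape ``(size, n)``.

    Davies-Harte circulant embedding of the fGn autocovariance
    ``r(k) = ((k+1)^2H - 2 k^2H + |k-1|^2H) / 2``; falls back to a Cholesky
    factorization if the embedding has materially negative eigenvalues.
    """
    rng = np.random.default_rng(rng)
    if not (0 < hurst < 1):
        raise ValueError("hurst must lie in (0, 1)")
    if abs(hurst - 0.5) < 1e-12:
        return rng.normal(size=(size, n))
    k = np.arange(n + 1, dtype=float)
    r = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))
    m = 2 * n
    circ = np.concatenate([r, r[-2:0:-1]])
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-8 * lam.max():
        cov = np.empty((n, n))
        idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        cov[:] = r[idx]
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
        return rng.normal(size=(size, n)) @ chol.T
    lam = np.clip(lam, 0.0, None)
    a = np.zeros((size, m), dtype=complex)
    a[:, 0] = np.sqrt(lam[0] / m) * rng.normal(size=size)
    a[:, n] = np.sqrt(lam[n] / m) * rng.normal(size=size)
    gr = rng.normal(size=(size, n - 1))
    gi = rng.normal(size=(size, n - 1))
    a[:, 1:n] = np.sqrt(lam[1:n] / (2 * m)) * (gr + 1j * gi)
    a[:, n + 1:] = np.conj(a[:, n - 1:0:-1])
    return np.fft.fft(a, axis=1).real[:, :n]


def simulate_fbm(
    n: int,
    alpha: float,
    D: float = 1.0,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Fractional Brownian motion with Hurst ``H = alpha/2``.

    Scaled so the ensemble MSD is ``4 D t^alpha`` in 2D.
    """
    if not (0 < alpha < 2):
        raise ValueError("fBm requires alpha in (0, 2)")
    rng = np.random.default_rng(rng)
    incr = fractional_gaussian_noise(n - 1, alpha / 2, rng, size=2)
    incr *= np.sqrt(2.0 * D) * dt ** (alpha / 2)
    pos = np.vstack([np.zeros(2), np.cumsum(incr.T, axis=0)])
    return Trajectory(pos, dt=dt)


def _sbm_D_profile(n: int, alpha: float, D0: float, dt: float) -> np.ndarray:
    """Per-step effective D such that the exact ensemble MSD is 4*D0*t^alpha."""
    t = np.arange(n, dtype=float) * dt
    incr_var = 2.0 * D0 * (t[1:] ** alpha - t[:-1] ** alpha)  # per axis, per step
    D = np.empty(n)
    D[1:] = incr_var / (2.0 * dt)
    D[0] = D[1]
    return D


def simulate_sbm(
    n: int,
    alpha: float,
    D0: float = 1.0,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Scaled Brownian motion: independent Gaussian steps, ``D(t) ~ t^(alpha-1)``."""
    if not (0 < alpha <= 2):
        raise ValueError("SBM requires alpha in (0, 2]")
    D = _sbm_D_profile(n, alpha, D0, dt)
    return simulate_piecewise_bm(D, dt=dt, rng=rng)


def simulate_ctrw(
    n: int,
    alpha: float,
    D: float = 1.0,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Continuous-time random walk sampled on the regular frame grid.

    Waiting times are Pareto with tail exponent ``1 + alpha`` (minimum one
    frame), jumps are instantaneous Gaussians; subdiffusive for alpha < 1.
    """
    if not (0 < alpha <= 1):
        raise ValueError("CTRW requires alpha in (0, 1]")
    rng = np.random.default_rng(rng)
    t_total = n * dt
    # minimum waiting time well below the frame interval so the power-law
    # regime is reached within the observation window
    t0 = 0.05 * dt
    waits = []
    acc = 0.0
    while acc < t_total:
        w = t0 * (1.0 + rng.pareto(alpha))
        waits.append(w)
        acc += w
    times = np.cumsum(waits)
    jumps = rng.normal(scale=np.sqrt(2.0 * D * dt), size=(len(waits), 2))
    path = np.cumsum(jumps, axis=0)
    grid = np.arange(n) * dt
    idx = np.searchsorted(times, grid, side="right")
    pos = np.vstack([np.zeros(2), path])[idx]
    return Trajectory(pos - pos[0], dt=dt)


def simulate_lw(
    n: int,
    alpha: float,
    D: float = 1.0,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Levy walk: constant-speed flights with power-law durations.

    Flight-time tail exponent ``sigma_L = 3 - alpha`` for alpha in (1, 2)
    (sub-ballistic superdiffusion); alpha = 2 uses a ballistic-regime tail.
    """
    if not (1 <= alpha <= 2):
        raise ValueError("LW requires alpha in [1, 2]")
    rng = np.random.default_rng(rng)
    sigma_l = 0.5 if alpha >= 2 else 3.0 - alpha
    speed = np.sqrt(2.0 * D / dt)
    pos = np.zeros((n, 2))
    i = 1
    cur = np.zeros(2)
    while i < n:
        dur = max(1, int(round(rng.pareto(sigma_l) + 1.0)))
        theta = rng.uniform(0, 2 * np.pi)
        v = speed * np.array([np.cos(theta), np.sin(theta)])
        for _ in range(dur):
            if i >= n:
                break
            cur = cur + v * dt
            pos[i] = cur
            i += 1
    return Trajectory(pos, dt=dt)


# ---------------------------------------------------------------------------
# ATTM
# ---------------------------------------------------------------------------

def sample_attm_D(
    sigma: float,
    D_bounds: tuple[float, float],
    rng: np.random.Generator | None = None,
    size: int = 1,
) -> np.ndarray:
    """Draws from the truncated power-law density ``~ D^(sigma-1)`` on D_bounds.

    Inverse-CDF sampling: ``F^-1(u) = (Dmin^s + u (Dmax^s - Dmin^s))^(1/s)``.
    """
    rng = np.random.default_rng(rng)
    lo, hi = D_bounds
    u = rng.uniform(size=size)
    return (lo ** sigma + u * (hi ** sigma - lo ** sigma)) ** (1.0 / sigma)


def simulate_attm(
    config: ATTMConfig,
    rng: np.random.Generator | None = None,
    dt: float = 1.0,
    stationary: bool = True,
) -> tuple[Trajectory, GroundTruthProfile]:
    """One ATTM realization truncated at ``config.n_steps`` steps.

    Brownian segments; each segment's D is drawn from the power law and its
    dwell is ``tau = round(D^-gamma)`` steps (at least one).

    With ``stationary=True`` (default) the switching process is observed in
    its equilibrium state: the window opens at a random time of an ongoing
    process, so the first segment's D is drawn from the dwell-length-biased
    density (~ ``D^(sigma-gamma-1)``) and only its residual dwell is seen.
    This is the appropriate convention for benchmark data mimicking an
    experiment (and removes the fresh-start renewal transient, which would
    otherwise inflate the per-trajectory segment count by ~25%).

    With ``stationary=False`` the process starts at a renewal.  The anomalous
    ensemble-MSD scaling ``t^(sigma/gamma)`` is a property of this fresh
    (aging) ensemble measured from the process origin; the equilibrium
    ensemble instead shows effectively Brownian scaling.
    """
    rng = np.random.default_rng(rng)
    n = config.n_steps
    D_steps = np.empty(n)
    cps: list[int] = []
    pos = 0
    if stationary:
        # equilibrium first segment: length-biased D, uniform residual dwell
        s_biased = config.sigma - config.gamma
        if abs(s_biased) < 1e-9:
            lo, hi = config.D_bounds
            D = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            D = float(sample_attm_D(s_biased, config.D_bounds, rng, size=1)[0])
        tau = max(1, int(round(D ** -config.gamma)))
        residual = max(1, int(np.ceil(rng.uniform() * tau)))
        end = min(n, residual)
        D_steps[:end] = D
        pos = end
    while pos < n:
        D = float(sample_attm_D(config.sigma, config.D_bounds, rng, size=1)[0])
        tau = max(1, int(round(D ** -config.gamma)))
        end = min(n, pos + tau)
        D_steps[pos:end] = D
        if pos > 0:
            cps.append(pos)
        pos = end
    traj = simulate_piecewise_bm(D_steps, dt=dt, rng=rng)
    truth = GroundTruthProfile(
        D_true=D_steps,
        alpha_true=np.ones(n),
        model_tag=np.full(n, "ATTM"),
        changepoints=np.array(cps, dtype=int),
    )
    return traj, truth


# ---------------------------------------------------------------------------
# segment dispatch & composition
# ---------------------------------------------------------------------------

def _check_admissible(model_tag: str, alpha: float) -> None:
    if model_tag in SUBDIFFUSIVE_ONLY and alpha > 1:
        raise ValueError(f"{model_tag} is subdiffusive only (alpha <= 1), got {alpha}")
    if model_tag in SUPERDIFFUSIVE_ONLY and alpha < 1:
        raise ValueError(f"{model_tag} is superdiffusive only (alpha >= 1), got {alpha}")


def simulate_anomalous_segment(
    model_tag: str,
    n: int,
    alpha: float,
    D: float = 1.0,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """A single-model segment whose ensemble MSD exponent is ``alpha``."""
    _check_admissible(model_tag, alpha)
    rng = np.random.default_rng(rng)
    if model_tag == "BM" or (model_tag in ("fBm", "SBM") and abs(alpha - 1) < 1e-12):
        return simulate_piecewise_bm(np.full(n, D), dt=dt, rng=rng)
    if model_tag == "fBm":
        return simulate_fbm(n, alpha, D, dt, rng)
    if model_tag == "SBM":
        return simulate_sbm(n, alpha, D, dt, rng)
    if model_tag == "CTRW":
        return simulate_ctrw(n, alpha, D, dt, rng)
    if model_tag == "LW":
        return simulate_lw(n, alpha, D, dt, rng)
    if model_tag == "ATTM":
        # sigma/gamma = alpha with gamma = 1; Brownian limit at alpha = 1
        if abs(alpha - 1) < 1e-12:
            return simulate_piecewise_bm(np.full(n, D), dt=dt, rng=rng)
        cfg = ATTMConfig(sigma=alpha, gamma=1.0, D_bounds=(1e-3 * D, D), n_steps=n)
        # fresh start: the segment's anomalous scaling is an aging property
        return simulate_attm(cfg, rng, dt, stationary=False)[0]
    raise ValueError(f"unknown model tag {model_tag!r}")


@dataclass
class SegmentSpec:
    """One segment of a composed heterogeneous trajectory."""

    model_tag: str
    dwell: int
    alpha: float
    D: float


def compose_trajectory(
    segment_specs: list[SegmentSpec],
    n_steps: int,
    rng: np.random.Generator | None = None,
    dt: float = 1.0,
    unit_scale: bool = False,
) -> tuple[Trajectory, GroundTruthProfile]:
    """Concatenate segments with position continuity; clip at ``n_steps``.

    With ``unit_scale`` every segment's displacements are rescaled to unit
    RMS step before concatenation (the scale-free convention used for the
    alpha dataset, where amplitude carries no label information).
    """
    if not segment_specs:
        raise ValueError("segment_specs must be nonempty")
    rng = np.random.default_rng(rng)
    pieces: list[np.ndarray] = []  # displacement blocks
    D_lab: list[np.ndarray] = []
    a_lab: list[np.ndarray] = []
    m_lab: list[np.ndarray] = []
    cps: list[int] = []
    total = 0
    for spec in segment_specs:
        if total >= n_steps:
            break
        m = min(spec.dwell, n_steps - total)
        # simulate one extra position so the joining displacement belongs
        # to the new segment
        seg = simulate_anomalous_segment(spec.model_tag, m + 1, spec.alpha, spec.D, dt, rng)
        disp = seg.displacements()[:m]
        if unit_scale:
            rms = np.sqrt(np.mean(np.sum(disp ** 2, axis=1)))
            if rms > 0:
                disp = disp / rms
        if total > 0:
            cps.append(total)
        pieces.append(disp)
        D_lab.append(np.full(m, spec.D))
        a_lab.append(np.full(m, spec.alpha))
        m_lab.append(np.full(m, spec.model_tag))
        total += m
    disp_all = np.vstack(pieces)
    pos = np.vstack([np.zeros(2), np.cumsum(disp_all, axis=0)])[:total]
    traj = Trajectory(pos, dt=dt)
    truth = GroundTruthProfile(
        D_true=np.concatenate(D_lab)[:total],
        alpha_true=np.concatenate(a_lab)[:total],
        model_tag=np.concatenate(m_lab)[:total],
        changepoints=np.array([c for c in cps if c < total], dtype=int),
    )
    return traj, truth


def add_localization_noise(
    traj: Trajectory,
    noise_sigma: float,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Add i.i.d. zero-mean Gaussian offsets of SD ``noise_sigma`` per axis."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    if noise_sigma == 0:
        return Trajectory(traj.positions.copy(), dt=traj.dt, traj_id=traj.traj_id)
    rng = np.random.default_rng(rng)
    noisy = traj.positions + rng.normal(scale=noise_sigma, size=traj.positions.shape)
    return Trajectory(noisy, dt=traj.dt, traj_id=traj.traj_id)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _sample_segment_specs(config: PiecewiseConfig, rng: np.random.Generator) -> list[SegmentSpec]:
    specs: list[SegmentSpec] = []
    total = 0
    while total < config.n_steps:
        dwell = int(sample_dwell_times(1, config.dwell_bounds, config.dwell_mean, rng)[0])
        if config.target == "D":
            logD = rng.uniform(np.log10(config.D_range[0]), np.log10(config.D_range[1]))
            specs.append(SegmentSpec("BM", dwell, 1.0, 10.0 ** logD))
        else:
            model = str(rng.choice(config.model_set))
            lo, hi = config.alpha_range
            if model in SUBDIFFUSIVE_ONLY:
                hi = min(hi, 1.0)
            if model in SUPERDIFFUSIVE_ONLY:
                lo = max(lo, 1.0)
            if model == "fBm":
                hi = min(hi, 1.999)  # fBm needs alpha < 2 strictly
            alpha = rng.uniform(lo, hi)
            specs.append(SegmentSpec(model, dwell, float(alpha), 1.0))
        total += dwell
    return specs


def generate_single_cp_benchmark(
    kind: str,
    n_traj: int,
    n_steps: int = 200,
    rng: np.random.Generator | int | None = None,
    D_range: tuple[float, float] = (1e-3, 1e3),
    alpha_range: tuple[float, float] = (0.05, 2.0),
    cp_bounds: tuple[int, int] = (10, 190),
    noise_sigma: float = 0.0,
) -> list[tuple[Trajectory, GroundTruthProfile]]:
    """Changepoint-detection benchmark: one changepoint per trajectory.

    ``kind='D'``: Brownian motion with two independent log-uniform diffusion
    coefficients.  ``kind='alpha'``: fBm with two independent uniform
    anomalous exponents and unit-scaled segments (the property change is in
    the increment correlations, not the amplitude).  The changepoint position
    is uniform on the integers ``cp_bounds`` (matching the dwell-time
    truncation bounds, so no segment is shorter than the minimum dwell).
    """
    if kind not in ("D", "alpha"):
        raise ValueError("kind must be 'D' or 'alpha'")
    rng = np.random.default_rng(rng)
    out = []
    for i in range(n_traj):
        cp = int(rng.integers(cp_bounds[0], cp_bounds[1] + 1))
        if kind == "D":
            logD = rng.uniform(np.log10(D_range[0]), np.log10(D_range[1]), size=2)
            specs = [
                SegmentSpec("BM", cp, 1.0, 10.0 ** logD[0]),
                SegmentSpec("BM", n_steps - cp, 1.0, 10.0 ** logD[1]),
            ]
            traj, truth = compose_trajectory(specs, n_steps, rng)
        else:
            lo, hi = alpha_range
            alphas = rng.uniform(lo, min(hi, 1.999), size=2)
            specs = [
                SegmentSpec("fBm", cp, float(alphas[0]), 1.0),
                SegmentSpec("fBm", n_steps - cp, float(alphas[1]), 1.0),
            ]
            traj, truth = compose_trajectory(specs, n_steps, rng, unit_scale=True)
        traj = add_localization_noise(traj, noise_sigma, rng)
        traj.traj_id = i
        out.append((traj, truth))
    return out


def generate_dataset(
    config: PiecewiseConfig,
    n_traj: int,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[Trajectory, GroundTruthProfile]]:
    """Labeled trajectories with abrupt changes of D (target='D') or alpha.

    Reproducible under a fixed seed.  For the alpha target each segment is
    rescaled to unit RMS step (alpha is scale free); for the D target the
    raw Brownian amplitudes carry the label.
    """
    if rng is None:
        rng = config.seed
    rng = np.random.default_rng(rng)
    out = []
    for i in range(n_traj):
        specs = _sample_segment_specs(config, rng)
        traj, truth = compose_trajectory(
            specs, config.n_steps, rng, unit_scale=(config.target == "alpha")
        )
        sig = config.noise_sigma
        if isinstance(sig, (tuple, list)):
            sig = float(rng.uniform(sig[0], sig[1]))
        traj = add_localization_noise(traj, float(sig), rng)
        traj.traj_id = i
        out.append((traj, truth))
    return out
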