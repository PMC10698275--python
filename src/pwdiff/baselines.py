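"""Classical TA-MSD estimators of diffusion properties.

The time-averaged mean squared displacement of a trajectory r(t) at lag
``Delta`` is

    TA-MSD(Delta) = (1 / (n - Delta)) * sum_t || r(t + Delta) - r(t) ||^2 .

For 2D Brownian motion TA-MSD(Delta) = 4 * D * Delta * dt, so a linear fit of
the first lags estimates D (with an intercept absorbing the 4*sigma^2
localization-noise offset), while the slope of log TA-MSD vs log Delta
estimates the anomalous exponent alpha.  ``sliding_profile`` turns either fit
into a per-step estimate by restricting the time average to a centered
window, which is the classical comparator for pointwise inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import PointwiseProfile, Trajectory

__all__ = ["MSDCurve", "tamsd", "fit_D", "fit_alpha", "sliding_profile", "ensemble_msd"]


@dataclass
class MSDCurve:
    """TA-MSD values per lag, with the number of averaged pairs."""

    lags: np.ndarray
    msd: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.msd < 0) or np.any(np.diff(self.lags) <= 0) or self.lags[0] < 1:
            raise ValueError("invalid MSD curve")


def tamsd(traj: Trajectory, max_lag: int) -> MSDCurve:
    """Exact time-averaged MSD over all start points for lags 1..max_lag."""
    pos = traj.positions
    n = pos.shape[0]
    if not 1 <= max_lag < n:
        raise ValueError("max_lag must satisfy 1 <= max_lag < n")
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    counts = np.empty(max_lag, dtype=int)
    for i, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        msd[i] = np.mean(np.sum(d * d, axis=1))
        counts[i] = n - lag
    return MSDCurve(lags=lags, msd=msd, counts=counts)


def _fit_D_curve(lags: np.ndarray, msd: np.ndarray, dt: float, allow_offset: bool) -> float:
    x = 4.0 * lags * dt
    if allow_offset:
        if lags.size < 2:
            raise ValueError("offset fit needs at least 2 lags")
        A = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, msd, rcond=None)
        return float(coef[0])
    return float(np.dot(x, msd) / np.dot(x, x))


def fit_D(
    traj: Trajectory,
    fit_lags: tuple[int, int] = (1, 2),
    allow_offset: bool = False,
) -> float:
    """Least-squares TA-MSD estimate of D, in (length unit)^2 / (time unit).

    Fits ``TA-MSD(Delta) = 4 D Delta dt`` (through the origin by default)
    over the inclusive lag range ``fit_lags``.  With ``allow_offset`` an
    intercept absorbs the static localization-noise term ``4 sigma^2``.
    """
    lo, hi = fit_lags
    curve = tamsd(traj, hi)
    sel = slice(lo - 1, hi)
    return _fit_D_curve(curve.lags[sel], curve.msd[sel], traj.dt, allow_offset)


def fit_alpha(traj: Trajectory, fit_lags: tuple[int, int] = (1, 10)) -> float:
    """Anomalous exponent: slope of log TA-MSD vs log lag over ``fit_lags``."""
    lo, hi = fit_lags
    if hi - lo < 1:
        raise ValueError("alpha fit needs at least 2 lags")
    curve = tamsd(traj, hi)
    sel = slice(lo - 1, hi)
    msd = curve.msd[sel]
    if np.any(msd <= 0):
        raise ValueError("zero TA-MSD in fit range; alpha undefined")
    return float(np.polyfit(np.log(curve.lags[sel]), np.log(msd), 1)[0])


def _windowed_lag_means(sq: np.ndarray, n: int, lag: int, window: int) -> np.ndarray:
    """Mean of the lag-``lag`` squared displacements over a centered window.

    ``sq`` holds ||r(t+lag) - r(t)||^2 for t = 0..n-lag-1.  The window of
    steps centered at step t is [t - window//2, t + (window+1)//2); only
    displacement pairs fully inside it contribute.  Edge windows truncate.
    """
    half_lo = window // 2
    half_hi = (window + 1) // 2
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    t = np.arange(n)
    a = np.clip(t - half_lo, 0, None)
    b = np.clip(t + half_hi - lag, a, sq.size)
    cnt = b - a
    out = np.full(n, np.nan)
    ok = cnt > 0
    out[ok] = (csum[b[ok]] - csum[a[ok]]) / cnt[ok]
    return out


def sliding_profile(
    traj: Trajectory,
    window: int = 30,
    target: str = "alpha",
    fit_lags: tuple[int, int] | None = None,
) -> PointwiseProfile:
    """Per-step TA-MSD estimate from a centered sliding window.

    ``target='D'`` fits TA-MSD(Delta) = 4 D Delta dt through the origin over
    lags 1..2 by default and reports log10 D; ``target='alpha'`` fits the
    log-log slope over lags 1..max(2, window//4).  Windows are truncated at
    the trajectory edges (at least window//2 points remain); steps whose
    window cannot support the largest fit lag fall back to the nearest valid
    estimate.
    """
    if window < 5:
        raise ValueError("window < 5 gives unstable fits")
    n = traj.n
    if window > n:
        raise ValueError("window must not exceed the trajectory length")
    if fit_lags is None:
        fit_lags = (1, 2) if target == "D" else (1, max(2, window // 4))
    lo, hi = fit_lags
    pos = traj.positions
    lag_means = []
    for lag in range(lo, hi + 1):
        d = pos[lag:] - pos[:-lag]
        sq = np.sum(d * d, axis=1)
        lag_means.append(_windowed_lag_means(sq, n, lag, window))
    M = np.vstack(lag_means)  # (n_lags, n)
    lags = np.arange(lo, hi + 1, dtype=float)
    if target == "D":
        x = 4.0 * lags * traj.dt
        vals = np.einsum("l,ln->n", x, M) / np.dot(x, x)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.log10(np.clip(vals, 1e-300, None))
    elif target == "alpha":
        lx = np.log(lags)
        lx = lx - lx.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            ly = np.log(np.clip(M, 1e-300, None))
        vals = np.einsum("l,ln->n", lx, ly) / np.dot(lx, lx)
    else:
        raise ValueError("target must be 'D' or 'alpha'")
    # fill edge steps where the window cannot hold the largest lag
    bad = ~np.isfinite(vals)
    if bad.any():
        idx = np.where(~bad)[0]
        vals = np.interp(np.arange(n), idx, vals[idx])
    return PointwiseProfile(values=vals, target=target, traj_id=traj.traj_id)


def ensemble_msd(trajectories: list[Trajectory]) -> np.ndarray:
    """Ensemble MSD from the origin, averaged over trajectories.

    Returns an array indexed by lag (entry 0 is zero); trajectories must
    share a common length.
    """
    P = np.stack([t.positions for t in trajectories])
    d = P - P[:, :1, :]
    return np.mean(np.sum(d * d, axis=2), axis=0)
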