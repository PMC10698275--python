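"""Core containers for single-particle-tracking data.

A :class:`Trajectory` is an ordered sequence of 2D positions sampled on a
regular time grid with frame interval ``dt``.  Simulated trajectories carry a
:class:`GroundTruthProfile` with the per-step diffusion coefficient ``D``, the
per-step anomalous exponent ``alpha``, the generating-model tag, and the list
of changepoints (step indices where either property changes).

Conventions used throughout the package:

* step indices are 0-based;
* a changepoint at index ``k`` means step ``k`` is the first step of the new
  segment;
* segments are half-open intervals ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory", "GroundTruthProfile", "PointwiseProfile"]


@dataclass
class Trajectory:
    """Ordered 2D positions on a regular time grid.

    Parameters
    ----------
    positions : ndarray, shape (n, 2)
        x, y coordinates in arbitrary (but consistent) length units.
    dt : float
        Frame interval in time units (default 1).
    traj_id : int or str, optional
        Identifier used in tabular I/O.
    """

    positions: np.ndarray
    dt: float = 1.0
    traj_id: object = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if self.positions.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 positions")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n(self) -> int:
        """Number of recorded positions (steps)."""
        return self.positions.shape[0]

    def displacements(self) -> np.ndarray:
        """Per-frame displacement vectors, shape (n - 1, 2)."""
        return np.diff(self.positions, axis=0)


@dataclass
class GroundTruthProfile:
    """Per-step ground-truth labels attached to a simulated trajectory."""

    D_true: np.ndarray
    alpha_true: np.ndarray
    model_tag: np.ndarray
    changepoints: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.D_true = np.asarray(self.D_true, dtype=float)
        self.alpha_true = np.asarray(self.alpha_true, dtype=float)
        self.model_tag = np.asarray(self.model_tag)
        self.changepoints = np.asarray(self.changepoints, dtype=int)
        n = self.D_true.shape[0]
        if not (self.alpha_true.shape[0] == n and self.model_tag.shape[0] == n):
            raise ValueError("label arrays must have equal length")
        if np.any(self.D_true <= 0):
            raise ValueError("D_true must be positive")
        if np.any((self.alpha_true <= 0) | (self.alpha_true > 2)):
            raise ValueError("alpha_true must lie in (0, 2]")
        cps = self.changepoints
        if cps.size and (np.any(np.diff(cps) <= 0) or cps[0] <= 0 or cps[-1] >= n):
            raise ValueError("changepoints must be strictly increasing and in (0, n)")

    @property
    def n(self) -> int:
        return self.D_true.shape[0]

    def segment_bounds(self) -> list[tuple[int, int]]:
        """Half-open ``[start, end)`` bounds implied by the changepoints."""
        edges = np.concatenate(([0], self.changepoints, [self.n]))
        return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class PointwiseProfile:
    """Per-step estimate of one diffusion property.

    ``target`` is ``"D"`` (values on log10 scale) or ``"alpha"`` (linear).
    """

    values: np.ndarray
    target: str
    traj_id: object = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be 1-D")
        if self.target not in ("D", "alpha"):
            raise ValueError("target must be 'D' or 'alpha'")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def D_linear(self) -> np.ndarray:
        """Diffusion-coefficient profile on the linear scale."""
        if self.target != "D":
            raise ValueError("D_linear is only defined for target='D'")
        return 10.0 ** self.values
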