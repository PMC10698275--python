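"""The pointwise sequence regressor: conv stack + self-attention encoder.

The network translates a trajectory into the diffusion property of interest
at every time step.  Per-step displacement features pass through a stack of
residual 1D convolutions (local statistics), sinusoidal positional encodings
are added, a transformer encoder captures global correlations, and a
pointwise feedforward head maps each step to a scalar squashed into the
training label range (log10 D in [-3, 3], or alpha in [0.05, 2]).  All
convolutions are stride-1 with symmetric padding and attention is
full-sequence, so the output length always equals the input length and the
model applies to trajectories of any length (longer than ``max_length`` via
overlapping windows with averaged overlaps).

Implementation note: the forward pass squashes the displacement features
through asinh, which is linear near zero and logarithmic at large amplitude.
The diffusion coefficient spans six decades in training, and a log-like
compression keeps the conv stack's activations in a trainable range without
discarding the amplitude information that carries the D label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from ._autograd import Tensor, concat
from .trajectory import PointwiseProfile, Trajectory

__all__ = ["ModelConfig", "PointwiseModel", "featurize", "predict_pointwise"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the pointwise regressor."""

    target: str = "D"
    conv_blocks: int = 3
    conv_channels: int = 64
    kernel_size: int = 3
    encoder_layers: int = 4
    attention_heads: int = 8
    embed_dim: int = 128
    ff_mult: int = 2
    max_length: int = 2048
    output_range: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.target not in ("D", "alpha"):
            raise ValueError("target must be 'D' or 'alpha'")
        if min(self.conv_blocks, self.encoder_layers, self.attention_heads,
               self.embed_dim, self.kernel_size) < 1:
            raise ValueError("all architecture counts must be >= 1")
        if self.embed_dim % self.attention_heads:
            raise ValueError("embed_dim must be divisible by attention_heads")
        if self.output_range is None:
            self.output_range = (-3.0, 3.0) if self.target == "D" else (0.05, 2.0)
        self.output_range = tuple(self.output_range)


def featurize(traj: Trajectory, target: str) -> np.ndarray:
    """Per-step displacement features, shape (n, 2).

    The first step's displacement is zero-padded so the feature sequence has
    one vector per step (feature ``i`` is the displacement arriving at
    position ``i``).  Displacements make the representation translation
    invariant; for the scale-free alpha target the whole sequence is further
    divided by the global displacement SD, for D the raw scale is the signal.
    """
    if traj.n < 2:
        raise ValueError("need at least 2 positions to featurize")
    feats = np.zeros((traj.n, 2))
    feats[1:] = traj.displacements()
    if target == "alpha":
        sd = feats[1:].std()
        if sd > 0:
            feats = feats / sd
    return feats


def _sinusoidal_encoding(length: int, dim: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(dim // 2)[None, :]
    angle = pos / (10000.0 ** (2 * i / dim))
    enc = np.zeros((length, dim))
    enc[:, 0::2] = np.sin(angle)
    enc[:, 1::2] = np.cos(angle[:, : dim - dim // 2])
    return enc


def _conv1d(x: Tensor, W: Tensor, b: Tensor, kernel: int) -> Tensor:
    """Stride-1 same-length 1D convolution on a (B, L, C) tensor."""
    L = x.data.shape[1]
    left = kernel // 2
    xp = x.pad_axis1(left, kernel - 1 - left)
    cols = concat([xp.slice_axis1(i, i + L) for i in range(kernel)], axis=2)
    return cols @ W + b


class PointwiseModel:
    """Parameter container + forward pass.  Deterministic in evaluation."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | int | None = None):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(rng))

    # ------------------------------------------------------------------
    def _add(self, name: str, array: np.ndarray) -> None:
        self.params[name] = Tensor(array, requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        C, E, k = cfg.conv_channels, cfg.embed_dim, cfg.kernel_size

        def glorot(shape, fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        self._add("stem_W", glorot((k * 2, C), k * 2, C))
        self._add("stem_b", np.zeros(C))
        for i in range(cfg.conv_blocks):
            self._add(f"conv{i}_W1", glorot((k * C, C), k * C, C))
            self._add(f"conv{i}_b1", np.zeros(C))
            self._add(f"conv{i}_W2", glorot((k * C, C), k * C, C))
            self._add(f"conv{i}_b2", np.zeros(C))
        self._add("proj_W", glorot((C, E), C, E))
        self._add("proj_b", np.zeros(E))
        for i in range(cfg.encoder_layers):
            for nm in ("q", "k", "v", "o"):
                self._add(f"enc{i}_W{nm}", glorot((E, E), E, E))
                self._add(f"enc{i}_b{nm}", np.zeros(E))
            self._add(f"enc{i}_Wff1", glorot((E, cfg.ff_mult * E), E, cfg.ff_mult * E))
            self._add(f"enc{i}_bff1", np.zeros(cfg.ff_mult * E))
            self._add(f"enc{i}_Wff2", glorot((cfg.ff_mult * E, E), cfg.ff_mult * E, E))
            self._add(f"enc{i}_bff2", np.zeros(E))
        self._add("head_W1", glorot((E, E), E, E))
        self._add("head_b1", np.zeros(E))
        self._add("head_W2", glorot((E, 1), E, 1))
        self._add("head_b2", np.zeros(1))

    # ------------------------------------------------------------------
    def forward(self, features: np.ndarray | Tensor) -> Tensor:
        """Raw per-step outputs in ``output_range``; shape (B, L).

        ``features`` has shape (B, L, 2); sequences longer than
        ``max_length`` are rejected here (see :meth:`predict` for windowing).
        """
        cfg = self.config
        p = self.params
        x = features if isinstance(features, Tensor) else Tensor(features)
        if x.data.ndim != 3:
            raise ValueError("features must have shape (B, L, channels)")
        B, L, _ = x.data.shape
        if L > cfg.max_length:
            raise ValueError(f"sequence length {L} exceeds max_length {cfg.max_length}")
        k = cfg.kernel_size

        # asinh amplitude compression (fixed, not learned)
        xd = np.arcsinh(x.data)
        if x.requires_grad:
            base = x
            xcomp = Tensor._make(xd, (base,), lambda g: base._accum(g / np.sqrt(1 + base.data ** 2)))
        else:
            xcomp = Tensor(xd)

        h = _conv1d(xcomp, p["stem_W"], p["stem_b"], k).gelu()
        for i in range(cfg.conv_blocks):
            y = h.layernorm_lastaxis()
            y = _conv1d(y, p[f"conv{i}_W1"], p[f"conv{i}_b1"], k).gelu()
            y = _conv1d(y, p[f"conv{i}_W2"], p[f"conv{i}_b2"], k)
            h = h + y
        h = h @ p["proj_W"] + p["proj_b"]
        h = h + Tensor(_sinusoidal_encoding(L, cfg.embed_dim))

        E, H = cfg.embed_dim, cfg.attention_heads
        dh = E // H
        scale = 1.0 / np.sqrt(dh)
        for i in range(cfg.encoder_layers):
            y = h.layernorm_lastaxis()
            q = (y @ p[f"enc{i}_Wq"] + p[f"enc{i}_bq"]).reshape(B, L, H, dh).transpose(0, 2, 1, 3)
            kk = (y @ p[f"enc{i}_Wk"] + p[f"enc{i}_bk"]).reshape(B, L, H, dh).transpose(0, 2, 1, 3)
            v = (y @ p[f"enc{i}_Wv"] + p[f"enc{i}_bv"]).reshape(B, L, H, dh).transpose(0, 2, 1, 3)
            att = (q @ kk.transpose(0, 1, 3, 2) * scale).softmax_lastaxis()
            z = (att @ v).transpose(0, 2, 1, 3).reshape(B, L, E)
            h = h + (z @ p[f"enc{i}_Wo"] + p[f"enc{i}_bo"])
            y = h.layernorm_lastaxis()
            y = (y @ p[f"enc{i}_Wff1"] + p[f"enc{i}_bff1"]).gelu()
            h = h + (y @ p[f"enc{i}_Wff2"] + p[f"enc{i}_bff2"])

        y = h.layernorm_lastaxis()
        y = (y @ p["head_W1"] + p["head_b1"]).gelu()
        y = y @ p["head_W2"] + p["head_b2"]
        lo, hi = cfg.output_range
        out = y.sigmoid() * (hi - lo) + lo
        return out.reshape(B, L)

    # ------------------------------------------------------------------
    def predict(self, traj: Trajectory) -> PointwiseProfile:
        """Pointwise prediction for one trajectory of any length."""
        feats = featurize(traj, self.config.target)
        n, M = traj.n, self.config.max_length
        if n <= M:
            vals = self.forward(feats[None]).data[0]
        else:
            # overlapping windows (50% stride), averaged where they overlap
            acc = np.zeros(n)
            cnt = np.zeros(n)
            step = M // 2
            starts = list(range(0, n - M + 1, step))
            if starts[-1] != n - M:
                starts.append(n - M)
            for s in starts:
                acc[s:s + M] += self.forward(feats[None, s:s + M]).data[0]
                cnt[s:s + M] += 1
            vals = acc / cnt
        return PointwiseProfile(values=vals, target=self.config.target, traj_id=traj.traj_id)

    def predict_batch(self, trajectories: list[Trajectory], batch_size: int = 64) -> list[PointwiseProfile]:
        """Vectorized prediction for equal-length trajectories."""
        out: list[PointwiseProfile] = []
        for i in range(0, len(trajectories), batch_size):
            chunk = trajectories[i:i + batch_size]
            feats = np.stack([featurize(t, self.config.target) for t in chunk])
            vals = self.forward(feats).data
            out.extend(
                PointwiseProfile(values=v, target=self.config.target, traj_id=t.traj_id)
                for v, t in zip(vals, chunk)
            )
        return out

    # ------------------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = np.asarray(arrays[k], dtype=float).reshape(t.data.shape)

    def save(self, path) -> None:
        """Checkpoint: npz of parameters with an embedded config manifest."""
        np.savez(path, __config__=np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8),
            **self.state_arrays())

    @classmethod
    def load(cls, path) -> "PointwiseModel":
        with np.load(path) as data:
            cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
            model = cls(cfg, rng=0)
            model.load_state({k: data[k] for k in data.files if k != "__config__"})
        return model


def predict_pointwise(traj: Trajectory, model: PointwiseModel, target: str | None = None) -> PointwiseProfile:
    """Functional wrapper around :meth:`PointwiseModel.predict`."""
    if target is not None and target != model.config.target:
        raise ValueError(f"model predicts {model.config.target!r}, not {target!r}")
    return model.predict(traj)
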