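"""Losses and the training loop for the pointwise regressors.

Two independent models are trained, one per property: the D model on
piecewise Brownian trajectories with abrupt changes of the diffusion
coefficient (L1 loss on log10 D, matching the relative-error metric), and
the alpha model on multi-model anomalous segments with unit-scaled
amplitudes (L1 loss on alpha).  Training data are generated on the fly with
an epoch-indexed seed stream, so every epoch sees fresh simulations while
the run stays exactly reproducible; the validation set is frozen once per
run.  Optimization is Adam with a one-cycle schedule (linear warmup, cosine
decay) and the best-validation checkpoint is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor
from .pointwise_model import ModelConfig, PointwiseModel, featurize
from .sim_models import PiecewiseConfig, generate_dataset
from .trajectory import GroundTruthProfile, PointwiseProfile, Trajectory

__all__ = ["TrainConfig", "loss", "train_model"]


@dataclass
class TrainConfig:
    """Training hyperparameters; the target is taken from the model config."""

    data: PiecewiseConfig = field(default_factory=PiecewiseConfig)
    epochs: int = 10
    batch_size: int = 32
    trajectories_per_epoch: int = 1024
    n_validation: int = 256
    learning_rate: float = 3e-4
    warmup_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_validation < 1 or self.trajectories_per_epoch < 1:
            raise ValueError("dataset sizes must be positive")


def loss(pred: PointwiseProfile | np.ndarray, true: GroundTruthProfile | np.ndarray,
         target: str) -> float:
    """Scalar training loss between a prediction and the ground truth.

    ``target='D'``: mean |log10 D_pred - log10 D_true| (scale-shift
    invariant, the log-space analogue of the relative error).
    ``target='alpha'``: mean |alpha_pred - alpha_true|.
    """
    if isinstance(pred, PointwiseProfile):
        pred = pred.values if target == "D" else pred.values
    pred = np.asarray(pred, dtype=float)
    if isinstance(true, GroundTruthProfile):
        true_vals = np.log10(true.D_true) if target == "D" else true.alpha_true
    else:
        true_vals = np.asarray(true, dtype=float)
        if target == "D":
            true_vals = np.log10(true_vals)
    if pred.shape != true_vals.shape:
        raise ValueError("profile length mismatch")
    return float(np.mean(np.abs(pred - true_vals)))


def _labels(truth: GroundTruthProfile, target: str) -> np.ndarray:
    return np.log10(truth.D_true) if target == "D" else truth.alpha_true


def _dataset_arrays(data, target: str) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([featurize(t, target) for t, _ in data])
    Y = np.stack([_labels(g, target) for _, g in data])
    return X, Y


class _Adam:
    def __init__(self, params: dict[str, Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
            p.grad = None


def _one_cycle(step: int, total: int, lr_max: float, warmup_fraction: float) -> float:
    warm = max(1, int(total * warmup_fraction))
    if step < warm:
        return lr_max * (step + 1) / warm
    frac = (step - warm) / max(1, total - warm)
    return lr_max * 0.5 * (1 + np.cos(np.pi * frac))


def _eval_loss(model: PointwiseModel, X: np.ndarray, Y: np.ndarray, batch: int = 64) -> float:
    tot = 0.0
    for i in range(0, X.shape[0], batch):
        out = model.forward(X[i:i + batch]).data
        tot += np.abs(out - Y[i:i + batch]).sum()
    return tot / Y.size


def train_model(
    train_config: TrainConfig,
    model_config: ModelConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[PointwiseModel, list[dict]]:
    """Train a pointwise model; returns the best-validation checkpoint.

    ``rng`` seeds parameter initialization; the data stream is seeded from
    ``train_config.seed`` with one sub-seed per epoch, so identical configs
    reproduce identical histories.
    """
    cfg, mcfg = train_config, model_config
    target = mcfg.target
    model = PointwiseModel(mcfg, rng=rng if rng is not None else cfg.seed)
    opt = _Adam(model.params)

    seedseq = np.random.SeedSequence(cfg.seed)
    val_seed, *epoch_seeds = seedseq.spawn(cfg.epochs + 1)
    val_data = generate_dataset(cfg.data, cfg.n_validation, np.random.default_rng(val_seed))
    Xv, Yv = _dataset_arrays(val_data, target)

    total_steps = cfg.epochs * (cfg.trajectories_per_epoch // cfg.batch_size)
    history: list[dict] = []
    best = {"val_loss": np.inf, "state": model.state_arrays(), "epoch": -1}
    step = 0
    for epoch in range(cfg.epochs):
        data = generate_dataset(cfg.data, cfg.trajectories_per_epoch,
                                np.random.default_rng(epoch_seeds[epoch]))
        X, Y = _dataset_arrays(data, target)
        train_losses = []
        for i in range(0, X.shape[0] - cfg.batch_size + 1, cfg.batch_size):
            xb, yb = X[i:i + cfg.batch_size], Y[i:i + cfg.batch_size]
            out = model.forward(xb)
            l = (out - Tensor(yb)).abs().mean()
            if not np.isfinite(l.data):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, step {step}"
                )
            l.backward()
            opt.step(_one_cycle(step, total_steps, cfg.learning_rate, cfg.warmup_fraction))
            train_losses.append(float(l.data))
            step += 1
        val_loss = _eval_loss(model, Xv, Yv)
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(train_losses)),
            "val_loss": float(val_loss),
        })
        if val_loss < best["val_loss"]:
            best = {"val_loss": val_loss, "state": model.state_arrays(), "epoch": epoch}
    model.load_state(best["state"])
    return model, history
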