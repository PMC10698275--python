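# pwdiff — pointwise diffusion properties from single-particle trajectories

Single-particle tracking (SPT) follows individual molecules — membrane
receptors, viruses, organelles — frame by frame through a microscopy movie.
The physics of their motion is summarized by two numbers: the diffusion
coefficient *D* (per-axis displacement variance 2·D·Δt) and the anomalous
diffusion exponent *α* in MSD(t) ∼ t^α (α < 1 subdiffusion, α = 1 Brownian,
α > 1 superdiffusion).  In living cells neither is constant: receptors bind
and unbind, switch between free, confined and actively transported states,
and feel crowding gradients, so *D* and *α* change along a single trajectory
— sometimes abruptly, sometimes continuously.

`pwdiff` is a toolkit for characterizing such heterogeneous diffusion at the
single-time-step level.  Its core is a sequence-to-sequence neural regressor
(a stack of residual 1D convolutions, a transformer encoder, and a pointwise
feedforward head) that maps a trajectory of any length to a per-step estimate
of log₁₀ *D* or *α*.  Around it, the package provides everything needed to
train, benchmark and exploit such pointwise estimates:

- **Simulators** (`pwdiff.sim_models`): piecewise Brownian motion with
  abrupt *D* changes (log-uniform *D* ∈ [10⁻³, 10³], truncated-exponential
  dwells on [10, 190] steps with mean 57); multi-model anomalous segments
  (fBm, SBM, CTRW, Lévy walks, α ∈ [0.05, 2]); scaled Brownian motion with
  D(t) ∼ t^(α−1); the annealed transient-time model (ATTM: *D* redrawn from
  a density ∝ D^(σ−1), dwell τ = D^(−γ), ensemble exponent α = σ/γ);
  Gaussian localization noise.
- **Classical baselines** (`pwdiff.baselines`): time-averaged MSD curves,
  *D* and *α* fits, and centered sliding-window pointwise profiles.
- **Kernel changepoint detection** (`pwdiff.segmentation`): exact penalized
  segmentation with an RBF kernel (median-heuristic bandwidth) applied to
  pointwise profiles or raw displacement series, and conversion of
  changepoints into per-segment tables (dwell τ, mean *D*, mean *α*).
- **Metrics** (`pwdiff.metrics`): mean relative error for *D*, mean absolute
  error for *α*, the changepoint Jaccard index with position tolerance ε,
  and stratified benchmark curves.
- **Segment-level analysis** (`pwdiff.downstream`): truncated power-law MLE
  for the *D* distribution tail (σ), robust τ-vs-*D* regression (γ), k-means
  diffusive-state clustering with elbow selection and time-weighted
  occupancies, turning-angle distributions, confinement radii.
- **Training** (`pwdiff.training`): L1 losses on log₁₀ *D* / *α*, Adam with
  a one-cycle schedule, on-the-fly simulated data with an epoch-indexed seed
  stream, best-validation checkpointing.

Everything is implemented in numpy/scipy (the network runs on a small
built-in reverse-mode autograd), so the package has no GPU or deep-learning
framework dependency and is fully reproducible on a single CPU.

## Worked example

Detect diffusion-coefficient changepoints on a simulated benchmark and
recover the generating parameters of an annealed heterogeneous medium:

```python
import numpy as np
import pandas as pd
from pwdiff.sim_models import ATTMConfig, generate_single_cp_benchmark, simulate_attm
from pwdiff.segmentation import detect_changepoints, displacement_series
from pwdiff.metrics import jaccard_cps
from pwdiff.downstream import dwell_vs_D, fit_powerlaw_tail

rng = np.random.default_rng(0)

# 1. changepoint detection on a single-changepoint Brownian benchmark
data = generate_single_cp_benchmark("D", 500, rng=rng)
ji = np.mean([
    jaccard_cps(
        truth.changepoints,
        detect_changepoints(displacement_series(traj),
                            source="raw_displacements").positions,
        eps=5,
    )
    for traj, truth in data
])
print(f"KCPD on raw displacements, 500 trajectories: mean JI = {ji:.3f}")

# 2. ATTM parameter recovery from ground-truth segments
rows = []
for _ in range(500):
    _, truth = simulate_attm(ATTMConfig(sigma=0.3, gamma=0.4), rng)
    for a, b in truth.segment_bounds():
        rows.append({"mean_D": truth.D_true[a], "tau": float(b - a)})
segments = pd.DataFrame(rows)
sigma = fit_powerlaw_tail(segments["mean_D"].to_numpy(), (10 ** -6.7, 1.0))
gamma = dwell_vs_D(segments)
print(f"{len(segments)} ATTM segments: sigma = {sigma:.3f} (true 0.3), "
      f"gamma = {gamma:.3f} (true 0.4), alpha = sigma/gamma = {sigma/gamma:.2f}")
```

Output:

```
KCPD on raw displacements, 500 trajectories: mean JI = 0.819
9613 ATTM segments: sigma = 0.266 (true 0.3), gamma = 0.398 (true 0.4), alpha = sigma/gamma = 0.67
```

A Jaccard index of 0.82 (tolerance ε = 5 steps) means most single
changepoints between two random diffusivities are found within five frames
directly from the displacement series.  The segment-level fits recover the
generating power-law exponents of the heterogeneous medium: σ is slightly
underestimated because the equilibrium-aged first segment of each trajectory
is drawn from the dwell-biased distribution (see `docs/methods.md`).

A command-line interface mirrors the library:

```sh
pwdiff simulate -c sim.yaml --seed 1 --out data/
pwdiff train    -c train.yaml --seed 1 --out model/
pwdiff predict  --model model/model.npz --input data/trajectories.csv --out profiles.csv
pwdiff segment  --input data/trajectories.csv --profiles profiles.csv --out seg/
pwdiff evaluate --labels data/labels.csv --profiles profiles.csv \
                --changepoints seg/changepoints.json --target D --out report.json
pwdiff analyze  --segments seg/segments.csv --out analysis.json
```

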