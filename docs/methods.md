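# Methods

## The estimation problem

A 2D trajectory r(t) sampled at a fixed frame interval Δt is modeled as a
diffusion process whose parameters may vary along the track.  The package
estimates, at every time step, either the diffusion coefficient *D*
(reported as log₁₀ *D*; per-axis increment variance 2 D Δt) or the anomalous
exponent *α* (MSD ∼ t^α).  Pointwise estimates turn downstream questions —
where does the motion change, how long are the dwells, how many diffusive
states exist — into standard changepoint and clustering problems on a clean
1D or 2D signal instead of on the raw stochastic displacements.

## The pointwise regressor

The network maps a per-step feature sequence to a per-step scalar:

1. **Features.** Displacements (Δx, Δy), zero-padded at the first step so
   input and output lengths match.  Displacements make the representation
   translation invariant.  For the *α* model the sequence is divided by its
   global displacement SD: *α* is a scale-free property and removing
   amplitude prevents the network from keying on it.  For the *D* model the
   raw scale *is* the signal and is preserved.
2. **Amplitude compression.** The forward pass applies asinh to the
   features.  *D* spans six decades in training; asinh is linear near zero
   and logarithmic at large amplitude, which keeps activations in a
   trainable range without discarding the scale information that carries
   the *D* label.
3. **Convolutional stack.** A stem convolution to `conv_channels`, then
   `conv_blocks` pre-norm residual blocks (LayerNorm → conv → GELU → conv →
   add).  All convolutions are stride-1 with symmetric padding, so length
   is preserved.  These layers extract local statistics (local MSD-like
   amplitudes, short-range correlations).
4. **Transformer encoder.** Sinusoidal positional encodings, computed for
   the actual input length, are added after a linear projection to
   `embed_dim`; then `encoder_layers` pre-norm blocks of multi-head
   self-attention and a feedforward layer.  Full-sequence attention lets
   every step use the whole trajectory as context, which is what makes a
   per-step estimate of an asymptotic quantity like *α* possible at all.
5. **Head.** A pointwise two-layer feedforward map to one scalar per step,
   squashed by a scaled sigmoid onto the training label range
   ([−3, 3] for log₁₀ *D*, [0.05, 2] for *α*).  Range-limited outputs
   stabilize training and reproduce the saturation behavior expected of a
   regressor trained on a bounded label range.

Sequences longer than `max_length` (default 2048) are processed in
overlapping windows (50% stride) and the overlaps averaged.

The default architecture (3 conv blocks of 64 channels, kernel 3; 4 encoder
layers, 8 heads, embed 128) is sized for CPU training.  The tests and the
calibration experiments use a further reduced variant (2 blocks of 16
channels, 1 encoder layer, 4 heads, embed 32) that trains in about a minute
per run; with ~5k training trajectories it reaches a validation L1 of ≈0.6
on log₁₀ D (constant predictor: ≈1.5) and ≈0.29 on α over fBm segments
(constant predictor: ≈0.49).  Accuracy improves substantially with more
epochs, data and width; the package deliberately reports only what its own
desk-scale runs produce.

The network and its training loop run on a small reverse-mode autograd
written on numpy (float64 throughout).  Gradients are verified against
finite differences in the test suite.  There is no dropout and no other
stochastic layer, so evaluation is exactly deterministic.

**Training.**  L1 loss on log₁₀ *D* (scale-shift invariant, the log-space
analogue of relative error) or on *α*.  Adam with a one-cycle schedule
(30% linear warmup, cosine decay).  Each epoch simulates a fresh dataset
from an epoch-indexed seed stream — effectively unlimited training data
with flat memory — while a validation set frozen at the start of the run
selects the returned checkpoint.  A non-finite loss aborts with a
diagnostic.  The *D* model trains on piecewise Brownian data only; the *α*
model on unit-scaled anomalous segments.

## Simulators

All generators are 2D, operate on a regular Δt grid with 0-based step
indices, and attach per-step ground truth (D, α, model tag, changepoints).
A changepoint at index k means step k — i.e. the displacement arriving at
position k — is the first step governed by the new parameters.  Segments
are half-open [start, end).

- **Dwell times** between abrupt changes: exponential truncated to
  [10, 190] steps with mean 57.  The rate is calibrated by root finding on
  the closed-form truncated-exponential mean (the truncation bounds and
  mean pin down the rate uniquely; feasible means lie strictly between the
  lower bound and the interval midpoint).
- **Piecewise Brownian motion**: independent Gaussian increments with
  per-step variance 2 D(t) Δt; per-segment D log-uniform on [10⁻³, 10³].
- **fBm**: exact fractional Gaussian noise by Davies–Harte circulant
  embedding (Cholesky fallback if the embedding is indefinite), Hurst
  H = α/2, scaled so the 2D ensemble MSD is 4 D t^α.  Exactness matters
  because several tests compare lag autocovariances to the closed form.
- **SBM**: independent Gaussian increments with variance
  2 D₀ (t^α − (t−Δt)^α) per axis, i.e. D(t) ∝ t^(α−1) with the exact
  ensemble MSD 4 D₀ t^α.
- **CTRW**: Pareto waiting times with tail exponent 1 + α and instantaneous
  Gaussian jumps, sampled on the frame grid.  The minimum waiting time is
  set to 0.05 Δt so the power-law MSD regime is reached within a ~200-frame
  window; with a minimum of one full frame the finite-time ensemble MSD
  slope at α = 0.5 is biased up to ≈0.59.
- **Lévy walk**: constant-speed flights with Pareto durations (tail
  exponent 3 − α for 1 < α < 2), random directions.
- **ATTM**: Brownian segments whose D is drawn from a truncated power law
  ∝ D^(σ−1) on (10^−6.7, 1) by inverse-CDF sampling, with deterministic
  dwell τ = round(D^(−γ)) steps (unit proportionality constant).  For
  σ = 0.3, γ = 0.4 this gives E[τ] ≈ 11.1 steps and therefore ≈ 18
  switches per 200-step trajectory.
- **Localization noise**: i.i.d. Gaussian position offsets; training draws
  the SD uniformly from [0, 0.5] (in the units of the unit-scaled or raw
  segments).  This adds the classic 4σ² offset to the TA-MSD and a negative
  lag-1 displacement correlation, both covered by tests.

**ATTM initialization.**  Two observables of the same model require
different time origins.  The mean number of segments seen in a finite
window is a property of an *ongoing* (equilibrium) switching process:
benchmark trajectories therefore start in the stationary state, with the
first segment's D drawn from the dwell-length-biased density
∝ D^(σ−γ−1) and a uniform residual dwell.  A fresh-start (renewal-origin)
process would inflate the count by the renewal transient — about 23.5
instead of ≈ 19 segments per 200 steps for the default parameters.  The
anomalous ensemble-MSD scaling t^(σ/γ), in contrast, is an aging property
defined from the process origin and is measured on fresh-start ensembles
(`stationary=False`); the equilibrium ensemble scales linearly.  One
consequence: the per-segment D values of stationary benchmark data contain
one dwell-biased draw per trajectory (~5% of segments), which biases the
pooled tail-exponent estimate slightly below σ (≈0.27 for σ = 0.3).

**Composition.**  Heterogeneous trajectories are concatenations of
single-model segments with position continuity (each segment contributes
its increments, including the joining displacement, which belongs to the
new segment).  For the α dataset every segment is rescaled to unit RMS step
before concatenation, because α carries no amplitude information and the α
model must not be able to exploit scale discontinuities.

**What the generators do not emulate:** photophysics (blinking, motion
blur), drift, frame-to-frame exposure averaging, variable localization
precision, 1D/3D motion, and state-dependent localization error.  Passing
benchmarks on these simulations therefore demonstrates the method's
statistical machinery, not robustness to every experimental artifact.

## Classical baselines

TA-MSD(Δ) = (1/(n−Δ)) Σ_t ‖r(t+Δ) − r(t)‖², computed exactly over all start
points.  D is fitted as TA-MSD = 4 D Δ Δt through the origin over lags 1–2
(near-optimal for Brownian paths); under noise an intercept absorbing 4σ²
can be enabled.  α is the log-log slope over a lag range.  The sliding
profile evaluates either fit in a window centered at each step (windows
truncate at the edges, keeping at least half a window; steps whose window
cannot hold the largest fit lag take the nearest valid estimate).  Centered
rather than causal windows were chosen so the profile's response to a
changepoint is symmetric, which localizes detected changes at the true
position instead of half a window late.  Default fit lags: 1–2 for D,
1–max(2, window/4) for α.

## Kernel changepoint detection

The segmentation cost of a partition is Σ_segments [(b−a) −
(1/(b−a)) Σ_{s,t∈[a,b)} K(x_s, x_t)] with an RBF kernel whose bandwidth
follows the median heuristic (γ = 1 / median pairwise squared distance),
plus a linear penalty per segment.  The exact optimum is found by dynamic
programming over all admissible segmentations (O(n²) with precomputed Gram
prefix sums; minimum segment length 3).  A constant series has zero cost
for every split, so the penalty yields the empty changepoint set.
Increasing the penalty can never increase the number of changepoints.

**Penalty calibration.**  The penalty is the one free parameter.  It is
calibrated per *task* on simulated 200-step single-changepoint benchmarks
and frozen in `DEFAULT_PENALTIES`:

- *D task* (penalty 3.0): maximizes the mean Jaccard index (tolerance
  ε = 5) of detection on raw two-channel displacement series over a
  single-changepoint Brownian benchmark with two log-uniform D values.
- *α task* (penalty 7.0): maximizes the mean JI (ε = 20) of detection on
  the *pointwise model's own α profiles* over a single-changepoint fBm
  benchmark (1000 trajectories; scaled-down α model).  The same penalty is
  applied to every series in the α task — including the sliding-TA-MSD
  baseline profile — because comparing detectors that were each tuned on
  their own input would measure the tuning, not the input quality.  A
  penalty tuned directly on the baseline profile would roughly double the
  baseline's JI (≈0.59 at its own optimum) while saying nothing about how
  informative the profile is at a fixed operating point.

The Jaccard index matches predicted to true changepoints greedily by
increasing distance (ties to the earlier true index), one-to-one;
JI = TP/(TP+FP+FN), and two empty sets give 1.  Reported benchmark JIs are
per-trajectory means.

Joint segmentation on (log₁₀ D, α) stacks the standardized channels so the
kernel sees comparable scales.  Per-segment D is averaged in log space and
reported linear.

## Downstream analysis

- **σ (D-distribution tail).**  Maximum-likelihood exponent of a truncated
  power law (density ∝ D^(σ−1) on given bounds), solved by root finding on
  the score equation; invariant under joint rescaling of values and bounds.
- **γ (dwell coupling).**  Theil–Sen slope of log τ vs log D, reported as
  γ = −slope.  The median-based slope is insensitive to the secondary
  2·D^(−γ) band produced when a changepoint between two similar-D segments
  is missed and their dwells merge.
- **State clustering.**  k-means on standardized (log₁₀ D, α) features; k
  is selected at the maximum-curvature elbow of the dispersion curve,
  computed on *log* inertia: diffusive states are often separated on very
  different scales (an immobile state sits decades below the mobile ones in
  D), and relative curvature finds the elbow of the full hierarchy where
  absolute curvature sees only the single largest split.  Occupancies are
  dwell-time weighted.  The 4-state synthetic mixture (immobile, confined,
  Brownian, directed) used in tests places Gaussian blobs at
  (log₁₀ D, α) = (−5, 0.25), (−1.2, 0.45), (−1, 0.9), (−0.85, 1.3) with
  within-state SDs of ≈0.2 in log₁₀ D and ≈0.07 in α and gamma-distributed
  dwells — spreads chosen to mimic clearly separated receptor states.
- **Turning angles** between consecutive displacements (0° persistence,
  180° reversal; zero steps skipped) and the **confinement radius**, defined
  here as the radius of gyration about the segment centroid (a simple,
  estimator-stable choice; any alternative definition can be swapped in at
  the call site).

## Problem sizes and reproducibility

The benchmark recomputation (`scripts/acceptance.py`) uses 2000
trajectories per changepoint benchmark, 10⁴ ATTM realizations, and 3000
SBM trajectories of 400 steps per ensemble — the published benchmark
scales — and finishes in well under a minute on one CPU.  The test suite
runs reduced ensembles (typically 300–3000 trajectories) with tolerances
widened to the corresponding Monte-Carlo error, and trains the reduced
architecture for a handful of epochs; the full suite completes in a few
minutes.  Every stochastic component takes an explicit seed or Generator;
dataset generation, training histories and CLI outputs are bit-reproducible
under a fixed seed.

## Known limitations

- The shipped default architecture is CPU-sized; at this scale pointwise
  accuracy is meaningfully below what a fully trained large model reaches,
  so the network-dependent headline benchmarks are checked as properties
  (beats the constant predictor; error grows on short segments) rather
  than as absolute numbers.
- The α model's training set mixes generating models with disjoint α
  supports (CTRW/ATTM subdiffusive, LW superdiffusive), which induces the
  well-known prediction discontinuity around α ≈ 1.
- KCPD is offline and quadratic in the trajectory length; very long tracks
  (≫10⁴ steps) should be windowed.
- The sliding-window baseline cannot resolve segments shorter than about
  half its window; ATTM-like data with many 1–5-step dwells require the
  pointwise model (or ground-truth segmentation) for faithful σ and γ
  recovery.
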