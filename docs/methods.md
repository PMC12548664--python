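# Methods

This note documents the models, numerical choices, and open design decisions
behind `dfcshapley`, in the order the pipeline runs.

## Synthetic data: a latent-state covariance block model

The generator (`syndata`) emulates the structure of a narrative-fMRI study:
31 subjects × 16 runs by default, 100 ROIs grouped into 7 contiguous
subnetworks (14–15 ROIs each), TR = 1.5 s, balanced 2×2 labels
(modality ∈ {audio, movie} × content ∈ {airport, restaurant}), with each
subject seeing 4 runs per label cell. Run length defaults to 125 samples
(187.5 s): with 30 s windows and 7.5 s overlap this yields exactly 8
windows per run, matching the windows-per-story count the pipeline's
defaults are sized for. (At a literal 180 s the same plan yields 7 windows;
the window count is always computed from the data, never hard-coded.)

Each run concatenates `n_states = 4` equal-length latent-state segments
(remainder absorbed by the last; boundaries optionally snapped to a sample
grid via `segment_align_samples` so each analysis window is dominated by
one state). Segment `s` of a run with labels (m, c) is drawn from a
zero-mean multivariate normal with covariance

    Σ_{m,c,s} = I + 0.1·(J − I) + Δ_modality(m) + Δ_content(c, s)

* **Baseline**: unit variance, uniform off-diagonal correlation 0.1 —
  small enough to keep matrices well-conditioned at R = 100, large enough
  that "connectivity" is nonzero everywhere.
* **Modality** adds ±ε_mod to all off-diagonal entries inside the declared
  modality-effect subnetwork blocks, sign set by the label, identically in
  every state: modality is decodable from any single window.
* **Content** adds ε_con inside *one* content-effect block per state; which
  block receives it cycles through the declared blocks, and content label 1
  starts the cycle one step later than label 0. Both labels therefore see
  the same multiset of state covariances in a different order: content is
  decodable only from the window *sequence* (provided `n_states` is a
  multiple of the cycle length; a warning is raised otherwise). With a
  single content block the cycle alternates increment-on/increment-off.

Draws are AR(1)-smoothed (`x_t = φ x_{t−1} + √(1−φ²) e_t`, φ = 0.4 by
default; the scaling keeps the stationary covariance equal to Σ), and white
observation noise (sd 0.5) is added. With φ = 0 and no noise each segment
is an i.i.d. sample from Σ, which is what the sample-covariance oracle
tests exploit.

**Positive definiteness.** The uniform background has a large bulk
eigenvalue along the all-ones direction; a block whose within-block
covariance b falls below roughly (m·c − 1)/(m − 1) (block size m,
background c) sends a block-contrast eigenvalue negative. For c = 0.1 and
m = 15 this caps the label-signed modality increment at about 0.06, hence
the study-scale default ε_mod = 0.05. Content increments are one-sided
(positive) and unconstrained in practice (default 0.3). If a configuration
does exceed the cone, the construction shrinks the increments by the
largest feasible factor (40-step bisection) and warns with that factor.

Per-run randomness derives from `SeedSequence([seed, subject, narrative])`,
so datasets are reproducible run-by-run and byte-identical across rebuilds.

**What the generator does not emulate**: hemodynamic response convolution,
1/f noise spectra, subject-specific connectomes, scanner drift, head
motion, or spatial autocorrelation between neighbouring parcels. Passing
tests on this generator demonstrates that the pipeline recovers the kinds
of structure it assumes — block-covariance class differences and
state-order codes — not that real fMRI contains them.

## Network construction

Nuisance regression is per-ROI OLS against `[intercept | regressors]`
(collinear columns dropped with a warning); the band-pass is a zero-phase
(forward–backward) order-4 Butterworth, default 0.01–0.08 Hz. Synthetic
runs are generated band-limited-by-construction and are not re-filtered by
default (`apply_bandpass=False`); the filter is there for real recordings.

Windows: step = window − overlap, trailing partial windows discarded.
Pearson correlation per window; the result is symmetrized exactly
(0.5·(C + Cᵀ) — BLAS output is not bit-symmetric) and clipped to [−1, 1].
The diagonal is zeroed: self-correlation is constant 1 with zero variance
across samples, which would otherwise divide by zero during normalization.
A zero-variance ROI inside a window yields zero correlations plus a
warning rather than an abort, so degenerate inputs flow through.

Z-normalization is **per edge across the training pool** (all training
samples and windows, population sd). This is the scope under which 0 maps
to the per-edge mean — the property that justifies zero-masking in the
attribution stage. Per-matrix scaling would not have that property; a
global-scalar mode exists behind `fit_normalizer(..., scope="global")`.
Edges constant in the pool pass through as 0 with a warning. By default the
normalizer is refitted inside every training repetition on that
repetition's training split (strict leakage avoidance);
`fit_normalizer_globally=True` reproduces the simpler fit-once-on-everything
protocol, and the report records which mode ran.

## Classifier

Architecture as in the README: R×R×τ×C temporal-filter convolution, ReLU,
global max-pool over the K = T − τ + 1 positions, MLP C → 64 → 32 →
n_classes with ReLU between layers and raw logits out. τ defaults to 4 for
the modality task and 8 for content and combined; C = 128; loss is softmax
cross-entropy on logits (2 or 4 classes).

* **Bias shape.** The convolution bias is per-channel, broadcast over
  temporal positions. A per-position bias b[k, c] would break the τ = 1
  order-invariance property outright; it is available via
  `ModelConfig.per_position_bias` for sensitivity experiments.
* **Bit-exact τ = 1 invariance.** Each temporal position's projection is
  computed by an independent vector–matrix product: batched GEMM kernels
  are alignment-sensitive in the last ulp, which would reduce "invariant"
  to "equal within 1e-16". With per-position GEMVs, permuting windows
  permutes rows of identical bit patterns and the max-pool result is
  bit-identical. K is at most a dozen, so the cost is negligible.
* **Training.** Batch size 1, Adam (lr 1e-4, β = 0.9/0.999, ε = 1e-8),
  20 epochs, per-epoch reshuffling from the training seed, final-epoch
  weights, no early stopping, weight decay, or schedule. Initialization is
  fan-in-scaled uniform U(±1/√fan_in). The implementation is plain numpy
  with hand-written backprop (max-pool routes the gradient to the argmax
  position; ReLU masks on pre-activations), deterministic given the seed.
* **Protocol.** `run_repetitions` draws n (default 15) independent
  stratified 80/20 sample-level splits (`StratifiedShuffleSplit`), trains
  one model per split, and reports accuracy plus macro-averaged
  precision/recall/F1 as mean ± sd. Macro averaging is the natural choice
  for a balanced design (macro ≈ micro there) and stays defined on
  unbalanced synthetic sets; classes absent from a test set are excluded
  from the macro with a warning. Argmax ties resolve to the lowest class
  index. Splits are sample-level by design (subjects can appear on both
  sides); the split indices are recorded for reuse by the attribution.

## Shapley attribution

The characteristic function v(S) is the accuracy of the repetition's
*fully trained* model on its *own* test split with every ROI outside S
masked (rows and columns zeroed in every window of the Z-normalized
tensor). Retraining for each coalition would multiply training cost by
2^|N| per repetition; a `retrain_per_coalition` flag exists for sensitivity
analysis. v(∅) is the measured accuracy on the all-zero tensor — a
constant prediction, not an assumed chance level — and efficiency
(Σφ = v(N) − v(∅)) is reported against it.

Exact computation enumerates all 2^|N| coalitions with a bitmask-keyed
cache (guarded at |N| ≤ 20; 7 players = 128 evaluations). The sampled
estimator draws uniform random player orderings and accumulates
v(pred ∪ {i}) − v(pred) for every player per ordering — the standard
Monte-Carlo permutation estimator, unbiased, zero-variance on additive
games, sharing the coalition cache across orderings (17 players at 100
orderings costs at most 1 + 17·100 evaluations before deduplication). Both
routes are tested against an independent all-orderings oracle. Per-ROI
attribution is the same machinery with each ROI its own player.

Aggregation: φ is computed inside each training repetition and reported
mean ± sd across repetitions, alongside per-repetition efficiency gaps.

## Controls

* `shuffle_series`: permutes raw time points before any network is built.
  Default mode draws an independent permutation per ROI, destroying
  inter-ROI correlation itself — the correct null for "is there any usable
  connectivity signal", and the mode consistent with chance-level outcomes.
  The `common_across_rois` mode applies one shared permutation, which
  preserves whole-run correlations exactly and destroys order only.
* `shuffle_windows`: permutes tensor slices along time; every slice stays
  bit-identical (a block permutation).
* `static_fc`: one whole-run correlation matrix, T = 1, classifier runs
  with τ = 1.

Controls are redrawn fresh in every training repetition, so the reported sd
includes permutation variability; control seeds derive from the
`ControlSpec` seed, independent of training seeds.

## Orchestration and seeding

A single master seed fans out via `SeedSequence.spawn` to four stage seeds
(simulation, training, attribution, controls); training spawns one seed per
repetition (split seed + per-repetition init/shuffle seeds). Every derived
seed is reduced below 2^31. Two runs from one master seed agree on every
recorded number. Built tensors can be cached in HDF5 keyed by a hash of the
upstream (simulation + window) configuration; changing any upstream field
changes the key.

## Desk-scale experiment presets (`experiments.py`)

Study-scale training (R = 100, C = 128, 15 repetitions, 496 runs) is hours
of CPU; the shipped presets shrink the *problem size* while keeping every
stage of the protocol intact, and state their choices explicitly:

* **Recovery** (R = 50, five 10-ROI subnetworks, 16 subjects × 8 runs,
  ε_mod = 0.09 in subnetwork 2, C = 16, 10 epochs, 3 repetitions): across
  10 master seeds the planted subnetwork should take the top mean φ. The
  effect is set high within the PD-feasible range (ε ≤ 0.1 at these block
  sizes) because the experiment tests attribution, not detection
  sensitivity.
* **Directionality** (R = 30, five 6-ROI subnetworks, 12 subjects × 8 runs,
  order-coded content ε_con = 0.35, static-coded modality ε_mod = 0.17,
  C = 16, 20 epochs, 2 repetitions): window shuffling should hurt content
  far more than modality, per-ROI series shuffling should land in the
  binomial chance band, and static FC should be above chance without
  beating the dynamic pipeline. The modality effect is chosen to saturate
  the modality task: whole-run correlation is a lower-variance estimator
  than 20-sample windowed correlation, so with a weak static-coded effect
  static FC can legitimately *exceed* the dynamic pipeline; at saturation
  the comparison reflects information content rather than estimator noise.

## Known limitations

* The numpy training loop is single-threaded per sample; study-scale
  configurations are possible but slow (no GPU path).
* The generator's content code is a global state-order permutation; it does
  not model graded or event-aligned content structure.
* Subject identity contributes no variance in the generator, so the
  sample-level vs subject-level split distinction (both implemented) has no
  bite on synthetic data.
* Sampled Shapley standard errors assume independent orderings; with a
  shared cache the estimates are exact reuses, not fresh draws, which is
  conservative for the error bars.
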