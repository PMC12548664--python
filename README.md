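# dfcshapley

Which brain subnetworks carry the information a classifier uses when it
decodes properties of a narrative stimulus from functional MRI?
`dfcshapley` is a reusable, fully seeded pipeline for answering that
question with **dynamic functional connectivity**, a **temporal-filter
convolutional classifier**, and **Shapley-value attribution** over
subnetwork coalitions — together with the permutation and
static-connectivity controls needed to interpret the result.

It is aimed at network-neuroscience researchers who have per-region BOLD
time series (e.g. Schaefer-100 parcel averages grouped into Yeo-style
subnetworks) and want a tested implementation of this analysis, plus a
synthetic-data generator with *planted, subnetwork-localized* class effects
so every stage can be validated offline against known ground truth.

## The method

1. **Temporal brain networks.** Each run's R×L ROI signal matrix is cleaned
   (optional nuisance regression, zero-phase 0.01–0.08 Hz band-pass) and
   converted to a tensor X ∈ [−1, 1]^{R×R×T}: Pearson correlation between
   every ROI pair inside sliding windows (default 30 s windows, 7.5 s
   overlap at TR = 1.5 s). Matrices are Z-normalized per edge against the
   training pool, so 0 becomes the per-edge mean.

2. **Classifier.** A single convolutional layer whose filter spans all R×R
   region pairs and slides only along time,

       Y[k,c] = ReLU( Σ_{i,j,p} X[i,j,k+p−1] · W[i,j,p,c] + b[c] ),   K = T − τ + 1,

   followed by global max-pooling Z[c] = max_k Y[k,c] and an MLP
   C → 64 → 32 → n_classes. With τ = 1 the model is provably (and here,
   bit-exactly) invariant to window order; with τ > 1 it can exploit
   temporal structure. Training: Adam (lr 1e-4), batch size 1, 20 epochs,
   repeated over 15 stratified 80/20 splits, metrics reported mean ± sd.

3. **Attribution.** Subnetworks are players of a cooperative game whose
   characteristic function v(S) is the trained model's test accuracy when
   every ROI outside coalition S is masked to zero (the per-edge mean).
   The Shapley value

       φ_i(v) = Σ_{S ⊆ N∖{i}} |S|!(|N|−|S|−1)!/|N|! · (v(S∪{i}) − v(S))

   is computed exactly (all 2^|N| coalitions, cached) for small player sets
   and by permutation sampling (default 100 orderings) for large ones.

4. **Controls.** Window shuffling (destroys order, keeps windows), per-ROI
   time-series shuffling (destroys connectivity itself), and a static
   whole-run connectivity baseline (T = 1, τ = 1).

The synthetic generator plants class effects in a latent-state covariance
block model: modality shifts within-subnetwork covariance in every state
(decodable from any single window), while content permutes the *order* of
states (decodable only from the window sequence) — so the controls have a
known correct outcome.

## Worked example

```python
from dfcshapley import (ControlSpec, ExperimentConfig, SimConfig, TrainConfig,
                        run_pipeline, summarize)

sim = SimConfig(n_subjects=8, n_narratives_per_subject=8, n_rois=20,
                n_timepoints=125, subnetwork_sizes=(4, 4, 4, 4, 4),
                modality_effect_subnets=(1,), content_effect_subnets=(2, 4),
                modality_effect_size=0.15, content_effect_size=0.35)
config = ExperimentConfig(
    task="modality", sim=sim, channels=16,
    train=TrainConfig(epochs=15, n_repetitions=3),
    controls=(ControlSpec("shuffle_windows"), ControlSpec("static_fc")),
    master_seed=0)
report = run_pipeline(config)
print(summarize(report))
```

prints

```
dfcshapley 0.1.0 — task: modality
metric                                 mean       sd
accuracy                             0.8462   0.1088
precision                            0.8694   0.0953
recall                               0.8492   0.1071
f1                                   0.8424   0.1114
accuracy [shuffle_windows]           0.9231   0.0628
accuracy [static_fc]                 0.7949   0.0725

Shapley values (exact) per subnetwork:
  subnetwork 0        -0.0410 ± 0.0336
  subnetwork 1        +0.5017 ± 0.0379
  subnetwork 2        -0.0004 ± 0.0456
  subnetwork 3        -0.0090 ± 0.0347
  subnetwork 4        -0.0667 ± 0.0155
```

Reading it: the modality classifier reaches 85% test accuracy (mean over 3
retrainings). Because this dataset codes modality *statically* (the same
covariance shift in every window), shuffling windows costs nothing and
static connectivity alone still decodes it — the temporal controls behave
exactly as the construction dictates. The attribution finds subnetwork 1,
the one the generator planted the modality effect in: removing it from a
coalition costs on average ≈ 0.50 accuracy, while the other four
subnetworks hover at zero. The φ values sum to v(N) − v(∅) (efficiency) by
construction of the exact method.

A CLI wraps the same machinery: `dfcshapley show-config`,
`dfcshapley simulate --out data/`, and
`dfcshapley run --config cfg.yaml --seed 0 --out report.json`.

## Real data

`run_pipeline` accepts externally prepared data through the same readers it
uses for its own output: one tab-separated R×L matrix per run with a JSON
sidecar (`tr`, subject, narrative, labels), plus a two-column parcellation
table (`roi_id`, `subnetwork_label`). Point `ExperimentConfig.data_dir` at
such a directory. Voxel-level preprocessing (registration, atlas
projection, motion-parameter estimation) is out of scope; motion regressors
are consumed, never estimated.

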