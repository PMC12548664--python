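"""Seeded synthetic BOLD-like datasets with planted, subnetwork-local effects.

The generator emulates the structure of a narrative-fMRI experiment: a cohort
of subjects, each with a fixed number of ~3-minute runs sampled at TR = 1.5 s,
100 ROIs grouped into contiguous subnetworks, and a balanced 2x2 label design
(modality in {audio, movie} x content in {airport, restaurant}).

Class information is planted through a latent-state covariance block model:

* Each run is a concatenation of ``n_states`` segments; segment ``s`` is drawn
  from a zero-mean multivariate normal with a state- and label-specific
  covariance, then AR(1)-smoothed in time, plus white observation noise.
* The **modality** label shifts the within-block covariance of the declared
  modality-effect subnetworks by +eps (modality 1) or -eps (modality 0) in
  every state — so modality is decodable from any single window.
* The **content** label controls the *order* in which content-effect
  subnetwork blocks receive their covariance increment across states (the
  same multiset of state covariances, cyclically shifted) — so content is
  decodable only from the sequence of windows, not from any one window.

This is the minimal mechanism that makes window order informative for one
label but not the other, mirroring what temporal-filter classifiers and
window-shuffle controls are designed to probe.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .core import (ParcellationMap, RoiTimeSeries, read_parcellation,
                   read_series, write_parcellation, write_series)

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "make_parcellation",
    "build_state_covariance",
    "simulate_run",
    "make_dataset",
    "write_dataset",
    "read_dataset",
]

MODALITY_NAMES = ("audio", "movie")
CONTENT_NAMES = ("airport", "restaurant")


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped defaults: 31 subjects x 16 narratives, 100 ROIs in a
    7-block parcellation, TR 1.5 s, runs of 125 samples (187.5 s) so the
    default 30 s / 7.5 s-overlap window plan yields 8 windows per run.

    ``modality_effect_size`` is the covariance increment (label-signed,
    +eps / -eps) applied within modality-effect blocks in every state;
    ``content_effect_size`` is the one-sided increment whose block-to-state
    assignment order encodes content.  ``segment_align_samples`` optionally
    snaps latent-state boundaries to a multiple of the window step so each
    analysis window is dominated by a single state.
    """

    n_subjects: int = 31
    n_narratives_per_subject: int = 16
    n_rois: int = 100
    n_timepoints: int = 125
    tr: float = 1.5
    subnetwork_sizes: tuple[int, ...] = (14, 14, 14, 14, 14, 15, 15)
    modality_effect_subnets: tuple[int, ...] = (0,)
    content_effect_subnets: tuple[int, ...] = (3, 6)
    modality_effect_size: float = 0.05
    content_effect_size: float = 0.3
    baseline_corr: float = 0.1
    n_states: int = 4
    noise_sd: float = 0.5
    ar_coeff: float = 0.4
    segment_align_samples: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.subnetwork_sizes) != self.n_rois:
            raise ValueError(
                f"subnetwork_sizes sum to {sum(self.subnetwork_sizes)}, "
                f"expected n_rois={self.n_rois}")
        if self.modality_effect_size < 0 or self.content_effect_size < 0:
            raise ValueError("effect sizes must be >= 0")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError(f"ar_coeff must be in [0, 1), got {self.ar_coeff}")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        n_blocks = len(self.subnetwork_sizes)
        for name, subs in (("modality", self.modality_effect_subnets),
                           ("content", self.content_effect_subnets)):
            bad = [s for s in subs if not 0 <= s < n_blocks]
            if bad:
                raise ValueError(
                    f"{name}_effect_subnets {bad} outside declared labels "
                    f"0..{n_blocks - 1}")


@dataclass
class SyntheticDataset:
    """Generated runs with labels, parcellation, and planted ground truth."""

    runs: list[tuple[int, int, RoiTimeSeries]]  # (subject_id, narrative_id, series)
    labels: list[tuple[int, int]]               # (modality, content) per run
    parcellation: ParcellationMap
    config: SimConfig

    @property
    def ground_truth(self) -> dict:
        return {
            "modality_effect_subnets": list(self.config.modality_effect_subnets),
            "content_effect_subnets": list(self.config.content_effect_subnets),
            "modality_effect_size": self.config.modality_effect_size,
            "content_effect_size": self.config.content_effect_size,
        }

    def task_labels(self, task: str) -> np.ndarray:
        """Per-run class labels: modality (2), content (2), combined (4)."""
        mod = np.array([m for m, _ in self.labels])
        con = np.array([c for _, c in self.labels])
        if task == "modality":
            return mod
        if task == "content":
            return con
        if task == "combined":
            return 2 * mod + con
        raise ValueError(f"unknown task {task!r}")


def make_parcellation(R: int, subnetwork_sizes: list[int]) -> ParcellationMap:
    """Assign contiguous ROI blocks to labels 0..K-1."""
    sizes = list(subnetwork_sizes)
    if any(s <= 0 for s in sizes):
        raise ValueError(f"subnetwork sizes must be positive, got {sizes}")
    if sum(sizes) != R:
        raise ValueError(
            f"subnetwork sizes sum to {sum(sizes)}, expected R={R}")
    labels = np.repeat(np.arange(len(sizes)), sizes)
    return ParcellationMap(labels=labels)


def _content_variants(config: SimConfig) -> list[int | None]:
    """The cycle of block targets for the content increment.

    With >= 2 content blocks the increment cycles through them; with one
    block it alternates on/off (None = no increment), so order still
    carries information.  Content label 1 starts the cycle one step later
    than label 0: same multiset of state covariances, different sequence,
    provided n_states is a multiple of the cycle length.
    """
    blocks: list[int | None] = sorted(config.content_effect_subnets)
    if not blocks or config.content_effect_size == 0:
        return []
    if len(blocks) == 1:
        blocks = [blocks[0], None]
    if config.n_states % len(blocks) != 0:
        warnings.warn(
            f"n_states={config.n_states} not a multiple of the content cycle "
            f"length {len(blocks)}; content labels will differ slightly in "
            "state frequencies, not only in order")
    return blocks


def build_state_covariance(parcellation: ParcellationMap, modality: int,
                           content: int, state_index: int,
                           config: SimConfig) -> np.ndarray:
    """Construct the R x R covariance for one latent state and label pair.

    Baseline is unit variance with uniform off-diagonal ``baseline_corr``.
    If the planted increments push the matrix off the positive-definite cone
    they are shrunk toward zero with a warning reporting the factor.
    """
    if not 0 <= state_index < config.n_states:
        raise ValueError(
            f"state_index {state_index} out of range 0..{config.n_states - 1}")
    R = parcellation.n_rois
    off = ~np.eye(R, dtype=bool)
    sigma = np.full((R, R), config.baseline_corr)
    np.fill_diagonal(sigma, 1.0)

    delta = np.zeros((R, R))
    sign = 1.0 if modality == 1 else -1.0
    for lbl in config.modality_effect_subnets:
        idx = parcellation.rois_of(int(lbl))
        delta[np.ix_(idx, idx)] += sign * config.modality_effect_size
    variants = _content_variants(config)
    if variants:
        target = variants[(state_index + content) % len(variants)]
        if target is not None:
            idx = parcellation.rois_of(int(target))
            delta[np.ix_(idx, idx)] += config.content_effect_size
    delta[~off] = 0.0

    out = sigma + delta
    min_eig = np.linalg.eigvalsh(out)[0]
    if min_eig <= 1e-8:
        # bisect the largest shrinkage of the increments that stays PD
        lo, hi = 0.0, 1.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if np.linalg.eigvalsh(sigma + mid * delta)[0] > 1e-8:
                lo = mid
            else:
                hi = mid
        warnings.warn(
            f"planted increments broke positive-definiteness (min eig "
            f"{min_eig:.3g}); shrinking them by factor {lo:.4f}")
        out = sigma + lo * delta
    return out


def _segment_bounds(config: SimConfig) -> list[tuple[int, int]]:
    """Equal-length state segments; the last absorbs the remainder.  With
    ``segment_align_samples`` set, interior boundaries snap to that grid."""
    L, n = config.n_timepoints, config.n_states
    cuts = [i * (L // n) for i in range(n)] + [L]
    if config.segment_align_samples:
        a = config.segment_align_samples
        cuts = [min(L, round(c / a) * a) for c in cuts]
        cuts[0], cuts[-1] = 0, L
    bounds = [(cuts[i], cuts[i + 1]) for i in range(n)]
    if any(e <= s for s, e in bounds):
        raise ValueError(
            f"segment alignment produced an empty state segment: {bounds}")
    return bounds


def simulate_run(subject_id: int, narrative_id: int, modality: int,
                 content: int, config: SimConfig,
                 seed: int | None = None) -> RoiTimeSeries:
    """Simulate one run: per-state multivariate-normal draws, AR(1)-smoothed,
    plus white noise.  Deterministic given (seed, subject_id, narrative_id).

    The AR recursion uses innovation scaling sqrt(1 - ar^2) so the stationary
    covariance of the smoothed signal equals the state covariance; with
    ``ar_coeff=0`` and ``noise_sd=0`` each segment is an i.i.d. draw from its
    state's covariance.
    """
    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(
        np.random.SeedSequence([base_seed, subject_id, narrative_id]))
    parc = make_parcellation(config.n_rois, list(config.subnetwork_sizes))
    R = config.n_rois
    segments = []
    prev = np.zeros(R)
    scale = np.sqrt(1.0 - config.ar_coeff ** 2)
    for s, (start, end) in enumerate(_segment_bounds(config)):
        cov = build_state_covariance(parc, modality, content, s, config)
        chol = np.linalg.cholesky(cov)
        innov = rng.standard_normal((end - start, R)) @ chol.T
        seg = np.empty_like(innov)
        x = prev
        for t in range(end - start):
            x = config.ar_coeff * x + scale * innov[t]
            seg[t] = x
        prev = x
        segments.append(seg)
    values = np.concatenate(segments, axis=0).T  # (R, L)
    if config.noise_sd > 0:
        values = values + config.noise_sd * rng.standard_normal(values.shape)
    return RoiTimeSeries(values=values, tr=config.tr)


def make_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate the full dataset with per-subject balanced 2x2 labels."""
    if config.n_narratives_per_subject % 4 != 0:
        raise ValueError(
            f"n_narratives_per_subject={config.n_narratives_per_subject} "
            "must be divisible by 4 to balance the 2x2 modality x content "
            "design")
    parc = make_parcellation(config.n_rois, list(config.subnetwork_sizes))
    runs, labels = [], []
    for subj in range(config.n_subjects):
        for narr in range(config.n_narratives_per_subject):
            modality, content = (narr % 4) // 2, narr % 2
            series = simulate_run(subj, narr, modality, content, config)
            runs.append((subj, narr, series))
            labels.append((modality, content))
    return SyntheticDataset(runs=runs, labels=labels, parcellation=parc,
                            config=config)


# ---------------------------------------------------------------------------
# Round-trippable on-disk layout: one TSV+JSON per run, parcellation TSV,
# config + ground truth as JSON.
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (subj, narr, series), (modality, content) in zip(dataset.runs,
                                                         dataset.labels):
        name = f"sub-{subj:03d}_run-{narr:03d}.tsv"
        write_series(series, directory / name, metadata={
            "subject_id": subj, "narrative_id": narr,
            "modality": modality, "content": content,
            "modality_name": MODALITY_NAMES[modality],
            "content_name": CONTENT_NAMES[content],
        })
    write_parcellation(dataset.parcellation, directory / "parcellation.tsv")
    cfg = asdict(dataset.config)
    (directory / "dataset.json").write_text(json.dumps(
        {"config": cfg, "ground_truth": dataset.ground_truth}, indent=1))


def read_dataset(directory: str | Path) -> SyntheticDataset:
    directory = Path(directory)
    info = json.loads((directory / "dataset.json").read_text())
    cfg_dict = dict(info["config"])
    for key in ("subnetwork_sizes", "modality_effect_subnets",
                "content_effect_subnets"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = SimConfig(**cfg_dict)
    parc = read_parcellation(directory / "parcellation.tsv")
    runs, labels = [], []
    for path in sorted(directory.glob("sub-*_run-*.tsv")):
        series, meta = read_series(path)
        runs.append((int(meta["subject_id"]), int(meta["narrative_id"]), series))
        labels.append((int(meta["modality"]), int(meta["content"])))
    return SyntheticDataset(runs=runs, labels=labels, parcellation=parc,
                            config=config)
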