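"""Permutation and static-connectivity controls for temporal structure.

Three seeded experiment variants probe what the classifier actually uses:

* ``shuffle_series`` — permute raw time points *before* building networks.
  The default ``independent_per_roi`` mode draws a fresh permutation per ROI,
  destroying both inter-ROI correlation and temporal order (accuracy should
  fall to chance).  The ``common_across_rois`` mode applies one shared
  permutation, which preserves instantaneous co-fluctuation (whole-run
  correlations are exactly unchanged) and destroys order only.
* ``shuffle_windows`` — permute whole connectivity windows after network
  construction, keeping each window's internal structure intact.  This is a
  block permutation: information carried by window *order* is destroyed,
  information within single windows survives.
* ``static_fc`` — replace the windowed tensor by a single whole-run Pearson
  matrix (T = 1), the classic static functional connectivity baseline; the
  classifier then runs with tau = 1.

Controls are redrawn fresh for every training repetition, so reported sd
reflects both split and permutation variability.  Control seeds are derived
from the ControlSpec's own seed, independent of training seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import RoiTimeSeries, TemporalNetwork
from .clf import MetricsReport, ModelConfig, TrainConfig, run_repetitions
from .netbuild import WindowSpec, build_temporal_network, window_correlation

__all__ = [
    "ControlSpec",
    "shuffle_series",
    "shuffle_windows",
    "static_fc",
    "run_control",
]


@dataclass(frozen=True)
class ControlSpec:
    kind: str  # shuffle_series | shuffle_windows | static_fc
    seed: int = 0
    series_shuffle_mode: str = "independent_per_roi"

    def __post_init__(self) -> None:
        if self.kind not in ("shuffle_series", "shuffle_windows", "static_fc"):
            raise ValueError(f"unknown control kind {self.kind!r}")
        if self.series_shuffle_mode not in ("independent_per_roi",
                                            "common_across_rois"):
            raise ValueError(
                f"unknown series_shuffle_mode {self.series_shuffle_mode!r}")


def shuffle_series(series: RoiTimeSeries, mode: str = "independent_per_roi",
                   seed: int = 0) -> RoiTimeSeries:
    """Permute time indices; each ROI keeps exactly its multiset of values."""
    rng = np.random.default_rng(seed)
    L = series.n_samples
    if mode == "common_across_rois":
        perm = rng.permutation(L)
        values = series.values[:, perm]
    elif mode == "independent_per_roi":
        values = np.empty_like(series.values)
        for r in range(series.n_rois):
            values[r] = series.values[r, rng.permutation(L)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return RoiTimeSeries(values=values, tr=series.tr,
                         roi_ids=list(series.roi_ids))


def shuffle_windows(net: TemporalNetwork, seed: int = 0) -> TemporalNetwork:
    """Permute the window axis; every slice stays bit-identical."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(net.n_windows)
    return TemporalNetwork(tensor=net.tensor[:, :, perm],
                           window_starts=[net.window_starts[p] for p in perm],
                           normalization_state=net.normalization_state)


def static_fc(series: RoiTimeSeries) -> TemporalNetwork:
    """Whole-run Pearson matrix as a T = 1 temporal network."""
    if series.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation")
    corr = window_correlation(series, (0, series.n_samples))
    return TemporalNetwork(tensor=corr[:, :, None], window_starts=[0],
                           normalization_state="raw")


def run_control(series_list: list[RoiTimeSeries], y: np.ndarray,
                control: ControlSpec, window: WindowSpec,
                model_cfg: ModelConfig, train_cfg: TrainConfig,
                **rep_kwargs) -> tuple[MetricsReport, list]:
    """Apply one control and rerun the full training protocol.

    shuffle_series re-permutes the raw series and rebuilds networks fresh
    for every repetition; shuffle_windows re-permutes tensors fresh per
    repetition; static_fc deterministically replaces the window stack
    (and forces tau = 1 on a T = 1 input).
    """
    control_ss = np.random.SeedSequence(control.seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in control_ss.spawn(train_cfg.n_repetitions)]

    if control.kind == "static_fc":
        nets = [static_fc(s) for s in series_list]
        cfg = replace(model_cfg, tau=1)
        return run_repetitions(nets, y, cfg, train_cfg, **rep_kwargs)

    if control.kind == "shuffle_windows":
        base = [build_temporal_network(s, window) for s in series_list]

        def provider(rep: int, _train_seed: int) -> list[TemporalNetwork]:
            run_rng = np.random.SeedSequence([rep_seeds[rep], 1])
            seeds = run_rng.generate_state(len(base)) % (2 ** 31)
            return [shuffle_windows(net, int(sd))
                    for net, sd in zip(base, seeds)]

        return run_repetitions(provider, y, model_cfg, train_cfg, **rep_kwargs)

    def provider(rep: int, _train_seed: int) -> list[TemporalNetwork]:
        run_rng = np.random.SeedSequence([rep_seeds[rep], 2])
        seeds = run_rng.generate_state(len(series_list)) % (2 ** 31)
        return [build_temporal_network(
                    shuffle_series(s, control.series_shuffle_mode, int(sd)),
                    window)
                for s, sd in zip(series_list, seeds)]

    return run_repetitions(provider, y, model_cfg, train_cfg, **rep_kwargs)
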