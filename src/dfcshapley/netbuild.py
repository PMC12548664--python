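"""From cleaned ROI time series to temporal brain networks.

The construction follows the standard sliding-window dynamic functional
connectivity recipe: optional nuisance regression against motion parameters,
zero-phase band-pass filtering of each ROI signal (default 0.01-0.08 Hz, the
usual resting/task BOLD band), Pearson correlation between every ROI pair
inside each overlapping window (default 30 s windows, 7.5 s overlap), and
per-edge Z-normalization of the resulting adjacency matrices against a
training pool.

Diagonal handling: self-correlation is identically 1 with zero variance
across samples, so the diagonal is zeroed before normalization; it carries
no information and would otherwise divide by zero.

Z-normalization scope: statistics are per edge (i, j), pooled over all
training samples and all windows.  This makes 0 the per-edge mean, which is
what justifies 0 as the masking value in the Shapley stage.  Per-matrix and
global-scalar modes are available via ``Normalizer.fit(..., scope=...)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import RoiTimeSeries, TemporalNetwork

__all__ = [
    "WindowSpec",
    "Normalizer",
    "regress_nuisance",
    "bandpass",
    "plan_windows",
    "window_correlation",
    "build_temporal_network",
    "fit_normalizer",
    "apply_normalizer",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in seconds; samples derived from the TR."""

    window_seconds: float = 30.0
    overlap_seconds: float = 7.5

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_seconds < self.window_seconds:
            raise ValueError(
                f"need 0 <= overlap ({self.overlap_seconds}) < window "
                f"({self.window_seconds})")

    def window_samples(self, tr: float) -> int:
        n = int(round(self.window_seconds / tr))
        if n < 3:
            raise ValueError(
                f"window of {self.window_seconds}s at tr={tr}s gives only "
                f"{n} samples; need >= 3")
        return n

    def step_samples(self, tr: float) -> int:
        step = self.window_samples(tr) - int(round(self.overlap_seconds / tr))
        if step < 1:
            raise ValueError("overlap leaves a step of < 1 sample")
        return step


def regress_nuisance(series: RoiTimeSeries,
                     regressors: np.ndarray | None) -> RoiTimeSeries:
    """Residualize each ROI signal against nuisance regressors by OLS.

    An intercept column is always included, so with an empty regressor set
    this reduces to mean-centering.  Collinear regressor columns are dropped
    with a warning.  Residuals are orthogonal to every retained regressor.
    """
    L = series.n_samples
    if regressors is None or (hasattr(regressors, "size") and regressors.size == 0):
        X = np.ones((L, 1))
    else:
        regressors = np.asarray(regressors, dtype=float)
        if regressors.ndim == 1:
            regressors = regressors[:, None]
        if regressors.shape[0] != L:
            raise ValueError(
                f"regressors have {regressors.shape[0]} rows, series has {L}")
        if regressors.shape[1] >= L:
            raise ValueError("more regressors than time samples")
        X = np.column_stack([np.ones(L), regressors])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # greedy scan keeps the earliest independent columns
            keep = [0]
            for j in range(1, X.shape[1]):
                trial = X[:, keep + [j]]
                if np.linalg.matrix_rank(trial) > len(keep):
                    keep.append(j)
            warnings.warn(
                f"dropping {X.shape[1] - len(keep)} collinear nuisance "
                "regressor column(s)")
            X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, series.values.T, rcond=None)
    resid = series.values - (X @ beta).T
    return RoiTimeSeries(values=resid, tr=series.tr, roi_ids=list(series.roi_ids))


def bandpass(series: RoiTimeSeries, low_hz: float = 0.01,
             high_hz: float = 0.08, order: int = 4) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass (forward-backward) per ROI.

    Removes the DC component and fluctuations outside [low_hz, high_hz].
    """
    nyq = 1.0 / (2.0 * series.tr)
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(
            f"high_hz={high_hz} not below Nyquist {nyq:.4g} Hz at tr={series.tr}s")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=1.0 / series.tr, output="sos")
    filtered = sps.sosfiltfilt(sos, series.values, axis=1)
    return RoiTimeSeries(values=filtered, tr=series.tr,
                         roi_ids=list(series.roi_ids))


def plan_windows(L: int, spec: WindowSpec, tr: float) -> list[tuple[int, int]]:
    """Half-open (start, end) sample windows: starts 0, step, 2*step, ...

    step = window - overlap; a trailing partial window is discarded.
    """
    w = spec.window_samples(tr)
    step = spec.step_samples(tr)
    if L < w:
        raise ValueError(f"series length {L} shorter than window {w} samples")
    return [(s, s + w) for s in range(0, L - w + 1, step)]


def window_correlation(series: RoiTimeSeries,
                       window: tuple[int, int]) -> np.ndarray:
    """Pearson correlation between every ROI pair within one window.

    Symmetric, entries in [-1, 1], diagonal zeroed.  An ROI with zero
    variance inside the window gets zero correlations and a warning.
    """
    start, end = window
    if end - start < 3:
        raise ValueError("window must span at least 3 samples")
    seg = series.values[:, start:end]
    sd = seg.std(axis=1)
    dead = sd == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} ROI(s) constant in window {window}; "
            "their correlations set to 0")
        seg = seg.copy()
        # unit noise-free placeholder rows avoid 0/0; zeroed below
        seg[dead] = np.arange(end - start)
    corr = np.corrcoef(seg)
    corr = 0.5 * (corr + corr.T)  # BLAS output is not bit-symmetric
    corr = np.clip(corr, -1.0, 1.0)
    corr[dead, :] = 0.0
    corr[:, dead] = 0.0
    np.fill_diagonal(corr, 0.0)
    return corr


def build_temporal_network(series: RoiTimeSeries,
                           spec: WindowSpec) -> TemporalNetwork:
    """Stack windowed correlation matrices into an R x R x T tensor."""
    windows = plan_windows(series.n_samples, spec, series.tr)
    slices = [window_correlation(series, w) for w in windows]
    return TemporalNetwork(tensor=np.stack(slices, axis=2),
                           window_starts=[w[0] for w in windows],
                           normalization_state="raw")


@dataclass
class Normalizer:
    """Per-edge Z-scoring statistics fitted on a training pool.

    ``mean``/``sd`` are R x R.  Edges whose pooled sd is zero pass through
    as 0 (flagged in ``dead_edges``).  The diagonal is always left at 0.
    """

    mean: np.ndarray
    sd: np.ndarray
    dead_edges: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dead_edges is None:
            self.dead_edges = self.sd == 0


def fit_normalizer(train_networks: list[TemporalNetwork],
                   scope: str = "per_edge") -> Normalizer:
    """Fit Z-normalization statistics on a pool of raw training networks.

    scope="per_edge" (default): mean/sd per edge (i, j) across all training
    samples and windows.  scope="global": one scalar mean/sd over all
    off-diagonal entries, broadcast to every edge.
    """
    if len(train_networks) < 2:
        raise ValueError("need at least 2 training networks to fit a normalizer")
    R = train_networks[0].n_rois
    pool = np.concatenate([net.tensor for net in train_networks], axis=2)
    if scope == "per_edge":
        mean = pool.mean(axis=2)
        sd = pool.std(axis=2)
    elif scope == "global":
        off = ~np.eye(R, dtype=bool)
        vals = pool[off, :]
        mean = np.full((R, R), vals.mean())
        sd = np.full((R, R), vals.std())
    else:
        raise ValueError(f"unknown scope {scope!r}")
    np.fill_diagonal(mean, 0.0)
    np.fill_diagonal(sd, 0.0)
    dead = sd == 0
    n_dead_off = int(dead.sum()) - R
    if n_dead_off > 0:
        warnings.warn(
            f"{n_dead_off} off-diagonal edge(s) constant in the training "
            "pool; they will pass through as 0")
    return Normalizer(mean=mean, sd=sd, dead_edges=dead)


def apply_normalizer(net: TemporalNetwork, norm: Normalizer) -> TemporalNetwork:
    """Z-score each edge of each window; dead edges and diagonal become 0."""
    if net.normalization_state != "raw":
        raise ValueError("network already normalized")
    safe_sd = np.where(norm.dead_edges, 1.0, norm.sd)
    z = (net.tensor - norm.mean[:, :, None]) / safe_sd[:, :, None]
    z[norm.dead_edges, :] = 0.0
    return TemporalNetwork(tensor=z, window_starts=list(net.window_starts),
                           normalization_state="znormalized")
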