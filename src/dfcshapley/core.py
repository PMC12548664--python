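"""Shared data containers and their on-disk formats.

Three objects travel between every stage of the pipeline:

* :class:`RoiTimeSeries` — one run's region-of-interest (ROI) signal matrix,
  R regions by L samples, with its sampling interval (the fMRI repetition
  time, TR).
* :class:`ParcellationMap` — the assignment of each ROI to a larger
  subnetwork (e.g. a Yeo-style 7-network scheme).  Subnetworks are the
  "players" of the Shapley attribution.
* :class:`TemporalNetwork` — the R x R x T tensor of windowed connectivity
  matrices, one R x R slice per sliding window.

On-disk formats are plain text (tab-separated values with a JSON sidecar for
run metadata) except for temporal-network tensors, which are stored in HDF5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeries",
    "ParcellationMap",
    "TemporalNetwork",
    "read_series",
    "write_series",
    "read_parcellation",
    "write_parcellation",
    "save_networks",
    "load_networks",
]


@dataclass
class RoiTimeSeries:
    """An R x L matrix of per-ROI signal with sampling interval ``tr``.

    Parameters
    ----------
    values : ndarray of shape (R, L)
        One row per ROI, one column per time sample.
    tr : float
        Sampling interval in seconds (the repetition time).
    roi_ids : sequence of str, optional
        Identifiers for each ROI; defaults to ``roi000, roi001, ...``.
    """

    values: np.ndarray
    tr: float
    roi_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (R x L) array")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 time samples")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite values")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not self.roi_ids:
            self.roi_ids = [f"roi{i:03d}" for i in range(self.values.shape[0])]
        if len(self.roi_ids) != self.values.shape[0]:
            raise ValueError("roi_ids length does not match number of rows")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ParcellationMap:
    """ROI index -> subnetwork label assignment.

    ``labels[r]`` is the integer subnetwork label of ROI ``r``.  Labels need
    not be contiguous but usually are (0..K-1).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "labels", np.asarray(self.labels, dtype=int).copy()
        )
        self.labels.setflags(write=False)

    @property
    def n_rois(self) -> int:
        return len(self.labels)

    @property
    def subnetworks(self) -> list[int]:
        """Distinct subnetwork labels in ascending order."""
        return sorted(int(x) for x in np.unique(self.labels))

    def rois_of(self, label: int) -> np.ndarray:
        """Indices of ROIs belonging to ``label``."""
        return np.flatnonzero(self.labels == label)

    def sizes(self) -> dict[int, int]:
        return {k: int((self.labels == k).sum()) for k in self.subnetworks}


@dataclass
class TemporalNetwork:
    """R x R x T stack of windowed connectivity matrices.

    ``normalization_state`` is ``"raw"`` straight out of the windowed
    Pearson computation (entries in [-1, 1], diagonal zero) or
    ``"znormalized"`` after per-edge Z-scoring against a training pool.
    """

    tensor: np.ndarray
    window_starts: list[int]
    normalization_state: str = "raw"

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3 or self.tensor.shape[0] != self.tensor.shape[1]:
            raise ValueError("tensor must have shape (R, R, T)")
        if len(self.window_starts) != self.tensor.shape[2]:
            raise ValueError("window_starts length must equal T")
        if self.normalization_state not in ("raw", "znormalized"):
            raise ValueError(f"unknown state {self.normalization_state!r}")

    @property
    def n_rois(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_windows(self) -> int:
        return self.tensor.shape[2]


# ---------------------------------------------------------------------------
# Text IO: ROI series as TSV (+ JSON sidecar), parcellation as two-column TSV
# ---------------------------------------------------------------------------

def write_series(series: RoiTimeSeries, path: str | Path,
                 metadata: dict | None = None) -> None:
    """Write one run as TSV (header row = sample times in seconds) plus a
    JSON sidecar ``<path>.json`` holding ``tr`` and any extra metadata."""
    path = Path(path)
    times = np.arange(series.n_samples) * series.tr
    frame = pd.DataFrame(series.values,
                         index=series.roi_ids,
                         columns=[f"{t:.6g}" for t in times])
    frame.to_csv(path, sep="\t", index_label="roi_id", float_format="%.17g")
    meta = {"tr": series.tr}
    if metadata:
        meta.update(metadata)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_series(path: str | Path) -> tuple[RoiTimeSeries, dict]:
    """Read a run written by :func:`write_series`; returns (series, metadata)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col="roi_id",
                        float_precision="round_trip")
    meta = json.loads(Path(str(path) + ".json").read_text())
    series = RoiTimeSeries(values=frame.to_numpy(dtype=float),
                           tr=float(meta["tr"]),
                           roi_ids=[str(i) for i in frame.index])
    return series, meta


def write_parcellation(parc: ParcellationMap, path: str | Path,
                       roi_ids: Sequence[str] | None = None) -> None:
    ids = list(roi_ids) if roi_ids else [f"roi{i:03d}" for i in range(parc.n_rois)]
    pd.DataFrame({"roi_id": ids, "subnetwork_label": parc.labels}).to_csv(
        path, sep="\t", index=False)


def read_parcellation(path: str | Path) -> ParcellationMap:
    frame = pd.read_csv(path, sep="\t")
    return ParcellationMap(labels=frame["subnetwork_label"].to_numpy(dtype=int))


# ---------------------------------------------------------------------------
# HDF5 tensor store: one dataset per run, attributes carry window bookkeeping
# ---------------------------------------------------------------------------

def save_networks(networks: dict[str, TemporalNetwork], path: str | Path) -> None:
    """Store temporal networks in an HDF5 container, one dataset per run id."""
    with h5py.File(path, "w") as h5:
        for run_id, net in networks.items():
            ds = h5.create_dataset(run_id, data=net.tensor)
            ds.attrs["window_starts"] = np.asarray(net.window_starts, dtype=int)
            ds.attrs["normalization_state"] = net.normalization_state


def load_networks(path: str | Path) -> dict[str, TemporalNetwork]:
    out: dict[str, TemporalNetwork] = {}
    with h5py.File(path, "r") as h5:
        for run_id in h5:
            ds = h5[run_id]
            out[run_id] = TemporalNetwork(
                tensor=ds[()],
                window_starts=[int(s) for s in ds.attrs["window_starts"]],
                normalization_state=str(ds.attrs["normalization_state"]),
            )
    return out
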