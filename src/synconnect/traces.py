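"""Trace normalization, fluorescence event detection, and raster binning.

Downstream network inference uses rank (Spearman) correlations, so it is
invariant to any per-neuron monotone normalization; normalization here
serves plotting and event detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .synth import TraceSet

__all__ = ["Raster", "normalize_traces", "detect_events", "bin_raster"]

MAD_TO_SD = 1.4826  # consistency factor for a normal distribution


@dataclass
class Raster:
    """Neuron-by-bin event-count matrix with half-open bins [lo, hi)."""

    counts: np.ndarray  # (n_neurons, n_bins), nonnegative ints
    bin_width: float  # s
    bin_edges: np.ndarray  # (n_bins + 1,), seconds

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("raster counts must be nonnegative")
        if self.bin_edges.size != self.counts.shape[1] + 1:
            raise ValueError("bin_edges must have n_bins + 1 entries")

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


def normalize_traces(t: TraceSet, method: str = "minmax",
                     baseline_percentile: float = 10.0) -> TraceSet:
    """Per-neuron normalization of a trace matrix.

    minmax maps each trace onto [0, 1]; zscore standardizes to mean 0 /
    sd 1; dff computes (F - F0)/F0 with F0 the per-trace
    ``baseline_percentile`` percentile.  A constant trace cannot be
    normalized — it is flagged with a warning and mapped to all zeros, and
    the neuron is retained.
    """
    x = t.traces
    if method == "minmax":
        lo = x.min(axis=1, keepdims=True)
        hi = x.max(axis=1, keepdims=True)
        span = hi - lo
        flat = span[:, 0] == 0
        span[flat] = 1.0
        out = (x - lo) / span
        out[flat] = 0.0
    elif method == "zscore":
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        flat = sd[:, 0] == 0
        sd[flat] = 1.0
        out = (x - mu) / sd
        out[flat] = 0.0
    elif method == "dff":
        f0 = np.percentile(x, baseline_percentile, axis=1, keepdims=True)
        denom = np.where(f0 == 0, 1.0, f0)
        flat = x.std(axis=1) == 0
        out = (x - f0) / denom
        out[flat] = 0.0
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if method in ("minmax", "zscore", "dff"):
        n_flat = int((x.std(axis=1) == 0).sum())
        if n_flat:
            warnings.warn(f"{n_flat} constant trace(s) mapped to zeros",
                          RuntimeWarning, stacklevel=2)
    new = TraceSet(traces=out, frame_rate=t.frame_rate, centroids=t.centroids,
                   region_label=t.region_label,
                   condition_label=t.condition_label)
    return new


def detect_events(t: TraceSet, threshold_sd: float = 2.5) -> list[np.ndarray]:
    """Onset times of fluorescence transients, per neuron.

    An event is an upward crossing of baseline + threshold_sd * robust-sd,
    where baseline is the per-trace median and robust-sd is 1.4826 x MAD.
    Consecutive supra-threshold frames merge into a single event timed at
    its onset frame.
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    out = []
    for row in t.traces:
        med = np.median(row)
        mad = np.median(np.abs(row - med))
        # floor guards against a zero MAD on noise-free traces, where
        # convolution round-off would otherwise count as crossings
        robust_sd = max(MAD_TO_SD * mad, 1e-9 * np.ptp(row))
        thr = med + threshold_sd * robust_sd
        above = row > thr
        onsets = np.nonzero(above & ~np.concatenate([[False], above[:-1]]))[0]
        out.append(onsets / t.frame_rate)
    return out


def bin_raster(events: list[np.ndarray], duration: float,
               bin_width: float = 100.0) -> Raster:
    """Count events per neuron in half-open [lo, hi) bins of ``bin_width``
    seconds; the last partial bin is retained."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_bins = int(np.ceil(duration / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, duration)
    edges[-1] = duration
    counts = np.zeros((len(events), n_bins), dtype=int)
    for i, ev in enumerate(events):
        ev = np.asarray(ev, dtype=float)
        if ev.size == 0:
            continue
        idx = np.floor(ev / bin_width).astype(int)
        idx = idx[(ev >= 0) & (ev < duration)]
        np.add.at(counts[i], idx, 1)
    return Raster(counts=counts, bin_width=bin_width, bin_edges=edges)
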