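"""Dynamic connectivity: per-timepoint Gaussian-weighted ROI-pair correlations.

Each edge of the network gets a full-length time series of Fisher-z
correlation coefficients: at every TR a Gaussian kernel (sd ~ window/3,
truncated to the 29-TR window, renormalized) weights the neighbourhood, a
weighted Pearson correlation is computed, Fisher-transformed, and the series
is finally z-normalized.  Near the edges the kernel is truncated rather than
the samples dropped, so the connectivity series stays aligned with the
heart-rate trace.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .cardiac import zscore
from .neural import NeuralSeries

__all__ = ["EdgeSeries", "weighted_corr", "edge_timeseries", "all_edges",
           "FISHER_CLIP"]

FISHER_CLIP = 1.0 - 1e-7


@dataclass
class EdgeSeries:
    """Per-TR Fisher-z weighted correlation for one unordered ROI pair."""

    values: np.ndarray
    tr_s: float
    label: str  # "roiA-roiB", lexicographic
    window_trs: int
    kernel_sd_trs: float
    z_normalized: bool = False
    degenerate: bool = False  # constant pre-z-score series (e.g. x == y)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in edge '{self.label}'")

    def __len__(self) -> int:
        return len(self.values)

    def as_neural(self) -> NeuralSeries:
        return NeuralSeries(self.values, self.tr_s, source=self.label,
                            z_normalized=self.z_normalized)


def weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Pearson correlation under nonnegative weights (normalized internally)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y, w must have equal lengths")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    w = w / total
    mx, my = w @ x, w @ y
    dx, dy = x - mx, y - my
    vx, vy = w @ (dx * dx), w @ (dy * dy)
    if vx <= 0 or vy <= 0:
        raise ValueError("zero weighted variance")
    r = (w @ (dx * dy)) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def _gaussian_kernel(window_trs: int, kernel_sd_trs: float) -> np.ndarray:
    half = (window_trs - 1) // 2
    offsets = np.arange(-half, half + 1, dtype=float)
    return np.exp(-0.5 * (offsets / kernel_sd_trs) ** 2)


def edge_timeseries(x: NeuralSeries, y: NeuralSeries, window_trs: int = 29,
                    kernel_sd_trs: float | None = None,
                    z_normalize: bool = True) -> EdgeSeries:
    """Sliding Gaussian-kernel correlation between two ROI series.

    The kernel sd defaults to window/3 TRs so that >=99% of the Gaussian
    mass lies inside the stated window; truncated tails are renormalized.
    The output has full length (edge windows truncated), each correlation is
    Fisher-transformed with |r| clipped at 1-1e-7, and by default the series
    is z-normalized.  A constant pre-z-score series (e.g. x identical to y)
    cannot be z-normalized and is returned flagged ``degenerate`` instead.
    """
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    if window_trs % 2 == 0:
        raise ValueError("window must be odd (center undefined otherwise)")
    if len(x) < window_trs:
        raise ValueError("series shorter than the window")
    if x.tr_s != y.tr_s:
        raise ValueError("TR mismatch between series")
    if kernel_sd_trs is None:
        kernel_sd_trs = window_trs / 3.0
    if kernel_sd_trs <= 0:
        raise ValueError("kernel_sd_trs must be positive")

    kernel = _gaussian_kernel(window_trs, kernel_sd_trs)
    xv, yv = x.values, y.values

    # Weighted moments at every center via correlation with the kernel;
    # "same" mode truncates the kernel at the edges and the renormalization
    # by sw handles the lost mass.
    def _conv(v):
        return np.convolve(v, kernel, mode="same")

    sw = _conv(np.ones_like(xv))
    sx, sy = _conv(xv) / sw, _conv(yv) / sw
    sxx = _conv(xv * xv) / sw - sx * sx
    syy = _conv(yv * yv) / sw - sy * sy
    sxy = _conv(xv * yv) / sw - sx * sy
    var_floor = 1e-15 * max(1.0, float(np.max(np.abs(xv))) ** 2,
                            float(np.max(np.abs(yv))) ** 2)
    denom = np.sqrt(np.maximum(sxx, var_floor) * np.maximum(syy, var_floor))
    r = np.clip(sxy / denom, -FISHER_CLIP, FISHER_CLIP)
    z = np.arctanh(r)

    label = x.source and y.source and "-".join(sorted([x.source, y.source])) or ""
    degenerate = bool(np.ptp(z) < 1e-12)
    if z_normalize and not degenerate:
        z = zscore(z)
    return EdgeSeries(z, x.tr_s, label, window_trs, kernel_sd_trs,
                      z_normalized=z_normalize and not degenerate,
                      degenerate=degenerate)


def all_edges(rois: Sequence[NeuralSeries], window_trs: int = 29,
              kernel_sd_trs: float | None = None,
              z_normalize: bool = True) -> List[EdgeSeries]:
    """EdgeSeries for every unordered ROI pair, in lexicographic label order."""
    if len(rois) < 2:
        raise ValueError("need at least 2 ROIs")
    labels = [r.source for r in rois]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate ROI labels: {sorted(labels)}")
    ordered = sorted(rois, key=lambda r: r.source)
    return [
        edge_timeseries(a, b, window_trs, kernel_sd_trs, z_normalize)
        for a, b in itertools.combinations(ordered, 2)
    ]
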