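"""Brain-heart coherence estimators.

Three per-subject, per-condition measures of the coupling between the
(hemodynamically lagged) heart-rate trace and a neural time series:

* ``bivariate_coherence`` — Fisher-z of the instantaneous Pearson
  correlation (the HR trace already carries the 6 s lag);
* ``dtw_coherence`` — dynamic time warping distance under a Sakoe-Chiba
  band (default 14 TRs, ~10 s), focusing the alignment on quick
  co-fluctuations rather than slow drifts;
* ``xcorr_max`` — the maximum positive correlation over a grid of whole-TR
  delays spanning +-10 s around the hemodynamically lagged alignment, so
  the raw-HR-to-BOLD delay is searched from lag-10 = -4 s (BOLD preceding
  the heart rate) up to lag+10 = 16 s (heart rate preceding BOLD well
  beyond the canonical hemodynamic delay).  Applied per voxel this yields
  a lag map.

Because the two movie conditions differ in duration, DTW distances are only
comparable after ``match_condition_lengths`` trims the head of the longer
condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .cardiac import HrTrace
from .dynconn import FISHER_CLIP
from .io_formats import Volume4D

__all__ = [
    "CoherenceRecord",
    "LagMap",
    "match_condition_lengths",
    "bivariate_coherence",
    "dtw_distance",
    "dtw_coherence",
    "xcorr_max",
    "lag_map",
]

MIN_XCORR_OVERLAP = 30


@dataclass
class CoherenceRecord:
    """One subject x condition x target x measure coherence value."""

    subject: str
    condition: str  # suspense | control | rest
    target: str  # roi label | edge label | voxel index
    measure: str  # bivariate_z | dtw_distance | xcorr_max_z
    value: float
    lag_s_at_max: Optional[float] = None  # xcorr only
    n_timepoints_used: int = 0
    flags: str = ""

    def __post_init__(self) -> None:
        if self.measure == "dtw_distance" and self.value < 0:
            raise ValueError("DTW distance must be nonnegative")
        if self.measure in ("bivariate_z", "xcorr_max_z") and not np.isfinite(self.value):
            raise ValueError(f"{self.measure} must be finite")


@dataclass
class LagMap:
    """Per-voxel cross-correlation maxima (Fisher z) and argmax lags (s).

    ``z`` and ``lag_s`` are 3D grids on the source volume's grid; ``lag_s``
    is NaN outside the brain mask and wherever no positive peak exists.
    """

    z: np.ndarray
    lag_s: np.ndarray
    affine: np.ndarray
    brain_mask: np.ndarray
    search_lags_s: np.ndarray = field(default_factory=lambda: np.array([]))


def match_condition_lengths(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Equalize lengths by dropping the FIRST samples of the longer series.

    Mirrors omitting the opening section of the longer (suspense) condition
    so both conditions contribute the same number of TRs.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("series must be nonempty")
    if len(a) > len(b):
        a = a[len(a) - len(b):]
    elif len(b) > len(a):
        b = b[len(b) - len(a):]
    return a, b


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    dx = x - x.mean()
    dy = y - y.mean()
    vx = dx @ dx
    vy = dy @ dy
    if vx <= 0 or vy <= 0:
        raise ValueError("constant series: correlation undefined")
    return float((dx @ dy) / np.sqrt(vx * vy))


def bivariate_coherence(hr: HrTrace, neural, subject: str = "", condition: str = "",
                        target: str = "") -> CoherenceRecord:
    """Fisher-z correlation between the lagged HR trace and a neural series."""
    nv = neural.values if hasattr(neural, "values") else np.asarray(neural, float)
    if len(hr.values) != len(nv):
        raise ValueError("HR and neural series lengths differ")
    r = _pearson(hr.values, nv)
    z = float(np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP)))
    return CoherenceRecord(subject, condition,
                           target or getattr(neural, "source", ""),
                           "bivariate_z", z, n_timepoints_used=len(nv))


def dtw_distance(a: np.ndarray, b: np.ndarray, band_trs: Optional[int] = 14) -> float:
    """Band-constrained dynamic time warping distance.

    Squared-difference local cost, symmetric (diagonal/left/up) recursion,
    endpoints anchored, cells with |i-j| > band infeasible; the distance is
    the square root of the accumulated cost.  ``band_trs=None`` means
    unconstrained.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValueError("series must be nonempty")
    band = max(n, m) if band_trs is None else int(band_trs)
    if band < 0:
        raise ValueError("band_trs must be >= 0")
    if band < abs(n - m):
        raise ValueError("band narrower than the length difference: "
                         "endpoint unreachable")
    inf = np.inf
    prev = np.full(m + 1, inf)
    prev[0] = 0.0
    cur = np.empty(m + 1)
    for i in range(1, n + 1):
        cur.fill(inf)
        lo = max(1, i - band)
        hi = min(m, i + band)
        ai = a[i - 1]
        for j in range(lo, hi + 1):
            d = ai - b[j - 1]
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = d * d + best
        prev, cur = cur, prev
    total = prev[m]
    assert np.isfinite(total), "band made the endpoint unreachable"
    return float(np.sqrt(total))


def dtw_coherence(hr: HrTrace, neural, band_trs: int = 14, subject: str = "",
                  condition: str = "", target: str = "") -> CoherenceRecord:
    """DTW distance between z-scored HR and neural series (equal lengths)."""
    nv = neural.values if hasattr(neural, "values") else np.asarray(neural, float)
    if len(hr.values) != len(nv):
        raise ValueError(
            "lengths differ; apply match_condition_lengths before DTW")
    dist = dtw_distance(hr.values, nv, band_trs)
    return CoherenceRecord(subject, condition,
                           target or getattr(neural, "source", ""),
                           "dtw_distance", dist, n_timepoints_used=len(nv))


def _xcorr_grid(tr_s: float, extra_lag_s: float) -> np.ndarray:
    """Whole-TR index offsets spanning +-extra_lag_s around alignment."""
    half = int(np.floor(extra_lag_s / tr_s))
    return np.arange(-half, half + 1)


def _offset_slices(j: int, n: int):
    if j >= 0:
        return slice(0, n - j), slice(j, n)
    return slice(-j, n), slice(0, n + j)


def xcorr_max(hr: HrTrace, neural, tr_s: Optional[float] = None,
              extra_lag_s: float = 10.0,
              min_overlap: int = MIN_XCORR_OVERLAP,
              subject: str = "", condition: str = "",
              target: str = "") -> CoherenceRecord:
    """Maximum positive cross-correlation over a whole-TR delay grid.

    ``hr`` carries the hemodynamic lag; the grid of candidate index offsets
    j spans +-``extra_lag_s`` around that alignment (positive j pairs the
    neural sample j TRs later than the HR sample, i.e. HR preceding BOLD by
    more than the hemodynamic lag).  The Pearson correlation is computed on
    each overlap (at least ``min_overlap`` samples); the returned value is
    the Fisher z of the maximum positive r, and ``lag_s_at_max`` is the
    raw-HR-to-BOLD delay ``hr.applied_lag_s + j*tr`` (positive = HR precedes
    BOLD; the search therefore reaches ``lag + extra`` = 16 s with the
    defaults).  With no positive r anywhere, the value is 0 with flag
    ``no_positive_peak``.
    """
    nv = neural.values if hasattr(neural, "values") else np.asarray(neural, float)
    tr = tr_s if tr_s is not None else hr.tr_s
    hv = hr.values
    n = min(len(hv), len(nv))
    grid = _xcorr_grid(tr, extra_lag_s)
    grid = grid[n - np.abs(grid) >= min_overlap]
    if len(grid) == 0:
        raise ValueError("overlap shorter than the minimum at every lag")
    best_r, best_j = -np.inf, None
    for j in grid:
        sh, sn = _offset_slices(int(j), n)
        r = _pearson(hv[sh], nv[sn])
        if r > best_r:
            best_r, best_j = r, int(j)
    if best_r <= 0:
        return CoherenceRecord(subject, condition, target, "xcorr_max_z", 0.0,
                               lag_s_at_max=None, n_timepoints_used=n,
                               flags="no_positive_peak")
    z = float(np.arctanh(np.clip(best_r, -FISHER_CLIP, FISHER_CLIP)))
    return CoherenceRecord(subject, condition, target, "xcorr_max_z", z,
                           lag_s_at_max=float(hr.applied_lag_s + best_j * tr),
                           n_timepoints_used=n - abs(best_j))


def lag_map(vol: Volume4D, hr: HrTrace, extra_lag_s: float = 10.0,
            min_overlap: int = MIN_XCORR_OVERLAP) -> LagMap:
    """xcorr_max for every in-brain voxel of a residualized volume.

    The brain mask is the set of voxels with nonzero temporal variance.
    Voxels with no positive correlation at any lag get z = 0 and lag NaN.
    """
    nt = vol.n_vols
    hv = hr.values[:nt]
    n = len(hv)
    flat = vol.data.reshape(-1, nt)[:, :n]
    var = flat.var(axis=1)
    brain = var > 0
    grid = _xcorr_grid(hr.tr_s, extra_lag_s)
    grid = grid[n - np.abs(grid) >= min_overlap]
    if len(grid) == 0:
        raise ValueError("overlap shorter than the minimum at every lag")

    Y = flat[brain]
    best_r = np.full(Y.shape[0], -np.inf)
    best_j = np.zeros(Y.shape[0], dtype=int)
    for j in grid:
        sh, sn = _offset_slices(int(j), n)
        h = hv[sh]
        h = h - h.mean()
        hn = np.sqrt(h @ h)
        seg = Y[:, sn]
        seg = seg - seg.mean(axis=1, keepdims=True)
        denom = hn * np.sqrt(np.einsum("ij,ij->i", seg, seg))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (seg @ h) / denom
        r = np.nan_to_num(r, nan=-np.inf)
        better = r > best_r
        best_r[better] = r[better]
        best_j[better] = j

    z = np.zeros(Y.shape[0])
    lag = np.full(Y.shape[0], np.nan)
    positive = best_r > 0
    z[positive] = np.arctanh(np.clip(best_r[positive], -FISHER_CLIP, FISHER_CLIP))
    lag[positive] = hr.applied_lag_s + best_j[positive] * hr.tr_s

    shape3 = vol.data.shape[:3]
    z_full = np.zeros(flat.shape[0])
    lag_full = np.full(flat.shape[0], np.nan)
    z_full[brain] = z
    lag_full[brain] = lag
    return LagMap(z=z_full.reshape(shape3), lag_s=lag_full.reshape(shape3),
                  affine=vol.affine.copy(), brain_mask=brain.reshape(shape3),
                  search_lags_s=hr.applied_lag_s + grid * hr.tr_s)
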