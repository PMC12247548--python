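"""Cardiac preprocessing: from a raw BPM series to an analysis-ready trace.

The fixed chain is: interpolate missing samples (cubic spline interior,
backward/forward fill at the edges) -> Savitzky-Golay smoothing -> resample
onto the fMRI TR grid with a hemodynamic lag (default 6 s, applied in
continuous time) -> Legendre-polynomial detrending (order matched to the
paired fMRI run via the one-order-per-150-s rule) -> z-normalization.
Heart-rate *variability* is deliberately out of scope: the coherence
measures downstream work on second-to-second BPM dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

from .io_formats import BpmSeries

__all__ = [
    "HrTrace",
    "interpolate_gaps",
    "savgol_smooth",
    "resample_with_lag",
    "legendre_detrend",
    "auto_polort_order",
    "zscore",
    "prepare_hr",
]


@dataclass
class HrTrace:
    """A heart-rate trace on the TR grid, optionally lagged / detrended / z-scored."""

    values: np.ndarray
    tr_s: float
    applied_lag_s: float = 0.0
    detrend_order: int = -1  # -1 = not detrended
    z_normalized: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("HrTrace values must be 1D")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.z_normalized and len(self.values) >= 2:
            sd = self.values.std(ddof=1)
            if abs(self.values.mean()) > 1e-9 or (sd > 0 and abs(sd - 1) > 1e-9):
                raise ValueError("z_normalized trace must have mean 0, sd 1")

    def __len__(self) -> int:
        return len(self.values)


def interpolate_gaps(series: BpmSeries) -> BpmSeries:
    """Fill missing BPM samples.

    Interior gaps use a cubic spline through the valid samples; gaps before
    the first (after the last) valid sample take the first (last) valid
    value.  With fewer than 4 valid samples the spline is underdetermined and
    linear interpolation is used instead (flagged in provenance).  Valid
    samples are returned unchanged.
    """
    valid = ~series.missing_mask
    n_valid = int(valid.sum())
    if n_valid < 2:
        raise ValueError("need at least 2 valid samples to interpolate")
    if not series.missing_mask.any():
        return series

    t, y = series.sample_times, series.values.copy()
    tv, yv = t[valid], series.values[valid]
    method = "cubic_spline"
    if n_valid < 4:
        method = "linear_fallback"
        interp = lambda q: np.interp(q, tv, yv)  # noqa: E731
    else:
        spline = CubicSpline(tv, yv)
        interp = spline

    missing_idx = np.flatnonzero(series.missing_mask)
    first_valid, last_valid = tv[0], tv[-1]
    for i in missing_idx:
        ti = t[i]
        if ti < first_valid:
            y[i] = yv[0]  # backward fill with first valid point
        elif ti > last_valid:
            y[i] = yv[-1]  # forward fill with last valid point
        else:
            y[i] = interp(ti)

    prov = dict(series.provenance)
    prov["gap_fill"] = {"method": method, "n_filled": len(missing_idx)}
    return BpmSeries(t, y, np.zeros_like(series.missing_mask), series.rate_hz,
                     provenance=prov)


def savgol_smooth(series: BpmSeries, window: int = 15, polyorder: int = 3) -> BpmSeries:
    """Savitzky-Golay smoothing of a gap-free BPM series.

    Defaults (window 15 samples = 15 s at 1 Hz, cubic) suit heart-rate
    smoothing scales; edges are handled by polynomial fits on truncated
    windows, so polynomials of degree <= polyorder pass through unchanged.
    """
    if series.missing_mask.any():
        raise ValueError("smooth requires a gap-free series; interpolate first")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > len(series):
        raise ValueError("window exceeds series length")
    smoothed = savgol_filter(series.values, window, polyorder, mode="interp")
    prov = dict(series.provenance)
    prov["savgol"] = {"window": window, "polyorder": polyorder}
    return BpmSeries(series.sample_times, smoothed, series.missing_mask,
                     series.rate_hz, provenance=prov)


def resample_with_lag(series: BpmSeries, tr_s: float, n_vols: int,
                      lag_s: float = 6.0) -> HrTrace:
    """Evaluate the BPM interpolant on the TR grid, shifted by a hemodynamic lag.

    The continuous interpolant of the (gap-free) series is evaluated at
    t_k = k*tr_s - lag_s.  Times before the first sample take the first
    value, so the lag pads the head; the shift is exact in seconds, never
    rounded to whole TRs.  Requesting more than 2 s beyond the series span
    is an error.
    """
    if series.missing_mask.any():
        raise ValueError("resample requires a gap-free series")
    if tr_s <= 0 or n_vols < 1:
        raise ValueError("tr_s must be positive and n_vols >= 1")
    t, y = series.sample_times, series.values
    t_query = np.arange(n_vols) * tr_s - lag_s
    overshoot = t_query[-1] - t[-1]
    if overshoot > 2.0:
        raise ValueError(
            f"requested grid extends {overshoot:.2f}s beyond the BPM series "
            "(limit 2 s)")
    if len(t) >= 4:
        interp = CubicSpline(t, y)
        vals = np.asarray(interp(np.clip(t_query, t[0], t[-1])))
    else:
        vals = np.interp(t_query, t, y)
    prov = dict(series.provenance)
    prov["resample"] = {"tr_s": tr_s, "n_vols": n_vols, "lag_s": lag_s}
    return HrTrace(vals, tr_s, applied_lag_s=lag_s, provenance=prov)


def _legendre_design(n: int, order: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n)
    return npleg.legvander(x, order)


def legendre_detrend(values: np.ndarray, order: int) -> np.ndarray:
    """Residual after least-squares projection onto Legendre polynomials 0..order."""
    y = np.asarray(values, dtype=float)
    if y.ndim != 1:
        raise ValueError("expected a 1D series")
    if order >= len(y):
        raise ValueError("detrend order must be below series length")
    if order < 0:
        return y.copy()
    X = _legendre_design(len(y), order)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient detrending basis")
    return y - X @ coef


def auto_polort_order(duration_s: float, seconds_per_order: float = 150.0) -> int:
    """Automatic drift-polynomial order: 1 + floor(duration / 150 s).

    This is the standard automatic rule for choosing how many low-frequency
    drift polynomials to remove from a run of a given length (an 8 min run
    gets order 4, a 5.5 min run order 3).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    return 1 + math.floor(duration_s / seconds_per_order)


def zscore(values: np.ndarray) -> np.ndarray:
    """Z-normalize with the n-1 denominator; constant input is an error."""
    y = np.asarray(values, dtype=float)
    if len(y) < 2:
        raise ValueError("zscore needs at least 2 samples")
    sd = y.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("constant series: z-score undefined")
    return (y - y.mean()) / sd


def prepare_hr(series: BpmSeries, tr_s: float, n_vols: int, lag_s: float = 6.0,
               savgol_window: int = 15, savgol_polyorder: int = 3,
               detrend_order: int | None = None,
               seconds_per_order: float = 150.0) -> HrTrace:
    """Run the full cardiac chain: interpolate -> smooth -> resample(+lag)
    -> detrend -> z-normalize.

    ``detrend_order`` defaults to the automatic rule applied to the paired
    fMRI run's duration (n_vols * tr_s), matching the detrending used on the
    neural side.
    """
    filled = interpolate_gaps(series)
    window = min(savgol_window, len(filled) - (1 - len(filled) % 2))
    if window % 2 == 0:
        window -= 1
    smoothed = savgol_smooth(filled, window=window, polyorder=min(savgol_polyorder, window - 1))
    trace = resample_with_lag(smoothed, tr_s, n_vols, lag_s)
    if detrend_order is None:
        detrend_order = auto_polort_order(n_vols * tr_s, seconds_per_order)
    detrended = legendre_detrend(trace.values, detrend_order)
    z = zscore(detrended)
    prov = dict(trace.provenance)
    prov["detrend_order"] = detrend_order
    prov["z_normalized"] = True
    return HrTrace(z, tr_s, applied_lag_s=lag_s, detrend_order=detrend_order,
                   z_normalized=True, provenance=prov)
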