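"""Domain containers and file I/O for the brain-heart coherence pipeline.

Everything the pipeline reads or writes passes through here: beats-per-minute
tables, NIfTI volumes and ROI masks, nuisance-regressor tables, coherence /
group-result tables, and the run configuration.  Readers validate the type
invariants and raise named errors instead of silently coercing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BpmSeries",
    "Volume4D",
    "RoiMask",
    "NuisanceSet",
    "RunConfig",
    "read_bpm",
    "write_bpm",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_records",
    "read_records",
    "expand_motion24",
]

_SPACING_TOL_S = 1e-6


@dataclass
class BpmSeries:
    """A beats-per-minute series sampled at a fixed rate (nominally 1 Hz).

    ``missing_mask`` is True where the sample is absent; ``values`` must be
    finite wherever the mask is False.
    """

    sample_times: np.ndarray  # seconds from scan start
    values: np.ndarray  # beats per minute
    missing_mask: np.ndarray  # True where sample missing
    rate_hz: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.sample_times.ndim != 1 or len(self.sample_times) < 2:
            raise ValueError("BpmSeries requires at least 2 samples")
        if not (len(self.sample_times) == len(self.values) == len(self.missing_mask)):
            raise ValueError("BpmSeries field lengths differ")
        dt = np.diff(self.sample_times)
        if np.any(dt <= 0):
            raise ValueError("non-monotone sample times")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if np.any(np.abs(dt - 1.0 / self.rate_hz) > _SPACING_TOL_S):
            raise ValueError("sample times not uniformly spaced at 1/rate_hz")
        valid = ~self.missing_mask
        if not np.all(np.isfinite(self.values[valid])):
            raise ValueError("non-finite value at a non-missing sample")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_valid(self) -> int:
        return int(np.sum(~self.missing_mask))

    @property
    def duration_s(self) -> float:
        return float(self.sample_times[-1] - self.sample_times[0])


@dataclass
class Volume4D:
    """A 4D BOLD grid (x, y, z, t) with spatial metadata and repetition time."""

    data: np.ndarray
    affine: np.ndarray  # 4x4 grid-to-world map
    tr_s: float
    voxel_size_mm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected a 4D grid, got {self.data.ndim}D")
        if min(self.data.shape[:3]) < 1 or self.data.shape[3] < 2:
            raise ValueError("spatial dims must be >=1 and time dim >=2")
        if self.tr_s <= 0:
            raise ValueError("missing TR: tr_s must be positive")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if self.voxel_size_mm is None:
            self.voxel_size_mm = np.linalg.norm(self.affine[:3, :3], axis=0)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_vols(self) -> int:
        return self.data.shape[3]


@dataclass
class RoiMask:
    """A boolean 3D mask on the same grid as its companion volume."""

    data: np.ndarray
    label: str
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise ValueError(f"mask '{self.label}' has no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class NuisanceSet:
    """Motion and tissue nuisance regressors for one run.

    ``derived24`` is the 24-parameter motion expansion: the 6 raw parameters,
    their temporal derivatives (first differences, leading row zero), and the
    element-wise squares of all 12.
    """

    motion6: np.ndarray  # (n_vols, 6)
    csf_mean: np.ndarray  # (n_vols,)
    wm_mean: np.ndarray  # (n_vols,)
    derived24: np.ndarray = None  # (n_vols, 24), built if absent

    def __post_init__(self) -> None:
        self.motion6 = np.atleast_2d(np.asarray(self.motion6, dtype=float))
        self.csf_mean = np.asarray(self.csf_mean, dtype=float).ravel()
        self.wm_mean = np.asarray(self.wm_mean, dtype=float).ravel()
        if self.motion6.shape[1] != 6:
            raise ValueError("motion6 must have 6 columns")
        n = self.motion6.shape[0]
        if len(self.csf_mean) != n or len(self.wm_mean) != n:
            raise ValueError("nuisance column lengths differ")
        if self.derived24 is None:
            self.derived24 = expand_motion24(self.motion6)
        else:
            self.derived24 = np.asarray(self.derived24, dtype=float)
            if self.derived24.shape != (n, 24):
                raise ValueError("derived24 must be (n_vols, 24)")
            expected = expand_motion24(self.motion6)
            if not np.allclose(self.derived24, expected, atol=1e-8):
                raise ValueError("derived24 inconsistent with motion6 expansion")

    @property
    def n_vols(self) -> int:
        return self.motion6.shape[0]


def expand_motion24(motion6: np.ndarray) -> np.ndarray:
    """6 motion parameters -> 24: raw, derivatives (leading zero), squares."""
    m = np.atleast_2d(np.asarray(motion6, dtype=float))
    if m.shape[1] != 6:
        raise ValueError("expected 6 motion columns")
    deriv = np.vstack([np.zeros((1, 6)), np.diff(m, axis=0)])
    raw12 = np.hstack([m, deriv])
    return np.hstack([raw12, raw12**2])


@dataclass
class RunConfig:
    """Run-wide analysis parameters.

    Defaults mirror the study design: TR 0.7 s, 6 s hemodynamic lag applied
    to the heart-rate series, 29-TR (20.3 s) connectivity window, 14-TR
    (~10 s) Sakoe-Chiba band, an extra 10 s lag for the voxel-wise
    cross-correlation search, 6 mm FWHM smoothing for voxel-wise analyses,
    one drift polynomial order per 150 s of run, two-tailed alpha .05 and
    cluster-forming voxel p .001.
    """

    tr_s: float = 0.7
    lag_s: float = 6.0
    window_trs: int = 29
    band_trs: int = 14
    extra_hr_lag_s: float = 10.0
    smooth_fwhm_mm: float = 6.0
    detrend_seconds_per_order: float = 150.0
    alpha: float = 0.05
    voxel_p: float = 0.001
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tr_s", "window_trs", "extra_hr_lag_s",
                     "detrend_seconds_per_order"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.band_trs < 0:
            raise ValueError("band_trs must be >= 0")
        if self.lag_s < 0 or self.smooth_fwhm_mm < 0:
            raise ValueError("lag_s and smooth_fwhm_mm must be >= 0")
        for name in ("alpha", "voxel_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_bpm(path: Union[str, Path]) -> BpmSeries:
    """Read a two-column (time_s, bpm) text table into a BpmSeries.

    Missing samples are rows whose bpm field is empty or non-finite; the
    sampling rate is inferred from the median spacing.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.strip().lower(): c for c in df.columns}
    if "time_s" not in cols or "bpm" not in cols:
        raise ValueError(f"{path}: expected columns time_s,bpm")
    times = pd.to_numeric(df[cols["time_s"]], errors="raise").to_numpy(float)
    bpm = pd.to_numeric(df[cols["bpm"]], errors="coerce").to_numpy(float)
    if len(times) < 2:
        raise ValueError(f"{path}: fewer than 2 samples")
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: non-monotone times")
    missing = ~np.isfinite(bpm)
    rate = 1.0 / float(np.median(np.diff(times)))
    return BpmSeries(times, np.where(missing, np.nan, bpm), missing, rate_hz=rate)


def write_bpm(series: BpmSeries, path: Union[str, Path]) -> None:
    df = pd.DataFrame({
        "time_s": series.sample_times,
        "bpm": np.where(series.missing_mask, np.nan, series.values),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_volume(path: Union[str, Path], tr_s: Optional[float] = None) -> Volume4D:
    """Read a 4D NIfTI-1 file; ``tr_s`` overrides a missing/zero header TR."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    tr = tr_s if tr_s is not None else header_tr
    if tr <= 0:
        raise ValueError(f"{path}: missing TR (header TR={header_tr}); pass tr_s")
    return Volume4D(data=data, affine=np.asarray(img.affine), tr_s=tr)


def write_volume(vol: Volume4D, path: Union[str, Path]) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = vol.tr_s
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_mask(path: Union[str, Path], label: str,
              companion: Optional[Volume4D] = None) -> RoiMask:
    """Read a NIfTI mask (nonzero = inside) on the companion volume's grid."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: mask must be 3D")
    if companion is not None and data.shape != companion.data.shape[:3]:
        raise ValueError(
            f"{path}: mask shape {data.shape} != volume spatial shape "
            f"{companion.data.shape[:3]}")
    return RoiMask(data=data > 0, label=label, affine=np.asarray(img.affine))


def write_mask(mask: RoiMask, path: Union[str, Path]) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


_RECORD_SORT = ["subject", "condition", "target", "measure"]


def write_records(records: Sequence, path: Union[str, Path]) -> None:
    """Write CoherenceRecord or GroupResult dataclasses as a sorted TSV."""
    path = Path(path)
    if len(records) == 0:
        path.write_text("\t".join(_RECORD_SORT) + "\n")
        return
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise ValueError("record list must be homogeneous")
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    sort_cols = [c for c in _RECORD_SORT if c in df.columns]
    if not sort_cols:
        sort_cols = [c for c in ("target", "measure") if c in df.columns]
    df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_records(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
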