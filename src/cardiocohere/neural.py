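"""fMRI denoising: nuisance-GLM residualization, ROI extraction, smoothing.

The denoising model regresses each voxel/ROI series on Legendre drift
polynomials, CSF and WM mean signals, and the 24-parameter motion expansion,
and keeps the residual.  Spatial smoothing (to a target FWHM) is applied only
on the voxel-wise branch of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .cardiac import _legendre_design, zscore
from .io_formats import NuisanceSet, RoiMask, Volume4D

__all__ = [
    "NeuralSeries",
    "build_nuisance_matrix",
    "residualize",
    "extract_roi_mean",
    "gaussian_smooth",
    "resample_mask_to_grid",
]

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class NeuralSeries:
    """A single time series on the TR grid: one ROI, one edge, or one voxel."""

    values: np.ndarray
    tr_s: float
    source: str = ""
    z_normalized: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("NeuralSeries values must be 1D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in series '{self.source}'")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    def __len__(self) -> int:
        return len(self.values)

    def zscored(self) -> "NeuralSeries":
        return NeuralSeries(zscore(self.values), self.tr_s, self.source,
                            z_normalized=True, provenance=dict(self.provenance))


def build_nuisance_matrix(nuis: NuisanceSet, n_vols: int,
                          polort_order: int) -> np.ndarray:
    """Assemble the denoising design: drift + CSF + WM + 24 motion columns.

    Columns are [Legendre 0..polort_order | csf | wm | motion24].  A
    condition number above 1e10 raises an error naming near-duplicate
    columns.
    """
    if nuis.n_vols != n_vols:
        raise ValueError(
            f"nuisance length {nuis.n_vols} != n_vols {n_vols}")
    drift = _legendre_design(n_vols, polort_order)
    X = np.hstack([
        drift,
        nuis.csf_mean[:, None],
        nuis.wm_mean[:, None],
        nuis.derived24,
    ])
    names = ([f"legendre_{k}" for k in range(polort_order + 1)]
             + ["csf", "wm"]
             + [f"motion_{k}" for k in range(1, 25)])
    cond = np.linalg.cond(X)
    if cond > 1e10:
        raise ValueError(
            "collinear nuisance design (condition number "
            f"{cond:.3g}): {_collinear_pairs(X, names)}")
    return X


def _collinear_pairs(X: np.ndarray, names: List[str]) -> str:
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    Xn = X / norms
    gram = np.abs(Xn.T @ Xn)
    pairs = []
    for i in range(X.shape[1]):
        for j in range(i + 1, X.shape[1]):
            if gram[i, j] > 1 - 1e-8:
                pairs.append(f"{names[i]}~{names[j]}")
    return ", ".join(pairs) if pairs else "no single offending pair found"


def residualize(y: Union[np.ndarray, Volume4D],
                X: np.ndarray) -> Union[np.ndarray, Volume4D]:
    """OLS residual of y (series, series matrix, or Volume4D) on design X."""
    X = np.asarray(X, dtype=float)
    if isinstance(y, Volume4D):
        nt = y.n_vols
        flat = y.data.reshape(-1, nt).T  # (t, voxels)
        resid = _residualize_matrix(flat, X)
        out = resid.T.reshape(y.data.shape)
        return Volume4D(out, y.affine.copy(), y.tr_s)
    arr = np.asarray(y, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    resid = _residualize_matrix(arr, X)
    return resid[:, 0] if squeeze else resid


def _residualize_matrix(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    if X.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"design rows {X.shape[0] if X.ndim == 2 else '?'} != time length "
            f"{Y.shape[0]}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def extract_roi_mean(vol: Volume4D, mask: RoiMask) -> NeuralSeries:
    """Per-TR unweighted mean over in-mask voxels."""
    if mask.data.shape != vol.data.shape[:3]:
        raise ValueError(
            f"mask shape {mask.data.shape} != volume spatial shape "
            f"{vol.data.shape[:3]}")
    values = vol.data[mask.data].mean(axis=0)
    return NeuralSeries(values, vol.tr_s, source=mask.label)


def gaussian_smooth(vol: Volume4D, fwhm_mm: float) -> Volume4D:
    """Per-volume 3D Gaussian smoothing to the given FWHM (mm).

    sigma per axis is fwhm / sqrt(8 ln 2) divided by the voxel size;
    reflecting boundaries keep the per-volume sum conserved.  fwhm 0 is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return Volume4D(vol.data.copy(), vol.affine.copy(), vol.tr_s)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vol.voxel_size_mm
    out = gaussian_filter(vol.data, sigma=tuple(sigma_vox) + (0.0,),
                          mode="reflect")
    return Volume4D(out, vol.affine.copy(), vol.tr_s)


def resample_mask_to_grid(mask: RoiMask, target: Volume4D) -> RoiMask:
    """Nearest-neighbour resample of a mask onto the target volume's grid.

    Each target voxel center is mapped to world space and back through the
    mask's affine; it is inside the resampled mask when its nearest mask
    voxel is inside.  Disjoint fields of view are an error.
    """
    nx, ny, nz = target.data.shape[:3]
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel(),
                    np.ones(ii.size)], axis=0).astype(float)
    world = target.affine @ vox
    src = np.linalg.inv(mask.affine) @ world
    idx = np.round(src[:3]).astype(int)
    shape = np.array(mask.data.shape)
    inside = np.all((idx >= 0) & (idx < shape[:, None]), axis=0)
    if not inside.any():
        raise ValueError("mask and target fields of view are disjoint")
    values = np.zeros(vox.shape[1], dtype=bool)
    sel = idx[:, inside]
    values[inside] = mask.data[sel[0], sel[1], sel[2]]
    out = values.reshape(nx, ny, nz)
    if not out.any():
        raise ValueError(
            f"mask '{mask.label}' resamples to zero voxels on the target grid")
    return RoiMask(out, mask.label, target.affine.copy())
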