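"""Synthetic two-condition (plus rest) heart-rate + neural data generator.

Every downstream stage is exercised against data with *known* brain-heart
coupling.  The generator emulates the study conditions: ~29 subjects, a
suspenseful movie (480 s), a non-suspenseful movie (330 s) and rest (420 s)
at TR 0.7 s; 1 Hz BPM series with a subject baseline (mean 66, between-
subject sd 9 bpm), condition mean offsets (suspense above control), slow
sinusoidal drift, AR(1) fluctuation and missing-completely-at-random
samples; ROI BOLD coupled to the z-scored heart rate at a 6 s hemodynamic
lag on standardized signals, so the population correlation with the lagged
regressor is beta / sqrt(beta^2 + sigma^2); ROI pairs whose shared-signal
gain is modulated by lagged heart rate with a condition-dependent slope
(positive coupling in the control condition, negative under suspense by
default); and small 4D volumes where a contiguous blob carries the lagged
signal over scanner drift + thermal noise.

Everything is reproducible from the config seed; per subject x condition
streams are spawned deterministically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cardiac import zscore
from .io_formats import BpmSeries, RoiMask, Volume4D, write_bpm, write_volume
from .neural import NeuralSeries

__all__ = ["SimConfig", "SimTruth", "ROI_LABELS", "CONDITIONS",
           "simulate_hr", "lagged_z_regressor", "simulate_roi_bold",
           "simulate_coupled_edge", "simulate_volume", "simulate_study"]

# The 10-region "defensive response network".
ROI_LABELS = ("amygdala_L", "amygdala_R", "ant_insula_L", "ant_insula_R",
              "dmPFC", "vmPFC", "sgACC", "BNST", "hypothalamus", "PAG")

CONDITIONS = ("suspense", "control", "rest")
_COND_INDEX = {c: i for i, c in enumerate(CONDITIONS)}

STUDY_ENROLLED = 55
STUDY_EXCLUDED_CARDIAC = 26  # oximeter-noise exclusions upstream


def _stable_hash(text: str) -> int:
    # str hash() is salted per interpreter run; CRC keeps streams reproducible
    import zlib
    return zlib.crc32(text.encode()) % 1000


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_subjects: int = STUDY_ENROLLED - STUDY_EXCLUDED_CARDIAC  # 29 retained
    duration_s: Dict[str, float] = field(default_factory=lambda: {
        "suspense": 480.0, "control": 330.0, "rest": 420.0})
    tr_s: float = 0.7
    hr_base_bpm: float = 66.0
    hr_base_sd_bpm: float = 9.0
    hr_condition_offset_bpm: Dict[str, float] = field(default_factory=lambda: {
        "suspense": 1.41, "control": -1.41, "rest": 0.53})
    hr_ar_coef: float = 0.9
    hr_noise_sd: float = 1.5  # stationary sd of the AR(1) fluctuation, bpm
    hr_drift_amp_bpm: float = 2.0
    hr_drift_period_s: float = 120.0
    coupling_lag_s: float = 6.0
    # standardized HR->BOLD coupling per condition (activity branch)
    activity_coupling: Dict[str, float] = field(default_factory=lambda: {
        "suspense": -0.3, "control": 0.3, "rest": 0.0})
    # gain-modulation of shared ROI-pair signal: gain = clip(a + b*zHR, 0, gmax)
    connectivity_gain_base: float = 0.6
    connectivity_coupling: Dict[str, float] = field(default_factory=lambda: {
        "suspense": -0.4, "control": 0.4, "rest": 0.0})
    connectivity_gain_max: float = 2.0
    drift_order: int = 3
    drift_amp: float = 0.5  # bold drift coefficient scale (standardized units)
    noise_sd: float = 1.0
    missing_frac: float = 0.05
    volume_grid: Tuple[int, int, int] = (12, 12, 12)
    volume_blob_halfwidth: int = 1  # blob = (2h+1)^3 cube
    volume_blob_coupling: float = 1.0
    volume_blob_lag_s: float = 6.0
    voxel_size_mm: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_frac < 0.5:
            raise ValueError("missing_frac must lie in [0, 0.5)")
        if abs(self.hr_ar_coef) >= 1:
            raise ValueError("|hr_ar_coef| must be < 1")
        if any(v < 60 for v in self.duration_s.values()):
            raise ValueError("condition durations must be >= 60 s")
        if self.n_subjects < 1 or self.tr_s <= 0:
            raise ValueError("n_subjects >= 1 and tr_s > 0 required")

    def n_vols(self, condition: str) -> int:
        return int(np.floor(self.duration_s[condition] / self.tr_s))

    def rng(self, subject: int, condition: str, stream: int = 0) -> np.random.Generator:
        cond_key = _COND_INDEX.get(condition, 3 + _stable_hash(condition))
        key = (self.seed, subject, cond_key, stream)
        return np.random.default_rng(np.random.SeedSequence(key))

    def subject_rng(self, subject: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, subject, 999)))


@dataclass
class SimTruth:
    """Ground truth for one subject x condition draw."""

    subject: str
    condition: str
    latent_hr: np.ndarray  # dense 1 Hz path, no noise masking
    latent_times_s: np.ndarray
    coupling_lag_s: float
    activity_coupling: float
    connectivity_coupling: float


def simulate_hr(cfg: SimConfig, subject: int,
                condition: str) -> Tuple[BpmSeries, np.ndarray]:
    """1 Hz BPM series and its latent (unmasked) path.

    BPM = subject baseline + condition offset + slow sinusoidal drift +
    stationary AR(1) fluctuation; a ``missing_frac`` of samples (never the
    first or last) are masked at random.
    """
    if condition not in cfg.duration_s:
        raise ValueError(f"unknown condition '{condition}'")
    base = cfg.hr_base_bpm + cfg.hr_base_sd_bpm * cfg.subject_rng(subject).standard_normal()
    rng = cfg.rng(subject, condition, stream=0)
    duration = cfg.duration_s[condition]
    t = np.arange(0.0, np.floor(duration) + 1.0)
    phase = rng.uniform(0, 2 * np.pi)
    drift = cfg.hr_drift_amp_bpm * np.sin(2 * np.pi * t / cfg.hr_drift_period_s + phase)

    rho = cfg.hr_ar_coef
    ar = np.zeros(len(t))
    if cfg.hr_noise_sd > 0:
        innov_sd = cfg.hr_noise_sd * np.sqrt(1 - rho**2)
        eps = rng.normal(0, innov_sd, len(t))
        ar[0] = rng.normal(0, cfg.hr_noise_sd)
        for k in range(1, len(t)):
            ar[k] = rho * ar[k - 1] + eps[k]

    latent = base + cfg.hr_condition_offset_bpm.get(condition, 0.0) + drift + ar
    missing = np.zeros(len(t), dtype=bool)
    n_missing = int(round(cfg.missing_frac * len(t)))
    if n_missing > 0:
        candidates = np.arange(1, len(t) - 1)
        missing[rng.choice(candidates, size=min(n_missing, len(candidates)),
                           replace=False)] = True
    values = np.where(missing, np.nan, latent)
    series = BpmSeries(t, values, missing, rate_hz=1.0,
                       provenance={"subject": subject, "condition": condition})
    return series, latent


def lagged_z_regressor(latent_hr: np.ndarray, latent_times_s: np.ndarray,
                       tr_s: float, n_vols: int, lag_s: float) -> np.ndarray:
    """Standardized lagged-HR regressor on the TR grid.

    The latent path is z-scored, evaluated at k*tr - lag (head clamped), and
    re-standardized so injected couplings are in exact correlation units.  A
    constant latent path yields a zero regressor.
    """
    if latent_hr.std(ddof=1) == 0:
        return np.zeros(n_vols)
    z = zscore(latent_hr)
    t_query = np.clip(np.arange(n_vols) * tr_s - lag_s,
                      latent_times_s[0], latent_times_s[-1])
    reg = np.interp(t_query, latent_times_s, z)
    if reg.std(ddof=1) == 0:
        return np.zeros(n_vols)
    return zscore(reg)


def _legendre_drift(n: int, order: int, amp: float,
                    rng: np.random.Generator) -> np.ndarray:
    from numpy.polynomial import legendre as npleg
    if order < 0 or amp == 0:
        return np.zeros(n)
    x = np.linspace(-1, 1, n)
    coef = rng.uniform(-amp, amp, order + 1)
    return npleg.legvander(x, order) @ coef


def simulate_roi_bold(cfg: SimConfig, latent_hr: np.ndarray,
                      latent_times_s: np.ndarray, roi: str, condition: str,
                      subject: int = 0,
                      coupling: Optional[float] = None) -> NeuralSeries:
    """Raw ROI series: beta * zHR(t - lag) + Legendre drift + white noise."""
    n_vols = cfg.n_vols(condition)
    beta = cfg.activity_coupling.get(condition, 0.0) if coupling is None else coupling
    reg = lagged_z_regressor(latent_hr, latent_times_s, cfg.tr_s, n_vols,
                             cfg.coupling_lag_s)
    rng = cfg.rng(subject, condition, stream=1 + _stable_hash(roi))
    drift = _legendre_drift(n_vols, cfg.drift_order, cfg.drift_amp, rng)
    noise = rng.normal(0, cfg.noise_sd, n_vols) if cfg.noise_sd > 0 else 0.0
    return NeuralSeries(beta * reg + drift + noise, cfg.tr_s, source=roi)


def simulate_coupled_edge(cfg: SimConfig, latent_hr: np.ndarray,
                          latent_times_s: np.ndarray,
                          edge: Tuple[str, str], condition: str,
                          subject: int = 0,
                          coupling: Optional[float] = None,
                          ) -> Tuple[NeuralSeries, NeuralSeries]:
    """Two ROI series whose time-varying correlation tracks lagged HR.

    A shared standard-normal latent s(t) enters both series with gain
    g(t) = clip(a + b * zHR(t - lag), 0, g_max) plus independent unit noise;
    a positive b makes the windowed correlation rise with lagged heart rate.
    """
    n_vols = cfg.n_vols(condition)
    b = cfg.connectivity_coupling.get(condition, 0.0) if coupling is None else coupling
    reg = lagged_z_regressor(latent_hr, latent_times_s, cfg.tr_s, n_vols,
                             cfg.coupling_lag_s)
    gain = np.clip(cfg.connectivity_gain_base + b * reg, 0.0,
                   cfg.connectivity_gain_max)
    roi_a, roi_b = edge
    rng = cfg.rng(subject, condition,
                  stream=2001 + _stable_hash(f"{roi_a}|{roi_b}"))
    shared = rng.standard_normal(n_vols)
    xa = gain * shared + rng.standard_normal(n_vols)
    xb = gain * shared + rng.standard_normal(n_vols)
    return (NeuralSeries(xa, cfg.tr_s, source=roi_a),
            NeuralSeries(xb, cfg.tr_s, source=roi_b))


def simulate_volume(cfg: SimConfig, latent_hr: np.ndarray,
                    latent_times_s: np.ndarray, condition: str,
                    subject: int = 0,
                    blob_coupling: Optional[float] = None,
                    ) -> Tuple[Volume4D, RoiMask]:
    """Small 4D volume with a coupled blob over drift + thermal noise."""
    n_vols = cfg.n_vols(condition)
    nx, ny, nz = cfg.volume_grid
    beta = cfg.volume_blob_coupling if blob_coupling is None else blob_coupling
    reg = lagged_z_regressor(latent_hr, latent_times_s, cfg.tr_s, n_vols,
                             cfg.volume_blob_lag_s)
    rng = cfg.rng(subject, condition, stream=5000)

    data = np.empty((nx, ny, nz, n_vols))
    drift_coefs = rng.uniform(-cfg.drift_amp, cfg.drift_amp,
                              (nx * ny * nz, cfg.drift_order + 1))
    from numpy.polynomial import legendre as npleg
    basis = npleg.legvander(np.linspace(-1, 1, n_vols), cfg.drift_order)
    data[:] = (drift_coefs @ basis.T).reshape(nx, ny, nz, n_vols)
    data += rng.normal(0, cfg.noise_sd, data.shape)

    cx, cy, cz = nx // 2, ny // 2, nz // 2
    h = cfg.volume_blob_halfwidth
    blob = np.zeros((nx, ny, nz), dtype=bool)
    blob[cx - h:cx + h + 1, cy - h:cy + h + 1, cz - h:cz + h + 1] = True
    data[blob] += beta * reg

    affine = np.diag([cfg.voxel_size_mm] * 3 + [1.0])
    vol = Volume4D(data, affine, cfg.tr_s)
    mask = RoiMask(blob, "blob", affine)
    return vol, mask


def simulate_study(cfg: SimConfig, out_dir: Optional[Path] = None,
                   rois: Sequence[str] = ROI_LABELS,
                   conditions: Optional[Sequence[str]] = None,
                   include_volumes: bool = False) -> dict:
    """Full multi-subject dataset with ground truth.

    Returns ``{"subjects": {sub: {cond: {...}}}, "truth": [SimTruth...],
    "config": cfg}``.  With ``edges="coupled"`` every ROI pair shares a
    gain-modulated latent (pairwise independent across edges is not
    modelled; downstream edge analyses draw each pair on demand).  When
    ``out_dir`` is given, per-subject BPM tables, ROI TSVs, optional
    volumes, and a truth manifest are written.
    """
    if conditions is None:
        conditions = tuple(cfg.duration_s.keys())
    out: dict = {"subjects": {}, "truth": [], "config": cfg}
    for s in range(cfg.n_subjects):
        sub_id = f"sub-{s + 1:02d}"
        out["subjects"][sub_id] = {}
        for cond in conditions:
            bpm, latent = simulate_hr(cfg, s, cond)
            roi_series = {
                roi: simulate_roi_bold(cfg, latent, bpm.sample_times, roi,
                                       cond, subject=s)
                for roi in rois
            }
            entry = {"bpm": bpm, "latent": latent, "rois": roi_series}
            if include_volumes:
                vol, blob = simulate_volume(cfg, latent, bpm.sample_times,
                                            cond, subject=s)
                entry["volume"] = vol
                entry["blob"] = blob
            out["subjects"][sub_id][cond] = entry
            out["truth"].append(SimTruth(
                subject=sub_id, condition=cond, latent_hr=latent,
                latent_times_s=bpm.sample_times,
                coupling_lag_s=cfg.coupling_lag_s,
                activity_coupling=cfg.activity_coupling.get(cond, 0.0),
                connectivity_coupling=cfg.connectivity_coupling.get(cond, 0.0)))

    if out_dir is not None:
        _write_study(out, Path(out_dir), include_volumes)
    return out


def _write_study(study: dict, out_dir: Path, include_volumes: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg: SimConfig = study["config"]
    for sub_id, conds in study["subjects"].items():
        sdir = out_dir / sub_id
        sdir.mkdir(exist_ok=True)
        for cond, entry in conds.items():
            write_bpm(entry["bpm"], sdir / f"{cond}_bpm.tsv")
            df = pd.DataFrame({roi: ns.values
                               for roi, ns in entry["rois"].items()})
            df.to_csv(sdir / f"{cond}_rois.tsv", sep="\t", index=False,
                      float_format="%.10g")
            if include_volumes and "volume" in entry:
                write_volume(entry["volume"], sdir / f"{cond}_bold.nii.gz")
    manifest = {
        "config": {k: (dict(v) if isinstance(v, dict) else
                       list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "truth": [{
            "subject": t.subject, "condition": t.condition,
            "coupling_lag_s": t.coupling_lag_s,
            "activity_coupling": t.activity_coupling,
            "connectivity_coupling": t.connectivity_coupling,
        } for t in study["truth"]],
    }
    (out_dir / "truth.json").write_text(json.dumps(manifest, indent=2))
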