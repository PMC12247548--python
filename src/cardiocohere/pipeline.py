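"""End-to-end orchestration: prep -> connectivity -> coherence -> group.

``run_pipeline`` walks a study directory (one folder per subject holding
per-condition BPM and ROI tables), runs the cardiac and neural chains,
builds dynamic-connectivity edges, computes the coherence records, fits the
paired group contrast, and emits a provenance manifest.  The stage order and
parameters come from a single :class:`~cardiocohere.io_formats.RunConfig`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .cardiac import auto_polort_order, legendre_detrend, prepare_hr, zscore, HrTrace
from .coherence import (CoherenceRecord, bivariate_coherence, dtw_coherence,
                        match_condition_lengths)
from .dynconn import all_edges
from .group import ConditionContrast, ContrastResults, GroupResult
from .io_formats import RunConfig, read_bpm, write_records
from .neural import NeuralSeries

__all__ = ["RunManifest", "run_pipeline", "report", "plot_d_matrix"]


@dataclass
class RunManifest:
    """Provenance for one pipeline run."""

    config: dict
    version: str
    seed: int
    started_at: str
    finished_at: str = ""
    input_hashes: Dict[str, str] = field(default_factory=dict)
    output_hashes: Dict[str, str] = field(default_factory=dict)
    stages: List[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _discover(data_dir: Path, conditions: Sequence[str]) -> Dict[str, Dict[str, Dict[str, Path]]]:
    layout: Dict[str, Dict[str, Dict[str, Path]]] = {}
    subjects = sorted(p for p in Path(data_dir).iterdir()
                      if p.is_dir() and p.name.startswith("sub-"))
    if not subjects:
        raise FileNotFoundError(f"no sub-* directories under {data_dir}")
    missing: List[str] = []
    for sdir in subjects:
        layout[sdir.name] = {}
        for cond in conditions:
            bpm = sdir / f"{cond}_bpm.tsv"
            rois = sdir / f"{cond}_rois.tsv"
            if not bpm.exists() or not rois.exists():
                missing.append(f"{sdir.name}/{cond}")
                continue
            entry = {"bpm": bpm, "rois": rois}
            nuis = sdir / f"{cond}_nuisance.tsv"
            if nuis.exists():
                entry["nuisance"] = nuis
            layout[sdir.name][cond] = entry
    if missing:
        raise FileNotFoundError(
            "missing subject/condition inputs: " + ", ".join(missing))
    return layout


def _prep_subject_condition(paths: Dict[str, Path], cfg: RunConfig,
                            ) -> Tuple[HrTrace, Dict[str, NeuralSeries]]:
    bpm = read_bpm(paths["bpm"])
    roi_df = pd.read_csv(paths["rois"], sep="\t")
    n_vols = len(roi_df)
    order = auto_polort_order(n_vols * cfg.tr_s, cfg.detrend_seconds_per_order)
    hr = prepare_hr(bpm, cfg.tr_s, n_vols, cfg.lag_s,
                    seconds_per_order=cfg.detrend_seconds_per_order)
    nuis_cols: Optional[np.ndarray] = None
    if "nuisance" in paths:
        nuis_cols = pd.read_csv(paths["nuisance"], sep="\t").to_numpy(float)
    rois: Dict[str, NeuralSeries] = {}
    for label in roi_df.columns:
        y = roi_df[label].to_numpy(float)
        resid = legendre_detrend(y, order)
        if nuis_cols is not None:
            from .neural import residualize
            resid = residualize(resid, np.hstack([np.ones((n_vols, 1)),
                                                  nuis_cols]))
        rois[label] = NeuralSeries(zscore(resid), cfg.tr_s, source=label,
                                   z_normalized=True)
    return hr, rois


def run_pipeline(cfg: RunConfig, data_dir: Path,
                 conditions: Sequence[str] = ("suspense", "control"),
                 measures: Sequence[str] = ("bivariate_z", "dtw_distance"),
                 out_dir: Optional[Path] = None,
                 contrast: Optional[Tuple[str, str]] = None) -> dict:
    """Execute the full analysis over a study directory.

    Returns ``{"records": [...], "results": ContrastResults, "manifest":
    RunManifest}``.  ROI activity and all-pairs dynamic-connectivity edges
    each get a bivariate Fisher-z coherence; DTW distances are computed on
    condition-length-matched series (the head of the longer condition is
    dropped so both contribute the same number of TRs).
    """
    data_dir = Path(data_dir)
    layout = _discover(data_dir, conditions)
    manifest = RunManifest(config=cfg.to_dict(), version=__version__,
                           seed=cfg.seed,
                           started_at=time.strftime("%Y-%m-%dT%H:%M:%S"))
    for sub, conds in layout.items():
        for cond, paths in conds.items():
            for kind, p in paths.items():
                manifest.input_hashes[f"{sub}/{cond}/{kind}"] = _sha256(p)

    prepped: Dict[str, Dict[str, dict]] = {}
    for sub, conds in layout.items():
        prepped[sub] = {}
        for cond, paths in conds.items():
            hr, rois = _prep_subject_condition(paths, cfg)
            edges = all_edges(list(rois.values()), cfg.window_trs)
            prepped[sub][cond] = {"hr": hr, "rois": rois,
                                  "edges": {e.label: e for e in edges}}
    manifest.stages += ["cardiac_prep", "neural_prep", "dynamic_connectivity"]

    min_len = min(len(entry["hr"])
                  for conds in prepped.values() for entry in conds.values())

    records: List[CoherenceRecord] = []
    for sub, conds in prepped.items():
        for cond, entry in conds.items():
            hr = entry["hr"]
            targets: Dict[str, np.ndarray] = {}
            for label, ns in entry["rois"].items():
                targets[label] = ns.values
            for label, es in entry["edges"].items():
                if es.degenerate:
                    continue
                targets[label] = es.values
            for label, values in targets.items():
                if "bivariate_z" in measures:
                    rec = bivariate_coherence(hr, values, subject=sub,
                                              condition=cond, target=label)
                    records.append(rec)
                if "dtw_distance" in measures:
                    # conditions differ in duration; drop the head of the
                    # longer so every condition contributes min_len TRs
                    h, _ = match_condition_lengths(hr.values,
                                                   np.empty(min_len))
                    v, _ = match_condition_lengths(values, np.empty(min_len))
                    records.append(dtw_coherence(
                        HrTrace(zscore(h), hr.tr_s,
                                applied_lag_s=hr.applied_lag_s,
                                z_normalized=True),
                        zscore(v), band_trs=cfg.band_trs, subject=sub,
                        condition=cond, target=label))
    manifest.stages.append("coherence")

    if contrast is None:
        contrast = tuple(conditions[:2])
    results = ConditionContrast(records, contrast=contrast,
                                alpha=cfg.alpha).fit()
    manifest.stages.append("group_inference")
    manifest.finished_at = time.strftime("%Y-%m-%dT%H:%M:%S")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rec_path = out_dir / "records.tsv"
        grp_path = out_dir / "group.tsv"
        write_records(records, rec_path)
        write_records(results.results, grp_path)
        manifest.output_hashes["records.tsv"] = _sha256(rec_path)
        manifest.output_hashes["group.tsv"] = _sha256(grp_path)
        manifest.write(out_dir / "manifest.json")

    return {"records": records, "results": results, "manifest": manifest}


def report(results: ContrastResults, measure: str = "bivariate_z") -> str:
    """Human-readable summary: contrast table plus the Cohen's d matrix.

    The matrix diagonal is heart-rate/activity coherence change, the lower
    triangle heart-rate/connectivity coherence change; ``**`` marks the
    Bonferroni-corrected (exploratory-family) threshold, ``*`` the
    uncorrected .05 level.
    """
    lines = [results.summary(), ""]
    df = results.table
    df_m = df[df["measure"] == measure]
    if df_m.empty:
        lines.append(f"(no {measure} results; d-matrix omitted)")
        return "\n".join(lines)
    mat = results.d_matrix(measure)
    ann = mat.copy().astype(object)
    lookup = {r.target: r for r in results.results if r.measure == measure}
    for i, row in enumerate(mat.index):
        for j, col in enumerate(mat.columns):
            if j > i or pd.isna(mat.iloc[i, j]):
                ann.iloc[i, j] = ""
                continue
            target = row if i == j else "-".join(sorted([row, col]))
            r = lookup.get(target)
            stars = ""
            if r is not None:
                if r.p_two_tailed < r.alpha_corrected:
                    stars = "**"
                elif r.p_two_tailed < results.model.alpha:
                    stars = "*"
            ann.iloc[i, j] = f"{mat.iloc[i, j]:+.2f}{stars}"
    lines.append(f"Cohen's d matrix ({measure}; diagonal = activity, "
                 "lower triangle = connectivity; ** corrected, * p<.05):")
    lines.append(ann.to_string())
    return "\n".join(lines)


def plot_d_matrix(results: ContrastResults, measure: str = "bivariate_z",
                  path: Optional[Path] = None):
    """Heatmap of the Cohen's d matrix (diagonal activity, lower triangle edges)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = results.d_matrix(measure)
    fig, ax = plt.subplots(figsize=(6, 5))
    data = np.ma.masked_invalid(mat.to_numpy(float))
    vmax = max(0.1, float(np.abs(data).max()))
    im = ax.imshow(data, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(mat.index)), mat.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Cohen's d")
    ax.set_title(f"Condition effect on brain-heart coherence ({measure})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
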