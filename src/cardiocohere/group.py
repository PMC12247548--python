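"""Group-level inference on coherence measures.

Paired two-tailed t-tests contrast each target x measure across conditions,
with paired Cohen's d (mean difference / sd of differences).  Bonferroni
families mirror the study design: the hypothesis family is the small set of
a-priori activation ROIs (alpha/5 with the defaults), and every other
roi/edge target falls in the exploratory family whose size is the total
count of activation + connectivity targets (55 for a 10-ROI network).

Voxel-wise lag-map contrasts are corrected by sign-flip permutation
cluster-extent thresholding: subject difference maps are randomly negated,
each permutation's maximum cluster extent (clusters formed two-tailed at the
voxel-wise p threshold) builds the null, and observed clusters survive when
their permutation-corrected p falls below alpha.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .coherence import CoherenceRecord

__all__ = [
    "GroupResult",
    "ClusterResult",
    "paired_t",
    "bonferroni",
    "contrast_table",
    "cluster_correct",
    "ConditionContrast",
    "ContrastResults",
    "HYPOTHESIS_ROIS",
]

logger = logging.getLogger(__name__)

# A-priori activation targets: bilateral amygdala, bilateral anterior
# insula, and dmPFC.
HYPOTHESIS_ROIS = ("amygdala_L", "amygdala_R", "ant_insula_L", "ant_insula_R",
                   "dmPFC")

_NN_STRUCTURES = {
    1: ndimage.generate_binary_structure(3, 1),  # faces
    2: ndimage.generate_binary_structure(3, 2),  # + edges
    3: ndimage.generate_binary_structure(3, 3),  # + corners
}


@dataclass
class GroupResult:
    """Paired-contrast statistics for one target x measure."""

    target: str
    measure: str
    contrast: str  # e.g. "suspense-control"
    t: float
    df: int
    p_two_tailed: float
    cohens_d: float
    family: str = "none"  # hypothesis | exploratory | none
    alpha_corrected: float = float("nan")
    significant_corrected: bool = False
    n_subjects: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_two_tailed <= 1:
            raise ValueError("p must lie in [0, 1]")
        if self.significant_corrected and not self.p_two_tailed < self.alpha_corrected:
            raise ValueError("significant_corrected requires p < alpha_corrected")


@dataclass
class ClusterResult:
    """One surviving cluster from the permutation-corrected lag-map contrast."""

    voxels: np.ndarray  # (k, 3) integer grid coordinates
    extent: int
    peak_world_mm: Tuple[int, int, int]
    peak_t: float
    corrected_p: float

    def __post_init__(self) -> None:
        if self.extent < 1:
            raise ValueError("extent must be >= 1")


def paired_t(diffs: np.ndarray) -> Tuple[float, int, float, float]:
    """t, df, two-tailed p, and paired Cohen's d of within-subject differences."""
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t undefined")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p), float(d.mean() / sd)


def bonferroni(family_size: int, alpha: float = 0.05) -> float:
    """Corrected per-test alpha: alpha divided by the family size."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return alpha / family_size


def _target_kind(target: str) -> str:
    return "edge" if "-" in target else "roi"


def contrast_table(records: Sequence[CoherenceRecord],
                   contrast: Tuple[str, str] = ("suspense", "control"),
                   alpha: float = 0.05,
                   hypothesis_rois: Sequence[str] = HYPOTHESIS_ROIS,
                   ) -> List[GroupResult]:
    """Paired contrasts for every target x measure present in the records.

    Subjects missing either condition for a target x measure are excluded
    listwise (logged); zero-variance differences are flagged and dropped.
    """
    cond_a, cond_b = contrast
    df = pd.DataFrame([{
        "subject": r.subject, "condition": r.condition, "target": r.target,
        "measure": r.measure, "value": r.value,
    } for r in records])
    if df.empty:
        raise ValueError("no records")
    df = df[df["condition"].isin(contrast)]
    contrast_name = f"{cond_a}-{cond_b}"
    hypothesis = set(hypothesis_rois)

    targets = df[["target", "measure"]].drop_duplicates()
    roi_edge_targets = {t for t in targets["target"].unique()}
    n_exploratory = len(roi_edge_targets)  # 10 ROIs + 45 edges = 55
    alpha_hyp = bonferroni(max(len(hypothesis & roi_edge_targets), 1), alpha)
    alpha_exp = bonferroni(max(n_exploratory, 1), alpha)

    results: List[GroupResult] = []
    n_excluded_total = 0
    for (target, measure), sub in df.groupby(["target", "measure"], sort=True):
        wide = sub.pivot_table(index="subject", columns="condition",
                               values="value", aggfunc="first")
        if cond_a not in wide.columns or cond_b not in wide.columns:
            continue
        complete = wide.dropna(subset=[cond_a, cond_b])
        n_excluded = len(wide) - len(complete)
        n_excluded_total += n_excluded
        if len(complete) < 3:
            raise ValueError(
                f"fewer than 3 complete subjects for {target}/{measure}")
        diffs = (complete[cond_a] - complete[cond_b]).to_numpy()
        if np.ptp(diffs) == 0 and diffs.std() == 0:
            logger.warning("zero-variance differences for %s/%s: excluded",
                           target, measure)
            continue
        t, dfree, p, d = paired_t(diffs)
        if target in hypothesis and _target_kind(target) == "roi":
            family, a_corr = "hypothesis", alpha_hyp
        else:
            family, a_corr = "exploratory", alpha_exp
        results.append(GroupResult(
            target=target, measure=measure, contrast=contrast_name,
            t=t, df=dfree, p_two_tailed=p, cohens_d=d, family=family,
            alpha_corrected=a_corr,
            significant_corrected=bool(p < a_corr),
            n_subjects=len(complete)))
    if n_excluded_total:
        logger.info("excluded %d incomplete subject cells listwise",
                    n_excluded_total)
    return results


def _cluster_extents(tmap: np.ndarray, t_crit: float,
                     structure: np.ndarray) -> List[Tuple[np.ndarray, int]]:
    """Clusters (label arrays) of supra-threshold voxels, both signs."""
    out = []
    for sign in (1.0, -1.0):
        mask = sign * tmap > t_crit
        if not mask.any():
            continue
        labels, n = ndimage.label(mask, structure=structure)
        for k in range(1, n + 1):
            out.append((labels == k, int((labels == k).sum())))
    return out


def _sign_matrix(n_subjects: int, n_perms: int,
                 rng: np.random.Generator) -> np.ndarray:
    if 2 ** n_subjects <= n_perms:
        signs = np.array(list(itertools.product((1.0, -1.0),
                                                repeat=n_subjects)))
    else:
        signs = rng.choice([1.0, -1.0], size=(n_perms, n_subjects))
    return signs


def cluster_correct(diff_maps: np.ndarray, voxel_p: float = 0.001,
                    alpha: float = 0.05, n_perms: int = 1000,
                    seed: int = 0, affine: Optional[np.ndarray] = None,
                    nn: int = 1,
                    ) -> Tuple[List[ClusterResult], int, np.ndarray]:
    """Sign-flip permutation cluster-extent correction of a paired contrast.

    ``diff_maps`` is (n_subjects, x, y, z).  Returns the surviving clusters,
    the extent threshold (ceil of the (1-alpha) quantile of the null maxima),
    and the null maximum-extent distribution.  Survival uses the corrected
    p = (1 + #{null max >= extent}) / (n_perms + 1) <= alpha.
    """
    diffs = np.asarray(diff_maps, dtype=float)
    if diffs.ndim != 4:
        raise ValueError("diff_maps must be (n_subjects, x, y, z)")
    n = diffs.shape[0]
    if n < 8:
        raise ValueError("need at least 8 subjects")
    if n_perms < 500:
        raise ValueError("need at least 500 permutations")
    structure = _NN_STRUCTURES[nn]
    rng = np.random.default_rng(seed)
    shape3 = diffs.shape[1:]
    flat = diffs.reshape(n, -1)
    df = n - 1
    t_crit = stats.t.ppf(1 - voxel_p / 2.0, df)

    # Sign flips leave per-voxel sums of squares unchanged, so every
    # permutation's t map comes from one matmul.
    sumsq = np.einsum("ij,ij->j", flat, flat)
    sd_floor = 1e-300

    def _tmap(signed_mean: np.ndarray) -> np.ndarray:
        var = (sumsq - n * signed_mean**2) / (n - 1)
        sd = np.sqrt(np.maximum(var, sd_floor))
        return signed_mean / (sd / math.sqrt(n))

    observed_t = _tmap(flat.mean(axis=0)).reshape(shape3)

    signs = _sign_matrix(n, n_perms, rng)
    means = (signs @ flat) / n
    null_max = np.zeros(len(signs), dtype=int)
    for p_idx in range(len(signs)):
        tmap = _tmap(means[p_idx]).reshape(shape3)
        extents = [e for _, e in _cluster_extents(tmap, t_crit, structure)]
        null_max[p_idx] = max(extents) if extents else 0

    quant = np.quantile(null_max, 1 - alpha, method="higher")
    extent_threshold = int(math.ceil(quant))
    n_null = len(null_max)

    clusters: List[ClusterResult] = []
    for mask, extent in _cluster_extents(observed_t, t_crit, structure):
        p_corr = (1 + int(np.sum(null_max >= extent))) / (n_null + 1)
        if p_corr <= alpha:
            coords = np.argwhere(mask)
            in_cluster_t = observed_t[mask]
            peak_idx = coords[np.argmax(np.abs(in_cluster_t))]
            if affine is not None:
                world = affine @ np.append(peak_idx, 1.0)
                peak_world = tuple(int(round(c)) for c in world[:3])
            else:
                peak_world = tuple(int(c) for c in peak_idx)
            clusters.append(ClusterResult(
                voxels=coords, extent=extent, peak_world_mm=peak_world,
                peak_t=float(observed_t[tuple(peak_idx)]),
                corrected_p=float(p_corr)))
    clusters.sort(key=lambda c: -c.extent)
    return clusters, extent_threshold, null_max


class ConditionContrast:
    """Paired-contrast model over a table of coherence records.

    Parameters
    ----------
    records
        CoherenceRecord sequence or a long DataFrame with columns
        subject, condition, target, measure, value.
    contrast
        (condition_a, condition_b); differences are a - b.
    """

    def __init__(self, records, contrast: Tuple[str, str] = ("suspense", "control"),
                 alpha: float = 0.05,
                 hypothesis_rois: Sequence[str] = HYPOTHESIS_ROIS):
        if isinstance(records, pd.DataFrame):
            records = [CoherenceRecord(
                subject=str(r.subject), condition=str(r.condition),
                target=str(r.target), measure=str(r.measure),
                value=float(r.value)) for r in records.itertuples()]
        self.records = list(records)
        self.contrast = tuple(contrast)
        self.alpha = alpha
        self.hypothesis_rois = tuple(hypothesis_rois)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ConditionContrast":
        return cls(df, **kwargs)

    def fit(self) -> "ContrastResults":
        results = contrast_table(self.records, self.contrast, self.alpha,
                                 self.hypothesis_rois)
        return ContrastResults(self, results)


class ContrastResults:
    """Fitted paired-contrast results with a summary table."""

    def __init__(self, model: ConditionContrast, results: List[GroupResult]):
        self.model = model
        self.results = results

    @property
    def table(self) -> pd.DataFrame:
        import dataclasses
        df = pd.DataFrame([dataclasses.asdict(r) for r in self.results])
        return df.sort_values(["measure", "family", "p_two_tailed"],
                              kind="mergesort").reset_index(drop=True)

    def summary(self) -> str:
        a, b = self.model.contrast
        df = self.table
        lines = [
            f"Paired contrast: {a} - {b}",
            f"targets: {df['target'].nunique()}   measures: "
            f"{sorted(df['measure'].unique())}",
            f"alpha: {self.model.alpha} (two-tailed); corrected alphas: "
            + ", ".join(f"{fam}={al:.6g}" for fam, al in
                        df.groupby('family')['alpha_corrected'].first().items()),
            "",
            df.to_string(
                index=False,
                columns=["target", "measure", "family", "t", "df",
                         "p_two_tailed", "cohens_d", "significant_corrected"],
                float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def d_matrix(self, measure: str = "bivariate_z") -> pd.DataFrame:
        """Cohen's d matrix: ROI activity on the diagonal, edges below it."""
        df = self.table
        df = df[df["measure"] == measure]
        rois = sorted(t for t in df["target"] if "-" not in t)
        mat = pd.DataFrame(np.nan, index=rois, columns=rois)
        for r in df.itertuples():
            if "-" in r.target:
                a_roi, b_roi = sorted(r.target.split("-", 1))
                if a_roi in rois and b_roi in rois:
                    mat.loc[max(a_roi, b_roi), min(a_roi, b_roi)] = r.cohens_d
            elif r.target in rois:
                mat.loc[r.target, r.target] = r.cohens_d
        return mat
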