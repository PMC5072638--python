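"""Group comparison and diagnostic-accuracy evaluation.

For each of the 16 indices (4 layers × 2 asymmetry modes × 2 summary
indices) the study evaluation reports normal and glaucoma group mean ± SD,
a two-sided Mann-Whitney test, and the AUROC with a DeLong 95% CI, for two
contrasts: all glaucoma vs normal, and bilateral glaucoma vs normal (using
the same target eyes). Diagnostic scores are oriented so that larger means
more glaucoma-like: the magnitude of the average negative difference, and
the black-superpixel count.

AUROC is computed through the Mann-Whitney identity
``AUROC = (#{pos > neg} + ties/2) / (n_pos * n_neg)``; its variance and the
paired two-curve comparison use DeLong's structural components. A
stratified-bootstrap CI is available as an alternative. No multiple-testing
correction is applied across the 16 indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .asymmetry import Mode, analyze_subject
from .grids import DiseaseLaterality, Group, Layer, SubjectRecord, ThicknessGrid

__all__ = [
    "mann_whitney",
    "auroc",
    "delong_variance",
    "auroc_ci_delong",
    "auroc_ci_bootstrap",
    "compare_auroc_paired",
    "average_thickness_index",
    "cohort_index_table",
    "run_study",
]


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two independent samples.

    Returns ``(U, p)`` where U counts ``a``-over-``b`` wins with midrank tie
    handling. The p-value is exact (full enumeration) when
    ``len(a)*len(b) <= 400`` and there are no ties; otherwise the normal
    approximation with tie and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= 400 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _split_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann-Whitney pair-count identity.

    ``labels`` are 1 for diseased, 0 for healthy; larger scores must mean
    more disease-like. 1.0 is perfect discrimination, 0.5 chance.
    """
    pos, neg = _split_scores(scores, labels)
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def _structural_components(pos: np.ndarray, neg: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUROC, DeLong variance) from structural components."""
    pos, neg = _split_scores(scores, labels)
    v10, v01 = _structural_components(pos, neg)
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    return auc, float(s10 / pos.size + s01 / neg.size)


def auroc_ci_delong(scores, labels) -> tuple[float, float, float]:
    """AUROC with Wald 95% CI from the DeLong variance, clipped to [0, 1]."""
    pos, neg = _split_scores(scores, labels)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("DeLong CI needs >= 2 subjects per class")
    auc, var = delong_variance(scores, labels)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return auc, float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def auroc_ci_bootstrap(scores, labels, n_boot: int = 2000,
                       rng: np.random.Generator | None = None) -> tuple[float, float, float]:
    """Stratified-percentile-bootstrap 95% CI (alternative to DeLong)."""
    rng = rng or np.random.default_rng()
    pos, neg = _split_scores(scores, labels)
    boots = np.empty(n_boot)
    lab = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
    for i in range(n_boot):
        s = np.concatenate([rng.choice(pos, pos.size), rng.choice(neg, neg.size)])
        boots[i] = auroc(s, lab)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auroc(np.concatenate([pos, neg]), lab), float(lo), float(hi)


def compare_auroc_paired(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong test of two ROC curves on the same subjects.

    Returns ``(z, p_two_sided)``. Degenerate zero-variance differences give
    p = 1 when the curves have equal area, else p = 0.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("scores_a, scores_b and labels must have the same length")
    mask_pos = labels == 1
    mask_neg = labels == 0
    if mask_pos.sum() < 2 or mask_neg.sum() < 2:
        raise ValueError("paired DeLong needs >= 2 subjects per class")
    v10a, v01a = _structural_components(scores_a[mask_pos], scores_a[mask_neg])
    v10b, v01b = _structural_components(scores_b[mask_pos], scores_b[mask_neg])
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var_diff <= 0:
        return 0.0, 1.0 if delta == 0 else 0.0
    z = float(delta / np.sqrt(var_diff))
    return z, float(2.0 * sps.norm.sf(abs(z)))


def average_thickness_index(grid: ThicknessGrid) -> float:
    """Mean macular thickness over non-missing cells, μm.

    Stand-in for the device's global average-thickness parameters used as
    the conventional comparison arm.
    """
    return grid.mean_thickness()


# ---------------------------------------------------------------------------
# study-level evaluation

_INDEX_NAMES = ("avg_negative_diff", "n_black")


def cohort_index_table(records: Iterable[SubjectRecord],
                       cutoff_inclusive: bool = False) -> pd.DataFrame:
    """Per-subject asymmetry indices: one row per subject×layer×mode."""
    rows = []
    for rec in records:
        indices = analyze_subject(rec, cutoff_inclusive=cutoff_inclusive)
        avg_thickness = {
            layer: average_thickness_index(rec.grid(rec.target_eye, layer)) for layer in Layer
        }
        for (layer, mode), idx in indices.items():
            rows.append({
                "subject_id": rec.subject_id,
                "group": rec.group.value,
                "disease_laterality": rec.disease_laterality.value,
                "layer": layer.value,
                "mode": mode.value,
                "avg_negative_diff": idx.avg_negative_diff_um,
                "n_negative": idx.n_negative,
                "n_black": idx.n_black,
                "n_missing": idx.n_missing,
                "avg_thickness": avg_thickness[layer],
            })
    return pd.DataFrame(rows)


def _evaluate_contrast(sub: pd.DataFrame, index: str) -> dict:
    normal = sub.loc[sub["group"] == Group.NORMAL.value, index].to_numpy(float)
    glaucoma = sub.loc[sub["group"] == Group.GLAUCOMA.value, index].to_numpy(float)
    # score orientation: larger = more glaucoma-like
    score = np.concatenate([-glaucoma, -normal]) if index == "avg_negative_diff" \
        else np.concatenate([glaucoma, normal])
    labels = np.concatenate([np.ones(glaucoma.size, int), np.zeros(normal.size, int)])
    auc, lo, hi = auroc_ci_delong(score, labels)
    return {"auroc": auc, "ci_lo": lo, "ci_hi": hi,
            "n_glaucoma": int(glaucoma.size), "n_normal": int(normal.size)}


def run_study(records_or_manifest, cutoff_inclusive: bool = False) -> pd.DataFrame:
    """Full evaluation table: 16 index rows with group stats and AUROCs.

    Accepts a :class:`~macusym.grids.CohortManifest` or an iterable of
    :class:`SubjectRecord`. Columns report normal/glaucoma mean ± SD and a
    Mann-Whitney p per index, and AUROC (DeLong 95% CI) for the
    total-glaucoma and bilateral-glaucoma contrasts; the bilateral contrast
    keeps the same target eyes, filtered to bilateral disease.
    Deterministic: a pure function of the cohort contents.
    """
    if hasattr(records_or_manifest, "iter_subjects"):
        records = records_or_manifest.iter_subjects()
    else:
        records = records_or_manifest
    per_subject = cohort_index_table(records, cutoff_inclusive=cutoff_inclusive)
    if set(per_subject["group"].unique()) != {Group.NORMAL.value, Group.GLAUCOMA.value}:
        raise ValueError("cohort must contain both NORMAL and GLAUCOMA subjects")

    bilateral = per_subject[
        (per_subject["group"] == Group.NORMAL.value)
        | (per_subject["disease_laterality"] == DiseaseLaterality.BILATERAL.value)
    ]
    has_bilateral = (bilateral["group"] == Group.GLAUCOMA.value).any()

    rows = []
    for layer in Layer:
        for mode in Mode:
            sub = per_subject[(per_subject["layer"] == layer.value)
                              & (per_subject["mode"] == mode.value)]
            for index in _INDEX_NAMES:
                normal = sub.loc[sub["group"] == Group.NORMAL.value, index].to_numpy(float)
                glaucoma = sub.loc[sub["group"] == Group.GLAUCOMA.value, index].to_numpy(float)
                _, p = mann_whitney(normal, glaucoma)
                row = {
                    "layer": layer.value,
                    "mode": mode.value,
                    "index": index,
                    "normal_mean": normal.mean(),
                    "normal_sd": normal.std(ddof=1),
                    "glaucoma_mean": glaucoma.mean(),
                    "glaucoma_sd": glaucoma.std(ddof=1),
                    "mann_whitney_p": p,
                }
                total = _evaluate_contrast(sub, index)
                row.update({f"total_{k}": v for k, v in total.items()
                            if k in ("auroc", "ci_lo", "ci_hi")})
                if has_bilateral:
                    bsub = bilateral[(bilateral["layer"] == layer.value)
                                     & (bilateral["mode"] == mode.value)]
                    bi = _evaluate_contrast(bsub, index)
                    row.update({f"bilateral_{k}": v for k, v in bi.items()
                                if k in ("auroc", "ci_lo", "ci_hi")})
                else:
                    row.update({"bilateral_auroc": np.nan,
                                "bilateral_ci_lo": np.nan, "bilateral_ci_hi": np.nan})
                rows.append(row)
    return pd.DataFrame(rows)
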