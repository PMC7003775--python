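"""Evaluation computations: Dice overlap, confusion ratios, ROC/AUC,
lesion volumes, percent volume difference, Bland-Altman limits of
agreement, and the cross-validation harnesses."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .mpmri_io import normalize_channels
from .signatures import sample_balanced, signature_sets_from_labels
from .ssae_seg import SsaeTrainConfig, segment_study, train_segmenter

__all__ = [
    "RocResult",
    "BlandAltmanResult",
    "dice",
    "confusion_metrics",
    "roc_auc",
    "lesion_volume",
    "percent_volume_difference",
    "bland_altman",
    "twofold_cv_segmentation",
    "loocv_classification",
]

LESION_CLASS = 3


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class BlandAltmanResult:
    mean_diff: float
    loa_low: float
    loa_high: float
    diffs: np.ndarray


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|); 0 (with warning) if both empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("Dice of two empty masks defined as 0")
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


def confusion_metrics(pred_labels, true_labels, positive_class=1):
    """(sensitivity, specificity, ppv, npv) from the 2x2 table.

    Ratios with a zero denominator are returned as ``None``.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("length mismatch")
    pos = true == positive_class
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present in the truth")
    ppos = pred == positive_class
    tp = int((ppos & pos).sum())
    fn = int((~ppos & pos).sum())
    tn = int((~ppos & ~pos).sum())
    fp = int((ppos & ~pos).sum())

    def ratio(num, den):
        return num / den if den > 0 else None

    return (ratio(tp, tp + fn), ratio(tn, tn + fp),
            ratio(tp, tp + fp), ratio(tn, tn + fn))


def roc_auc(scores, labels, positive_class=1) -> RocResult:
    """ROC by threshold sweep over the unique scores; tie-aware AUC.

    The trapezoidal AUC over the sweep equals the normalized
    Mann-Whitney U statistic (ties counted 1/2).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive_class
    if y.all() or (~y).all():
        raise ValueError("both classes required for ROC")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # cumulative counts at each unique threshold (predict positive if score >= t)
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    P, Nn = int(y.sum()), int((~y).sum())
    tpr = np.r_[0.0, tps / P]
    fpr = np.r_[0.0, fps / Nn]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def lesion_volume(mask: np.ndarray, voxel_spacing) -> float:
    """Voxel count times voxel volume, in mm^3."""
    return float(np.asarray(mask, dtype=bool).sum()) \
        * float(np.prod(voxel_spacing))


def percent_volume_difference(v_test: float, v_ref: float,
                              mode: str = "reference") -> float:
    """Percent difference between a measured and a reference volume.

    ``mode="reference"``: 100*|v_test - v_ref| / v_ref;
    ``mode="symmetric"``: denominator is the pair mean.
    """
    if mode == "reference":
        if v_ref <= 0:
            raise ValueError("reference volume must be positive")
        return 100.0 * abs(v_test - v_ref) / v_ref
    if mode == "symmetric":
        denom = (v_test + v_ref) / 2.0
        if denom <= 0:
            raise ValueError("volumes must have a positive mean")
        return 100.0 * abs(v_test - v_ref) / denom
    raise ValueError(f"unknown mode: {mode}")


def bland_altman(v1, v2) -> BlandAltmanResult:
    """Limits of agreement: mean(v1-v2) +/- 1.96 * SD(v1-v2)."""
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    diffs = a - b
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(mean_diff=mean_diff,
                             loa_low=mean_diff - 1.96 * sd,
                             loa_high=mean_diff + 1.96 * sd,
                             diffs=diffs)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        return mask
    struct = np.ones((3,) * mask.ndim, dtype=bool)
    lab, n = ndimage.label(mask, structure=struct)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def twofold_cv_segmentation(
    cohort,
    cfg: SsaeTrainConfig | None = None,
    seed: int = 0,
    cap_per_class: int = 1000,
    keep_largest_component: bool = True,
) -> pd.DataFrame:
    """Twofold cross-validated lesion Dice over a phantom cohort.

    Subjects are split into two random halves; a segmenter trained on
    each half segments the subjects of the other, so every subject is
    scored exactly once by a model that never saw it.  The scored lesion
    object is by default the largest connected component of the
    voxelwise lesion mask, mirroring how lesions are extracted for
    classification (disable via ``keep_largest_component``).  Returns a
    frame with columns subject_id, phenotype, fold, dice,
    volume_pred_mm3 and volume_true_mm3.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 subjects")
    cfg = cfg or SsaeTrainConfig()
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(cohort))
    folds = [idx[: len(cohort) // 2], idx[len(cohort) // 2:]]

    normalized = [normalize_channels(ph.study) for ph in cohort]
    per_subject_sets = [
        signature_sets_from_labels(normalized[i], cohort[i].truth_labels,
                                   max_per_class=cap_per_class,
                                   seed=seed + 17 * i)
        for i in range(len(cohort))
    ]
    rows = []
    for f, train_idx in enumerate(folds):
        test_idx = folds[1 - f]
        pooled = [s for i in train_idx for s in per_subject_sets[i]]
        training = sample_balanced(pooled, cap_per_class=cap_per_class,
                                   seed=seed + f)
        model = train_segmenter(training, cfg,
                                channel_order=normalized[0].channel_order)
        for i in test_idx:
            seg = segment_study(model, normalized[i])
            pred_mask = seg.mask(LESION_CLASS)
            if keep_largest_component:
                pred_mask = _largest_component(pred_mask)
            true_mask = cohort[i].truth_labels.mask(LESION_CLASS)
            rows.append({
                "subject_id": cohort[i].study.subject_id,
                "phenotype": cohort[i].lesion_phenotype,
                "fold": 1 - f,
                "dice": dice(pred_mask, true_mask),
                "volume_pred_mm3": lesion_volume(
                    pred_mask, cohort[i].study.voxel_spacing),
                "volume_true_mm3": lesion_volume(
                    true_mask, cohort[i].study.voxel_spacing),
            })
    return pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)


def loocv_classification(features, labels, ratios=None, seed: int = 0):
    """Leave-one-out classification harness.

    Runs the cost-ratio grid search by LOOCV AUC, then reports the ROC
    over the pooled leave-one-out scores at the selected ratio and the
    confusion metrics at the zero-score operating point.

    Returns ``(RocResult, confusion tuple, CostGridResult)``.
    """
    from .sae_svm import DEFAULT_COST_RATIOS, cross_validated_scores, grid_search_ratio

    ratios = ratios if ratios is not None else DEFAULT_COST_RATIOS
    grid = grid_search_ratio(features, labels, ratios, cv="loocv", seed=seed)
    scores = cross_validated_scores(features, labels, grid.best_ratio,
                                    cv="loocv", seed=seed)
    roc = roc_auc(scores, labels)
    conf = confusion_metrics((scores > 0).astype(int), np.asarray(labels))
    return roc, conf, grid
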