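"""Reference cohort experiments.

Scaled-down synthetic-cohort runs of the two headline evaluations:
twofold cross-validated lesion segmentation Dice, and leave-one-out
cross-validated benign/malignant classification.  Both are driven
entirely by the phantom generator, so they run offline and are
reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evalmetrics import loocv_classification, twofold_cv_segmentation
from .mpmri_io import normalize_channels
from .phantom import generate_cohort
from .sae_svm import (
    build_feature_vector,
    extract_lesion_record,
    train_lesion_sae,
    MALIGNANT,
    BENIGN,
)
from .signatures import sample_balanced, signature_sets_from_labels
from .ssae_seg import SsaeTrainConfig, segment_study, train_segmenter

__all__ = [
    "SegmentationExperimentResult",
    "ClassificationExperimentResult",
    "run_segmentation_experiment",
    "run_classification_experiment",
]


@dataclass
class SegmentationExperimentResult:
    table: pd.DataFrame
    mean_dice_malignant: float
    mean_dice_benign: float
    n_subjects: int


@dataclass
class ClassificationExperimentResult:
    auc: float
    sensitivity: float            # fraction in [0, 1]
    specificity: float | None
    best_ratio: tuple[float, float]
    scores: np.ndarray
    labels: np.ndarray
    n_subjects: int


def run_segmentation_experiment(
    n_subjects: int = 20,
    seed: int = 0,
    cfg: SsaeTrainConfig | None = None,
    cap_per_class: int = 1000,
) -> SegmentationExperimentResult:
    """Twofold cross-validated SSAE segmentation on a half-benign cohort."""
    cfg = cfg or SsaeTrainConfig(seed=seed)
    cohort = generate_cohort(n_subjects, benign_fraction=0.5, seed=seed)
    table = twofold_cv_segmentation(cohort, cfg=cfg, seed=seed,
                                    cap_per_class=cap_per_class)
    by_phen = table.groupby("phenotype")["dice"].mean()
    return SegmentationExperimentResult(
        table=table,
        mean_dice_malignant=float(by_phen.get("malignant", np.nan)),
        mean_dice_benign=float(by_phen.get("benign", np.nan)),
        n_subjects=n_subjects,
    )


def run_classification_experiment(
    n_subjects: int = 40,
    seed: int = 0,
    cfg: SsaeTrainConfig | None = None,
    cap_per_class: int = 1000,
    feature_mode: str = "node_stats",
) -> ClassificationExperimentResult:
    """LOOCV SAE-SVM classification of segmented phantom lesions.

    One segmenter is trained on the cohort's balanced signatures (the
    cross-validated quantity is the lesion classifier, not the
    segmenter); lesions come from its segmentations, are encoded by the
    unsupervised lesion autoencoder, summarized by the statistics layer
    and classified by the cost-weighted SVM with the ratio grid searched
    by LOOCV AUC.
    """
    cfg = cfg or SsaeTrainConfig(seed=seed)
    cohort = generate_cohort(n_subjects, benign_fraction=0.5, seed=seed)
    normalized = [normalize_channels(ph.study) for ph in cohort]

    pooled = [
        s for i, ph in enumerate(cohort)
        for s in signature_sets_from_labels(normalized[i], ph.truth_labels,
                                            max_per_class=cap_per_class,
                                            seed=seed + 17 * i)
    ]
    training = sample_balanced(pooled, cap_per_class=cap_per_class, seed=seed)
    segmenter = train_segmenter(training, cfg,
                                channel_order=normalized[0].channel_order)

    records = []
    labels = []
    for i, ph in enumerate(cohort):
        seg = segment_study(segmenter, normalized[i])
        rec = extract_lesion_record(normalized[i], seg)
        rec.label = MALIGNANT if ph.lesion_phenotype == "malignant" else BENIGN
        records.append(rec)
        labels.append(rec.label)
    labels = np.asarray(labels)

    all_sigs = np.vstack([r.signatures for r in records])
    sae = train_lesion_sae(all_sigs, cfg)
    for rec in records:
        rec.encoded = sae.encode(rec.signatures)
        rec.feature_vector = build_feature_vector(rec, feature_mode)
    features = np.vstack([r.feature_vector for r in records])

    roc, conf, grid = loocv_classification(features, labels, seed=seed)
    from .sae_svm import cross_validated_scores

    scores = cross_validated_scores(features, labels, grid.best_ratio,
                                    cv="loocv", seed=seed)
    return ClassificationExperimentResult(
        auc=roc.auc,
        sensitivity=conf[0],
        specificity=conf[1],
        best_ratio=grid.best_ratio,
        scores=scores,
        labels=labels,
        n_subjects=n_subjects,
    )
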