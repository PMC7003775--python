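"""Lesion benign/malignant classification.

An unsupervised single sparse autoencoder (sigmoid encoder, linear
decoder) encodes the per-voxel signatures of each segmented lesion; a
statistics layer summarizes each hidden node's activations over the
lesion (mean, SD, max, min) into a fixed-length feature vector; a linear
soft-margin SVM with per-class misclassification costs separates benign
from malignant, with the benign:malignant cost ratio grid-searched by
cross-validated AUC over {1, 1.5, 2, 2.5, 3, 3.5, 4} : 1.

Label convention: benign = 0, malignant = 1; malignant is the positive
class and receives positive decision scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .mpmri_io import LabelMap, MpMriStudy
from .ssae_seg import SaeLayer, SsaeTrainConfig, train_sae_layer

__all__ = [
    "BENIGN",
    "MALIGNANT",
    "DEFAULT_COST_RATIOS",
    "LesionRecord",
    "CostGridResult",
    "SvmModel",
    "train_lesion_sae",
    "statistics_layer",
    "build_feature_vector",
    "train_cost_weighted_svm",
    "classify_lesion",
    "extract_lesion_record",
    "grid_search_ratio",
    "cross_validated_scores",
]

BENIGN, MALIGNANT = 0, 1
LESION_CLASS = 3

#: benign:malignant misclassification penalty grid
DEFAULT_COST_RATIOS: tuple[tuple[float, float], ...] = (
    (1.0, 1.0), (1.5, 1.0), (2.0, 1.0), (2.5, 1.0),
    (3.0, 1.0), (3.5, 1.0), (4.0, 1.0),
)


@dataclass
class LesionRecord:
    """One segmented lesion with its signature and feature representations."""

    subject_id: str
    lesion_mask: np.ndarray
    signatures: np.ndarray          # N_les x D
    encoded: np.ndarray | None = None   # N_les x d_hidden
    feature_vector: np.ndarray | None = None
    label: int | None = None        # BENIGN / MALIGNANT / None

    def __post_init__(self) -> None:
        self.signatures = np.atleast_2d(np.asarray(self.signatures, dtype=float))
        if self.signatures.shape[0] < 1:
            raise ValueError("lesion must contain at least one voxel")


@dataclass
class CostGridResult:
    ratios: list[tuple[float, float]]
    auc_per_ratio: list[float]
    best_ratio: tuple[float, float]


@dataclass
class SvmModel:
    """Fitted scaler + linear SVM plus the layout it expects."""

    scaler: StandardScaler
    svm: SVC
    cost_ratio: tuple[float, float]
    n_features: int
    feature_mode: str = "node_stats"

    def decision_scores(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature layout mismatch: got {X.shape[1]} features, "
                f"model expects {self.n_features}")
        return self.svm.decision_function(self.scaler.transform(X))


def train_lesion_sae(all_lesion_signatures: np.ndarray,
                     cfg: SsaeTrainConfig | None = None) -> SaeLayer:
    """Train the unsupervised lesion autoencoder (sigmoid enc, linear dec).

    Labels are never consulted; the same objective and hyperparameters as
    the segmentation stack apply (L2 0.001, sparsity 0.25, weight 4).
    """
    cfg = cfg or SsaeTrainConfig()
    X = np.atleast_2d(np.asarray(all_lesion_signatures, dtype=float))
    if X.shape[0] < cfg.hidden_size:
        raise ValueError(f"need at least {cfg.hidden_size} lesion signatures")
    return train_sae_layer(X, cfg.hidden_size, cfg,
                           activation="sigmoid", decoder_activation="linear")


def statistics_layer(encoded: np.ndarray) -> np.ndarray:
    """Per-node (mean, sd, max, min) over lesion voxels, node-major.

    Layout: [mean_1, sd_1, max_1, min_1, mean_2, ...]; the SD is the
    unbiased estimator and 0 for a single-voxel lesion.
    """
    M = np.atleast_2d(np.asarray(encoded, dtype=float))
    if M.shape[0] < 1 or M.size == 0:
        raise ValueError("empty encoding matrix")
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1) if M.shape[0] > 1 else np.zeros(M.shape[1])
    mx = M.max(axis=0)
    mn = M.min(axis=0)
    return np.column_stack([mean, sd, mx, mn]).ravel()


def build_feature_vector(record: LesionRecord,
                         mode: str = "node_stats") -> np.ndarray:
    """Lesion feature vector from the encoded map (+ optional raw-channel stats).

    ``node_stats``: the 4*d_hidden statistics-layer vector.
    ``node_plus_channel_stats``: additionally (mean, sd, max, min) of each
    raw input channel over the lesion voxels (4*d_hidden + 4*D values).
    """
    if record.encoded is None:
        raise ValueError("record has no encoded feature map")
    feats = statistics_layer(record.encoded)
    if mode == "node_stats":
        return feats
    if mode == "node_plus_channel_stats":
        return np.concatenate([feats, statistics_layer(record.signatures)])
    raise ValueError(f"unknown feature mode: {mode}")


def _fit_svm(X: np.ndarray, y: np.ndarray,
             ratio: tuple[float, float]) -> tuple[StandardScaler, SVC]:
    scaler = StandardScaler().fit(X)
    svm = SVC(kernel="linear", C=1.0,
              class_weight={BENIGN: ratio[0], MALIGNANT: ratio[1]})
    svm.fit(scaler.transform(X), y)
    return scaler, svm


def _cv_folds(n: int, cv: str, seed: int, labels: np.ndarray):
    if cv == "loocv":
        for i in range(n):
            yield np.array([i]), np.r_[np.arange(i), np.arange(i + 1, n)]
    elif cv == "kfold10":
        from sklearn.model_selection import StratifiedKFold
        k = min(10, int(np.min(np.bincount(labels))))
        skf = StratifiedKFold(n_splits=max(k, 2), shuffle=True,
                              random_state=seed)
        for _, (train, test) in enumerate(skf.split(np.zeros(n), labels)):
            yield test, train
    else:
        raise ValueError(f"unknown cv scheme: {cv}")


def cross_validated_scores(features, labels, ratio, cv: str = "loocv",
                           seed: int = 0) -> np.ndarray:
    """Out-of-fold decision scores for one cost ratio."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    scores = np.empty(len(y))
    for test, train in _cv_folds(len(y), cv, seed, y):
        if len(np.unique(y[train])) < 2:
            raise ValueError("a training fold lost one class")
        scaler, svm = _fit_svm(X[train], y[train], ratio)
        scores[test] = svm.decision_function(scaler.transform(X[test]))
    return scores


def grid_search_ratio(features, labels, ratios=DEFAULT_COST_RATIOS,
                      cv: str = "loocv", seed: int = 0) -> CostGridResult:
    """Pick the cost ratio maximizing cross-validated AUC (ties -> smaller)."""
    from .evalmetrics import roc_auc

    ratios = [tuple(r) for r in ratios]
    if not ratios:
        raise ValueError("empty ratio grid")
    aucs = []
    for ratio in ratios:
        scores = cross_validated_scores(features, labels, ratio, cv=cv,
                                        seed=seed)
        aucs.append(roc_auc(scores, labels).auc)
    best = int(np.argmax(aucs))  # argmax keeps the first (smallest) on ties
    return CostGridResult(ratios=ratios, auc_per_ratio=aucs,
                          best_ratio=ratios[best])


def train_cost_weighted_svm(features, labels, ratios=DEFAULT_COST_RATIOS,
                            cv: str = "loocv", seed: int = 0,
                            feature_mode: str = "node_stats"):
    """Grid-search the cost ratio, then refit on all data at the best ratio."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    grid = grid_search_ratio(X, y, ratios, cv=cv, seed=seed)
    scaler, svm = _fit_svm(X, y, grid.best_ratio)
    model = SvmModel(scaler=scaler, svm=svm, cost_ratio=grid.best_ratio,
                     n_features=X.shape[1], feature_mode=feature_mode)
    return model, grid


def classify_lesion(model: SvmModel, record: LesionRecord):
    """Signed decision score and label (malignant iff score > 0)."""
    feats = record.feature_vector
    if feats is None:
        feats = build_feature_vector(record, model.feature_mode)
    score = float(model.decision_scores(feats.reshape(1, -1))[0])
    return score, MALIGNANT if score > 0 else BENIGN


def extract_lesion_record(
    study: MpMriStudy,
    segmentation: LabelMap,
    sae: SaeLayer | None = None,
    label: int | None = None,
) -> LesionRecord:
    """Largest connected lesion component of a segmentation as a record.

    Falls back to the single hottest-probability voxel being absent —
    i.e. raises — when the segmentation contains no lesion voxels.
    """
    lesion = segmentation.mask(LESION_CLASS)
    if not lesion.any():
        raise ValueError(
            f"segmentation of {study.subject_id} contains no lesion voxels")
    struct = np.ones((3, 3, 3), dtype=bool)
    lab, n = ndimage.label(lesion, structure=struct)
    if n > 1:
        sizes = ndimage.sum_labels(lesion, lab, index=np.arange(1, n + 1))
        lesion = lab == (1 + int(np.argmax(sizes)))
    record = LesionRecord(
        subject_id=study.subject_id,
        lesion_mask=lesion,
        signatures=study.signatures(lesion),
        label=label,
    )
    if sae is not None:
        record.encoded = sae.encode(record.signatures)
    return record
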