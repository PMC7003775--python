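"""Baseline architectures for the segmentation comparison experiment.

A supervised MLP sharing the autoencoder stack's exact architecture
(5 hidden layers x 10 satlin nodes + softmax, no pretraining), and a
patch-based 2-D CNN over in-slice 5x5 signature neighborhoods
(conv 3x3 -> ReLU -> maxpool 2x2 with 128/64/32/16 filters, then a fully
connected softmax layer).  With 5x5 inputs four 2x2 poolings are
geometrically impossible, so pooling is skipped once the spatial extent
drops below 2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .mpmri_io import CLASS_LEGEND, LabelMap, MpMriStudy, normalize_channels
from .signatures import TissueSignatureSet, sample_balanced, signature_sets_from_labels
from .ssae_seg import (
    SaeLayer,
    SsaeModel,
    SsaeTrainConfig,
    _init_weights,
    segment_study,
    train_segmenter,
)

__all__ = [
    "relu",
    "PatchSet",
    "CnnConfig",
    "CnnModel",
    "train_mlp",
    "extract_patches",
    "train_cnn",
    "compare_architectures",
]

PATCH = 5
LESION_CLASS = 3


def relu(x):
    """Rectified linear unit: 0 for x<0, x otherwise."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


@dataclass
class PatchSet:
    """N x 5 x 5 x D in-slice signature neighborhoods with labels."""

    patches: np.ndarray
    labels: np.ndarray
    center_index: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=float)
        if self.patches.ndim != 4 or self.patches.shape[1:3] != (PATCH, PATCH):
            raise ValueError("patches must have shape N x 5 x 5 x D")
        self.labels = np.asarray(self.labels, dtype=int)


def train_mlp(training: TissueSignatureSet, cfg: SsaeTrainConfig,
              learning_rate: float = 0.2, momentum: float = 0.9,
              epochs: int | None = None) -> SsaeModel:
    """Supervised MLP with the SSAE's layer dimensions, trained end-to-end.

    Random initialization (no unsupervised pretraining) followed by joint
    full-batch gradient descent with momentum on cross-entropy.  Hidden
    units are leaky-rectified: from random init a 5-deep saturating or
    hard-rectified stack dies under plain gradient descent (saturated
    units receive zero gradient and never recover), whereas the
    unsupervised pretraining of the SSAE sidesteps this — which is the
    point of the comparison.  Optimizer settings are shared with the
    patch CNN for fairness.
    """
    from .ssae_seg import _ACTIVATIONS, _clip_gradients, _softmax

    X = training.signatures
    y = training.labels
    if set(np.unique(y)) != set(CLASS_LEGEND):
        raise ValueError("all 4 classes must be present")
    rng = np.random.default_rng(cfg.seed)
    dims = [training.n_features] + [cfg.hidden_size] * cfg.n_layers
    layers = [
        SaeLayer(W_enc=_init_weights(dims[k + 1], dims[k], rng),
                 b_enc=np.zeros(dims[k + 1]),
                 W_dec=np.zeros((dims[k], dims[k + 1])),
                 b_dec=np.zeros(dims[k]),
                 activation="leaky_relu")
        for k in range(cfg.n_layers)
    ]
    n_classes = len(CLASS_LEGEND)
    Wh = _init_weights(n_classes, cfg.hidden_size, rng)
    bh = np.zeros(n_classes)
    N = X.shape[0]
    Y = np.zeros((N, n_classes))
    Y[np.arange(N), y] = 1.0
    epochs = epochs if epochs is not None else \
        cfg.max_epochs + cfg.fine_tune_epochs
    act, act_g = _ACTIVATIONS["leaky_relu"]
    vels = [[np.zeros_like(l.W_enc), np.zeros_like(l.b_enc)] for l in layers]
    vWh, vbh = np.zeros_like(Wh), np.zeros_like(bh)
    for epoch in range(epochs):
        acts, zs = [X], []
        H = X
        for layer in layers:
            Z = H @ layer.W_enc.T + layer.b_enc
            zs.append(Z)
            H = act(Z)
            acts.append(H)
        P = _softmax(H @ Wh.T + bh)
        if not np.isfinite(P).all():
            raise RuntimeError(f"MLP training diverged at epoch {epoch}")
        G = (P - Y) / N
        gWh = G.T @ H + 2 * cfg.l2_penalty * Wh
        gbh = G.sum(axis=0)
        dH = G @ Wh
        grads = []
        for k in range(cfg.n_layers - 1, -1, -1):
            dZ = dH * act_g(zs[k])
            grads.append((k, dZ.T @ acts[k] + 2 * cfg.l2_penalty
                          * layers[k].W_enc, dZ.sum(axis=0)))
            dH = dZ @ layers[k].W_enc
        flat = _clip_gradients(tuple([gWh, gbh]
                                     + [g for _, a, b_ in grads
                                        for g in (a, b_)]))
        vWh = momentum * vWh - learning_rate * flat[0]
        vbh = momentum * vbh - learning_rate * flat[1]
        Wh += vWh
        bh += vbh
        for (k, _, _), gW, gb in zip(grads, flat[2::2], flat[3::2]):
            vels[k][0] = momentum * vels[k][0] - learning_rate * gW
            vels[k][1] = momentum * vels[k][1] - learning_rate * gb
            layers[k].W_enc += vels[k][0]
            layers[k].b_enc += vels[k][1]
    return SsaeModel(layers=layers, softmax_W=Wh, softmax_b=bh)


def extract_patches(study: MpMriStudy, voxels) -> PatchSet:
    """In-slice 5x5 neighborhoods across all channels, reflect-padded."""
    voxels = [tuple(int(c) for c in v) for v in voxels]
    if not voxels:
        raise ValueError("empty voxel list")
    shape = study.grid_shape
    for v in voxels:
        if not all(0 <= v[i] < shape[i] for i in range(3)):
            raise ValueError(f"voxel {v} outside grid {shape}")
    stacked = study.stacked()  # x, y, z, D
    r = PATCH // 2
    padded = np.pad(stacked, ((r, r), (r, r), (0, 0), (0, 0)), mode="reflect")
    patches = np.empty((len(voxels), PATCH, PATCH, stacked.shape[-1]))
    for n, (x, y, z) in enumerate(voxels):
        patches[n] = padded[x:x + PATCH, y:y + PATCH, z, :]
    return PatchSet(patches=patches, labels=np.zeros(len(voxels), dtype=int),
                    center_index=voxels)


@dataclass
class CnnConfig:
    filters: tuple[int, ...] = (128, 64, 32, 16)
    learning_rate: float = 0.02
    momentum: float = 0.9
    max_epochs: int = 100
    l2_penalty: float = 1e-4
    seed: int = 0


class CnnModel:
    """Minimal patch CNN: (conv3x3 same -> ReLU -> maxpool2x2?) per stage,
    then a fully connected softmax layer.  Full-batch gradient descent."""

    def __init__(self, in_channels: int, n_classes: int, cfg: CnnConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.conv_W: list[np.ndarray] = []
        self.conv_b: list[np.ndarray] = []
        c_in, spatial = in_channels, PATCH
        self.pooled: list[bool] = []
        for c_out in cfg.filters:
            fan = 9 * c_in + c_out
            self.conv_W.append(rng.uniform(-1, 1, (3, 3, c_in, c_out))
                               * np.sqrt(6.0 / fan))
            self.conv_b.append(np.zeros(c_out))
            do_pool = spatial >= 2
            self.pooled.append(do_pool)
            if do_pool:
                spatial //= 2
            c_in = c_out
        self.fc_dim = spatial * spatial * c_in
        self.fc_W = rng.uniform(-1, 1, (n_classes, self.fc_dim)) \
            * np.sqrt(6.0 / (self.fc_dim + n_classes))
        self.fc_b = np.zeros(n_classes)

    @property
    def parameter_count(self) -> int:
        """Trainable parameter count; per conv layer (3*3*c_in + 1) * c_out."""
        n = sum(W.size + b.size for W, b in zip(self.conv_W, self.conv_b))
        return int(n + self.fc_W.size + self.fc_b.size)

    # -- forward / backward -------------------------------------------------

    @staticmethod
    def _conv(X, W, b):
        N, H, Wd, _ = X.shape
        Xp = np.pad(X, ((0, 0), (1, 1), (1, 1), (0, 0)))
        out = np.broadcast_to(b, (N, H, Wd, W.shape[-1])).copy()
        for di in range(3):
            for dj in range(3):
                out += np.einsum("nijc,co->nijo",
                                 Xp[:, di:di + H, dj:dj + Wd, :], W[di, dj])
        return out

    @staticmethod
    def _conv_backward(X, W, dOut):
        N, H, Wd, _ = X.shape
        Xp = np.pad(X, ((0, 0), (1, 1), (1, 1), (0, 0)))
        dW = np.zeros_like(W)
        dXp = np.zeros_like(Xp)
        for di in range(3):
            for dj in range(3):
                patch = Xp[:, di:di + H, dj:dj + Wd, :]
                dW[di, dj] = np.einsum("nijc,nijo->co", patch, dOut)
                dXp[:, di:di + H, dj:dj + Wd, :] += np.einsum(
                    "nijo,co->nijc", dOut, W[di, dj])
        db = dOut.sum(axis=(0, 1, 2))
        return dW, db, dXp[:, 1:-1, 1:-1, :]

    @staticmethod
    def _pool(X):
        # 2x2 stride-2 max pooling; odd trailing rows/cols are dropped
        N, H, W, C = X.shape
        H2, W2 = H // 2, W // 2
        Xc = X[:, : 2 * H2, : 2 * W2, :].reshape(N, H2, 2, W2, 2, C)
        win = Xc.transpose(0, 1, 3, 5, 2, 4).reshape(N, H2, W2, C, 4)
        arg = win.argmax(axis=-1)
        out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
        return out, arg

    @staticmethod
    def _pool_backward(dOut, arg, x_shape):
        N, H2, W2, C = dOut.shape
        dwin = np.zeros((N, H2, W2, C, 4))
        np.put_along_axis(dwin, arg[..., None], dOut[..., None], axis=-1)
        dXc = dwin.reshape(N, H2, W2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dX = np.zeros(x_shape)
        dX[:, : 2 * H2, : 2 * W2, :] = dXc.reshape(N, 2 * H2, 2 * W2, C)
        return dX

    def _forward(self, X):
        caches = []
        A = X
        for k in range(len(self.conv_W)):
            Z = self._conv(A, self.conv_W[k], self.conv_b[k])
            R = relu(Z)
            if self.pooled[k]:
                P, pc = self._pool(R)
            else:
                P, pc = R, None
            caches.append((A, Z, R.shape, pc))
            A = P
        flat = A.reshape(A.shape[0], -1)
        logits = flat @ self.fc_W.T + self.fc_b
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, flat, A.shape, caches

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        probs, *_ = self._forward(np.asarray(patches, dtype=float))
        return probs

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(patches), axis=1)

    def fit(self, patches: np.ndarray, labels: np.ndarray) -> "CnnModel":
        X = np.asarray(patches, dtype=float)
        y = np.asarray(labels, dtype=int)
        N = X.shape[0]
        n_classes = self.fc_W.shape[0]
        Y = np.zeros((N, n_classes))
        Y[np.arange(N), y] = 1.0
        lr, l2 = self.cfg.learning_rate, self.cfg.l2_penalty
        mom = self.cfg.momentum
        vel = {"fc_W": np.zeros_like(self.fc_W),
               "fc_b": np.zeros_like(self.fc_b)}
        for k in range(len(self.conv_W)):
            vel[f"W{k}"] = np.zeros_like(self.conv_W[k])
            vel[f"b{k}"] = np.zeros_like(self.conv_b[k])
        for epoch in range(self.cfg.max_epochs):
            probs, flat, a_shape, caches = self._forward(X)
            loss = -np.mean(np.log(np.clip(probs[np.arange(N), y],
                                           1e-300, None)))
            if not np.isfinite(loss):
                raise RuntimeError(f"CNN training diverged at epoch {epoch}")
            G = (probs - Y) / N
            gfcW = G.T @ flat + 2 * l2 * self.fc_W
            gfcb = G.sum(axis=0)
            dA = (G @ self.fc_W).reshape(a_shape)
            updates = []
            for k in range(len(self.conv_W) - 1, -1, -1):
                A_in, Z, r_shape, pc = caches[k]
                dR = self._pool_backward(dA, pc, r_shape) if pc is not None \
                    else dA
                dZ = dR * (Z > 0)
                dWk, dbk, dA = self._conv_backward(A_in, self.conv_W[k], dZ)
                updates.append((k, dWk + 2 * l2 * self.conv_W[k], dbk))
            vel["fc_W"] = mom * vel["fc_W"] - lr * gfcW
            vel["fc_b"] = mom * vel["fc_b"] - lr * gfcb
            self.fc_W += vel["fc_W"]
            self.fc_b += vel["fc_b"]
            for k, dWk, dbk in updates:
                vel[f"W{k}"] = mom * vel[f"W{k}"] - lr * dWk
                vel[f"b{k}"] = mom * vel[f"b{k}"] - lr * dbk
                self.conv_W[k] += vel[f"W{k}"]
                self.conv_b[k] += vel[f"b{k}"]
        return self


def train_cnn(patches: PatchSet, cfg: CnnConfig | None = None) -> CnnModel:
    """Train the patch CNN on a labeled patch set."""
    cfg = cfg or CnnConfig()
    classes = set(np.unique(patches.labels))
    if classes != set(CLASS_LEGEND):
        raise ValueError(f"patch set must contain all 4 classes, got {classes}")
    model = CnnModel(in_channels=patches.patches.shape[-1],
                     n_classes=len(CLASS_LEGEND), cfg=cfg)
    return model.fit(patches.patches, patches.labels)


def _segment_with_cnn(model: CnnModel, study: MpMriStudy,
                      batch: int = 4096) -> LabelMap:
    voxels = [tuple(v) for v in np.ndindex(study.grid_shape)]
    pred = np.empty(len(voxels), dtype=np.int16)
    for start in range(0, len(voxels), batch):
        ps = extract_patches(study, voxels[start:start + batch])
        pred[start:start + len(ps.center_index)] = model.predict(ps.patches)
    return LabelMap(labels=pred.reshape(study.grid_shape))


def compare_architectures(
    cohort,
    seed: int = 0,
    ssae_cfg: SsaeTrainConfig | None = None,
    cnn_cfg: CnnConfig | None = None,
    cap_per_class: int = 1000,
) -> pd.DataFrame:
    """Train SSAE, MLP and CNN on identical twofold splits; lesion Dice table.

    Returns one row per architecture with mean and SD of per-subject
    lesion Dice versus the phantom truth.
    """
    from .evalmetrics import dice

    ssae_cfg = ssae_cfg or SsaeTrainConfig()
    cnn_cfg = cnn_cfg or CnnConfig()
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(cohort))
    folds = [idx[: len(cohort) // 2], idx[len(cohort) // 2:]]
    normalized = [normalize_channels(ph.study) for ph in cohort]

    per_arch: dict[str, list[float]] = {"ssae": [], "mlp": [], "cnn": []}
    for f, train_idx in enumerate(folds):
        test_idx = folds[1 - f]
        pooled = [
            s for i in train_idx
            for s in signature_sets_from_labels(
                normalized[i], cohort[i].truth_labels,
                max_per_class=cap_per_class, seed=seed + 17 * i)
        ]
        training = sample_balanced(pooled, cap_per_class=cap_per_class,
                                   seed=seed + f)
        fold_cfg = replace(ssae_cfg, seed=ssae_cfg.seed + f)
        ssae = train_segmenter(training, fold_cfg)
        mlp = train_mlp(training, fold_cfg)
        voxels = [prov[1] for prov in training.provenance]
        subj_of_row = [prov[0] for prov in training.provenance]
        by_subj: dict[str, MpMriStudy] = {
            normalized[i].subject_id: normalized[i] for i in train_idx}
        patch_list, label_list = [], []
        for r, (sid, vox) in enumerate(zip(subj_of_row, voxels)):
            ps = extract_patches(by_subj[sid], [vox])
            patch_list.append(ps.patches[0])
            label_list.append(training.labels[r])
        patches = PatchSet(patches=np.stack(patch_list),
                           labels=np.array(label_list),
                           center_index=voxels)
        cnn = train_cnn(patches, replace(cnn_cfg, seed=cnn_cfg.seed + f))

        for i in test_idx:
            truth = cohort[i].truth_labels.mask(LESION_CLASS)
            per_arch["ssae"].append(dice(
                segment_study(ssae, normalized[i]).mask(LESION_CLASS), truth))
            per_arch["mlp"].append(dice(
                segment_study(mlp, normalized[i]).mask(LESION_CLASS), truth))
            per_arch["cnn"].append(dice(
                _segment_with_cnn(cnn, normalized[i]).mask(LESION_CLASS),
                truth))
    rows = [{"architecture": arch,
             "mean_dice": float(np.mean(vals)),
             "sd_dice": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
            for arch, vals in per_arch.items()]
    return pd.DataFrame(rows)
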