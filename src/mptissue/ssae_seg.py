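"""Stacked sparse autoencoder segmentation network.

Greedy layer-wise pretraining of sparse autoencoders (saturating-linear
units, KL-divergence sparsity penalty plus L2 weight decay), a softmax
head over the four tissue classes, optional joint fine-tuning, and
voxelwise volume segmentation.

Default architecture: 5 hidden layers of 10 nodes each.  Optimization is
deterministic full-batch gradient descent with a fixed learning rate;
the parameters with the lowest observed loss are returned.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .mpmri_io import CLASS_LEGEND, LabelMap, MpMriStudy
from .signatures import TissueSignatureSet

__all__ = [
    "satlin",
    "kl_sparsity",
    "SaeLayer",
    "SsaeTrainConfig",
    "SsaeModel",
    "train_sae_layer",
    "pretrain_stack",
    "train_softmax_head",
    "fine_tune",
    "train_segmenter",
    "segment_study",
    "sae_loss",
]

_EPS = 1e-7


def satlin(x):
    """Saturating linear unit: 0 for x<=0, x on (0,1), 1 for x>=1."""
    return np.clip(x, 0.0, 1.0)


def _satlin_grad(z):
    return ((z > 0.0) & (z < 1.0)).astype(float)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


_ACTIVATIONS = {
    "satlin": (satlin, _satlin_grad),
    "sigmoid": (_sigmoid, lambda z: _sigmoid(z) * (1.0 - _sigmoid(z))),
    "linear": (lambda z: z, lambda z: np.ones_like(z)),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0.0).astype(float)),
    "leaky_relu": (lambda z: np.where(z > 0.0, z, 0.1 * z),
                   lambda z: np.where(z > 0.0, 1.0, 0.1)),
}


def kl_sparsity(rho_hat: np.ndarray, rho: float) -> float:
    """KL-divergence sparsity penalty between target and mean activations.

    ``sum_j rho*ln(rho/rho_hat_j) + (1-rho)*ln((1-rho)/(1-rho_hat_j))``;
    components of ``rho_hat`` are clipped into (eps, 1-eps).  Zero iff
    every component equals ``rho``, strictly positive otherwise.
    """
    r = np.clip(np.asarray(rho_hat, dtype=float), _EPS, 1.0 - _EPS)
    return float(np.sum(rho * np.log(rho / r)
                        + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - r))))


def _kl_grad(rho_hat: np.ndarray, rho: float) -> np.ndarray:
    # wider clip than the loss (1e-2): bounds the gradient near saturation,
    # where satlin units would otherwise receive explosive updates
    r = np.clip(np.asarray(rho_hat, dtype=float), 1e-2, 1.0 - 1e-2)
    return -rho / r + (1.0 - rho) / (1.0 - r)


def _clip_gradients(grads, max_norm: float = 5.0):
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
    if total > max_norm:
        scale = max_norm / total
        return tuple(g * scale for g in grads)
    return grads


@dataclass
class SaeLayer:
    """One sparse-autoencoder layer (encoder + decoder weights)."""

    W_enc: np.ndarray  # d_out x d_in
    b_enc: np.ndarray  # d_out
    W_dec: np.ndarray  # d_in x d_out
    b_dec: np.ndarray  # d_in
    activation: str = "satlin"
    decoder_activation: str = "linear"

    @property
    def d_in(self) -> int:
        return self.W_enc.shape[1]

    @property
    def d_out(self) -> int:
        return self.W_enc.shape[0]

    def encode(self, X: np.ndarray) -> np.ndarray:
        act, _ = _ACTIVATIONS[self.activation]
        return act(np.atleast_2d(X) @ self.W_enc.T + self.b_enc)

    def decode(self, H: np.ndarray) -> np.ndarray:
        act, _ = _ACTIVATIONS[self.decoder_activation]
        return act(np.atleast_2d(H) @ self.W_dec.T + self.b_dec)


@dataclass
class SsaeTrainConfig:
    """Hyperparameters for pretraining, head training and fine-tuning.

    The regularization defaults (L2 penalty 0.001, sparsity proportion
    0.25, sparsity weight 4) are the published operating point; the
    optimizer settings (plain full-batch gradient descent) are ours.
    """

    l2_penalty: float = 0.001
    #: weight decay for the supervised head and fine-tuning; kept much
    #: smaller than the autoencoder penalty so the head can exploit small
    #: encoding gaps between classes
    head_l2_penalty: float = 1e-5
    sparsity_proportion: float = 0.25
    sparsity_weight: float = 4.0
    n_layers: int = 5
    hidden_size: int = 10
    max_epochs: int = 400
    learning_rate: float = 0.1
    head_epochs: int = 800
    head_learning_rate: float = 1.0
    fine_tune_epochs: int = 400
    fine_tune_learning_rate: float = 0.5
    fine_tune: bool = True
    #: gradient leak through saturated satlin units during supervised joint
    #: training (forward pass stays exact); 0 disables
    saturation_leak: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sparsity_proportion < 1.0:
            raise ValueError("sparsity_proportion must be in (0, 1)")
        if self.l2_penalty < 0 or self.sparsity_weight < 0:
            raise ValueError("penalties must be non-negative")


@dataclass
class SsaeModel:
    """Encoder stack plus softmax classification head."""

    layers: list[SaeLayer]
    softmax_W: np.ndarray  # n_classes x d_hidden
    softmax_b: np.ndarray  # n_classes
    class_legend: dict[int, str] = field(default_factory=lambda: dict(CLASS_LEGEND))
    channel_order: list[str] | None = None

    def encode(self, X: np.ndarray) -> np.ndarray:
        H = np.atleast_2d(np.asarray(X, dtype=float))
        for layer in self.layers:
            H = layer.encode(H)
        return H

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self.encode(X) @ self.softmax_W.T + self.softmax_b
        return _softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        # np.argmax breaks ties toward the lower class id
        return np.argmax(self.predict_proba(X), axis=1)

    @property
    def input_dim(self) -> int:
        return self.layers[0].d_in

    def channel_order_hash(self) -> str | None:
        if self.channel_order is None:
            return None
        return hashlib.sha256("|".join(self.channel_order).encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        payload = {
            "layers": [
                {"W_enc": l.W_enc.tolist(), "b_enc": l.b_enc.tolist(),
                 "W_dec": l.W_dec.tolist(), "b_dec": l.b_dec.tolist(),
                 "activation": l.activation,
                 "decoder_activation": l.decoder_activation}
                for l in self.layers
            ],
            "softmax_W": self.softmax_W.tolist(),
            "softmax_b": self.softmax_b.tolist(),
            "class_legend": {str(k): v for k, v in self.class_legend.items()},
            "channel_order": self.channel_order,
        }
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def load(path: str | Path) -> "SsaeModel":
        d = json.loads(Path(path).read_text())
        layers = [SaeLayer(np.array(l["W_enc"]), np.array(l["b_enc"]),
                           np.array(l["W_dec"]), np.array(l["b_dec"]),
                           l["activation"], l["decoder_activation"])
                  for l in d["layers"]]
        return SsaeModel(layers=layers, softmax_W=np.array(d["softmax_W"]),
                         softmax_b=np.array(d["softmax_b"]),
                         class_legend={int(k): v
                                       for k, v in d["class_legend"].items()},
                         channel_order=d["channel_order"])


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _init_weights(d_out: int, d_in: int, rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-limit, limit, size=(d_out, d_in))


def sae_loss(layer: SaeLayer, X: np.ndarray, cfg: SsaeTrainConfig) -> float:
    """Full autoencoder objective for a parameter snapshot (test hook)."""
    X = np.atleast_2d(X)
    H = layer.encode(X)
    Xhat = layer.decode(H)
    mse = float(np.mean(np.sum((X - Xhat) ** 2, axis=1)))
    l2 = cfg.l2_penalty * (float(np.sum(layer.W_enc ** 2))
                           + float(np.sum(layer.W_dec ** 2)))
    kl = cfg.sparsity_weight * kl_sparsity(H.mean(axis=0),
                                           cfg.sparsity_proportion)
    return mse + l2 + kl


def _sae_grads(layer: SaeLayer, X: np.ndarray, cfg: SsaeTrainConfig):
    """Analytic gradients of :func:`sae_loss` w.r.t. all four parameter arrays."""
    N = X.shape[0]
    act, act_g = _ACTIVATIONS[layer.activation]
    dec_act, dec_g = _ACTIVATIONS[layer.decoder_activation]
    Z = X @ layer.W_enc.T + layer.b_enc
    H = act(Z)
    Zd = H @ layer.W_dec.T + layer.b_dec
    Xhat = dec_act(Zd)
    R = Xhat - X

    dZd = (2.0 / N) * R * dec_g(Zd)
    gWd = dZd.T @ H + 2.0 * cfg.l2_penalty * layer.W_dec
    gbd = dZd.sum(axis=0)

    dH = dZd @ layer.W_dec
    if cfg.sparsity_weight > 0:
        dH = dH + (cfg.sparsity_weight / N) * _kl_grad(
            H.mean(axis=0), cfg.sparsity_proportion)
    dZ = dH * act_g(Z)
    gWe = dZ.T @ X + 2.0 * cfg.l2_penalty * layer.W_enc
    gbe = dZ.sum(axis=0)
    return gWe, gbe, gWd, gbd


def train_sae_layer(
    X: np.ndarray,
    d_out: int,
    cfg: SsaeTrainConfig,
    *,
    activation: str = "satlin",
    decoder_activation: str = "linear",
) -> SaeLayer:
    """Train one sparse autoencoder layer by full-batch gradient descent.

    Objective: mean squared reconstruction error + L2 weight decay on
    encoder and decoder + the KL sparsity penalty on mean hidden
    activations.  Returns the best-loss parameters seen; deterministic
    given ``cfg.seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N, d_in = X.shape
    if N < d_out:
        raise ValueError(f"need at least d_out={d_out} rows, got {N}")
    rng = np.random.default_rng(cfg.seed)
    layer = SaeLayer(
        W_enc=_init_weights(d_out, d_in, rng),
        # positive encoder bias keeps saturating-linear units alive at init
        b_enc=np.full(d_out, cfg.sparsity_proportion),
        W_dec=_init_weights(d_in, d_out, rng),
        b_dec=np.zeros(d_in),
        activation=activation,
        decoder_activation=decoder_activation,
    )
    best = _snapshot(layer)
    best_loss = sae_loss(layer, X, cfg)
    lr = cfg.learning_rate
    for epoch in range(cfg.max_epochs):
        gWe, gbe, gWd, gbd = _clip_gradients(_sae_grads(layer, X, cfg))
        layer.W_enc -= lr * gWe
        layer.b_enc -= lr * gbe
        layer.W_dec -= lr * gWd
        layer.b_dec -= lr * gbd
        loss = sae_loss(layer, X, cfg)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite autoencoder loss at epoch {epoch} "
                f"(learning_rate={lr}); lower the learning rate")
        if loss < best_loss:
            best_loss = loss
            best = _snapshot(layer)
    _restore(layer, best)
    return layer


def _snapshot(layer: SaeLayer):
    return (layer.W_enc.copy(), layer.b_enc.copy(),
            layer.W_dec.copy(), layer.b_dec.copy())


def _restore(layer: SaeLayer, snap) -> None:
    layer.W_enc, layer.b_enc, layer.W_dec, layer.b_dec = \
        snap[0].copy(), snap[1].copy(), snap[2].copy(), snap[3].copy()


def pretrain_stack(X, cfg: SsaeTrainConfig) -> list[SaeLayer]:
    """Greedy layer-wise pretraining.

    Layer k is trained on the encodings produced by layers 1..k-1; every
    hidden layer has ``cfg.hidden_size`` nodes.
    """
    if isinstance(X, TissueSignatureSet):
        X = X.signatures
    X = np.atleast_2d(np.asarray(X, dtype=float))
    layers: list[SaeLayer] = []
    H = X
    for k in range(cfg.n_layers):
        layer_cfg = replace(cfg, seed=cfg.seed + k)
        layer = train_sae_layer(H, cfg.hidden_size, layer_cfg)
        layers.append(layer)
        H = layer.encode(H)
    return layers


def train_softmax_head(
    encoded: np.ndarray, labels: np.ndarray, cfg: SsaeTrainConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial logistic regression by full-batch gradient descent."""
    H = np.atleast_2d(np.asarray(encoded, dtype=float))
    y = np.asarray(labels, dtype=int)
    classes = sorted(CLASS_LEGEND)
    missing = set(classes) - set(np.unique(y))
    if missing:
        raise ValueError(f"classes missing from training labels: {missing}")
    n_classes, d = len(classes), H.shape[1]
    N = H.shape[0]
    Y = np.zeros((N, n_classes))
    Y[np.arange(N), y] = 1.0
    rng = np.random.default_rng(cfg.seed + 1000)
    W = _init_weights(n_classes, d, rng)
    b = np.zeros(n_classes)
    lr = cfg.head_learning_rate
    for _ in range(cfg.head_epochs):
        P = _softmax(H @ W.T + b)
        G = (P - Y) / N
        W -= lr * (G.T @ H + 2.0 * cfg.head_l2_penalty * W)
        b -= lr * G.sum(axis=0)
    return W, b


def _ce_loss(model: SsaeModel, X: np.ndarray, Y: np.ndarray,
             l2: float) -> float:
    P = model.predict_proba(X)
    ce = -float(np.mean(np.log(np.clip(P[Y.astype(bool)], 1e-300, None))))
    reg = sum(float(np.sum(l.W_enc ** 2)) for l in model.layers) \
        + float(np.sum(model.softmax_W ** 2))
    return ce + l2 * reg


def fine_tune(model: SsaeModel, X, labels, cfg: SsaeTrainConfig) -> SsaeModel:
    """Joint supervised fine-tuning of the stack and head.

    Full-batch gradient descent on cross-entropy + L2; if the final loss
    exceeds the starting loss the pre-fine-tune weights are restored with
    a warning.  With ``cfg.fine_tune`` false the model is returned
    unchanged.
    """
    if not cfg.fine_tune:
        return model
    if isinstance(X, TissueSignatureSet):
        labels = X.labels
        X = X.signatures
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(labels, dtype=int)
    N = X.shape[0]
    n_classes = model.softmax_W.shape[0]
    Y = np.zeros((N, n_classes))
    Y[np.arange(N), y] = 1.0
    l2 = cfg.head_l2_penalty

    def act_grad(layer, Z):
        g = _ACTIVATIONS[layer.activation][1](Z)
        if cfg.saturation_leak > 0 and layer.activation == "satlin":
            g = np.maximum(g, cfg.saturation_leak)
        return g

    start = ([_snapshot(l) for l in model.layers],
             model.softmax_W.copy(), model.softmax_b.copy())
    start_loss = _ce_loss(model, X, Y, l2)
    best, best_loss = start, start_loss
    lr = cfg.fine_tune_learning_rate
    for epoch in range(cfg.fine_tune_epochs):
        # forward pass, caching pre-activations
        acts = [X]
        zs = []
        H = X
        for layer in model.layers:
            Z = H @ layer.W_enc.T + layer.b_enc
            zs.append(Z)
            H = _ACTIVATIONS[layer.activation][0](Z)
            acts.append(H)
        P = _softmax(H @ model.softmax_W.T + model.softmax_b)
        G = (P - Y) / N
        gW_soft = G.T @ H + 2.0 * l2 * model.softmax_W
        gb_soft = G.sum(axis=0)
        dH = G @ model.softmax_W
        grads = []
        for k in range(len(model.layers) - 1, -1, -1):
            layer = model.layers[k]
            dZ = dH * act_grad(layer, zs[k])
            gW = dZ.T @ acts[k] + 2.0 * l2 * layer.W_enc
            gb = dZ.sum(axis=0)
            grads.append((k, gW, gb))
            dH = dZ @ layer.W_enc
        flat = [gW_soft, gb_soft] + [g for _, gW, gb in grads for g in (gW, gb)]
        clipped = _clip_gradients(tuple(flat))
        gW_soft, gb_soft = clipped[0], clipped[1]
        model.softmax_W -= lr * gW_soft
        model.softmax_b -= lr * gb_soft
        for (k, _, _), gW, gb in zip(grads, clipped[2::2], clipped[3::2]):
            model.layers[k].W_enc -= lr * gW
            model.layers[k].b_enc -= lr * gb
        loss = _ce_loss(model, X, Y, l2)
        if not np.isfinite(loss):
            warnings.warn("fine-tuning diverged; reverting to pretrained weights")
            loss = np.inf
            best, best_loss = start, start_loss
            break
        if loss < best_loss:
            best_loss = loss
            best = ([_snapshot(l) for l in model.layers],
                    model.softmax_W.copy(), model.softmax_b.copy())
    if best_loss > start_loss:
        warnings.warn("fine-tuning did not improve the loss; reverting")
        best = start
    for layer, snap in zip(model.layers, best[0]):
        _restore(layer, snap)
    model.softmax_W, model.softmax_b = best[1].copy(), best[2].copy()
    return model


def train_segmenter(
    training: TissueSignatureSet,
    cfg: SsaeTrainConfig,
    channel_order: list[str] | None = None,
) -> SsaeModel:
    """Pretrain the stack, train the softmax head, optionally fine-tune."""
    layers = pretrain_stack(training.signatures, cfg)
    H = training.signatures
    for layer in layers:
        H = layer.encode(H)
    W, b = train_softmax_head(H, training.labels, cfg)
    model = SsaeModel(layers=layers, softmax_W=W, softmax_b=b,
                      channel_order=channel_order)
    return fine_tune(model, training.signatures, training.labels, cfg)


def segment_study(model: SsaeModel, study: MpMriStudy) -> LabelMap:
    """Voxelwise argmax segmentation of a normalized study.

    Ties at the argmax resolve toward the lower class id.  The study's
    channel order must match the model's recorded layout when present.
    """
    if study.n_channels != model.input_dim:
        raise ValueError(
            f"study has {study.n_channels} channels, model expects "
            f"{model.input_dim}")
    if model.channel_order is not None \
            and list(study.channel_order) != list(model.channel_order):
        raise ValueError("study channel order does not match the model layout")
    X = study.signatures()
    pred = model.predict(X).astype(np.int16)
    return LabelMap(labels=pred.reshape(study.grid_shape),
                    legend=dict(model.class_legend))
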