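"""Eigenimage linear contrast filter.

Fits the D-dimensional linear filter that maximizes the projection of a
desired tissue signature while suppressing undesired tissue signatures,
applies it to a study to form a scalar contrast volume, and thresholds
that volume (mean + 1.96 SD over a foreground mask) into a lesion mask
used as the radiological ground truth for segmentation scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .mpmri_io import MpMriStudy
from .signatures import TissueSignatureSet

__all__ = [
    "EigenFilterWeights",
    "fit_eigenimage_filter",
    "apply_eigenimage",
    "threshold_eigenimage",
]


@dataclass
class EigenFilterWeights:
    """Linear filter weights, normalized so ``w @ desired_mean == 1``."""

    w: np.ndarray
    desired_mean: np.ndarray
    ridge: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.desired_mean = np.asarray(self.desired_mean, dtype=float)
        if abs(float(self.w @ self.desired_mean) - 1.0) > 1e-9:
            raise ValueError("weights violate the unit-projection constraint")

    def to_json(self, path: str | Path, channel_order: list[str] | None = None):
        payload = {"w": self.w.tolist(), "desired_mean": self.desired_mean.tolist(),
                   "ridge": self.ridge, "channel_order": channel_order}
        Path(path).write_text(json.dumps(payload, indent=2))

    @staticmethod
    def from_json(path: str | Path) -> "EigenFilterWeights":
        d = json.loads(Path(path).read_text())
        return EigenFilterWeights(np.array(d["w"]), np.array(d["desired_mean"]),
                                  d["ridge"])


def _as_matrix(s) -> np.ndarray:
    if isinstance(s, TissueSignatureSet):
        return s.signatures
    return np.atleast_2d(np.asarray(s, dtype=float))


def fit_eigenimage_filter(
    desired, undesired, ridge: float = 1e-6
) -> EigenFilterWeights:
    """Closed-form constrained least-squares fit of the contrast filter.

    Minimizes ``sum_i (w @ u_i)^2 + ridge * ||w||^2`` over undesired rows
    ``u_i`` subject to ``w @ d_bar = 1`` where ``d_bar`` is the mean of
    the desired rows; solution ``w ∝ C^{-1} d_bar`` with
    ``C = U^T U + ridge * I``.
    """
    D = _as_matrix(desired)
    U = _as_matrix(undesired)
    if D.size == 0 or U.size == 0:
        raise ValueError("desired and undesired sets must be nonempty")
    if D.shape[1] != U.shape[1]:
        raise ValueError("dimensionality mismatch between desired and undesired")
    d_bar = D.mean(axis=0)
    C = U.T @ U + ridge * np.eye(U.shape[1])
    try:
        w = np.linalg.solve(C, d_bar)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular undesired covariance; increase ridge") from exc
    scale = float(w @ d_bar)
    if abs(scale) < 1e-300:
        raise ValueError("degenerate contrast: desired mean annihilated by C^-1")
    w = w / scale
    return EigenFilterWeights(w=w, desired_mean=d_bar, ridge=float(ridge))


def apply_eigenimage(study: MpMriStudy, weights: EigenFilterWeights) -> np.ndarray:
    """Project every voxel signature onto the filter: EI(v) = w @ sig(v)."""
    if weights.w.shape[0] != study.n_channels:
        raise ValueError(
            f"filter dimension {weights.w.shape[0]} != study channels "
            f"{study.n_channels}")
    return np.einsum("...d,d->...", study.stacked(), weights.w)


def threshold_eigenimage(
    ei: np.ndarray,
    foreground: np.ndarray,
    *,
    z: float = 1.96,
    two_sided: bool = False,
    keep_largest_component: bool = True,
) -> np.ndarray:
    """Histogram threshold of the contrast volume into a lesion mask.

    The cut is ``mean + z * SD`` of EI over the foreground (one-sided
    upper by default; ``two_sided`` also keeps values below
    ``mean - z * SD``).  Optionally only the largest 26-connected
    component is retained.
    """
    ei = np.asarray(ei, dtype=float)
    fg = np.asarray(foreground, dtype=bool)
    if fg.shape != ei.shape:
        raise ValueError("foreground shape mismatch")
    if not fg.any():
        raise ValueError("empty foreground mask")
    vals = ei[fg]
    sd = float(vals.std())
    if sd == 0.0:
        raise ValueError("zero-variance contrast over foreground")
    mu = float(vals.mean())
    mask = fg & (ei > mu + z * sd)
    if two_sided:
        mask |= fg & (ei < mu - z * sd)
    if keep_largest_component and mask.any():
        struct = np.ones((3,) * mask.ndim, dtype=bool)
        lab, n = ndimage.label(mask, structure=struct)
        if n > 1:
            sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
    return mask
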