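"""Tissue-signature extraction.

Signatures are per-voxel columns across channels.  Labeled sets are built
from sparse seed points via intensity region growing on individual
channels, fused by a voxelwise logical AND, then sampled to a balanced
training set with a per-class cap.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .mpmri_io import CLASS_LEGEND, LabelMap, MpMriStudy

__all__ = [
    "TissueSignatureSet",
    "region_grow",
    "multiparametric_roi",
    "extract_signatures",
    "sample_balanced",
    "auto_seeds",
    "signature_sets_from_labels",
]


@dataclass
class TissueSignatureSet:
    """N x D signature matrix with aligned labels and provenance rows."""

    signatures: np.ndarray
    labels: np.ndarray
    provenance: list[tuple[str, tuple[int, int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signatures = np.atleast_2d(np.asarray(self.signatures, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if self.signatures.shape[0] != self.labels.shape[0]:
            raise ValueError("signatures and labels row counts differ")
        if self.provenance and len(self.provenance) != len(self.labels):
            raise ValueError("provenance length mismatch")

    def __len__(self) -> int:
        return int(self.labels.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.signatures.shape[1])

    @staticmethod
    def concatenate(sets: "list[TissueSignatureSet]") -> "TissueSignatureSet":
        if not sets:
            raise ValueError("no sets to concatenate")
        return TissueSignatureSet(
            signatures=np.vstack([s.signatures for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            provenance=sum((list(s.provenance) for s in sets), []),
        )


def _neighbor_offsets(ndim_3d: bool) -> list[tuple[int, int, int]]:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            zs = (-1, 0, 1) if ndim_3d else (0,)
            for dz in zs:
                if (dx, dy, dz) != (0, 0, 0):
                    offs.append((dx, dy, dz))
    return offs


def region_grow(
    volume: np.ndarray,
    seed_voxel: tuple[int, ...],
    tolerance_fraction: float = 0.05,
    *,
    mode: str = "3d",
    tolerance_reference: str = "region_mean",
    eps_abs: float = 0.0,
) -> np.ndarray:
    """Grow a connected region from a seed by intensity similarity.

    A frontier voxel ``v`` is accepted iff
    ``|I(v) - mu_R| <= max(tolerance_fraction * |mu_R|, eps_abs)`` where
    ``mu_R`` is the running mean of the accepted region
    (``tolerance_reference="region_mean"``) — or, with
    ``tolerance_reference="global_sd"``, iff
    ``|I(v) - mu_R| <= tolerance_fraction * std(volume)``.

    Growth uses 26-connectivity in 3-D (``mode="3d"``) or 8-connectivity
    within the seed's slice (``mode="2d"``).  The frontier is processed in
    lexicographic voxel order, so output is deterministic; a voxel
    examined and rejected once is never revisited.

    Returns a boolean mask (single connected component containing the seed).
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim == 2:
        vol = vol[:, :, None]
        seed_voxel = (*seed_voxel, 0) if len(seed_voxel) == 2 else seed_voxel
        mode = "2d"
    seed = tuple(int(c) for c in seed_voxel)
    if len(seed) != 3:
        raise ValueError("seed must be a 3-tuple (or 2-tuple for 2-D input)")
    if not all(0 <= seed[i] < vol.shape[i] for i in range(3)):
        raise ValueError(f"seed {seed} outside grid {vol.shape}")
    if not np.isfinite(vol[seed]):
        raise ValueError("seed voxel is non-finite")
    if tolerance_reference not in ("region_mean", "global_sd"):
        raise ValueError(f"unknown tolerance_reference: {tolerance_reference}")
    global_band = tolerance_fraction * float(np.std(vol))

    offsets = _neighbor_offsets(mode == "3d")
    mask = np.zeros(vol.shape, dtype=bool)
    visited = np.zeros(vol.shape, dtype=bool)
    mask[seed] = visited[seed] = True
    total, count = float(vol[seed]), 1
    heap: list[tuple[int, int, int]] = []
    for off in offsets:
        nb = (seed[0] + off[0], seed[1] + off[1], seed[2] + off[2])
        if all(0 <= nb[i] < vol.shape[i] for i in range(3)) and not visited[nb]:
            visited[nb] = True
            heapq.heappush(heap, nb)
    while heap:
        v = heapq.heappop(heap)
        mu = total / count
        if tolerance_reference == "region_mean":
            band = max(tolerance_fraction * abs(mu), eps_abs)
        else:
            band = max(global_band, eps_abs)
        if np.isfinite(vol[v]) and abs(vol[v] - mu) <= band:
            mask[v] = True
            total += float(vol[v])
            count += 1
            for off in offsets:
                nb = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if all(0 <= nb[i] < vol.shape[i] for i in range(3)) \
                        and not visited[nb]:
                    visited[nb] = True
                    heapq.heappush(heap, nb)
    if volume.ndim == 2:
        return mask[:, :, 0]
    return mask


def multiparametric_roi(masks: list[np.ndarray]) -> np.ndarray:
    """Voxelwise logical AND of per-channel ROIs."""
    if not masks:
        raise ValueError("empty mask list")
    shapes = {np.asarray(m).shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"masks have inconsistent shapes: {shapes}")
    out = np.ones(masks[0].shape, dtype=bool)
    for m in masks:
        out &= np.asarray(m, dtype=bool)
    if not out.any():
        warnings.warn("multiparametric ROI is empty (disjoint channel ROIs)")
    return out


def extract_signatures(
    study: MpMriStudy, roi: np.ndarray, class_id: int
) -> TissueSignatureSet:
    """One signature row per ROI voxel, channelwise in ``channel_order``."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != study.grid_shape:
        raise ValueError("roi shape does not match study grid")
    if not roi.any():
        raise ValueError("empty roi")
    sigs = study.signatures(roi)
    voxels = [tuple(int(c) for c in v) for v in np.argwhere(roi)]
    return TissueSignatureSet(
        signatures=sigs,
        labels=np.full(len(voxels), int(class_id)),
        provenance=[(study.subject_id, v) for v in voxels],
    )


def sample_balanced(
    sets: list[TissueSignatureSet],
    cap_per_class: int = 1000,
    seed: int = 0,
) -> TissueSignatureSet:
    """Uniform class-balanced sample pooled across subjects.

    Per class, ``min(cap_per_class, available)`` rows are drawn without
    replacement from the pooled sets; all classes are then truncated to
    the minimum per-class count so the result is exactly balanced.
    Deterministic given ``seed``.
    """
    pool = TissueSignatureSet.concatenate(sets)
    classes = sorted(CLASS_LEGEND)
    counts = {c: int((pool.labels == c).sum()) for c in classes}
    empty = [c for c, n in counts.items() if n == 0]
    if empty:
        raise ValueError(f"classes with zero signatures: {empty}")
    target = min(min(cap_per_class, n) for n in counts.values())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(pool.labels == c)
        chosen = rng.choice(idx, size=target, replace=False)
        keep.append(np.sort(chosen))
    sel = np.concatenate(keep)
    return TissueSignatureSet(
        signatures=pool.signatures[sel],
        labels=pool.labels[sel],
        provenance=[pool.provenance[i] for i in sel] if pool.provenance else [],
    )


def auto_seeds(
    truth: LabelMap, n_per_class: int = 1, seed: int = 0
) -> dict[int, list[tuple[int, int, int]]]:
    """Pick class-representative seed voxels from a truth label map.

    Testing convenience for phantom runs (stands in for manual seed
    selection): per class, candidate voxels are the eroded class interior
    (falling back to the full class mask) and ``n_per_class`` are drawn
    deterministically.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, list[tuple[int, int, int]]] = {}
    for cid in sorted(CLASS_LEGEND):
        m = truth.mask(cid)
        if not m.any():
            raise ValueError(f"class {cid} absent from truth labels")
        interior = ndimage.binary_erosion(m, iterations=1)
        cands = np.argwhere(interior if interior.any() else m)
        take = min(n_per_class, len(cands))
        idx = rng.choice(len(cands), size=take, replace=False)
        out[cid] = [tuple(int(c) for c in cands[i]) for i in np.sort(idx)]
    return out


def signature_sets_from_labels(
    study: MpMriStudy,
    truth: LabelMap,
    max_per_class: int = 1000,
    seed: int = 0,
) -> list[TissueSignatureSet]:
    """Per-class signature sets sampled directly from a truth label map.

    Phantom/testing convenience: bypasses seeded region growing (which
    emulates manual ROI drawing on patient data) by sampling up to
    ``max_per_class`` voxels of each class.
    """
    rng = np.random.default_rng(seed)
    sets = []
    for cid in sorted(CLASS_LEGEND):
        m = truth.mask(cid)
        if not m.any():
            raise ValueError(f"class {cid} absent from truth labels")
        voxels = np.argwhere(m)
        if len(voxels) > max_per_class:
            voxels = voxels[np.sort(rng.choice(len(voxels), size=max_per_class,
                                               replace=False))]
        roi = np.zeros(study.grid_shape, dtype=bool)
        roi[tuple(voxels.T)] = True
        sets.append(extract_signatures(study, roi, cid))
    return sets
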