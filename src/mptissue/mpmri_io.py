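"""Multichannel MRI study container, NIfTI round-trip I/O, ADC map
derivation and intensity normalization.

A study is an ordered set of co-registered 3-D scalar channel volumes
(T1w, T2w, DWI at two b-values, a derived ADC map and a series of DCE
frames).  The per-voxel column across channels, taken in ``channel_order``,
is the raw tissue signature used by every downstream stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "MpMriStudy",
    "LabelMap",
    "CLASS_LEGEND",
    "compute_adc",
    "normalize_channels",
    "read_study",
    "write_study",
    "read_labelmap",
    "write_labelmap",
]

#: Canonical tissue-class legend shared across the package.
CLASS_LEGEND = {0: "background", 1: "fat", 2: "glandular", 3: "lesion"}

#: Frozen channel layout. DCE frames are appended as ``dce_01 .. dce_NN``.
BASE_CHANNEL_ORDER = ("t1w", "t2w", "dwi_b0", "dwi_bhigh", "adc")


def dce_channel_names(n_frames: int) -> list[str]:
    """Channel names for ``n_frames`` dynamic contrast-enhanced frames."""
    return [f"dce_{i + 1:02d}" for i in range(n_frames)]


def default_channel_order(n_dce_frames: int) -> list[str]:
    """The frozen channel order: T1w, T2w, DWI pair, ADC, then DCE frames."""
    return list(BASE_CHANNEL_ORDER) + dce_channel_names(n_dce_frames)


@dataclass
class MpMriStudy:
    """An ordered set of co-registered 3-D scalar channel volumes.

    Parameters
    ----------
    channels
        Mapping from channel name to a 3-D float array. All channels must
        share one grid shape.
    channel_order
        Permutation of the channel names fixing the signature layout.
    voxel_spacing
        Voxel edge lengths in mm, (x, y, z).
    subject_id
        Free-form identifier.
    """

    channels: dict[str, np.ndarray]
    channel_order: list[str]
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("study has no channels")
        if sorted(self.channel_order) != sorted(self.channels):
            raise ValueError("channel_order is not a permutation of channel names")
        shapes = {ch: v.shape for ch, v in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channels have inconsistent shapes: {shapes}")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def n_channels(self) -> int:
        """Signature dimensionality D."""
        return len(self.channel_order)

    def stacked(self) -> np.ndarray:
        """Volumes stacked on a trailing channel axis, shape (*grid, D)."""
        return np.stack([self.channels[c] for c in self.channel_order], axis=-1)

    def signature_at(self, voxel: tuple[int, int, int]) -> np.ndarray:
        """The D-vector of channel intensities at one voxel."""
        return np.array([self.channels[c][voxel] for c in self.channel_order])

    def signatures(self, mask: np.ndarray | None = None) -> np.ndarray:
        """N x D matrix of signatures, one row per voxel of ``mask``.

        With ``mask=None`` every voxel is returned in C order.
        """
        stacked = self.stacked()
        if mask is None:
            return stacked.reshape(-1, self.n_channels)
        return stacked[np.asarray(mask, dtype=bool)]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing))


@dataclass
class LabelMap:
    """Integer tissue-class volume with values in {0, 1, 2, 3}."""

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=lambda: dict(CLASS_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer volume")
        extra = set(np.unique(self.labels)) - set(self.legend)
        if extra:
            raise ValueError(f"labels contain values outside the legend: {extra}")

    def mask(self, class_id: int) -> np.ndarray:
        return self.labels == class_id


def compute_adc(
    s0: np.ndarray,
    s_b: np.ndarray,
    b: float,
    *,
    eps: float = 1e-6,
    adc_max: float = 4.0,
) -> np.ndarray:
    """Apparent diffusion coefficient map from a DWI pair.

    ADC(v) = ln(s0(v) / s_b(v)) / b, reported in 1e-3 mm^2/s, at voxels
    where both signals exceed ``eps``; 0 elsewhere.  Output clipped to
    [0, adc_max].

    Parameters
    ----------
    s0, s_b
        Signal volumes at b=0 and at the high b-value; same shape.
    b
        The high b-value in s/mm^2; must be positive.
    """
    s0 = np.asarray(s0, dtype=float)
    s_b = np.asarray(s_b, dtype=float)
    if s0.shape != s_b.shape:
        raise ValueError(f"shape mismatch: {s0.shape} vs {s_b.shape}")
    if b <= 0:
        raise ValueError(f"b must be positive, got {b}")
    valid = (s0 > eps) & (s_b > eps)
    adc = np.zeros_like(s0)
    # scale by 1e3: b is in s/mm^2 and the map is reported in 1e-3 mm^2/s
    np.divide(np.log(s0, where=valid, out=np.zeros_like(s0))
              - np.log(s_b, where=valid, out=np.zeros_like(s_b)),
              b / 1e3, out=adc, where=valid)
    return np.clip(adc, 0.0, adc_max)


#: channels with physical units and a known range get a fixed affine map
#: instead of a data-driven one (the ADC map is quantitative,
#: 0..4 x 1e-3 mm^2/s); data-driven scaling would let one tissue's
#: between-subject variation rescale the whole axis.
DEFAULT_FIXED_RANGES = {"adc": (0.0, 4.0)}


def _default_scale_groups(channel_order: Sequence[str]) -> list[list[str]]:
    """Channels acquired as one sequence share one intensity scale.

    All DCE frames form a single time series (a per-frame scale would
    imprint the enhancing tissue's kinetics onto non-enhancing tissue),
    and the two DWI b-values share one scale (preserving their signal
    ratio).  Remaining channels are scaled individually.
    """
    groups: list[list[str]] = []
    dce = [c for c in channel_order if c.startswith("dce_")]
    if dce:
        groups.append(dce)
    dwi = [c for c in channel_order if c.startswith("dwi_")]
    if dwi:
        groups.append(dwi)
    grouped = {c for g in groups for c in g}
    groups.extend([c] for c in channel_order if c not in grouped)
    return groups


def normalize_channels(
    study: MpMriStudy,
    method: str = "percentile",
    percentiles: tuple[float, float] = (0.1, 99.9),
    fixed_ranges: Mapping[str, tuple[float, float]] | None = None,
    scale_groups: Sequence[Sequence[str]] | None = None,
) -> MpMriStudy:
    """Map each channel to [0, 1] with per-sequence scaling.

    ``method="percentile"`` uses a robust min-max over the given
    percentiles followed by clipping; ``method="minmax"`` uses the full
    range.  Channels named in ``fixed_ranges`` (default: the quantitative
    ADC map over [0, 4]) use the stated fixed affine map.  Channels in
    one ``scale_groups`` entry (default: all DCE frames as one group and
    the DWI pair as another) share a single scale computed over their
    pooled values.  A constant channel maps to all zeros with a warning.
    """
    if method not in ("percentile", "minmax"):
        raise ValueError(f"unknown normalization method: {method}")
    if fixed_ranges is None:
        fixed_ranges = DEFAULT_FIXED_RANGES
    if scale_groups is None:
        scale_groups = _default_scale_groups(study.channel_order)
    grouped = [c for g in scale_groups for c in g]
    if sorted(grouped) != sorted(study.channel_order):
        raise ValueError("scale_groups must partition the channel names")

    out: dict[str, np.ndarray] = {}
    for group in scale_groups:
        free = [c for c in group if c not in fixed_ranges]
        if free:
            pooled = np.concatenate(
                [np.ravel(study.channels[c]) for c in free])
            if method == "percentile":
                glo, ghi = np.percentile(pooled, percentiles)
            else:
                glo, ghi = float(pooled.min()), float(pooled.max())
        for name in group:
            vol = np.asarray(study.channels[name], dtype=float)
            lo, hi = fixed_ranges.get(name, (glo, ghi))
            if hi - lo <= 0:
                warnings.warn(
                    f"channel {name!r} is constant; normalized to zeros")
                out[name] = np.zeros_like(vol)
            else:
                out[name] = np.clip((vol - lo) / (hi - lo), 0.0, 1.0)
    return MpMriStudy(
        channels=out,
        channel_order=list(study.channel_order),
        voxel_spacing=study.voxel_spacing,
        subject_id=study.subject_id,
    )


def _affine(voxel_spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_spacing
    return aff


def write_study(study: MpMriStudy, path: str | Path) -> Path:
    """Write one NIfTI per channel plus a JSON manifest; returns the manifest path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    aff = _affine(study.voxel_spacing)
    files = {}
    for name in study.channel_order:
        fname = f"{study.subject_id}_{name}.nii"
        nib.save(nib.Nifti1Image(study.channels[name].astype(np.float64), aff),
                 str(path / fname))
        files[name] = fname
    manifest = {
        "subject_id": study.subject_id,
        "voxel_spacing": list(study.voxel_spacing),
        "channel_order": list(study.channel_order),
        "channel_files": files,
        "indexing": "0-based (x, y, z)",
    }
    mpath = path / f"{study.subject_id}_study.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def read_study(manifest_path: str | Path) -> MpMriStudy:
    """Read a study written by :func:`write_study`; bit-exact round-trip."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    channels: dict[str, np.ndarray] = {}
    for name in manifest["channel_order"]:
        if name not in manifest["channel_files"]:
            raise ValueError(f"manifest missing channel {name!r}")
        fpath = root / manifest["channel_files"][name]
        if not fpath.exists():
            raise FileNotFoundError(f"missing channel file for {name!r}: {fpath}")
        channels[name] = np.asarray(nib.load(str(fpath)).dataobj, dtype=np.float64)
    shapes = {n: v.shape for n, v in channels.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"inconsistent channel shapes: {shapes}")
    return MpMriStudy(
        channels=channels,
        channel_order=list(manifest["channel_order"]),
        voxel_spacing=tuple(manifest["voxel_spacing"]),
        subject_id=manifest["subject_id"],
    )


def write_labelmap(labelmap: LabelMap, path: str | Path,
                   voxel_spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(labelmap.labels.astype(np.int16),
                             _affine(voxel_spacing)), str(path))
    return path


def read_labelmap(path: str | Path) -> LabelMap:
    labels = np.asarray(nib.load(str(path)).dataobj).astype(np.int16)
    return LabelMap(labels=labels)
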