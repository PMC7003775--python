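"""Synthetic co-registered multiparametric breast MRI phantoms.

Generates four-class (background / fat / glandular / lesion) volumes with
known truth labels, class-conditional ADC values and contrast-enhancement
kinetics: malignant lesions wash in fast and wash out, benign lesions rise
slowly and persist.  Channel layout matches :mod:`mptissue.mpmri_io`.

Geometry is deliberately simple (nested ellipsoids plus a spherical
lesion); the purpose is a controllable, fully labeled test bed, not
anatomical realism.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .mpmri_io import (
    BASE_CHANNEL_ORDER,
    CLASS_LEGEND,
    LabelMap,
    MpMriStudy,
    dce_channel_names,
    default_channel_order,
    write_labelmap,
    write_study,
)

__all__ = [
    "EnhancementCurve",
    "TissueClassSpec",
    "PhantomSpec",
    "PhantomStudy",
    "generate_phantom",
    "generate_cohort",
    "default_phantom_spec",
    "write_cohort",
]

BACKGROUND, FAT, GLANDULAR, LESION = 0, 1, 2, 3

#: Channels whose class means are specified directly (DWI_bhigh and ADC
#: are derived from the class ADC; DCE frames from the enhancement curve).
SYNTH_CHANNELS = ("t1w", "t2w", "dwi_b0")


@dataclass(frozen=True)
class EnhancementCurve:
    """Piecewise-linear relative-enhancement curve over DCE frames.

    Frame 0 is the precontrast baseline (fraction 0).  The curve rises
    linearly to ``peak_fraction`` at ``peak_frame`` (0-based), then moves
    linearly to ``final_fraction`` at the last frame.  ``final < peak``
    gives wash-out, ``final >= peak`` a persistent rise.
    """

    peak_fraction: float = 0.0
    peak_frame: int = 0
    final_fraction: float = 0.0

    def fractions(self, n_frames: int) -> np.ndarray:
        if n_frames < 1:
            raise ValueError("need at least one DCE frame")
        f = np.zeros(n_frames)
        peak = min(self.peak_frame, n_frames - 1)
        if peak > 0:
            f[: peak + 1] = np.linspace(0.0, self.peak_fraction, peak + 1)
        else:
            f[0] = 0.0 if n_frames > 1 else self.peak_fraction
        if n_frames - 1 > peak:
            f[peak:] = np.linspace(self.peak_fraction, self.final_fraction,
                                   n_frames - peak)
        if np.any(f < 0):
            raise ValueError("enhancement fractions must be non-negative")
        return f


FLAT_CURVE = EnhancementCurve()
#: fast wash-in then wash-out (negative late slope)
MALIGNANT_CURVE = EnhancementCurve(peak_fraction=1.6, peak_frame=2, final_fraction=0.9)
#: slow persistent rise (non-negative late slope)
BENIGN_CURVE = EnhancementCurve(peak_fraction=0.35, peak_frame=2, final_fraction=0.8)
GLANDULAR_CURVE = EnhancementCurve(peak_fraction=0.08, peak_frame=3, final_fraction=0.18)


@dataclass
class TissueClassSpec:
    """Per-class signal statistics driving phantom synthesis.

    ``per_channel_mean``/``per_channel_sd`` cover the directly synthesized
    non-DCE channels (T1w, T2w, DWI b0); DWI at the high b-value and the
    ADC channel are derived from ``adc_mean`` (in 1e-3 mm^2/s), and DCE
    frames from ``enhancement_curve``.  The SDs are between-subject
    jitter scales used by :func:`generate_cohort`, not voxel noise.
    """

    class_id: int
    per_channel_mean: np.ndarray
    per_channel_sd: np.ndarray
    adc_mean: float
    adc_sd: float
    enhancement_curve: EnhancementCurve = FLAT_CURVE

    def __post_init__(self) -> None:
        self.per_channel_mean = np.asarray(self.per_channel_mean, dtype=float)
        self.per_channel_sd = np.asarray(self.per_channel_sd, dtype=float)
        if self.per_channel_mean.shape != (len(SYNTH_CHANNELS),):
            raise ValueError(
                f"per_channel_mean must have length {len(SYNTH_CHANNELS)}")
        if self.per_channel_sd.shape != self.per_channel_mean.shape:
            raise ValueError("per_channel_sd length mismatch")
        if np.any(self.per_channel_sd < 0) or self.adc_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def _default_class_specs(phenotype: str) -> dict[int, TissueClassSpec]:
    # class-conditional ADC statistics (1e-3 mm^2/s): lesions 1.26 +/- 0.13
    # (malignant) vs 1.74 +/- 0.17 (benign); glandular tissue differs by
    # patient group, 2.16 +/- 0.46 (malignant) vs 2.34 +/- 0.33 (benign)
    if phenotype == "malignant":
        lesion_adc, gland_adc = (1.26, 0.13), (2.16, 0.46)
    else:
        lesion_adc, gland_adc = (1.74, 0.17), (2.34, 0.33)
    lesion_curve = MALIGNANT_CURVE if phenotype == "malignant" else BENIGN_CURVE
    return {
        BACKGROUND: TissueClassSpec(
            BACKGROUND, [0.02, 0.02, 0.02], [0.003, 0.003, 0.003],
            adc_mean=0.0, adc_sd=0.0, enhancement_curve=FLAT_CURVE),
        FAT: TissueClassSpec(
            FAT, [0.90, 0.35, 0.30], [0.03, 0.02, 0.02],
            adc_mean=0.40, adc_sd=0.05, enhancement_curve=FLAT_CURVE),
        GLANDULAR: TissueClassSpec(
            GLANDULAR, [0.45, 0.60, 0.70], [0.03, 0.03, 0.03],
            adc_mean=gland_adc[0], adc_sd=gland_adc[1],
            enhancement_curve=GLANDULAR_CURVE),
        LESION: TissueClassSpec(
            LESION, [0.55, 0.70, 0.85], [0.03, 0.03, 0.03],
            adc_mean=lesion_adc[0], adc_sd=lesion_adc[1],
            enhancement_curve=lesion_curve),
    }


@dataclass
class PhantomSpec:
    """Full description of one synthetic study."""

    grid_shape: tuple[int, int, int] = (64, 64, 8)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    n_dce_frames: int = 8
    b_values: tuple[float, float] = (0.0, 800.0)
    class_specs: dict[int, TissueClassSpec] | None = None
    lesion_phenotype: str = "malignant"
    lesion_radius_voxels: float = 6.0
    lesion_center: tuple[float, float, float] | None = None
    noise_sd: float = 0.05
    heterogeneity_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_phenotype not in ("benign", "malignant"):
            raise ValueError(f"unknown phenotype: {self.lesion_phenotype}")
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError(f"non-positive grid shape: {self.grid_shape}")
        if self.n_dce_frames < 1:
            raise ValueError("need at least one DCE frame")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.class_specs is None:
            self.class_specs = _default_class_specs(self.lesion_phenotype)
        missing = set(CLASS_LEGEND) - set(self.class_specs)
        if missing:
            raise ValueError(f"missing class specs: {missing}")
        if self.lesion_radius_voxels <= 0:
            raise ValueError("lesion radius must be positive")
        # physical radius converted to a per-axis voxel extent
        r_mm = self.lesion_radius_voxels * self.voxel_spacing[0]
        for dim, sp in zip(self.grid_shape, self.voxel_spacing):
            if r_mm / sp >= dim / 2:
                raise ValueError(
                    "lesion radius must be < half the smallest grid dimension")


@dataclass
class PhantomStudy:
    """A generated study bundled with its ground truth."""

    study: MpMriStudy
    truth_labels: LabelMap
    lesion_phenotype: str
    lesion_volume_mm3: float


def default_phantom_spec(phenotype: str = "malignant", seed: int = 0,
                         **overrides) -> PhantomSpec:
    """Desk-scale default spec (64 x 64 x 8 grid, 8 DCE frames)."""
    return PhantomSpec(lesion_phenotype=phenotype, seed=seed, **overrides)


def _build_truth(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.grid_shape
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    labels = np.zeros(spec.grid_shape, dtype=np.int16)

    breast = ((x - cx) / (0.44 * nx)) ** 2 + ((y - cy) / (0.44 * ny)) ** 2 \
        + ((z - cz) / (0.48 * nz)) ** 2 <= 1.0
    glandular = ((x - cx) / (0.28 * nx)) ** 2 + ((y - cy) / (0.28 * ny)) ** 2 \
        + ((z - cz) / (0.40 * nz)) ** 2 <= 1.0
    labels[breast] = FAT
    labels[glandular] = GLANDULAR

    if spec.lesion_center is None:
        lc = (cx, cy, cz)
    else:
        lc = spec.lesion_center
    # physical sphere: radius in mm = radius_voxels * in-plane spacing
    r_mm = spec.lesion_radius_voxels * spec.voxel_spacing[0]
    d2 = ((x - lc[0]) * spec.voxel_spacing[0]) ** 2 \
        + ((y - lc[1]) * spec.voxel_spacing[1]) ** 2 \
        + ((z - lc[2]) * spec.voxel_spacing[2]) ** 2
    lesion = (d2 <= r_mm ** 2) & glandular
    labels[lesion] = LESION
    return labels


def generate_phantom(spec: PhantomSpec) -> PhantomStudy:
    """Synthesize one multiparametric study with truth labels.

    Channels are T1w, T2w, DWI(b0), DWI(b_high), ADC and DCE frames.
    Before noise, DWI(b_high) = DWI(b0) * exp(-b * ADC_class * 1e-3)
    voxelwise and DCE_k = T1w_class * (1 + enhancement_fraction_k).
    Additive Gaussian noise is applied per channel after synthesis,
    scaled by the channel's noiseless peak amplitude.  Identical specs
    (including ``seed``) produce bit-identical output.
    """
    labels = _build_truth(spec)
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    n_dce = spec.n_dce_frames
    b_high = spec.b_values[1]

    # per-voxel class-deterministic fields
    per_class = {cid: spec.class_specs[cid] for cid in CLASS_LEGEND}
    chan: dict[str, np.ndarray] = {c: np.zeros(shape) for c in SYNTH_CHANNELS}
    adc = np.zeros(shape)
    dce = {name: np.zeros(shape) for name in dce_channel_names(n_dce)}
    for cid, cs in per_class.items():
        m = labels == cid
        if not m.any():
            continue
        for j, cname in enumerate(SYNTH_CHANNELS):
            chan[cname][m] = cs.per_channel_mean[j]
        adc[m] = cs.adc_mean
        fracs = cs.enhancement_curve.fractions(n_dce)
        base = cs.per_channel_mean[0]  # T1w-weighted baseline
        for k, name in enumerate(dce_channel_names(n_dce)):
            dce[name][m] = base * (1.0 + fracs[k])

    if spec.heterogeneity_amplitude > 0:
        from scipy.ndimage import gaussian_filter
        fld = gaussian_filter(rng.standard_normal(shape), sigma=6.0)
        fld *= spec.heterogeneity_amplitude / max(np.abs(fld).max(), 1e-12)
        for cname in SYNTH_CHANNELS:
            chan[cname] *= 1.0 + fld
        for name in dce:
            dce[name] *= 1.0 + fld

    # derived diffusion channels, forward model applied before noise
    dwi_bhigh = chan["dwi_b0"] * np.exp(-b_high * adc * 1e-3)

    volumes: dict[str, np.ndarray] = {
        "t1w": chan["t1w"], "t2w": chan["t2w"], "dwi_b0": chan["dwi_b0"],
        "dwi_bhigh": dwi_bhigh, "adc": adc, **dce,
    }
    order = default_channel_order(n_dce)
    if spec.noise_sd > 0:
        for name in order:
            scale = spec.noise_sd * max(float(np.abs(volumes[name]).max()), 1e-12)
            volumes[name] = volumes[name] + rng.normal(0.0, scale, size=shape)

    study = MpMriStudy(channels=volumes, channel_order=order,
                       voxel_spacing=spec.voxel_spacing,
                       subject_id=f"phantom_{spec.seed}")
    truth = LabelMap(labels=labels)
    vol = float((labels == LESION).sum()) * float(np.prod(spec.voxel_spacing))
    return PhantomStudy(study=study, truth_labels=truth,
                        lesion_phenotype=spec.lesion_phenotype,
                        lesion_volume_mm3=vol)


def generate_cohort(
    n_subjects: int,
    benign_fraction: float,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    jitter_scale: float = 1.0,
) -> list[PhantomStudy]:
    """Generate a cohort of jittered phantoms.

    Each subject gets a deterministic per-subject seed derived from
    ``seed``; the lesion center and radius always vary, and the class
    means are jittered within ``jitter_scale`` times the class SDs
    (``jitter_scale=0`` gives identical tissue signals across subjects).
    Exactly ``round(n * benign_fraction)`` subjects are benign.
    """
    if jitter_scale < 0:
        raise ValueError("jitter_scale must be non-negative")
    if n_subjects < 2:
        raise ValueError("cohort needs at least 2 subjects")
    if not 0.0 <= benign_fraction <= 1.0:
        raise ValueError("benign_fraction must be in [0, 1]")
    base = base_spec or PhantomSpec()
    n_benign = int(round(n_subjects * benign_fraction))
    phenotypes = ["benign"] * n_benign + ["malignant"] * (n_subjects - n_benign)
    rng = np.random.default_rng(seed)
    rng.shuffle(phenotypes)

    cohort: list[PhantomStudy] = []
    for i, phen in enumerate(phenotypes):
        sub_rng = np.random.default_rng([seed, i])
        specs = _default_class_specs(phen)
        for cid, cs in specs.items():
            jit_means = cs.per_channel_mean + jitter_scale * sub_rng.normal(
                0.0, cs.per_channel_sd)
            jit_adc = cs.adc_mean + jitter_scale * sub_rng.normal(0.0, cs.adc_sd) \
                if cs.adc_sd > 0 else cs.adc_mean
            specs[cid] = replace(
                cs, per_channel_mean=np.clip(jit_means, 1e-3, None),
                adc_mean=float(np.clip(jit_adc, 0.0, 4.0)))
        nx, ny, nz = base.grid_shape
        center = (
            (nx - 1) / 2 + sub_rng.uniform(-0.08, 0.08) * nx,
            (ny - 1) / 2 + sub_rng.uniform(-0.08, 0.08) * ny,
            (nz - 1) / 2 + sub_rng.uniform(-0.5, 0.5),
        )
        radius = base.lesion_radius_voxels * sub_rng.uniform(0.8, 1.2)
        spec = replace(
            base, class_specs=specs, lesion_phenotype=phen,
            lesion_center=center, lesion_radius_voxels=radius,
            seed=int(sub_rng.integers(0, 2**31 - 1)),
        )
        ph = generate_phantom(spec)
        ph.study.subject_id = f"subj_{i:03d}"
        cohort.append(ph)
    return cohort


def write_cohort(cohort: list[PhantomStudy], outdir: str | Path) -> Path:
    """Write every study + truth and a cohort manifest CSV; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ph in cohort:
        sid = ph.study.subject_id
        sdir = outdir / sid
        manifest = write_study(ph.study, sdir)
        lpath = write_labelmap(ph.truth_labels, sdir / f"{sid}_truth.nii",
                               ph.study.voxel_spacing)
        rows.append({
            "subject_id": sid,
            "phenotype": ph.lesion_phenotype,
            "lesion_volume_mm3": f"{ph.lesion_volume_mm3:.6g}",
            "study_manifest": str(manifest.relative_to(outdir)),
            "truth_labels": str(lpath.relative_to(outdir)),
        })
    mpath = outdir / "cohort.csv"
    with open(mpath, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return mpath
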