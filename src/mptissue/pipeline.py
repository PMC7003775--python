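"""End-to-end pipeline orchestration.

Drives phantom simulation, signature extraction, eigenimage ground
truth, segmenter training/evaluation, lesion classification and the
summary report from a single config dict (YAML/JSON on disk).  Every
random draw traces to the config seed; rerunning with the same config
reproduces the summary (single-threaded reference mode).
"""

from __future__ import annotations

import copy
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .eigenimage import apply_eigenimage, fit_eigenimage_filter, threshold_eigenimage
from .evalmetrics import (
    bland_altman,
    dice,
    lesion_volume,
    loocv_classification,
    percent_volume_difference,
    twofold_cv_segmentation,
)
from .mpmri_io import MpMriStudy, normalize_channels, read_labelmap, read_study, write_labelmap
from .phantom import PhantomStudy, generate_cohort, write_cohort
from .sae_svm import (
    BENIGN,
    MALIGNANT,
    build_feature_vector,
    classify_lesion,
    extract_lesion_record,
    train_cost_weighted_svm,
    train_lesion_sae,
)
from .signatures import (
    TissueSignatureSet,
    auto_seeds,
    extract_signatures,
    multiparametric_roi,
    region_grow,
    sample_balanced,
    signature_sets_from_labels,
)
from .ssae_seg import SsaeModel, SsaeTrainConfig, segment_study, train_segmenter

__all__ = ["DEFAULT_CONFIG", "STAGES", "load_config", "run_pipeline",
           "validate_external_cohort", "permute_orientation"]

SCHEMA_VERSION = 1

STAGES = ["simulate", "signatures", "ei-truth", "train-seg", "segment",
          "train-clf", "classify", "evaluate"]
#: short aliases accepted by ``--stages``
STAGE_ALIASES = {"sim": "simulate", "sig": "signatures", "ei": "ei-truth",
                 "seg": "segment", "clf": "classify", "eval": "evaluate"}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {
        "n_subjects": 20,
        "benign_fraction": 0.5,
        "noise_sd": 0.05,
        "grid_shape": [64, 64, 8],
        "voxel_spacing": [1.0, 1.0, 3.0],
        "n_dce_frames": 8,
        "lesion_radius_voxels": 6.0,
    },
    "signatures": {
        "source": "labels",          # "labels" (phantom truth) or "region_grow"
        "cap_per_class": 1000,
        "region_grow_channels": ["t1w", "t2w", "dwi_b0"],
        "seeds_per_class": 3,
        "tolerance_fraction": 0.05,
    },
    "eigenimage": {"ridge": 1e-6, "z": 1.96, "keep_largest_component": True},
    "train": {
        "l2_penalty": 0.001,
        "sparsity_proportion": 0.25,
        "sparsity_weight": 4.0,
        "n_layers": 5,
        "hidden_size": 10,
        "max_epochs": 400,
        "learning_rate": 0.1,
        "head_epochs": 800,
        "head_learning_rate": 1.0,
        "fine_tune_epochs": 400,
        "fine_tune_learning_rate": 0.5,
        "fine_tune": True,
    },
    "classify": {"cv": "loocv", "feature_mode": "node_stats"},
    "segmentation_truth": "phantom",  # "phantom" or "ei"
}


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML/JSON config file over the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _train_config(cfg: dict, seed: int) -> SsaeTrainConfig:
    return SsaeTrainConfig(seed=seed, **cfg["train"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _StageLedger:
    """Per-stage completion markers with artifact hashes, for --resume."""

    def __init__(self, outdir: Path, resume: bool):
        self.dir = outdir / "stages"
        self.dir.mkdir(parents=True, exist_ok=True)
        self.resume = resume

    def complete(self, stage: str, artifacts: list[Path]) -> None:
        payload = {str(p): _sha256(p) for p in artifacts if p.exists()}
        (self.dir / f"{stage}.json").write_text(json.dumps(payload, indent=2))

    def is_done(self, stage: str) -> bool:
        if not self.resume:
            return False
        marker = self.dir / f"{stage}.json"
        if not marker.exists():
            return False
        try:
            recorded = json.loads(marker.read_text())
        except json.JSONDecodeError:
            return False
        return all(Path(p).exists() and _sha256(Path(p)) == h
                   for p, h in recorded.items())


def _region_grow_sets(study: MpMriStudy, truth, sig_cfg: dict,
                      seed: int) -> list[TissueSignatureSet]:
    seeds = auto_seeds(truth, n_per_class=sig_cfg["seeds_per_class"], seed=seed)
    sets = []
    for cid, points in seeds.items():
        rois = []
        for point in points:
            masks = [region_grow(study.channels[c], point,
                                 sig_cfg["tolerance_fraction"])
                     for c in sig_cfg["region_grow_channels"]]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rois.append(multiparametric_roi(masks))
        roi = np.logical_or.reduce(rois)
        if not roi.any():
            # always keep at least the seed voxels themselves
            roi = np.zeros(study.grid_shape, dtype=bool)
            for point in points:
                roi[point] = True
        sets.append(extract_signatures(study, roi, cid))
    return sets


def run_pipeline(
    config: dict | str | Path | None = None,
    outdir: str | Path = "pipeline_out",
    seed: int | None = None,
    stages: str | None = None,
    resume: bool = False,
) -> dict:
    """Run the pipeline through ``stages`` (a terminal stage name or None).

    Returns the summary dict (also written to ``<outdir>/summary.json``
    when the evaluate stage runs).
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    if seed is not None:
        cfg = {**cfg, "seed": int(seed)}
    seed = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stop = STAGE_ALIASES.get(stages, stages) if stages else STAGES[-1]
    if stop not in STAGES:
        raise ValueError(f"unknown stage {stages!r}; choose from {STAGES}")
    active = STAGES[: STAGES.index(stop) + 1]
    ledger = _StageLedger(outdir, resume)
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": seed,
        "config": copy.deepcopy(cfg),
        "stages_run": [],
    }

    # ---- simulate --------------------------------------------------------
    cohort_dir = outdir / "cohort"
    ccfg = cfg["cohort"]
    from .phantom import PhantomSpec
    base_spec = PhantomSpec(grid_shape=tuple(ccfg["grid_shape"]),
                            voxel_spacing=tuple(ccfg["voxel_spacing"]),
                            n_dce_frames=ccfg["n_dce_frames"],
                            noise_sd=ccfg["noise_sd"],
                            lesion_radius_voxels=ccfg["lesion_radius_voxels"])
    if ledger.is_done("simulate"):
        cohort = _load_cohort(cohort_dir)
    else:
        cohort = generate_cohort(ccfg["n_subjects"], ccfg["benign_fraction"],
                                 base_spec=base_spec, seed=seed)
        manifest = write_cohort(cohort, cohort_dir)
        ledger.complete("simulate", [manifest])
    summary["stages_run"].append("simulate")
    if "simulate" == stop:
        return summary

    normalized = [normalize_channels(ph.study) for ph in cohort]
    sig_cfg = cfg["signatures"]

    # ---- signatures ------------------------------------------------------
    per_subject_sets: list[list[TissueSignatureSet]] = []
    for i, ph in enumerate(cohort):
        if sig_cfg["source"] == "region_grow":
            sets = _region_grow_sets(normalized[i], ph.truth_labels, sig_cfg,
                                     seed + 17 * i)
        else:
            sets = signature_sets_from_labels(
                normalized[i], ph.truth_labels,
                max_per_class=sig_cfg["cap_per_class"], seed=seed + 17 * i)
        per_subject_sets.append(sets)
    training = sample_balanced([s for sub in per_subject_sets for s in sub],
                               cap_per_class=sig_cfg["cap_per_class"],
                               seed=seed)
    sig_path = outdir / "signatures.csv"
    if not ledger.is_done("signatures"):
        _write_signature_table(training, normalized[0].channel_order, sig_path)
        ledger.complete("signatures", [sig_path])
    summary["stages_run"].append("signatures")
    summary["n_training_signatures"] = len(training)
    if "signatures" == stop:
        return summary

    # ---- ei-truth --------------------------------------------------------
    ei_cfg = cfg["eigenimage"]
    ei_dir = outdir / "ei_truth"
    ei_dir.mkdir(exist_ok=True)
    ei_rows = []
    ei_masks = []
    for i, ph in enumerate(cohort):
        sets = {int(s.labels[0]): s for s in per_subject_sets[i]}
        filt = fit_eigenimage_filter(
            sets[3], TissueSignatureSet.concatenate([sets[1], sets[2]]),
            ridge=ei_cfg["ridge"])
        ei = apply_eigenimage(normalized[i], filt)
        foreground = ph.truth_labels.labels > 0
        try:
            mask = threshold_eigenimage(
                ei, foreground, z=ei_cfg["z"],
                keep_largest_component=ei_cfg["keep_largest_component"])
        except ValueError:
            mask = np.zeros(foreground.shape, dtype=bool)
        ei_masks.append(mask)
        if not ledger.is_done("ei-truth"):
            write_labelmap(
                _as_labelmap(mask), ei_dir / f"{ph.study.subject_id}_ei.nii",
                ph.study.voxel_spacing)
        ei_rows.append({"subject_id": ph.study.subject_id,
                        "dice_vs_truth": dice(mask, ph.truth_labels.mask(3))})
    ei_table = pd.DataFrame(ei_rows)
    if not ledger.is_done("ei-truth"):
        ei_table.to_csv(ei_dir / "ei_dice.csv", index=False)
        ledger.complete("ei-truth", [ei_dir / "ei_dice.csv"])
    summary["stages_run"].append("ei-truth")
    summary["ei_mean_dice_vs_truth"] = float(ei_table["dice_vs_truth"].mean())
    if "ei-truth" == stop:
        return summary

    # ---- train-seg (twofold CV + final model) ----------------------------
    tcfg = _train_config(cfg, seed)
    cv_path = outdir / "segmentation_cv.csv"
    model_path = outdir / "segmenter.json"
    if ledger.is_done("train-seg"):
        cv_table = pd.read_csv(cv_path)
        segmenter = SsaeModel.load(model_path)
    else:
        cv_table = twofold_cv_segmentation(
            cohort, cfg=tcfg, seed=seed,
            cap_per_class=sig_cfg["cap_per_class"])
        cv_table.to_csv(cv_path, index=False)
        segmenter = train_segmenter(training, tcfg,
                                    channel_order=normalized[0].channel_order)
        segmenter.save(model_path)
        ledger.complete("train-seg", [cv_path, model_path])
    summary["stages_run"].append("train-seg")
    by_phen = cv_table.groupby("phenotype")["dice"].agg(["mean", "std"])
    summary["segmentation_cv"] = {
        phen: {"mean_dice": float(row["mean"]),
               "sd_dice": float(row["std"]) if np.isfinite(row["std"]) else 0.0}
        for phen, row in by_phen.iterrows()
    }
    if "train-seg" == stop:
        return summary

    # ---- segment ---------------------------------------------------------
    seg_dir = outdir / "segmentations"
    seg_dir.mkdir(exist_ok=True)
    segmentations = []
    seg_rows = []
    for i, ph in enumerate(cohort):
        seg = segment_study(segmenter, normalized[i])
        segmentations.append(seg)
        spath = write_labelmap(seg, seg_dir / f"{ph.study.subject_id}_seg.nii",
                               ph.study.voxel_spacing)
        truth_choice = cfg["segmentation_truth"]
        ref_mask = ei_masks[i] if truth_choice == "ei" \
            else ph.truth_labels.mask(3)
        seg_rows.append({
            "subject_id": ph.study.subject_id,
            "phenotype": ph.lesion_phenotype,
            "dice": dice(seg.mask(3), ref_mask),
            "volume_pred_mm3": lesion_volume(seg.mask(3),
                                             ph.study.voxel_spacing),
            "volume_true_mm3": ph.lesion_volume_mm3,
        })
    seg_table = pd.DataFrame(seg_rows)
    seg_table.to_csv(seg_dir / "segmentation_dice.csv", index=False)
    ledger.complete("segment", [seg_dir / "segmentation_dice.csv"])
    summary["stages_run"].append("segment")
    if "segment" == stop:
        return summary

    # ---- train-clf + classify -------------------------------------------
    records = []
    labels = []
    for i, ph in enumerate(cohort):
        try:
            rec = extract_lesion_record(normalized[i], segmentations[i])
        except ValueError:
            warnings.warn(f"no lesion segmented for {ph.study.subject_id}; "
                          "subject excluded from classification")
            continue
        rec.label = MALIGNANT if ph.lesion_phenotype == "malignant" else BENIGN
        records.append(rec)
        labels.append(rec.label)
    labels_arr = np.asarray(labels)
    sae = train_lesion_sae(np.vstack([r.signatures for r in records]), tcfg)
    mode = cfg["classify"]["feature_mode"]
    for rec in records:
        rec.encoded = sae.encode(rec.signatures)
        rec.feature_vector = build_feature_vector(rec, mode)
    features = np.vstack([r.feature_vector for r in records])
    svm_model, grid = train_cost_weighted_svm(
        features, labels_arr, cv=cfg["classify"]["cv"], seed=seed,
        feature_mode=mode)
    roc, conf, _ = loocv_classification(features, labels_arr, seed=seed)
    pred_rows = []
    for rec in records:
        score, label = classify_lesion(svm_model, rec)
        pred_rows.append({"subject_id": rec.subject_id, "true": rec.label,
                          "score": score, "predicted": label})
    pred_table = pd.DataFrame(pred_rows)
    pred_path = outdir / "classification.csv"
    pred_table.to_csv(pred_path, index=False)
    ledger.complete("train-clf", [pred_path])
    ledger.complete("classify", [pred_path])
    summary["stages_run"] += ["train-clf", "classify"]
    summary["classification"] = {
        "n_lesions": int(len(records)),
        "loocv_auc": roc.auc,
        "sensitivity": conf[0],
        "specificity": conf[1],
        "ppv": conf[2],
        "npv": conf[3],
        "best_cost_ratio": list(grid.best_ratio),
        "grid_auc": dict(zip([f"{r[0]}:{r[1]}" for r in grid.ratios],
                             grid.auc_per_ratio)),
    }
    if "classify" == stop:
        return summary

    # ---- evaluate --------------------------------------------------------
    vols_pred = seg_table["volume_pred_mm3"].to_numpy()
    vols_true = seg_table["volume_true_mm3"].to_numpy()
    pct = [percent_volume_difference(p, t)
           for p, t in zip(vols_pred, vols_true) if t > 0]
    ba = bland_altman(vols_pred, vols_true)
    corr = float(np.corrcoef(vols_pred, vols_true)[0, 1])
    summary["volume_agreement"] = {
        "mean_percent_difference": float(np.mean(pct)),
        "sd_percent_difference": float(np.std(pct, ddof=1)),
        "correlation": corr,
        "bland_altman": {"mean_diff": ba.mean_diff, "loa_low": ba.loa_low,
                         "loa_high": ba.loa_high},
    }
    summary["per_subject_dice"] = cv_table[
        ["subject_id", "phenotype", "dice"]].to_dict("records")
    spath = outdir / "summary.json"
    spath.write_text(json.dumps(summary, indent=2))
    ledger.complete("evaluate", [spath])
    summary["stages_run"].append("evaluate")
    return summary


def _as_labelmap(mask: np.ndarray):
    from .mpmri_io import LabelMap
    return LabelMap(labels=mask.astype(np.int16),
                    legend={0: "background", 1: "fat", 2: "glandular",
                            3: "lesion"})


def _write_signature_table(tset: TissueSignatureSet, channel_order, path: Path):
    frame = pd.DataFrame(tset.signatures, columns=channel_order)
    frame["label"] = tset.labels
    if tset.provenance:
        frame["subject_id"] = [p[0] for p in tset.provenance]
        frame["voxel"] = [f"{v[0]},{v[1]},{v[2]}" for _, v in tset.provenance]
    frame.to_csv(path, index=False)


def _load_cohort(cohort_dir: Path) -> list[PhantomStudy]:
    rows = pd.read_csv(cohort_dir / "cohort.csv")
    cohort = []
    for _, row in rows.iterrows():
        study = read_study(cohort_dir / row["study_manifest"])
        truth = read_labelmap(cohort_dir / row["truth_labels"])
        cohort.append(PhantomStudy(
            study=study, truth_labels=truth,
            lesion_phenotype=row["phenotype"],
            lesion_volume_mm3=float(row["lesion_volume_mm3"])))
    return cohort


def permute_orientation(study: MpMriStudy, axes=(2, 1, 0)) -> MpMriStudy:
    """Axis-permuted copy of a study (e.g., axial -> sagittal emulation)."""
    return MpMriStudy(
        channels={c: np.transpose(v, axes) for c, v in study.channels.items()},
        channel_order=list(study.channel_order),
        voxel_spacing=tuple(study.voxel_spacing[a] for a in axes),
        subject_id=study.subject_id + "_perm",
    )


def validate_external_cohort(segmenter: SsaeModel, cohort,
                             reference_volumes=None) -> dict:
    """Volume-agreement report for an external (e.g., reoriented) cohort.

    ``cohort`` is a list of :class:`PhantomStudy` (or objects with
    ``study``/``lesion_volume_mm3``); ``reference_volumes`` overrides the
    per-subject reference lesion volumes.
    """
    refs = reference_volumes if reference_volumes is not None else [
        ph.lesion_volume_mm3 for ph in cohort]
    if refs is None or any(r is None for r in refs):
        raise ValueError("missing reference lesion volumes")
    rows = []
    for ph, ref in zip(cohort, refs):
        study = normalize_channels(ph.study)
        seg = segment_study(segmenter, study)
        vol = lesion_volume(seg.mask(3), study.voxel_spacing)
        rows.append({"subject_id": study.subject_id, "volume_mpdl_mm3": vol,
                     "volume_ref_mm3": float(ref),
                     "percent_difference": percent_volume_difference(vol, ref)
                     if ref > 0 else np.nan})
    table = pd.DataFrame(rows)
    v1 = table["volume_mpdl_mm3"].to_numpy()
    v2 = table["volume_ref_mm3"].to_numpy()
    ba = bland_altman(v1, v2)
    return {
        "table": table,
        "mean_percent_difference": float(table["percent_difference"].mean()),
        "sd_percent_difference": float(table["percent_difference"].std(ddof=1)),
        "correlation": float(np.corrcoef(v1, v2)[0, 1]),
        "bland_altman": ba,
    }
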