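"""End-to-end orchestration: generate -> preprocess -> prior -> patches ->
train -> evaluate.

One master seed derives independent streams for data generation, the
patient split, model initialization/training, augmentation, and the
bootstrap, so a run is reproducible end to end: two runs with the same
config produce byte-identical metrics JSON.
"""
from __future__ import annotations

import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.filters import threshold_otsu

from .boxes import Box
from .evaluate import (
    ScoreMap,
    auroc,
    couple_scores,
    expected_false_positives,
    precision_at_threshold,
    UndefinedMetricError,
    volume_at_fn,
    volume_vs_fn_curve,
    youden_threshold,
)
from .model import CNNConfig, TrainConfig, score_patches, train_classifier
from .patches import (
    AugmentParams,
    PatchSample,
    extract_resize_patch,
    label_patches,
    partition_roi,
    split_patients,
)
from .phantoms import AnnotatedScan, PhantomParams, RegionPrior, generate_cohort
from .preprocess import apply_affine_box, extract_body_roi, fit_roi_affine
from .prior import build_heatmap, compute_patch_prior, region_histogram

__all__ = ["PipelineConfig", "run_pipeline", "compare_partitions"]


@dataclass(frozen=True)
class PipelineConfig:
    n_patients: int = 40
    scans_per_patient_max: int = 2
    k: int = 3
    patch_side: int = 32
    prior_floor: float = 1e-3
    proportions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0
    n_bootstrap: int = 500
    max_fn_rate: float = 0.1
    phantom: PhantomParams = field(default_factory=PhantomParams)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: AugmentParams = field(default_factory=AugmentParams)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")

    def module_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        names = ["data", "split", "model", "augment", "bootstrap"]
        children = ss.spawn(len(names))
        return {
            name: int(child.generate_state(1)[0] % 2 ** 31)
            for name, child in zip(names, children)
        }

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must hold a mapping")
        known = {
            "n_patients", "scans_per_patient_max", "k", "patch_side", "prior_floor",
            "proportions", "seed", "n_bootstrap", "max_fn_rate",
            "phantom", "cnn", "train", "augment",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key, typ in (("phantom", PhantomParams), ("cnn", CNNConfig),
                         ("train", TrainConfig), ("augment", AugmentParams)):
            if key in raw and isinstance(raw[key], dict):
                sub = dict(raw[key])
                for tkey in ("volume_shape", "voxel_spacing_mm", "body_axes_mm",
                             "dense_units", "zoom_range"):
                    if tkey in sub and isinstance(sub[tkey], list):
                        sub[tkey] = tuple(sub[tkey])
                if key == "phantom" and isinstance(sub.get("region_prior"), dict):
                    sub["region_prior"] = RegionPrior(sub["region_prior"])
                raw[key] = typ(**sub)
        if "proportions" in raw and isinstance(raw["proportions"], list):
            raw["proportions"] = tuple(raw["proportions"])
        return cls(**raw)


def _body_norm_range(intensities: np.ndarray) -> tuple[float, float]:
    """Scan-level 1st/99th intensity percentiles over the body mask."""
    thr = threshold_otsu(np.asarray(intensities, dtype=float))
    body = intensities[intensities >= thr]
    lo, hi = np.percentile(body, [1.0, 99.0])
    return float(lo), float(hi)


@dataclass
class _PreparedCohort:
    """Cohort + per-scan ROI/affine bookkeeping, shared across k values."""

    cohort: list[AnnotatedScan]
    splits: tuple[set, set, set]
    rois: dict[str, Box]
    norm_ranges: dict[str, tuple[float, float]]
    reference_scan_id: str
    seeds: dict[str, int]

    def scans_in(self, id_set: set) -> list[AnnotatedScan]:
        return [s for s in self.cohort if s.patient_id in id_set]

    def checksum(self) -> int:
        crc = 0
        for scan in self.cohort:
            crc = zlib.crc32(np.ascontiguousarray(scan.volume).tobytes(), crc)
        return crc


def prepare_cohort(config: PipelineConfig) -> _PreparedCohort:
    seeds = config.module_seeds()
    phantom = PhantomParams(**{**asdict_params(config.phantom), "seed": seeds["data"]})
    cohort = generate_cohort(phantom, config.n_patients, config.scans_per_patient_max)
    cohort.sort(key=lambda s: (s.patient_id, s.scan_id))
    splits = split_patients(
        [s.patient_id for s in cohort], config.proportions, seed=seeds["split"]
    )
    rois = {s.scan_id: extract_body_roi(s.as_volume3d()) for s in cohort}
    norm_ranges = {s.scan_id: _body_norm_range(s.volume) for s in cohort}
    train_scans = [s for s in cohort if s.patient_id in splits[0]]
    reference_scan_id = min((s.scan_id for s in train_scans), default=None)
    if reference_scan_id is None:
        raise ValueError("empty training split")
    return _PreparedCohort(cohort, splits, rois, norm_ranges, reference_scan_id, seeds)


def asdict_params(params) -> dict:
    d = asdict(params)
    if "region_prior" in d:
        d["region_prior"] = params.region_prior
    return d


def _extract_scan(prep: _PreparedCohort, scan: AnnotatedScan, k: int, patch_side: int):
    """(patches array (k^3, s, s, s), labels, samples list) for one scan."""
    roi = prep.rois[scan.scan_id]
    grid = partition_roi(roi, k)
    labels = label_patches(grid, scan.boxes)
    vol = scan.as_volume3d()
    nr = prep.norm_ranges[scan.scan_id]
    x = np.stack(
        [
            extract_resize_patch(vol, grid.bounds(f), patch_side, norm_range=nr)
            for f in range(grid.n_patches)
        ]
    )
    samples = [
        PatchSample(
            intensities=x[f],
            label=int(labels[f]),
            scan_id=scan.scan_id,
            patch_index=grid.unravel(f),
            bounds=grid.bounds(f),
        )
        for f in range(grid.n_patches)
    ]
    return x, labels, samples, grid


def run_for_k(config: PipelineConfig, prep: _PreparedCohort, k: int) -> dict:
    """Run prior building, patch extraction, training, and evaluation for
    one partition size; returns the stage outputs and metrics."""
    train_ids, val_ids, test_ids = prep.splits
    ref_roi = prep.rois[prep.reference_scan_id]
    grid_ref = partition_roi(ref_roi, k)

    # --- spatial prior from the training annotations, registered ----------
    train_scans = prep.scans_in(train_ids)
    registered_boxes: list[list[Box]] = []
    registered_centers: list[list[np.ndarray]] = []
    for scan in train_scans:
        amap = fit_roi_affine(prep.rois[scan.scan_id], ref_roi)
        boxes = [apply_affine_box(amap, b, clip_to=ref_roi) for b in scan.boxes]
        boxes = [b for b in boxes if b is not None]
        registered_boxes.append(boxes)
        registered_centers.append([b.center for b in boxes])
    heatmap = build_heatmap(registered_boxes, ref_roi)
    prior = compute_patch_prior(registered_centers, grid_ref, floor=config.prior_floor)
    all_centers = np.array([c for cs in registered_centers for c in cs])
    region_hist = region_histogram(all_centers, ref_roi)

    # --- patch datasets ----------------------------------------------------
    split_of = {}
    for ids, name in ((train_ids, "train"), (val_ids, "val"), (test_ids, "test")):
        for pid in ids:
            split_of[pid] = name
    per_scan = {}
    for scan in prep.cohort:
        x, labels, samples, grid = _extract_scan(prep, scan, k, config.patch_side)
        per_scan[scan.scan_id] = (x, labels, samples, grid)
    def stacked(name):
        xs, ys = [], []
        for scan in prep.cohort:
            if split_of[scan.patient_id] != name:
                continue
            x, labels, _, _ = per_scan[scan.scan_id]
            xs.append(x)
            ys.append(labels)
        return np.concatenate(xs), np.concatenate(ys)

    x_train, y_train = stacked("train")
    x_val, y_val = stacked("val")

    # --- augmentation closure over positive training patches ---------------
    aug_params = AugmentParams(
        max_translation_mm=config.augment.max_translation_mm,
        zoom_range=config.augment.zoom_range,
        seed=prep.seeds["augment"],
    )
    pos_samples = []
    for scan in prep.cohort:
        if split_of[scan.patient_id] != "train":
            continue
        _, labels, samples, _ = per_scan[scan.scan_id]
        vol = scan.as_volume3d()
        nr = prep.norm_ranges[scan.scan_id]
        for f in np.flatnonzero(labels):
            pos_samples.append((samples[f], vol, nr))

    def augment_fn(rng):
        from .patches import augment_patch

        return np.stack(
            [
                augment_patch(s, aug_params, vol, norm_range=nr, rng=rng).intensities
                for s, vol, nr in pos_samples
            ]
        )

    train_cfg = TrainConfig(**{**asdict(config.train), "seed": prep.seeds["model"]})
    model = train_classifier(
        x_train, y_train, x_val, y_val, train_cfg, config.cnn, augment_fn=augment_fn
    )

    # --- scoring ------------------------------------------------------------
    def score_split(name):
        maps_raw, maps_cpl, labels = [], [], []
        for scan in prep.cohort:
            if split_of[scan.patient_id] != name:
                continue
            x, lab, _, _ = per_scan[scan.scan_id]
            raw = ScoreMap(k=k, scores=score_patches(model, x, k=k))
            maps_raw.append(raw)
            maps_cpl.append(couple_scores(raw, prior))
            labels.append(lab)
        return maps_raw, maps_cpl, labels

    val_raw, val_cpl, val_labels = score_split("val")
    test_raw, test_cpl, test_labels = score_split("test")

    def pooled(maps, labels):
        return (
            np.concatenate([m.scores for m in maps]),
            np.concatenate(labels),
        )

    sv_raw, yv = pooled(val_raw, val_labels)
    sv_cpl, _ = pooled(val_cpl, val_labels)
    st_raw, yt = pooled(test_raw, test_labels)
    st_cpl, _ = pooled(test_cpl, test_labels)

    thr_raw = youden_threshold(sv_raw, yv)
    thr_cpl = youden_threshold(sv_cpl, yv)
    roc_raw = auroc(st_raw, yt, n_bootstrap=config.n_bootstrap, seed=prep.seeds["bootstrap"])
    roc_cpl = auroc(st_cpl, yt, n_bootstrap=config.n_bootstrap, seed=prep.seeds["bootstrap"])

    def safe_precision(scores, labels, thr):
        try:
            return precision_at_threshold(scores, labels, thr)
        except UndefinedMetricError:
            return None

    neg = yt == 0
    fp_rate = float(np.mean(st_raw[neg] >= thr_raw))
    exp_fp_mean, exp_fp_round = expected_false_positives(k ** 3 - 1, fp_rate)

    curve_raw = volume_vs_fn_curve(test_raw, test_labels)
    curve_cpl = volume_vs_fn_curve(test_cpl, test_labels)

    metrics = {
        "k": k,
        "n_patches": k ** 3,
        "auroc_raw": roc_raw.auroc,
        "auroc_raw_ci": [roc_raw.ci_low, roc_raw.ci_high],
        "auroc_coupled": roc_cpl.auroc,
        "auroc_coupled_ci": [roc_cpl.ci_low, roc_cpl.ci_high],
        "youden_threshold_raw": thr_raw,
        "youden_threshold_coupled": thr_cpl,
        "precision_raw": safe_precision(st_raw, yt, thr_raw),
        "precision_coupled": safe_precision(st_cpl, yt, thr_cpl),
        "fp_rate_at_youden": fp_rate,
        "expected_false_positives": {"mean": exp_fp_mean, "rounded": exp_fp_round},
        "volume_at_fn_raw": volume_at_fn(curve_raw, config.max_fn_rate),
        "volume_at_fn_coupled": volume_at_fn(curve_cpl, config.max_fn_rate),
        "max_fn_rate": config.max_fn_rate,
        "n_train_patches": int(y_train.size),
        "n_test_scans": len(test_raw),
        "epochs_trained": len(model.history),
        "best_val_auroc": max(h["val_auroc"] for h in model.history),
    }
    return {
        "metrics": metrics,
        "model": model,
        "prior": prior,
        "heatmap": heatmap,
        "region_histogram": region_hist,
        "grid_ref": grid_ref,
        "curves": {"raw": curve_raw, "coupled": curve_cpl},
        "test_scores": {"raw": st_raw, "coupled": st_cpl, "labels": yt},
    }


def _write_outputs(out_dir: Path, config: PipelineConfig, prep, result: dict,
                   stage_times: dict) -> None:
    import nibabel as nib

    out_dir.mkdir(parents=True, exist_ok=True)
    metrics = result["metrics"]
    (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True))
    for name, curve in result["curves"].items():
        pd.DataFrame(
            {
                "threshold": curve.thresholds,
                "fn_rate": curve.fn_rate,
                "volume_fraction": curve.volume_fraction,
            }
        ).to_csv(out_dir / f"curve_{name}.csv", index=False)
    prior = result["prior"]
    grid = result["grid_ref"]
    rows = [
        {"patch_index": f, "i": i, "j": j, "k": l, "prob": prior.prob[f]}
        for f, (i, j, l) in ((f, grid.unravel(f)) for f in range(grid.n_patches))
    ]
    pd.DataFrame(rows).to_csv(out_dir / "patch_prior.csv", index=False)
    pd.DataFrame(
        sorted(result["region_histogram"].items()), columns=["region", "percent"]
    ).to_csv(out_dir / "region_histogram.csv", index=False)
    heat = result["heatmap"]
    nib.save(
        nib.Nifti1Image(heat.normalized.astype(np.float32), np.eye(4)),
        out_dir / "heatmap.nii.gz",
    )
    report = {
        "seed": config.seed,
        "module_seeds": prep.seeds,
        "cohort_checksum": prep.checksum(),
        "reference_scan": prep.reference_scan_id,
        "n_scans": len(prep.cohort),
        "stage_seconds": stage_times,
        "outputs": sorted(p.name for p in out_dir.iterdir()),
        "metrics": metrics,
    }
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute all stages; returns the run report as a dict and optionally
    writes metrics/curves/prior/heatmap under ``out_dir``."""
    times = {}
    t0 = time.perf_counter()
    prep = prepare_cohort(config)
    times["prepare"] = round(time.perf_counter() - t0, 3)
    t0 = time.perf_counter()
    result = run_for_k(config, prep, config.k)
    times["run"] = round(time.perf_counter() - t0, 3)
    if out_dir is not None:
        _write_outputs(Path(out_dir), config, prep, result, times)
    report = {
        "seed": config.seed,
        "module_seeds": prep.seeds,
        "cohort_checksum": prep.checksum(),
        "reference_scan": prep.reference_scan_id,
        "stage_seconds": times,
        "metrics": result["metrics"],
    }
    report["_result"] = result
    return report


def compare_partitions(config: PipelineConfig, k_list) -> pd.DataFrame:
    """One pipeline run per partition size on the same cohort and split."""
    k_list = list(k_list)
    if len(k_list) < 2:
        raise ValueError("need at least two partition sizes to compare")
    prep = prepare_cohort(config)
    checksum = prep.checksum()
    rows = []
    for k in k_list:
        result = run_for_k(config, prep, k)
        m = result["metrics"]
        rows.append(
            {
                "k": k,
                "n_patches": m["n_patches"],
                "auroc_raw": m["auroc_raw"],
                "auroc_coupled": m["auroc_coupled"],
                "precision_raw": m["precision_raw"],
                "precision_coupled": m["precision_coupled"],
                "volume_at_fn_raw": m["volume_at_fn_raw"],
                "volume_at_fn_coupled": m["volume_at_fn_coupled"],
                "cohort_checksum": checksum,
            }
        )
    return pd.DataFrame(rows)
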