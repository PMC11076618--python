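"""End-to-end orchestration: simulate → pre-process → segment → classify
→ measure → test.

The per-image chain mirrors the three-step analysis workflow (image
pre-processing, fibre segmentation, fibre classification) followed by
morphometry; the cohort layer joins per-image metrics to the study
metadata and fits the mixed-model statistics.  Every tunable parameter
is echoed verbatim into a run manifest, partial failures are isolated
per image, and two identical seeded runs produce byte-identical CSV
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

import fibremorph
from fibremorph import imaging, morphometry, segmentation
from fibremorph.fibre_typing import (
    DEFAULT_COVERAGE_THRESHOLD,
    DEFAULT_MIN_AREA_UM2,
    classify_image,
    compare_to_annotation,
    records_to_frame,
    summarise_agreement,
)
from fibremorph.imaging import MultiChannelImage, load_image, preprocess
from fibremorph.segmentation import DEFAULT_MIN_FIBRE_DIAMETER_UM
from fibremorph.stats import DEFAULT_ALPHA, fit_metric_lmm, results_to_frame
from fibremorph.synthetic import CohortDesign, GroundTruth, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Per-image analysis parameters, all echoed into the run manifest."""

    stretch_percentiles: tuple[float, float] = (1.0, 99.0)
    binarise_method: str = "otsu"
    backend: str = "watershed"
    min_fibre_diameter: float = DEFAULT_MIN_FIBRE_DIAMETER_UM
    smooth_sigma: float = 2.0
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD
    min_area_um2: float = DEFAULT_MIN_AREA_UM2
    compute_mfd: bool = True


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    design: CohortDesign | None = None
    input_dir: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)
    alpha: float = DEFAULT_ALPHA
    log_ftr: bool = True
    seed: int = 0
    out_dir: str | None = None

    def manifest(self) -> dict:
        cfg = dataclasses.asdict(self)
        cfg["software_version"] = fibremorph.__version__
        blob = json.dumps(cfg, sort_keys=True, default=str)
        cfg["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()
        return cfg


@dataclass
class RunBundle:
    """Results of one run: per-image tables, metrics, statistics, errors."""

    fibre_tables: dict[str, pd.DataFrame]
    image_metrics: pd.DataFrame
    stats: dict[str, pd.DataFrame]
    manifest: dict
    errors: dict[str, str] = field(default_factory=dict)


def process_image(
    image: MultiChannelImage,
    params: PipelineParams | None = None,
    external_labels: np.ndarray | None = None,
) -> dict:
    """Run the per-image chain on one multi-channel image.

    Returns the pre-processing products, interior fibre records (with
    MFD filled in), the label map and the per-image metrics.
    """
    params = params or PipelineParams()
    pre = preprocess(image, params.stretch_percentiles, params.binarise_method)
    label_map = segmentation.segment_fibres(
        pre["seg_input"], backend=params.backend, pixel_size=image.pixel_size,
        min_fibre_diameter=params.min_fibre_diameter,
        smooth_sigma=params.smooth_sigma, external_labels=external_labels)
    rois = segmentation.labels_to_rois(label_map, image.pixel_size)
    interior = segmentation.filter_border_rois(rois)
    records, counts = classify_image(
        interior, pre["slow_mask"], pre["fast_mask"],
        min_area=params.min_area_um2, coverage_threshold=params.coverage_threshold)
    if params.compute_mfd:
        for roi, rec in zip(interior, records):
            if rec.assigned_class != "noise":
                rec.mfd_um = morphometry.min_feret_diameter(roi)
    metrics = morphometry.image_metrics(records, pre["collagen_mask"])
    return {"pre": pre, "label_map": label_map, "rois": interior,
            "records": records, "counts": counts, "metrics": metrics}


def _metrics_row(image_id: str, metrics) -> dict:
    return {
        "image_id": image_id, "n_slow": metrics.n_slow, "n_fast": metrics.n_fast,
        "n_hybrid": metrics.n_hybrid, "n_noise": metrics.n_noise,
        "ftr": metrics.ftr, "hybrid_pct": metrics.hybrid_pct,
        "collagen_pct": metrics.collagen_pct,
    }


def run(config: RunConfig) -> RunBundle:
    """Execute a full configured run.

    Inputs come either from a simulation design (``config.design``) or
    from a directory with a ``metadata.csv`` naming image paths.  A
    failure in one image is recorded and the run continues; the run only
    fails outright when every image fails.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    if config.design is not None:
        bundle = generate_cohort(config.design,
                                 out_dir / "simulated" if out_dir else None)
        metadata = bundle.metadata
        get_image = lambda row: bundle.images[row["image_id"]]  # noqa: E731
    elif config.input_dir is not None:
        input_dir = Path(config.input_dir)
        metadata = pd.read_csv(input_dir / "metadata.csv")
        get_image = lambda row: load_image(input_dir / row["path"])  # noqa: E731
    else:
        raise ValueError("RunConfig needs either a design or an input_dir")

    fibre_tables: dict[str, pd.DataFrame] = {}
    metric_rows: list[dict] = []
    errors: dict[str, str] = {}
    for _, row in metadata.iterrows():
        image_id = row["image_id"]
        try:
            result = process_image(get_image(row), config.params)
        except Exception as exc:  # isolate per-image failures
            logger.error("image %s failed: %s", image_id, exc)
            errors[image_id] = f"{type(exc).__name__}: {exc}"
            logger.debug(traceback.format_exc())
            continue
        fibre_tables[image_id] = records_to_frame(result["records"])
        metric_rows.append(_metrics_row(image_id, result["metrics"]))

    if not metric_rows:
        raise RuntimeError(f"all {len(metadata)} images failed: {errors}")

    image_metrics = pd.DataFrame(metric_rows).merge(
        metadata.drop(columns=[c for c in ("path", "seed") if c in metadata]),
        on="image_id", how="left")
    cols = [c for c in ("group", "side", "region") if c in image_metrics]
    if cols:
        image_metrics["condition"] = image_metrics[cols].astype(str).agg(" ".join, axis=1)

    stats_frames: dict[str, pd.DataFrame] = {}
    if "condition" in image_metrics and image_metrics["condition"].nunique() >= 2:
        for metric, log in (("ftr", config.log_ftr), ("hybrid_pct", False),
                            ("collagen_pct", False)):
            try:
                results = fit_metric_lmm(
                    image_metrics, metric, condition_col="condition",
                    animal_col="animal_id", log_transform=log, alpha=config.alpha)
                stats_frames[metric] = results_to_frame(results)
            except Exception as exc:
                logger.warning("statistics for %s failed: %s", metric, exc)

    manifest = config.manifest()
    manifest["n_images"] = int(len(metadata))
    manifest["n_failed"] = int(len(errors))
    manifest["errors"] = errors

    if out_dir:
        tables_dir = out_dir / "fibre_tables"
        tables_dir.mkdir(exist_ok=True)
        for image_id, table in fibre_tables.items():
            table.to_csv(tables_dir / f"{image_id}.csv", index=False)
        image_metrics.to_csv(out_dir / "image_metrics.csv", index=False)
        for metric, frame in stats_frames.items():
            frame.to_csv(out_dir / f"stats_{metric}.csv", index=False)
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str))

    return RunBundle(fibre_tables=fibre_tables, image_metrics=image_metrics,
                     stats=stats_frames, manifest=manifest, errors=errors)


# ---------------------------------------------------------------------------
# Validation harnesses
# ---------------------------------------------------------------------------

def score_against_truth(truth: GroundTruth, label_map, records) -> dict:
    """Score a segmentation + classification result against simulator truth.

    Segmented ROIs are matched one-to-one to interior ground-truth fibres
    by Hungarian assignment on IoU (minimum IoU 0.5).  Returns fibre
    recall, mean matched IoU, and per-fibre class accuracy over interior
    ground-truth fibres.
    """
    from scipy.optimize import linear_sum_assignment

    gt = truth.label_image.astype(np.int64)
    seg = (label_map.labels if hasattr(label_map, "labels") else label_map).astype(np.int64)
    interior = truth.fibres.loc[~truth.fibres["touches_border"]]
    gt_ids = interior["fibre_id"].to_numpy()
    true_class = dict(zip(interior["fibre_id"], interior["true_class"]))
    rec_class = {r.roi_id: r.assigned_class for r in records}
    seg_ids = np.array(sorted(rec_class))
    if len(gt_ids) == 0 or len(seg_ids) == 0:
        return {"n_truth": int(len(gt_ids)), "n_matched": 0, "recall": 0.0,
                "mean_iou": float("nan"), "class_accuracy_pct": float("nan")}

    # joint pixel histogram -> IoU matrix
    gt_areas = dict(zip(*np.unique(gt, return_counts=True)))
    seg_areas = dict(zip(*np.unique(seg, return_counts=True)))
    pair_codes, counts = np.unique(gt * (seg.max() + 1) + seg, return_counts=True)
    gt_pos = {g: i for i, g in enumerate(gt_ids)}
    seg_pos = {s: j for j, s in enumerate(seg_ids)}
    iou = np.zeros((len(gt_ids), len(seg_ids)))
    for code, inter in zip(pair_codes, counts):
        g, s = divmod(int(code), int(seg.max() + 1))
        if g in gt_pos and s in seg_pos:
            union = gt_areas[g] + seg_areas[s] - inter
            iou[gt_pos[g], seg_pos[s]] = inter / union

    rows, cols = linear_sum_assignment(-iou)
    matched = [(gt_ids[r], seg_ids[c], iou[r, c])
               for r, c in zip(rows, cols) if iou[r, c] >= 0.5]
    correct = sum(true_class[g] == rec_class[s] for g, s, _ in matched)
    return {
        "n_truth": int(len(gt_ids)),
        "n_matched": len(matched),
        "recall": len(matched) / len(gt_ids),
        "mean_iou": float(np.mean([m[2] for m in matched])) if matched else float("nan"),
        "class_accuracy_pct": 100.0 * correct / len(gt_ids),
    }

def validate_fov_representativeness(
    section_image: MultiChannelImage,
    fov_shape: tuple[int, int],
    n_fovs: int,
    seed: int = 0,
    params: PipelineParams | None = None,
) -> dict:
    """Check that random small fields of view represent the whole section.

    The FTR of ``n_fovs`` randomly positioned FOV crops is compared with
    the FTR of the full section by a paired (one-sample) t-test on the
    per-FOV differences; a homogeneous section should yield a
    non-significant p.  Raises ``ValueError`` when the FOV exceeds the
    section.
    """
    h, w = section_image.shape
    fh, fw = fov_shape
    if fh > h or fw > w:
        raise ValueError("FOV is larger than the section")
    params = params or PipelineParams()

    section_ftr = process_image(section_image, params)["metrics"].ftr

    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_fovs):
        r0 = int(rng.integers(0, h - fh + 1))
        c0 = int(rng.integers(0, w - fw + 1))
        crop = MultiChannelImage(
            channels={name: ch[r0:r0 + fh, c0:c0 + fw]
                      for name, ch in section_image.channels.items()},
            pixel_size=section_image.pixel_size,
            provenance=f"fov({r0},{c0})")
        fov_ftr = process_image(crop, params)["metrics"].ftr
        rows.append({"fov": k + 1, "row0": r0, "col0": c0,
                     "fov_ftr": fov_ftr, "section_ftr": section_ftr})
    table = pd.DataFrame(rows)

    fov_ftrs = table["fov_ftr"].to_numpy(dtype=float)
    defined = np.isfinite(fov_ftrs)
    if (fh, fw) == (h, w) or np.allclose(fov_ftrs[defined], section_ftr):
        p = 1.0
    elif defined.sum() >= 2 and np.isfinite(section_ftr):
        p = float(sps.ttest_1samp(fov_ftrs[defined], section_ftr).pvalue)
    else:
        p = float("nan")
    return {"table": table, "section_ftr": section_ftr, "p": p,
            "mean_fov_ftr": float(np.nanmean(fov_ftrs))}


def validate_against_annotation(
    fibre_tables: dict[str, pd.DataFrame],
    annotations: dict[str, pd.DataFrame],
) -> dict:
    """Compare automated classification with expert annotations.

    ``annotations`` maps image_id to a table with ``roi_id`` and
    ``class`` columns.  Returns per-image percent correct, the
    mean/median/IQR summary across images, and a pooled confusion
    matrix; ids present in only one table are listed, not fatal.
    """
    per_image = {}
    confusions = []
    unmatched: dict[str, list] = {}
    for image_id, annot in annotations.items():
        auto = fibre_tables.get(image_id)
        if auto is None:
            unmatched[image_id] = ["<entire image missing from run outputs>"]
            continue
        report = compare_to_annotation(auto, annot)
        per_image[image_id] = report["pct_correct"]
        if report["defined"]:
            confusions.append(report["confusion"])
        extra = sorted(set(annot["roi_id"]) ^ set(auto["roi_id"]))
        if extra:
            unmatched[image_id] = extra
    pooled = (pd.concat(confusions).groupby(level=0).sum()
              if confusions else pd.DataFrame())
    return {"per_image_pct": per_image,
            "summary": summarise_agreement(list(per_image.values())),
            "confusion": pooled, "unmatched_ids": unmatched}
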