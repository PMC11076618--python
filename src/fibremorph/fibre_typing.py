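"""Slow / fast / hybrid / noise classification of segmented fibres.

Each interior ROI is classified from two ingredients: its area and the
fraction of its pixels covered by the binarised slow (red) and fast
(green) myosin channels.  Objects below the minimum area, or stained in
neither channel, are noise ("other structures"); staining above
threshold in both channels marks a hybrid fibre undergoing type
conversion; otherwise the single stained channel decides the type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fibremorph.imaging import BinaryMask
from fibremorph.segmentation import ROI

CLASS_LABELS = ("slow", "fast", "hybrid", "noise")

#: Default coverage threshold shared by both myosin channels.
DEFAULT_COVERAGE_THRESHOLD = 0.3

#: Default minimum fibre area: a 15 µm-diameter circle, the physiological
#: lower bound for adult large-mammal fibres.
DEFAULT_MIN_AREA_UM2 = math.pi * (15.0 / 2.0) ** 2


@dataclass
class FibreRecord:
    """Measurements and assigned class for one segmented ROI."""

    roi_id: int
    area_um2: float
    slow_coverage: float
    fast_coverage: float
    assigned_class: str = ""
    mfd_um: float = float("nan")


def measure_coverage(
    roi: ROI,
    slow_mask: BinaryMask | np.ndarray,
    fast_mask: BinaryMask | np.ndarray,
) -> tuple[float, float]:
    """Fraction of the ROI's pixels that are foreground in each myosin mask."""
    if roi.area_px == 0:
        raise ValueError("cannot measure coverage of an empty ROI")
    slow = slow_mask.mask if isinstance(slow_mask, BinaryMask) else np.asarray(slow_mask, bool)
    fast = fast_mask.mask if isinstance(fast_mask, BinaryMask) else np.asarray(fast_mask, bool)
    if slow.shape != roi.image_shape or fast.shape != roi.image_shape:
        raise ValueError("mask dimensions do not match the ROI's image")
    r0, c0 = roi.offset
    h, w = roi.mask.shape
    window = (slice(r0, r0 + h), slice(c0, c0 + w))
    n = roi.area_px
    slow_cov = float(np.count_nonzero(slow[window] & roi.mask)) / n
    fast_cov = float(np.count_nonzero(fast[window] & roi.mask)) / n
    return slow_cov, fast_cov


def classify_roi(
    record: FibreRecord,
    min_area: float = DEFAULT_MIN_AREA_UM2,
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> str:
    """Apply the four-way classification rule to one measured ROI.

    area < min_area -> noise; both coverages >= threshold -> hybrid;
    exactly one >= threshold -> that class; neither -> noise (an
    unstained object).
    """
    if record.area_um2 < min_area:
        return "noise"
    slow_hit = record.slow_coverage >= coverage_threshold
    fast_hit = record.fast_coverage >= coverage_threshold
    if slow_hit and fast_hit:
        return "hybrid"
    if slow_hit:
        return "slow"
    if fast_hit:
        return "fast"
    return "noise"


def classify_image(
    rois: list[ROI],
    slow_mask: BinaryMask | np.ndarray,
    fast_mask: BinaryMask | np.ndarray,
    min_area: float = DEFAULT_MIN_AREA_UM2,
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> tuple[list[FibreRecord], dict[str, int]]:
    """Measure and classify every interior ROI of one image.

    Returns the per-fibre records and the class counts
    ``{n_slow, n_fast, n_hybrid, n_noise}``; every ROI receives exactly
    one class, so the counts sum to ``len(rois)``.
    """
    records: list[FibreRecord] = []
    counts = {"n_slow": 0, "n_fast": 0, "n_hybrid": 0, "n_noise": 0}
    for roi in rois:
        slow_cov, fast_cov = measure_coverage(roi, slow_mask, fast_mask)
        record = FibreRecord(roi_id=roi.id, area_um2=roi.area_um2,
                             slow_coverage=slow_cov, fast_coverage=fast_cov)
        record.assigned_class = classify_roi(record, min_area, coverage_threshold)
        counts[f"n_{record.assigned_class}"] += 1
        records.append(record)
    return records, counts


def records_to_frame(records: list[FibreRecord]) -> pd.DataFrame:
    """Tidy per-image fibre table (one row per ROI)."""
    return pd.DataFrame([
        {"roi_id": r.roi_id, "area_um2": r.area_um2, "slow_cov": r.slow_coverage,
         "fast_cov": r.fast_coverage, "class": r.assigned_class, "mfd_um": r.mfd_um}
        for r in records
    ], columns=["roi_id", "area_um2", "slow_cov", "fast_cov", "class", "mfd_um"])


def compare_to_annotation(
    auto: list[FibreRecord] | pd.DataFrame,
    manual: pd.DataFrame | dict[int, str],
) -> dict:
    """Per-image agreement between automated and manual classification.

    ``manual`` maps roi_id to expert class (dict, or a table with
    ``roi_id`` and ``class`` columns).  Agreement is computed over the
    shared roi_ids only; with zero shared ids the percentage is
    undefined and flagged.
    """
    if isinstance(auto, pd.DataFrame):
        auto_classes = dict(zip(auto["roi_id"], auto["class"]))
    else:
        auto_classes = {r.roi_id: r.assigned_class for r in auto}
    if isinstance(manual, pd.DataFrame):
        manual_classes = dict(zip(manual["roi_id"], manual["class"]))
    else:
        manual_classes = dict(manual)

    shared = sorted(set(auto_classes) & set(manual_classes))
    if not shared:
        return {"pct_correct": float("nan"), "n_shared": 0, "defined": False,
                "confusion": pd.DataFrame()}
    matches = sum(auto_classes[i] == manual_classes[i] for i in shared)
    confusion = pd.crosstab(
        pd.Series([manual_classes[i] for i in shared], name="manual"),
        pd.Series([auto_classes[i] for i in shared], name="auto"),
    )
    return {"pct_correct": 100.0 * matches / len(shared), "n_shared": len(shared),
            "defined": True, "confusion": confusion}


def summarise_agreement(per_image_pct: list[float]) -> dict:
    """Mean, median and IQR of per-image percent-correct values."""
    values = np.asarray([p for p in per_image_pct if np.isfinite(p)], dtype=float)
    if values.size == 0:
        return {"mean": float("nan"), "median": float("nan"), "iqr": float("nan"),
                "n_images": 0}
    q1, q3 = np.percentile(values, [25, 75])
    return {"mean": float(values.mean()), "median": float(np.median(values)),
            "iqr": float(q3 - q1), "n_images": int(values.size)}
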