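"""Per-fibre and per-image morphometry.

Fibre size is quantified by the minimum Feret diameter (MFD): the
smallest caliper width of the fibre outline over all directions, which
is robust to obliquely sectioned fibres.  Per-image readouts are the
fibre-type ratio (FTR = n_slow / n_fast), the hybrid-fibre percentage,
and the collagen area fraction.  Nerve cross-sections are summarised by
axon diameter (AD), overall diameter (OD) and myelin thickness
MT = (OD − AD) / 2, with AD and OD taken as equivalent-circle diameters
2·sqrt(area/π) of the inner and outer regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from fibremorph.imaging import BinaryMask
from fibremorph.segmentation import ROI
from fibremorph.fibre_typing import FibreRecord


# ---------------------------------------------------------------------------
# Minimum Feret diameter
# ---------------------------------------------------------------------------

def min_feret_of_points(points: np.ndarray) -> float:
    """Minimum caliper width of a planar point set.

    The Feret widths of a set equal those of its convex hull, and the
    minimum width of a convex polygon is attained perpendicular to one
    of its edges (rotating-calipers), so the minimum over hull edges of
    the hull's extent normal to that edge is exact.  Degenerate
    (collinear) sets return width 0 with a warning.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 3:
        raise ValueError("need at least three 2-D points")
    try:
        hull = ConvexHull(points)
    except QhullError:
        warnings.warn("degenerate (collinear) point set: Feret width 0", stacklevel=2)
        return 0.0
    verts = points[hull.vertices]
    n = len(verts)
    best = np.inf
    for i in range(n):
        edge = verts[(i + 1) % n] - verts[i]
        length = np.hypot(*edge)
        if length == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / length
        proj = verts @ normal
        best = min(best, proj.max() - proj.min())
    return float(best)


def max_feret_of_points(points: np.ndarray) -> float:
    """Maximum caliper width (largest pairwise hull-vertex distance)."""
    points = np.asarray(points, dtype=float)
    try:
        verts = points[ConvexHull(points).vertices]
    except QhullError:
        verts = points
    diff = verts[:, None, :] - verts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def _roi_corner_points(roi: ROI) -> np.ndarray:
    """Corner lattice of the ROI's pixels (each pixel spans a unit square)."""
    coords = roi.pixel_coords().astype(float)
    offsets = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    return (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2)


def min_feret_diameter(roi: ROI, pixel_size: float | None = None) -> float:
    """Minimum Feret diameter of an ROI, in µm.

    Computed on the corner lattice of the ROI's pixel set, so a single
    pixel has width one pixel rather than zero.
    """
    pixel_size = roi.pixel_size if pixel_size is None else pixel_size
    return min_feret_of_points(_roi_corner_points(roi)) * pixel_size


def max_feret_diameter(roi: ROI, pixel_size: float | None = None) -> float:
    """Maximum Feret diameter of an ROI, in µm."""
    pixel_size = roi.pixel_size if pixel_size is None else pixel_size
    return max_feret_of_points(_roi_corner_points(roi)) * pixel_size


# ---------------------------------------------------------------------------
# Image-level metrics
# ---------------------------------------------------------------------------

def fibre_type_ratio(n_slow: int, n_fast: int) -> float:
    """FTR = n_slow / n_fast.  Undefined (NaN) when n_fast = 0.

    Hybrid fibres count towards neither side; the ratio uses pure
    classes only.
    """
    if n_slow < 0 or n_fast < 0:
        raise ValueError("counts must be non-negative")
    if n_fast == 0:
        return float("nan")
    return n_slow / n_fast


def collagen_area_fraction(
    collagen_mask: BinaryMask | np.ndarray,
    analysis_region: np.ndarray | None = None,
) -> float:
    """Percentage of analysed pixels covered by collagen.

    Analyses the whole image unless ``analysis_region`` restricts it; an
    empty analysis region is undefined (NaN, with a warning).
    """
    mask = collagen_mask.mask if isinstance(collagen_mask, BinaryMask) \
        else np.asarray(collagen_mask, bool)
    if analysis_region is None:
        total = mask.size
        fg = int(mask.sum())
    else:
        region = np.asarray(analysis_region, bool)
        if region.shape != mask.shape:
            raise ValueError("analysis region dimensions do not match the mask")
        total = int(region.sum())
        fg = int((mask & region).sum())
    if total == 0:
        warnings.warn("empty analysis region: collagen fraction undefined", stacklevel=2)
        return float("nan")
    return 100.0 * fg / total


@dataclass
class NerveMetrics:
    """AD, OD (equivalent-circle diameters, µm) and MT = (OD − AD)/2."""

    ad: float
    od: float

    def __post_init__(self) -> None:
        if not (self.od >= self.ad >= 0):
            raise ValueError("require od >= ad >= 0")

    @property
    def mt(self) -> float:
        return (self.od - self.ad) / 2.0


def _equivalent_diameter(area_px: int, pixel_size: float) -> float:
    return 2.0 * np.sqrt(area_px * pixel_size ** 2 / np.pi)


def nerve_metrics(
    inner_mask: np.ndarray,
    outer_mask: np.ndarray,
    pixel_size: float,
) -> NerveMetrics:
    """AD/OD/MT from the axon (inner) and axon+myelin (outer) regions."""
    inner = np.asarray(inner_mask, bool)
    outer = np.asarray(outer_mask, bool)
    if (inner & ~outer).any():
        raise ValueError("inner boundary is not contained in the outer boundary")
    return NerveMetrics(ad=_equivalent_diameter(int(inner.sum()), pixel_size),
                        od=_equivalent_diameter(int(outer.sum()), pixel_size))


def measure_nerve_image(
    image: np.ndarray,
    pixel_size: float,
    min_axon_diameter: float = 1.0,
) -> pd.DataFrame:
    """Measure AD/MT/OD for every myelinated axon in a nerve section.

    The grayscale section is split into three intensity classes (dark
    myelin, intermediate axoplasm, light background) by two-level Otsu
    thresholding.  Each axoplasm component is an axon; its overall
    region is the connected component of axoplasm-plus-myelin that
    contains it.  Components smaller than ``min_axon_diameter`` are
    discarded as staining debris.
    """
    from skimage.filters import threshold_multiotsu

    image = np.asarray(image)
    t_lo, t_hi = threshold_multiotsu(image, classes=3)
    myelin = image < t_lo
    axoplasm = (image >= t_lo) & (image < t_hi)

    axon_labels, n_axons = ndi.label(axoplasm)
    union_labels, _ = ndi.label(axoplasm | myelin)
    min_area_px = np.pi * (min_axon_diameter / 2.0) ** 2 / pixel_size ** 2

    union_areas = np.bincount(union_labels.ravel())
    rows = []
    for i in range(1, n_axons + 1):
        region = axon_labels == i
        area_in = int(region.sum())
        if area_in < min_area_px:
            continue
        rr, cc = np.nonzero(region)
        union_id = union_labels[rr[0], cc[0]]
        area_out = int(union_areas[union_id]) if union_id > 0 else area_in
        metrics = NerveMetrics(ad=_equivalent_diameter(area_in, pixel_size),
                               od=_equivalent_diameter(area_out, pixel_size))
        rows.append({
            "axon_id": len(rows) + 1,
            "centre_x_um": float(cc.mean() + 0.5) * pixel_size,
            "centre_y_um": float(rr.mean() + 0.5) * pixel_size,
            "ad_um": metrics.ad, "mt_um": metrics.mt, "od_um": metrics.od,
        })
    return pd.DataFrame(rows, columns=["axon_id", "centre_x_um", "centre_y_um",
                                       "ad_um", "mt_um", "od_um"])


@dataclass
class ImageMetrics:
    """Per-image morphometric readouts.

    ``ftr`` and derived quantities are NaN (undefined) when the image
    holds no fibres of the required classes.
    """

    n_slow: int
    n_fast: int
    n_hybrid: int
    n_noise: int
    ftr: float
    hybrid_pct: float
    collagen_pct: float
    mfd_by_class: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_fibres(self) -> int:
        return self.n_slow + self.n_fast + self.n_hybrid


def image_metrics(
    records: list[FibreRecord],
    collagen_mask: BinaryMask | np.ndarray | None = None,
    analysis_region: np.ndarray | None = None,
) -> ImageMetrics:
    """Aggregate classified fibre records into per-image metrics.

    The FTR is computed per image (one field of view per slide); hybrid
    percentage is over classified fibres (noise excluded); MFD values
    are collected per class for the diameter distributions.
    """
    counts = {"slow": 0, "fast": 0, "hybrid": 0, "noise": 0}
    mfd: dict[str, list[float]] = {"slow": [], "fast": [], "hybrid": []}
    for rec in records:
        counts[rec.assigned_class] += 1
        if rec.assigned_class in mfd and np.isfinite(rec.mfd_um):
            mfd[rec.assigned_class].append(rec.mfd_um)

    n_classified = counts["slow"] + counts["fast"] + counts["hybrid"]
    hybrid_pct = 100.0 * counts["hybrid"] / n_classified if n_classified else float("nan")
    collagen_pct = (collagen_area_fraction(collagen_mask, analysis_region)
                    if collagen_mask is not None else float("nan"))
    return ImageMetrics(
        n_slow=counts["slow"], n_fast=counts["fast"], n_hybrid=counts["hybrid"],
        n_noise=counts["noise"],
        ftr=fibre_type_ratio(counts["slow"], counts["fast"]),
        hybrid_pct=hybrid_pct, collagen_pct=collagen_pct,
        mfd_by_class={k: np.asarray(v) for k, v in mfd.items()},
    )
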