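"""Fibre instance segmentation and ROI handling.

The default backend is a classical distance-transform watershed on the
composed segmentation input (fibre interiors bright, collagen boundaries
dark), so the pipeline runs self-contained.  An ``external-labelmap``
backend ingests a label image produced by any instance-segmentation tool
(e.g. a learned model), bit-compatibly: everything downstream is a pure
function of the label map, never of backend internals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

#: Physiological lower bound for adult large-mammal fibre diameters (µm);
#: used as the minimum seed separation of the watershed.
DEFAULT_MIN_FIBRE_DIAMETER_UM = 15.0


@dataclass
class LabelMap:
    """Integer instance grid: 0 = background, k >= 1 = fibre id."""

    labels: np.ndarray
    backend: str = ""
    params: dict = field(default_factory=dict)

    @property
    def n_labels(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class ROI:
    """One segmented fibre candidate.

    The pixel set is stored as a cropped boolean mask plus its offset
    (top-left corner, row/col) in the full image; pixel coordinates
    follow the half-open convention with origin at the top-left, x to
    the right and y down.
    """

    id: int
    mask: np.ndarray          # cropped bool mask
    offset: tuple[int, int]   # (row0, col0) of the crop in the image
    image_shape: tuple[int, int]
    pixel_size: float
    touches_border: bool

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size ** 2

    def pixel_coords(self) -> np.ndarray:
        """(n, 2) array of (row, col) coordinates in the full image."""
        rr, cc = np.nonzero(self.mask)
        return np.column_stack([rr + self.offset[0], cc + self.offset[1]])

    def full_mask(self) -> np.ndarray:
        out = np.zeros(self.image_shape, dtype=bool)
        r0, c0 = self.offset
        out[r0:r0 + self.mask.shape[0], c0:c0 + self.mask.shape[1]] = self.mask
        return out


def segment_fibres(
    seg_input: np.ndarray,
    backend: str = "watershed",
    pixel_size: float = 0.5,
    min_fibre_diameter: float = DEFAULT_MIN_FIBRE_DIAMETER_UM,
    smooth_sigma: float = 2.0,
    external_labels: np.ndarray | None = None,
) -> LabelMap:
    """Produce one labelled region per fibre.

    ``watershed`` backend: smooth, Otsu-threshold the bright fibre
    interiors against the dark collagen lattice, seed markers from local
    maxima of the distance transform (minimum separation =
    ``min_fibre_diameter``) and region-grow to the boundaries.

    ``external-labelmap`` backend: wrap ``external_labels`` unchanged, so
    any instance-segmentation tool can substitute bit-compatibly.
    """
    if backend == "external-labelmap":
        if external_labels is None:
            raise ValueError("external-labelmap backend requires external_labels")
        return LabelMap(labels=np.asarray(external_labels).astype(np.int32),
                        backend=backend, params={})
    if backend != "watershed":
        raise ValueError(f"unknown segmentation backend: {backend!r}")

    seg_input = np.asarray(seg_input)
    params = {"pixel_size": pixel_size, "min_fibre_diameter": min_fibre_diameter,
              "smooth_sigma": smooth_sigma}

    smoothed = gaussian(seg_input.astype(np.float64), sigma=smooth_sigma,
                        preserve_range=True)
    if smoothed.max() <= smoothed.min():
        warnings.warn("empty or constant segmentation input: no fibres found",
                      stacklevel=2)
        return LabelMap(np.zeros(seg_input.shape, np.int32), "watershed", params)
    threshold = threshold_otsu(smoothed)
    foreground = smoothed > threshold
    if not foreground.any():
        warnings.warn("empty foreground after thresholding: no fibres found",
                      stacklevel=2)
        return LabelMap(np.zeros(seg_input.shape, np.int32), "watershed", params)

    distance = ndi.distance_transform_edt(foreground)
    min_sep_px = max(int(round(min_fibre_diameter / pixel_size / 2.0)), 1)
    peaks = peak_local_max(distance, min_distance=min_sep_px, labels=foreground,
                           exclude_border=False)
    markers = np.zeros(seg_input.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        warnings.warn("no watershed seeds found", stacklevel=2)
        return LabelMap(np.zeros(seg_input.shape, np.int32), "watershed", params)

    labels = watershed(-distance, markers, mask=foreground)
    return LabelMap(labels=labels.astype(np.int32), backend="watershed", params=params)


def labels_to_rois(label_map: LabelMap | np.ndarray, pixel_size: float) -> list[ROI]:
    """Convert a label map into one ROI per label id.

    Area is pixel count x pixel_size²; ``touches_border`` is set iff any
    pixel of the label lies on the outermost row or column.
    """
    labels = label_map.labels if isinstance(label_map, LabelMap) else np.asarray(label_map)
    h, w = labels.shape
    rois: list[ROI] = []
    for prop in regionprops(labels):
        r0, c0, r1, c1 = prop.bbox
        touches = bool(r0 == 0 or c0 == 0 or r1 == h or c1 == w)
        rois.append(ROI(
            id=int(prop.label),
            mask=prop.image.copy(),
            offset=(r0, c0),
            image_shape=(h, w),
            pixel_size=pixel_size,
            touches_border=touches,
        ))
    return rois


def filter_border_rois(rois: list[ROI]) -> list[ROI]:
    """Drop ROIs that touch the image border (partial fibres).

    Only fibres fully inside the field of view are classified.
    """
    kept = [roi for roi in rois if not roi.touches_border]
    removed = len(rois) - len(kept)
    if removed:
        logger.info("excluded %d border-touching ROIs (%d kept)", removed, len(kept))
    return kept
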