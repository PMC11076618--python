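"""Image I/O and pre-processing.

Implements the pre-processing chain applied to each microscopy image
before segmentation: conversion to 8-bit grayscale, collagen enhancement
by histogram stretching, composition of the segmentation input
(slow + fast − enhanced collagen, clipped to [0, 255]) and channel
binarisation.  Images are three-channel fluorescence acquisitions with a
fixed canonical channel order: ``slow`` (red, slow myosin), ``fast``
(green, fast myosin) and ``collagen`` (orange).

All operations are pure: the same input always yields the same output.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Canonical channel order; also the page order of multi-page TIFF output.
CHANNEL_ORDER: tuple[str, str, str] = ("slow", "fast", "collagen")

#: Default micrometres per pixel when no resolution metadata is available.
DEFAULT_PIXEL_SIZE_UM = 0.5


@dataclass
class MultiChannelImage:
    """A pixel grid with named channels and a physical pixel size.

    Parameters
    ----------
    channels
        Mapping of channel name to a 2-D array.  All channels must share
        identical dimensions.
    pixel_size
        Micrometres per pixel (isotropic). Must be positive.
    provenance
        Source path or simulator seed, recorded for the run manifest.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel dimensions differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def bit_depth(self) -> int:
        dtype = next(iter(self.channels.values())).dtype
        return np.iinfo(dtype).bits if np.issubdtype(dtype, np.integer) else 32

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class BinaryMask:
    """Foreground/background mask derived from one channel.

    The thresholding method and value are recorded so every mask is
    traceable to the parameters that produced it.
    """

    mask: np.ndarray
    source_channel: str = ""
    method: str = ""
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def foreground_pixels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _pixel_size_from_tags(page: "tifffile.TiffPage") -> float | None:
    """Extract µm/px from TIFF resolution tags, if present and sane."""
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags.get("ResolutionUnit")
    except (KeyError, AttributeError):
        return None
    num, den = (xres if isinstance(xres, tuple) else (xres, 1))
    if not num:
        return None
    pixels_per_unit = num / den
    unit_value = getattr(unit, "value", unit)
    unit_value = getattr(unit_value, "value", unit_value)  # enum -> int
    if unit_value == 3:  # centimetre
        um_per_unit = 1e4
    elif unit_value == 2:  # inch
        um_per_unit = 2.54e4
    else:
        return None
    return um_per_unit / pixels_per_unit


def load_image(
    path: str | Path,
    channel_order: Sequence[str] = CHANNEL_ORDER,
    pixel_size: float | None = None,
) -> MultiChannelImage:
    """Read a multi-channel TIFF into a :class:`MultiChannelImage`.

    Both common dialects are accepted: multi-page (one page per channel,
    page order = ``channel_order``) and RGB-interleaved (last axis is the
    channel axis).  Pixel size is taken from the TIFF resolution tags when
    present, otherwise from ``pixel_size`` (falling back to the package
    default).

    Raises
    ------
    ValueError
        If the file holds fewer channels than ``channel_order`` names; the
        error names the first missing channel.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        tag_pixel_size = _pixel_size_from_tags(tif.pages[0])

    n_wanted = len(channel_order)
    if arr.ndim == 2:
        planes = arr[None]
    elif arr.ndim == 3:
        # Disambiguate (C, H, W) vs (H, W, C): the channel axis is the
        # short one; ties go to channels-first (our own writer's layout).
        if arr.shape[0] <= arr.shape[-1]:
            planes = arr
        else:
            planes = np.moveaxis(arr, -1, 0)
    else:
        raise ValueError(f"unsupported TIFF layout with shape {arr.shape}")

    if planes.shape[0] < n_wanted:
        missing = channel_order[planes.shape[0]]
        raise ValueError(f"missing channel: {missing} (file has {planes.shape[0]} channels)")

    channels = {name: np.ascontiguousarray(planes[i]) for i, name in enumerate(channel_order)}
    resolved = tag_pixel_size or pixel_size or DEFAULT_PIXEL_SIZE_UM
    return MultiChannelImage(channels=channels, pixel_size=resolved, provenance=str(path))


def save_image(image: MultiChannelImage, path: str | Path,
               channel_order: Sequence[str] = CHANNEL_ORDER) -> Path:
    """Write a multi-page TIFF, one page per channel in canonical order.

    Pixel size is stored in the resolution tags (pixels per centimetre).
    """
    path = Path(path)
    stack = np.stack([image.channels[name] for name in channel_order])
    pixels_per_cm = 1e4 / image.pixel_size
    tifffile.imwrite(
        path,
        stack,
        photometric="minisblack",
        resolution=(pixels_per_cm, pixels_per_cm),
        resolutionunit="CENTIMETER",
    )
    return path


def save_mask(mask: BinaryMask | np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit {0, 255} TIFF."""
    arr = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    tifffile.imwrite(Path(path), (arr.astype(np.uint8) * 255))
    return Path(path)


def save_sidecar(params: Mapping, path: str | Path) -> Path:
    """Echo processing parameters into a JSON sidecar for provenance."""
    path = Path(path)
    path.write_text(json.dumps(dict(params), indent=2, sort_keys=True, default=str))
    return path


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def to_grayscale8(channel: np.ndarray) -> np.ndarray:
    """Convert an integer channel to 8-bit by linear rescale of its
    nominal dtype range to [0, 255], rounding half up.

    8-bit input is returned unchanged (identity).
    """
    channel = np.asarray(channel)
    if channel.dtype == np.uint8:
        return channel
    if not np.issubdtype(channel.dtype, np.integer):
        raise TypeError(f"expected an integer dtype, got {channel.dtype}")
    info = np.iinfo(channel.dtype)
    span = info.max - info.min
    scaled = (channel.astype(np.float64) - info.min) * (255.0 / span)
    return np.floor(scaled + 0.5).astype(np.uint8)


def enhance_collagen(
    channel: np.ndarray,
    low_percentile: float = 1.0,
    high_percentile: float = 99.0,
) -> np.ndarray:
    """Enhance collagen structures by percentile histogram stretching.

    Intensities at or below the low percentile map to 0, at or above the
    high percentile to 255, linearly in between.  A constant channel is
    returned unchanged with a warning (the stretch is undefined).
    """
    if not (0 <= low_percentile < high_percentile <= 100):
        raise ValueError("require 0 <= low < high <= 100")
    channel = np.asarray(channel)
    lo, hi = np.percentile(channel, [low_percentile, high_percentile])
    if hi <= lo:
        warnings.warn("histogram stretch is undefined on a (near-)constant channel; "
                      "returning input unchanged", stacklevel=2)
        return channel.copy()
    stretched = (channel.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.clip(np.floor(stretched + 0.5), 0, 255).astype(np.uint8)


def compose_segmentation_input(
    slow_channel: np.ndarray,
    fast_channel: np.ndarray,
    enhanced_collagen: np.ndarray,
) -> np.ndarray:
    """Compose the single-channel segmentation input.

    Pixelwise ``clip(slow + fast − collagen, 0, 255)``: fibre interiors
    (bright in either myosin channel) stay bright while the enhanced
    collagen lattice darkens the boundaries between fibres.
    """
    arrays = [np.asarray(a) for a in (slow_channel, fast_channel, enhanced_collagen)]
    if len({a.shape for a in arrays}) > 1:
        raise ValueError("channel dimensions differ")
    s, f, c = (a.astype(np.int32) for a in arrays)
    return np.clip(s + f - c, 0, 255).astype(np.uint8)


def binarise_channel(
    channel: np.ndarray,
    method: str = "otsu",
    source_channel: str = "",
) -> BinaryMask:
    """Binarise a channel into foreground and background.

    ``method`` is ``"otsu"`` (default) or ``"fixed:<t>"`` for a pinned
    threshold.  Foreground is strictly above the threshold.  Otsu on a
    constant channel is degenerate: an all-background mask is returned
    with a warning.
    """
    from skimage.filters import threshold_otsu

    channel = np.asarray(channel)
    if method.startswith("fixed:"):
        t = float(method.split(":", 1)[1])
    elif method == "otsu":
        if channel.min() == channel.max():
            warnings.warn("constant channel: Otsu threshold undefined, "
                          "returning all-background mask", stacklevel=2)
            return BinaryMask(np.zeros(channel.shape, bool), source_channel,
                              "otsu-degenerate", float(channel.flat[0]))
        t = float(threshold_otsu(channel))
    else:
        raise ValueError(f"unknown binarisation method: {method!r}")
    return BinaryMask(channel > t, source_channel, method, t)


def preprocess(
    image: MultiChannelImage,
    stretch_percentiles: tuple[float, float] = (1.0, 99.0),
    binarise_method: str = "otsu",
) -> dict:
    """Run the full pre-processing chain on one image.

    Returns a dict with the 8-bit channels, the enhanced collagen
    channel, the composed segmentation input, and binary masks for the
    slow, fast and collagen channels.
    """
    slow8 = to_grayscale8(image["slow"])
    fast8 = to_grayscale8(image["fast"])
    coll8 = to_grayscale8(image["collagen"])
    enhanced = enhance_collagen(coll8, *stretch_percentiles)
    seg_input = compose_segmentation_input(slow8, fast8, enhanced)
    return {
        "slow8": slow8,
        "fast8": fast8,
        "collagen8": coll8,
        "collagen_enhanced": enhanced,
        "seg_input": seg_input,
        "slow_mask": binarise_channel(slow8, binarise_method, "slow"),
        "fast_mask": binarise_channel(fast8, binarise_method, "fast"),
        # collagen is quantified from the acquired channel; the enhanced
        # version only serves the segmentation-input composition
        "collagen_mask": binarise_channel(coll8, binarise_method, "collagen"),
    }
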