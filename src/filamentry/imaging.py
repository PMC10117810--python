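"""Whole-colony image segmentation and the f-measure.

The f-measure of a colony is the total area of its filamentous
(pseudohyphal) protrusions: the area enclosed by the outer boundary of all
protrusions, ``A_outer``, minus the area enclosed by the boundary of the
central colony mass, ``A_inner``.  The pipeline that produces it from a
single brightfield micrograph is

1. :func:`standardize`  — rescale to a uniform resolution and convert to
   grayscale;
2. :func:`binarize`     — Gaussian blur then a global (Otsu by default)
   threshold, oriented by colony polarity;
3. :func:`fill_voids`   — eliminate enclosed background voids created by
   overlapping filaments or filaments rejoining the colony mass;
4. :func:`extract_boundaries` — measure ``A_outer`` on the filled object and
   ``A_inner`` on the same object after a morphological opening with a disk
   whose radius exceeds the filament half-width, so that protrusions are
   stripped and only the central mass remains.

:func:`measure_image` composes the four stages.  Areas are pixel counts of
filled regions; boundary polygons are retained only for QC overlays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, transform

from .exceptions import (
    ConfigurationError,
    InputError,
    NoColonyFound,
    OpeningTooAggressive,
    SegmentationWarning,
)

__all__ = [
    "ColonyImage",
    "PreprocessConfig",
    "BinaryMask",
    "SegmentationResult",
    "standardize",
    "binarize",
    "fill_voids",
    "extract_boundaries",
    "measure_image",
    "read_image",
]

#: default physical pixel size: 2.2 um sensor pixels at 2.5x magnification
DEFAULT_PIXEL_SIZE_UM = 2.2 / 2.5


@dataclass
class ColonyImage:
    """A single whole-colony micrograph.

    ``pixels`` is a 2-D grayscale or 3-D colour array with intensities in
    [0, 255].  ``pixel_size_um`` (optional) is the physical edge length of
    one pixel and enables calibrated (mm²) output.
    """

    pixels: np.ndarray
    source_id: str = ""
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.size == 0:
            raise InputError(f"image {self.source_id!r} is empty")
        if px.ndim not in (2, 3):
            raise InputError(f"image {self.source_id!r} must be 2-D or 3-D")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise InputError("pixel_size_um must be positive")
        self.pixels = px

    @property
    def is_grayscale(self) -> bool:
        return self.pixels.ndim == 2


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable parameters of the segmentation pipeline.

    Defaults mirror the measurement tool's fixed behaviour: 2560×1920
    working resolution, 5×5 Gaussian blur, a standard (Otsu) global
    threshold, all enclosed voids filled, and a 15 px opening disk to
    isolate the central mass at full resolution.  ``colony_polarity`` is
    ``"dark"`` for brightfield colonies darker than the agar.
    """

    target_resolution: tuple[int, int] = (2560, 1920)  # (width, height)
    blur_kernel: tuple[int, int] = (5, 5)
    threshold_method: str = "otsu"
    threshold_value: float | None = None
    fill_all_holes: bool = True
    min_void_area_px2: float = 0.0
    opening_radius_px: int = 15
    colony_polarity: str = "dark"

    def __post_init__(self) -> None:
        w, h = self.target_resolution
        if w <= 0 or h <= 0:
            raise ConfigurationError("target_resolution must be positive")
        for k in self.blur_kernel:
            if k < 1 or k % 2 == 0:
                raise ConfigurationError("blur_kernel entries must be odd and >= 1")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ConfigurationError(
                f"unknown threshold_method {self.threshold_method!r}"
            )
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ConfigurationError("fixed threshold requires threshold_value")
        if self.opening_radius_px < 1:
            raise ConfigurationError("opening_radius_px must be >= 1")
        if self.min_void_area_px2 < 0:
            raise ConfigurationError("min_void_area_px2 must be non-negative")
        if self.colony_polarity not in ("dark", "light"):
            raise ConfigurationError("colony_polarity must be 'dark' or 'light'")

    def with_(self, **kwargs: Any) -> "PreprocessConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class BinaryMask:
    """Boolean raster; True marks colony foreground."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InputError("mask must be a non-empty 2-D boolean array")

    @property
    def area_px2(self) -> int:
        return int(self.pixels.sum())


@dataclass
class SegmentationResult:
    """Areas and QC intermediates for one measured colony.

    ``f_measure_px2 = a_outer_px2 − a_inner_px2`` always holds;
    ``f_measure_calibrated`` (mm²) is present when the source image carried
    a physical pixel size.
    """

    source_id: str
    a_outer_px2: float
    a_inner_px2: float
    f_measure_px2: float
    f_measure_calibrated: float | None = None
    qc: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.a_inner_px2 < 0 or self.a_outer_px2 < self.a_inner_px2:
            raise ValueError("requires a_outer_px2 >= a_inner_px2 >= 0")


# --------------------------------------------------------------------------
# pipeline stages
# --------------------------------------------------------------------------

_LUMA = np.array([0.299, 0.587, 0.114])  # ITU-R 601 luminance weights


def standardize(image: ColonyImage, config: PreprocessConfig) -> ColonyImage:
    """Convert to single-channel at the configured working resolution.

    Colour inputs are collapsed with standard luminance weighting; the
    raster is then rescaled directly to ``target_resolution`` (the fixed-
    output behaviour of the measurement tool), so a 4:3 input keeps its
    aspect and others are stretched.
    """
    px = np.asarray(image.pixels, dtype=float)
    if px.ndim == 3:
        if px.shape[2] == 4:  # drop alpha
            px = px[:, :, :3]
        if px.shape[2] != 3:
            raise InputError(f"cannot interpret {px.shape[2]}-channel image")
        px = px @ _LUMA
    w, h = config.target_resolution
    if px.shape != (h, w):
        px = transform.resize(
            px, (h, w), order=1, preserve_range=True, anti_aliasing=px.shape[0] > h
        )
    px = np.clip(px, 0.0, 255.0)
    return ColonyImage(
        pixels=px, source_id=image.source_id, pixel_size_um=image.pixel_size_um
    )


def _sigma_from_kernel(k: int) -> float:
    # kernel-size -> sigma convention used when only an odd kernel is given
    return 0.3 * ((k - 1) * 0.5 - 1.0) + 0.8


def binarize(image: ColonyImage, config: PreprocessConfig) -> BinaryMask:
    """Blur then globally threshold a standardized image.

    The Gaussian sigma is derived from the configured kernel size; the
    threshold is Otsu's unless a fixed value is configured.  Foreground is
    the side of the threshold matching ``colony_polarity``.
    """
    if not image.is_grayscale:
        raise InputError("binarize expects a standardized (grayscale) image")
    ky, kx = config.blur_kernel
    blurred = filters.gaussian(
        image.pixels.astype(float),
        sigma=(_sigma_from_kernel(ky), _sigma_from_kernel(kx)),
        preserve_range=True,
    )
    if config.threshold_method == "fixed":
        t = float(config.threshold_value)
    else:
        lo, hi = blurred.min(), blurred.max()
        if hi - lo < 1e-9:
            raise NoColonyFound(f"image {image.source_id!r} has uniform intensity")
        t = float(filters.threshold_otsu(blurred))
    fg = blurred < t if config.colony_polarity == "dark" else blurred > t
    if not fg.any() or fg.all():
        raise NoColonyFound(
            f"threshold left no separable colony in {image.source_id!r}"
        )
    return BinaryMask(pixels=fg)


def fill_voids(mask: BinaryMask, config: PreprocessConfig) -> BinaryMask:
    """Fill enclosed background voids inside the colony object.

    Voids arise where filaments overlap or curl back onto the colony mass.
    With ``fill_all_holes`` every enclosed background component becomes
    foreground; otherwise only voids smaller than ``min_void_area_px2``.
    """
    px = mask.pixels
    if config.fill_all_holes:
        return BinaryMask(pixels=ndi.binary_fill_holes(px))
    filled = ndi.binary_fill_holes(px)
    holes = filled & ~px
    labels, n = ndi.label(holes)
    if n == 0:
        return BinaryMask(pixels=px.copy())
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = px.copy()
    for lab, area in zip(range(1, n + 1), areas):
        if area < config.min_void_area_px2:
            keep |= labels == lab
    return BinaryMask(pixels=keep)


def _disk_opening(mask: np.ndarray, radius: float) -> np.ndarray:
    """Morphological opening by a Euclidean disk, via two distance transforms.

    Erosion keeps pixels at distance >= radius from the background; dilation
    of the eroded set brings back pixels within radius of it.  Equivalent to
    opening with a true disk but O(n) regardless of radius.
    """
    if not mask.any():
        return mask.copy()
    eroded = ndi.distance_transform_edt(mask) >= radius
    if not eroded.any():
        return eroded
    # anti-extensivity: clip the dilation back to the input, which the exact
    # (continuous) opening satisfies but the discrete radius tests may not
    return (ndi.distance_transform_edt(~eroded) <= radius) & mask


def _largest_component(mask: np.ndarray) -> tuple[np.ndarray, int, int]:
    labels, n = ndi.label(mask)
    if n == 0:
        return np.zeros_like(mask), 0, 0
    counts = np.bincount(labels.ravel())[1:]
    lab = int(np.argmax(counts)) + 1
    return labels == lab, int(counts[lab - 1]), n


def _longest_contour(mask: np.ndarray) -> np.ndarray | None:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return None
    return max(contours, key=len)


def extract_boundaries(
    mask: BinaryMask, config: PreprocessConfig, *, keep_qc: bool = True
) -> SegmentationResult:
    """Measure ``A_outer`` and ``A_inner`` on a void-filled mask.

    ``A_outer`` is the pixel area of the dominant colony object; ``A_inner``
    is the area of that object after opening with a disk of
    ``opening_radius_px``, which removes every protrusion thinner than
    about twice the radius while leaving the central mass intact.
    """
    if not mask.pixels.any():
        raise NoColonyFound("mask is empty")
    colony, outer_area, n_comp = _largest_component(mask.pixels)
    if n_comp > 1 and outer_area < 0.9 * mask.area_px2:
        warnings.warn(
            f"largest object holds only {outer_area / mask.area_px2:.0%} of the "
            "foreground; expected a single dominant colony",
            SegmentationWarning,
            stacklevel=2,
        )
    opened = _disk_opening(colony, float(config.opening_radius_px))
    if not opened.any():
        raise OpeningTooAggressive(
            f"opening radius {config.opening_radius_px}px erased the colony "
            f"(object area {outer_area}px^2)"
        )
    core, inner_area, _ = _largest_component(opened)

    qc: dict[str, Any] = {}
    if keep_qc:
        qc = {
            "filled_mask": colony,
            "opened_mask": core,
            "outer_contour": _longest_contour(colony),
            "inner_contour": _longest_contour(core),
        }
    return SegmentationResult(
        source_id="",
        a_outer_px2=float(outer_area),
        a_inner_px2=float(inner_area),
        f_measure_px2=float(outer_area - inner_area),
        qc=qc,
    )


def measure_image(
    image: ColonyImage, config: PreprocessConfig, *, keep_qc: bool = True
) -> SegmentationResult:
    """Full pipeline: standardize → binarize → fill voids → boundaries.

    Returns the f-measure in px² (clamped at zero should the subtraction
    ever come out negative) and, when the image carries a physical pixel
    size, in mm² as ``f_measure_px2 · (pixel_size_um / 1000)²``.
    """
    std = standardize(image, config)
    mask = binarize(std, config)
    mask = fill_voids(mask, config)
    result = extract_boundaries(mask, config, keep_qc=keep_qc)
    result.source_id = image.source_id
    f = result.a_outer_px2 - result.a_inner_px2
    if f < 0:  # defensive: cannot happen with the opening-based A_inner
        warnings.warn(
            f"negative f-measure {f} for {image.source_id!r}; clamping to 0",
            SegmentationWarning,
            stacklevel=2,
        )
        f = 0.0
    result.f_measure_px2 = f
    if image.pixel_size_um is not None:
        result.f_measure_calibrated = f * (image.pixel_size_um / 1000.0) ** 2
    return result


def read_image(path, pixel_size_um: float | None = None) -> ColonyImage:
    """Load a JPEG/PNG/TIFF micrograph from disk."""
    import imageio.v3 as iio

    try:
        px = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read image {path}: {exc}") from exc
    return ColonyImage(pixels=px, source_id=str(path), pixel_size_um=pixel_size_um)
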