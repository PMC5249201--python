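"""Tissue/background segmentation and the tile-inclusion domain.

Masson-trichrome tissue (collagen blue, muscle/cytoplasm red-purple) is
saturated and dark against a near-white slide background, so a luminance
threshold separates the two reliably.  The threshold is either fixed or
picked automatically by Otsu's method on the luminance of non-erased pixels.

Manually deleted structures (large bronchi and vessels, diameter > 200 um)
can arrive in two forms: a separate exclusion mask, or regions painted pure
white into the image itself, which are recognised as "sentinel" pixels within
a small channel distance of (255, 255, 255).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, remove_small_holes, remove_small_objects

from .image_io import BinaryMask, FractionImage, SectionImage

__all__ = [
    "SegmentationParams",
    "segment_tissue",
    "soft_tissue_fraction",
    "lung_footprint",
    "inclusion_mask",
]

#: Rec. 601 luma weights.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class SegmentationParams:
    """Knobs for segmentation and footprint extraction.

    mode
        ``binary_native``: segment at scan resolution, then block-reduce to
        fractions (preferred; tile densities become near-continuous).
        ``soft_analysis``: continuous per-pixel fraction directly at the
        analysis resolution, for inputs that only exist reduced.
    luminance_threshold
        Fixed cut in (0, 255), or ``"auto"`` for Otsu on non-sentinel pixels.
    white_sentinel_tolerance
        Channel distance from pure white treated as an erased pixel.
    footprint_closing_radius_px / footprint_min_hole_px
        Morphology used to turn the thin septal network into a solid section
        footprint: closing bridges alveolar lumens (~50-100 um at 3.632
        um/px), hole filling absorbs enclosed lumens.
    """

    mode: str = "binary_native"
    luminance_threshold: float | str = "auto"
    white_sentinel_tolerance: int = 2
    footprint_closing_radius_px: int = 10
    footprint_min_hole_px: int = 5000
    footprint_min_component_fraction: float = 1e-3

    def __post_init__(self) -> None:
        if self.mode not in ("binary_native", "soft_analysis"):
            raise ValueError(f"unknown segmentation mode {self.mode!r}")
        if self.luminance_threshold != "auto":
            t = float(self.luminance_threshold)
            if not 0 < t < 255:
                raise ValueError(f"luminance_threshold must be in (0, 255), got {t}")
        if self.footprint_closing_radius_px < 0 or self.footprint_min_hole_px < 0:
            raise ValueError("footprint morphology parameters must be >= 0")


def _luminance(pixels: np.ndarray) -> np.ndarray:
    return np.asarray(pixels, dtype=np.float64) @ _LUMA


def _sentinel(pixels: np.ndarray, tolerance: int) -> np.ndarray:
    return (pixels >= 255 - tolerance).all(axis=2)


def _resolve_threshold(image: SectionImage, params: SegmentationParams) -> tuple[float, np.ndarray, np.ndarray]:
    lum = _luminance(image.pixels)
    sentinel = _sentinel(image.pixels, params.white_sentinel_tolerance)
    if params.luminance_threshold == "auto":
        if not (~sentinel).any():
            raise ValueError(
                f"section {image.label!r} contains only erased/white pixels; cannot auto-threshold"
            )
        values = lum[~sentinel]
        if np.ptp(values) == 0:
            raise ValueError(f"section {image.label!r} has constant luminance; cannot auto-threshold")
        threshold = float(threshold_otsu(values))
    else:
        threshold = float(params.luminance_threshold)
    return threshold, lum, sentinel


def segment_tissue(image: SectionImage, params: SegmentationParams | None = None) -> BinaryMask:
    """Binary tissue mask: luminance below threshold and not an erased pixel."""
    params = params or SegmentationParams()
    threshold, lum, sentinel = _resolve_threshold(image, params)
    tissue = (lum < threshold) & ~sentinel
    return BinaryMask(tissue, image.pixel_size_um, semantics="tissue")


def soft_tissue_fraction(image: SectionImage, params: SegmentationParams | None = None) -> FractionImage:
    """Continuous tissue evidence per pixel: (threshold - luminance)/threshold, clamped.

    Yields 1 for pure black, 0 at/above the threshold and for erased pixels.
    Intended for inputs that only exist at the reduced analysis resolution,
    where a hard binary call would quantise 2x2-pixel tile densities to
    multiples of 1/4.
    """
    params = params or SegmentationParams()
    threshold, lum, sentinel = _resolve_threshold(image, params)
    frac = np.clip((threshold - lum) / threshold, 0.0, 1.0)
    frac[sentinel] = 0.0
    return FractionImage(frac, image.pixel_size_um)


def lung_footprint(tissue: BinaryMask | FractionImage, params: SegmentationParams | None = None) -> BinaryMask:
    """Solid section footprint from the (thin, holey) tissue raster.

    Closing with a disk bridges alveolar lumens, interior holes below
    ``footprint_min_hole_px`` are filled, and connected components smaller
    than 0.1% of the image area are dropped as debris.
    """
    params = params or SegmentationParams()
    binary = np.asarray(tissue.pixels) > 0
    if not binary.any():
        raise ValueError("empty tissue raster: no footprint")
    fp = closing(binary, disk(params.footprint_closing_radius_px))
    if params.footprint_min_hole_px > 1:
        # fill holes strictly smaller than footprint_min_hole_px
        fp = remove_small_holes(fp, max_size=params.footprint_min_hole_px - 1)
    min_size = int(np.ceil(params.footprint_min_component_fraction * binary.size))
    if min_size > 1:
        # drop components strictly smaller than 0.1% of the image area; debris-only
        # input legitimately yields an empty footprint
        fp = remove_small_objects(fp, max_size=min_size - 1)
    return BinaryMask(fp, tissue.pixel_size_um, semantics="footprint")


def inclusion_mask(footprint: BinaryMask, exclusion: BinaryMask | None = None) -> BinaryMask:
    """Domain eligible for tiling: footprint minus excluded structures."""
    if exclusion is None:
        return BinaryMask(footprint.pixels.copy(), footprint.pixel_size_um, semantics="inclusion")
    if exclusion.shape != footprint.shape:
        raise ValueError(
            f"exclusion shape {exclusion.shape} does not match footprint shape {footprint.shape}"
        )
    incl = footprint.pixels.astype(bool) & ~exclusion.pixels.astype(bool)
    return BinaryMask(incl, footprint.pixel_size_um, semantics="inclusion")
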