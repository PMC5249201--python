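"""End-to-end quantification of one section: image -> tile densities -> histogram.

Stage order mirrors the acquisition workflow: excluded structures are
removed (mask or white-sentinel pixels), tissue is segmented, the raster is
reduced to the analysis resolution, the micro-tile grid is laid over the
inclusion domain, and per-tile densities are graded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classification import DensityHistogram, histogram
from .image_io import BinaryMask, FractionImage, SectionImage, block_reduce_fraction
from .segmentation import (
    SegmentationParams,
    inclusion_mask,
    lung_footprint,
    segment_tissue,
    soft_tissue_fraction,
)
from .tiling import TileDensityMap, make_grid, tile_densities

__all__ = ["QuantifyResult", "quantify_section"]


@dataclass
class QuantifyResult:
    """Everything the pipeline derives from one section image."""

    label: str
    fractions: FractionImage
    footprint: BinaryMask
    inclusion: BinaryMask
    tile_map: TileDensityMap
    hist: DensityHistogram


def _reduce_exclusion(exclusion: BinaryMask, factor: int) -> BinaryMask:
    """Exclusion at the analysis resolution: any excluded native pixel excludes."""
    frac = block_reduce_fraction(exclusion, factor)
    return BinaryMask(frac.pixels > 0, frac.pixel_size_um, semantics="exclusion")


def quantify_section(
    image: SectionImage,
    exclusion: BinaryMask | None = None,
    seg_params: SegmentationParams | None = None,
    reduction_factor: int = 8,
    tile_side_px: int = 2,
    min_inclusion: float = 1.0,
) -> QuantifyResult:
    """Run segmentation -> reduction -> tiling -> classification on one section.

    In ``binary_native`` mode the image is segmented at its own (native)
    resolution and block-reduced by ``reduction_factor`` (default 8, the x20
    to x2.5 magnification step); in ``soft_analysis`` mode the image is
    already at the analysis resolution and a continuous per-pixel fraction is
    used without reduction.
    """
    seg_params = seg_params or SegmentationParams()
    if exclusion is not None and exclusion.shape != image.shape:
        raise ValueError(
            f"section {image.label!r}: exclusion mask shape {exclusion.shape} "
            f"does not match image shape {image.shape}"
        )
    if seg_params.mode == "binary_native":
        tissue = segment_tissue(image, seg_params)
        fractions = block_reduce_fraction(tissue, reduction_factor)
        excl_red = _reduce_exclusion(exclusion, reduction_factor) if exclusion is not None else None
    else:
        fractions = soft_tissue_fraction(image, seg_params)
        excl_red = exclusion
    footprint = lung_footprint(fractions, seg_params)
    incl = inclusion_mask(footprint, excl_red)
    grid = make_grid(*fractions.shape, tile_side_px, fractions.pixel_size_um)
    dmap = tile_densities(fractions, grid, incl, min_inclusion=min_inclusion)
    return QuantifyResult(
        label=image.label,
        fractions=fractions,
        footprint=footprint,
        inclusion=incl,
        tile_map=dmap,
        hist=histogram(dmap, label=image.label),
    )
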