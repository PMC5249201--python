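"""Micro-tile grid, per-tile pulmonary tissue density and the Dm index.

The section is covered by a regular grid of small square micro-tiles (default
2 px = 7.264 um at the 3.632 um/px analysis resolution, i.e. ~52.8 um^2 per
tile).  The density d of a tile is the tissue area inside it divided by the
*total* tile area; the mean over included tiles is the mean tissue density
index Dm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import BinaryMask, FractionImage

__all__ = ["TileGrid", "TileDensityMap", "DensityIndexes", "make_grid", "tile_densities", "mean_density"]


@dataclass(frozen=True)
class TileGrid:
    """Non-overlapping square tiles anchored at the raster origin (0, 0)."""

    tile_side_px: int
    n_rows: int
    n_cols: int
    pixel_size_um: float
    image_height_px: int
    image_width_px: int

    @property
    def tile_area_um2(self) -> float:
        return (self.tile_side_px * self.pixel_size_um) ** 2


@dataclass
class TileDensityMap:
    """Per-tile densities with inclusion flags.

    ``density`` is NaN where a tile is not included (partial border tile or
    insufficient overlap with the inclusion domain).
    """

    grid: TileGrid
    density: np.ndarray
    included: np.ndarray

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=np.float64)
        self.included = np.asarray(self.included, dtype=bool)
        expected = (self.grid.n_rows, self.grid.n_cols)
        if self.density.shape != expected or self.included.shape != expected:
            raise ValueError(f"density/included must have grid shape {expected}")
        vals = self.density[self.included]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("tile densities must lie in [0, 1]")

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def included_densities(self) -> np.ndarray:
        return self.density[self.included]


@dataclass(frozen=True)
class DensityIndexes:
    """Per-section (or per-animal) summary: Dm, HDFm and bookkeeping."""

    Dm: float
    HDFm: float
    threshold_class: int
    n_tiles: int


def make_grid(
    image_height_px: int, image_width_px: int, tile_side_px: int, pixel_size_um: float
) -> TileGrid:
    """Tile grid covering the raster; trailing partial tiles are flagged downstream."""
    if image_height_px < 1 or image_width_px < 1:
        raise ValueError("image dimensions must be positive")
    if tile_side_px < 1:
        raise ValueError("tile side must be >= 1 px")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    if tile_side_px > image_height_px and tile_side_px > image_width_px:
        raise ValueError(
            f"tile side {tile_side_px} px exceeds both image dimensions "
            f"({image_height_px}x{image_width_px})"
        )
    n_rows = -(-image_height_px // tile_side_px)
    n_cols = -(-image_width_px // tile_side_px)
    return TileGrid(int(tile_side_px), int(n_rows), int(n_cols), float(pixel_size_um),
                    int(image_height_px), int(image_width_px))


def tile_densities(
    fractions: FractionImage | BinaryMask,
    grid: TileGrid,
    inclusion: BinaryMask,
    min_inclusion: float = 1.0,
) -> TileDensityMap:
    """Per-tile tissue density over the inclusion domain.

    A tile is included iff it is a full (non-partial) tile and the fraction
    of its pixels inside the inclusion domain is at least ``min_inclusion``.
    Density always uses the full tile pixel count as denominator, matching
    the definition of d as tissue area over total tile area.
    """
    if not 0 < min_inclusion <= 1:
        raise ValueError(f"min_inclusion must be in (0, 1], got {min_inclusion}")
    arr = np.asarray(fractions.pixels, dtype=np.float64)
    inc = np.asarray(inclusion.pixels, dtype=np.float64)
    if arr.shape != (grid.image_height_px, grid.image_width_px):
        raise ValueError(f"raster shape {arr.shape} does not match grid")
    if inc.shape != arr.shape:
        raise ValueError(f"inclusion shape {inc.shape} does not match raster shape {arr.shape}")
    if abs(fractions.pixel_size_um - inclusion.pixel_size_um) > 1e-9:
        raise ValueError("fraction and inclusion rasters have different pixel pitch")

    s = grid.tile_side_px
    full_rows = grid.image_height_px // s
    full_cols = grid.image_width_px // s

    density = np.full((grid.n_rows, grid.n_cols), np.nan)
    included = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    if full_rows and full_cols:
        crop = arr[: full_rows * s, : full_cols * s]
        d = crop.reshape(full_rows, s, full_cols, s).sum(axis=(1, 3)) / (s * s)
        inc_crop = inc[: full_rows * s, : full_cols * s]
        cover = inc_crop.reshape(full_rows, s, full_cols, s).sum(axis=(1, 3)) / (s * s)
        ok = cover >= min_inclusion - 1e-12
        included[:full_rows, :full_cols] = ok
        block = density[:full_rows, :full_cols]
        block[ok] = d[ok]
        density[:full_rows, :full_cols] = block
    dmap = TileDensityMap(grid, density, included)
    if dmap.n_included == 0:
        raise ValueError("no included tile: empty section or inclusion domain too small")
    return dmap


def mean_density(dmap: TileDensityMap) -> float:
    """Dm: arithmetic mean of the included tile densities."""
    if dmap.n_included == 0:
        raise ValueError("cannot compute Dm of an empty tile map")
    return float(dmap.included_densities().mean())
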