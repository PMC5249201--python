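"""Pseudocolor 2D reconstruction of a section from its tile density classes.

Each included tile is painted with the color of its density class on a fixed
20-step gradient from light blue (class 1, low density) to yellow (class 20,
high density); excluded tiles take the background color.  The output raster
has the analysis pixel pitch, so reconstructions overlay 1:1 on the reduced
section image.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classification import CLASS_WIDTH, N_CLASSES, classes_of
from .image_io import SectionImage
from .tiling import TileDensityMap

__all__ = ["ColorScale", "default_color_scale", "load_palette", "write_legend", "render_density_map"]

_LIGHT_BLUE = np.array([173, 216, 230], dtype=np.float64)
_YELLOW = np.array([255, 255, 0], dtype=np.float64)


@dataclass(frozen=True)
class ColorScale:
    """20 ordered class colors plus a background color for excluded tiles."""

    colors: np.ndarray
    background: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        arr = np.asarray(self.colors, dtype=np.uint8)
        if arr.shape != (N_CLASSES, 3):
            raise ValueError(f"color scale needs {N_CLASSES} RGB triplets, got shape {arr.shape}")
        object.__setattr__(self, "colors", arr)


def default_color_scale() -> ColorScale:
    """Linear RGB interpolation light blue -> yellow over the 20 classes."""
    t = np.linspace(0.0, 1.0, N_CLASSES)[:, None]
    colors = np.round(_LIGHT_BLUE * (1 - t) + _YELLOW * t).astype(np.uint8)
    return ColorScale(colors)


def load_palette(path: str | Path, background: tuple[int, int, int] = (255, 255, 255)) -> ColorScale:
    """Read a palette file of 20 lines ``class,R,G,B``."""
    colors = np.zeros((N_CLASSES, 3), dtype=np.uint8)
    seen = set()
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().startswith("#"):
                continue
            k = int(row[0])
            if not 1 <= k <= N_CLASSES:
                raise ValueError(f"palette class {k} outside 1..{N_CLASSES}")
            colors[k - 1] = [int(v) for v in row[1:4]]
            seen.add(k)
    if len(seen) != N_CLASSES:
        raise ValueError(f"palette defines {len(seen)} classes, expected {N_CLASSES}")
    return ColorScale(colors, background)


def write_legend(scale: ColorScale, path: str | Path) -> None:
    """CSV legend mapping class -> density interval -> color."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "density_low", "density_high", "R", "G", "B"])
        for k in range(1, N_CLASSES + 1):
            lo, hi = (k - 1) * CLASS_WIDTH, k * CLASS_WIDTH
            r, g, b = (int(v) for v in scale.colors[k - 1])
            w.writerow([k, f"{lo:.2f}", f"{hi:.2f}", r, g, b])


def render_density_map(dmap: TileDensityMap, scale: ColorScale | None = None) -> SectionImage:
    """Paint every included tile with its class color; excluded tiles background."""
    scale = scale or default_color_scale()
    g = dmap.grid
    tile_class = np.zeros((g.n_rows, g.n_cols), dtype=np.int64)  # 0 = background
    tile_class[dmap.included] = classes_of(dmap.density[dmap.included])
    lut = np.vstack([np.asarray(scale.background, dtype=np.uint8), scale.colors])
    tiles_rgb = lut[tile_class]
    out = np.repeat(np.repeat(tiles_rgb, g.tile_side_px, axis=0), g.tile_side_px, axis=1)
    return SectionImage(out, g.pixel_size_um, label="reconstruction")
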