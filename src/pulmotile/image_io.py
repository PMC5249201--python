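"""Section image and mask I/O with physical pixel-size metadata.

Whole lung sections are handled as plain RGB rasters (TIFF or PNG) with a
user-supplied pixel pitch in micrometres per pixel.  Scanners record the
native pitch in vendor metadata that is not standardised, so the pitch is an
explicit argument everywhere rather than something inferred from the file.

The analysis pipeline works at a reduced resolution: a binary tissue mask at
native scan resolution is block-averaged into a per-pixel tissue *fraction*
image (``block_reduce_fraction``), which is what the tiling stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "SectionImage",
    "BinaryMask",
    "FractionImage",
    "MASK_SEMANTICS",
    "read_section",
    "write_section",
    "read_mask",
    "write_mask",
    "block_reduce_fraction",
]

#: Recognised interpretations of a binary mask.
MASK_SEMANTICS = ("tissue", "footprint", "exclusion", "inclusion")


def _check_pitch(pixel_size_um: float) -> float:
    if not np.isfinite(pixel_size_um) or pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be positive, got {pixel_size_um!r}")
    return float(pixel_size_um)


@dataclass
class SectionImage:
    """An RGB raster of a stained lung section.

    Attributes
    ----------
    pixels
        ``(H, W, 3)`` uint8 array, row-major, origin top-left.
    pixel_size_um
        Physical pixel pitch in micrometres per pixel.
    label
        Free-text identifier (animal / section).
    """

    pixels: np.ndarray
    pixel_size_um: float
    label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB array, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        self.pixel_size_um = _check_pitch(self.pixel_size_um)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class BinaryMask:
    """A binary raster annotating a section (same grid, 0/1 values)."""

    pixels: np.ndarray
    pixel_size_um: float
    semantics: str = "tissue"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
        self.pixels = (arr != 0).astype(np.uint8)
        self.pixel_size_um = _check_pitch(self.pixel_size_um)
        if self.semantics not in MASK_SEMANTICS:
            raise ValueError(f"semantics must be one of {MASK_SEMANTICS}, got {self.semantics!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class FractionImage:
    """Per-pixel tissue fraction in [0, 1] at the analysis resolution."""

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"fraction image must be 2-D, got shape {arr.shape}")
        if arr.size and (np.nanmin(arr) < -1e-12 or np.nanmax(arr) > 1 + 1e-12):
            raise ValueError("tissue fractions must lie in [0, 1]")
        self.pixels = np.clip(arr, 0.0, 1.0)
        self.pixel_size_um = _check_pitch(self.pixel_size_um)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_section(path: str | Path, pixel_size_um: float, label: str | None = None) -> SectionImage:
    """Read a TIFF/PNG section image, promoting grayscale to RGB.

    An alpha channel, if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"section image not found: {path}")
    with Image.open(path) as im:
        rgb = im.convert("RGB")
        arr = np.asarray(rgb, dtype=np.uint8)
    return SectionImage(arr, pixel_size_um, label=label if label is not None else path.stem)


def write_section(image: SectionImage, path: str | Path) -> None:
    """Write a section image losslessly (PNG or uncompressed/deflate TIFF)."""
    Image.fromarray(image.pixels, mode="RGB").save(Path(path))


def read_mask(path: str | Path, pixel_size_um: float, semantics: str = "exclusion") -> BinaryMask:
    """Read a single-channel mask raster; any nonzero value maps to 1.

    Multi-channel files are accepted only when all channels agree.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask not found: {path}")
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        if not (arr == arr[..., :1]).all():
            raise ValueError(f"mask {path} has unequal channels; expected single-channel raster")
        arr = arr[..., 0]
    return BinaryMask(arr != 0, pixel_size_um, semantics=semantics)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit raster (0 outside, 255 inside)."""
    Image.fromarray((mask.pixels * 255).astype(np.uint8), mode="L").save(Path(path))


def block_reduce_fraction(mask: BinaryMask | FractionImage, factor: int) -> FractionImage:
    """Block-average a raster by an integer factor into a tissue-fraction image.

    Each output pixel is the mean of its ``factor x factor`` block.  Trailing
    partial blocks are averaged over their actual pixel count, so border
    tissue is not diluted by zero padding.  The output pitch is the input
    pitch times ``factor``.  With the default scan workflow this is the x20
    to x2.5 magnification reduction (factor 8), or factor 4 from a 0.908
    um/px raster to the 3.632 um/px analysis resolution.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"reduction factor must be an integer >= 1, got {factor!r}")
    factor = int(factor)
    arr = np.asarray(mask.pixels, dtype=np.float64)
    h, w = arr.shape
    out_h = -(-h // factor)
    out_w = -(-w // factor)
    pad_h = out_h * factor - h
    pad_w = out_w * factor - w
    padded = np.pad(arr, ((0, pad_h), (0, pad_w)))
    counts = np.pad(np.ones((h, w)), ((0, pad_h), (0, pad_w)))
    sums = padded.reshape(out_h, factor, out_w, factor).sum(axis=(1, 3))
    ns = counts.reshape(out_h, factor, out_w, factor).sum(axis=(1, 3))
    return FractionImage(sums / ns, mask.pixel_size_um * factor)
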