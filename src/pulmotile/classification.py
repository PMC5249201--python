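"""20-class density grading, frequency histograms, HDFm and its calibration.

Tile densities in [0, 1] are graded into 20 classes of width 0.05
(lower-inclusive, class 20 closed at 1.0).  The per-class frequency f_k is
the number of included tiles in class k over the total included tile count.

HDFm, the high tissue density frequency, is the summed frequency from a
threshold class up to class 20.  The threshold is calibrated on the control
group: it is the lowest class from which every class's mean control
frequency stays below a cutoff (1% by default) — in healthy parenchyma,
densities that high occur only as background noise (residual collagen
fibres, erythrocytes), so mass above the threshold in a treated lung is
attributable to fibrotic alteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .tiling import DensityIndexes, TileDensityMap, mean_density

__all__ = [
    "N_CLASSES",
    "CLASS_WIDTH",
    "DensityHistogram",
    "CalibrationResult",
    "CalibrationError",
    "class_of",
    "classes_of",
    "class_midpoints",
    "histogram",
    "calibrate_threshold",
    "hdf",
    "density_indexes",
]

N_CLASSES = 20
CLASS_WIDTH = 0.05


class CalibrationError(RuntimeError):
    """No admissible HDFm threshold exists for the given control group."""


@dataclass
class DensityHistogram:
    """Frequencies f_1..f_20 of tile densities for one section/animal."""

    freq: np.ndarray
    n_tiles: int
    label: str = ""

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=np.float64)
        if self.freq.shape != (N_CLASSES,):
            raise ValueError(f"freq must have {N_CLASSES} entries, got shape {self.freq.shape}")
        if (self.freq < 0).any():
            raise ValueError("frequencies must be non-negative")
        if self.n_tiles > 0 and abs(self.freq.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")


@dataclass(frozen=True)
class CalibrationResult:
    """Control-calibrated HDFm threshold class and the control mean spectrum."""

    threshold_class: int
    cutoff: float
    control_mean_freq: np.ndarray


def classes_of(density: np.ndarray) -> np.ndarray:
    """Vectorised density -> class index (1..20)."""
    d = np.asarray(density, dtype=np.float64)
    if d.size and ((d < 0).any() or (d > 1).any()):
        bad = d[(d < 0) | (d > 1)][0]
        raise ValueError(f"density outside [0, 1]: {bad}")
    # compare against the canonical doubles of the decimal boundaries k/20:
    # dividing by CLASS_WIDTH would misplace exact boundaries (0.95/0.05 = 18.999...)
    edges = np.arange(1, N_CLASSES) / N_CLASSES
    k = np.searchsorted(edges, d, side="right") + 1
    return np.minimum(k.astype(np.int64), N_CLASSES)


def class_of(density: float) -> int:
    """Class k with density in [(k-1)*0.05, k*0.05); class 20 is closed at 1."""
    return int(classes_of(np.asarray([density]))[0])


def class_midpoints() -> np.ndarray:
    """Midpoint density of each class, for linking Dm to its histogram."""
    return (np.arange(N_CLASSES) + 0.5) * CLASS_WIDTH


def histogram(dmap: TileDensityMap, label: str = "") -> DensityHistogram:
    """Frequency distribution of the included tiles' density classes."""
    dens = dmap.included_densities()
    if dens.size == 0:
        raise ValueError("cannot histogram an empty tile map")
    counts = np.bincount(classes_of(dens) - 1, minlength=N_CLASSES)
    return DensityHistogram(counts / dens.size, int(dens.size), label=label)


def pool_histograms(hists: Sequence[DensityHistogram], label: str = "") -> DensityHistogram:
    """Tile-pooled combination of several histograms (e.g. sections of one animal)."""
    if not hists:
        raise ValueError("no histograms to pool")
    n = sum(h.n_tiles for h in hists)
    freq = sum(h.freq * h.n_tiles for h in hists) / n
    return DensityHistogram(freq, n, label=label)


def calibrate_threshold(
    control: Iterable[DensityHistogram],
    cutoff: float = 0.01,
    combine: str = "mean",
) -> CalibrationResult:
    """Lowest class from which every mean control frequency is below the cutoff.

    ``combine="mean"`` averages histograms across control sections/animals
    (each section weighted equally); ``combine="pool"`` weights by tile count.
    The threshold is contiguous to class 20: the scan runs from the top down
    and stops at the first class at or above the cutoff, so isolated quiet
    classes further down do not extend the range.
    """
    hists = list(control)
    if not hists:
        raise ValueError("calibration requires at least one control histogram")
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    if combine == "mean":
        mean_freq = np.mean([h.freq for h in hists], axis=0)
    elif combine == "pool":
        mean_freq = pool_histograms(hists).freq
    else:
        raise ValueError(f"combine must be 'mean' or 'pool', got {combine!r}")

    threshold = None
    for k in range(N_CLASSES, 0, -1):
        if mean_freq[k - 1] >= cutoff:
            break
        threshold = k
    if threshold is None:
        raise CalibrationError(
            f"control mean frequency of class {N_CLASSES} is >= cutoff {cutoff}; "
            "no admissible HDFm threshold"
        )
    return CalibrationResult(threshold, float(cutoff), mean_freq)


def hdf(hist: DensityHistogram, threshold_class: int) -> float:
    """HDFm: summed frequency from ``threshold_class`` through class 20."""
    if not 1 <= threshold_class <= N_CLASSES:
        raise ValueError(f"threshold class must be in 1..{N_CLASSES}, got {threshold_class}")
    return float(hist.freq[threshold_class - 1 :].sum())


def density_indexes(dmap: TileDensityMap, threshold_class: int, label: str = "") -> DensityIndexes:
    """Dm and HDFm of one tile map under an already-calibrated threshold."""
    hist = histogram(dmap, label=label)
    return DensityIndexes(
        Dm=mean_density(dmap),
        HDFm=hdf(hist, threshold_class),
        threshold_class=int(threshold_class),
        n_tiles=hist.n_tiles,
    )
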