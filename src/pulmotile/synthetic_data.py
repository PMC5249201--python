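"""Synthetic lung sections and dose-response studies with known ground truth.

A control mouse lung section at 25% tissue area is emulated as a thin septal
network: a smoothed Gaussian random field defines a cellular pattern, and
tissue is placed within a fixed distance of the field's zero contour so that
walls have uniform thickness and the global tissue fraction hits the target
exactly (the distance quantile is the threshold).  Fibrotic foci are disks of
high per-pixel tissue probability placed by dart throwing until a requested
coverage of the footprint is reached; bronchi/vessels are rings recorded in
an exclusion mask.  The RGB rendering uses Masson-trichrome-like hues
(red-purple septa, blue-shifted fibrotic tissue, near-white background) plus
Gaussian channel noise.

A study bundles one section per animal, with per-animal lesion coverage set
by a monotone dose -> coverage map, and covariates (Ashcroft score, micro-CT
HU peak, Cdyn, FVC, weights) generated as saturating monotone functions of
the achieved lesion coverage plus noise.

All randomness flows from a single seed (per-study, per-animal seeds are
derived via ``numpy.random.SeedSequence``), so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter
from skimage.draw import disk as draw_disk

from .classification import CalibrationResult, DensityHistogram, calibrate_threshold, hdf, histogram
from .image_io import BinaryMask, FractionImage, SectionImage, block_reduce_fraction
from .pipeline import quantify_section
from .segmentation import SegmentationParams
from .tiling import TileDensityMap, make_grid, mean_density, tile_densities

__all__ = [
    "SectionParams",
    "StudyParams",
    "CovariateNoise",
    "SectionBundle",
    "SimulatedStudy",
    "simulate_section",
    "simulate_study",
]

# Masson-trichrome-like rendering hues (R, G, B)
_BG_COLOR = np.array([247.0, 245.0, 248.0])
_SEPTA_COLOR = np.array([150.0, 80.0, 115.0])   # red-purple septa / vessel walls
_LESION_COLOR = np.array([95.0, 105.0, 165.0])  # blue-shifted fibrotic collagen


@dataclass(frozen=True)
class SectionParams:
    """Geometry, texture and lesion parameters of one synthetic section.

    Defaults describe a desk-scale control section: 1.8 x 1.8 mm at 0.908
    um/px native pitch, reduced x4 to the 3.632 um/px analysis resolution,
    25% baseline tissue fraction.  ``alveole_scale_um`` is the characteristic
    spacing of the septal network; at 25% tissue it yields ~3 um walls, thin
    relative to the 7.26 um micro-tile, which reproduces the control-lung
    regime where per-class frequencies above ~class 12 stay below 1%.
    """

    width_um: float = 1800.0
    height_um: float = 1800.0
    native_pitch_um: float = 0.908
    baseline_septal_fraction: float = 0.25
    alveole_scale_um: float = 10.0
    lesion_coverage: float = 0.0
    lesion_density: float = 0.9
    lesion_radius_um: float = 100.0
    lesion_radius_sigma: float = 0.3
    n_vessels: int = 3
    vessel_diameter_um: float = 250.0
    noise_sd: float = 5.0
    seed: int = 0
    reduction_factor: int = 4
    tile_side_px: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.baseline_septal_fraction < 1:
            raise ValueError("baseline_septal_fraction must be in (0, 1)")
        if not 0 <= self.lesion_coverage <= 1:
            raise ValueError("lesion_coverage must be in [0, 1]")
        if not 0 < self.lesion_density <= 1:
            raise ValueError("lesion_density must be in (0, 1]")
        if self.native_pitch_um <= 0 or self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("physical extents and pitch must be positive")


@dataclass(frozen=True)
class CovariateNoise:
    """Noise scales of the simulated external readouts."""

    ashcroft_sd: float = 0.6
    microct_sd: float = 20.0
    cdyn_sd: float = 0.0025
    fvc_sd: float = 0.05
    lung_weight_sd: float = 10.0
    body_weight_sd: float = 0.8


@dataclass(frozen=True)
class StudyParams:
    """Design of a synthetic dose-response study.

    Mirrors a 14-day bleomycin dose-response design: one saline control group
    (n=6) and four dose groups (n=12 each).  ``dose_to_coverage`` maps dose
    (mg/kg) to mean fibrotic coverage of the footprint; the default map puts
    group-mean Dm increments over control in the ~18-42% range.  Per-animal
    coverage scatters around the group mean by a lognormal factor
    (``coverage_dispersion``), emulating biological variability.
    """

    n_control: int = 6
    n_per_dose: int = 12
    doses: Sequence[float] = (0.25, 0.5, 0.75, 1.0)
    dose_to_coverage: Mapping[float, float] = field(
        default_factory=lambda: {0.25: 0.07, 0.5: 0.10, 0.75: 0.13, 1.0: 0.16}
    )
    coverage_dispersion: float = 0.2
    covariate_noise: CovariateNoise = field(default_factory=CovariateNoise)
    section: SectionParams = field(default_factory=SectionParams)
    calibration_cutoff: float = 0.01
    measure: str = "pipeline"  # "pipeline" (segment the RGB image) or "truth" (truth mask)
    master_seed: int = 0
    keep_sections: bool = False

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_per_dose < 1:
            raise ValueError("group sizes must be >= 1")
        if not self.doses:
            raise ValueError("at least one dose group is required")
        covs = [self.dose_to_coverage.get(d) for d in self.doses]
        if any(c is None for c in covs):
            raise ValueError("dose_to_coverage must map every dose")
        if any(b <= a for a, b in zip(covs, covs[1:])):
            raise ValueError("dose_to_coverage must be strictly increasing along doses")
        if self.measure not in ("pipeline", "truth"):
            raise ValueError("measure must be 'pipeline' or 'truth'")


@dataclass
class SectionBundle:
    """One simulated section with its ground truth."""

    image: SectionImage
    exclusion: BinaryMask
    truth: BinaryMask
    truth_densities: TileDensityMap
    footprint: BinaryMask
    achieved_coverage: float
    params: SectionParams


@dataclass
class SimulatedStudy:
    """A simulated study: per-animal table, calibration, and histograms."""

    table: pd.DataFrame
    calibration: CalibrationResult
    histograms: list[DensityHistogram]
    bundles: list[SectionBundle]
    params: StudyParams


def _septal_network(h: int, w: int, footprint: np.ndarray, params: SectionParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Uniform-thickness wall network at the requested tissue fraction."""
    sigma = params.alveole_scale_um / params.native_pitch_um / 3.0
    g = gaussian_filter(rng.standard_normal((h, w)), sigma, mode="reflect")
    pos = g > 0
    edge = np.zeros((h, w), dtype=bool)
    edge[:-1, :] |= pos[:-1, :] != pos[1:, :]
    edge[:, :-1] |= pos[:, :-1] != pos[:, 1:]
    # sub-pixel jitter breaks distance ties so the quantile hits the target fraction
    d = distance_transform_edt(~edge) + rng.uniform(0.0, 0.999, (h, w))
    thr = np.quantile(d[footprint], params.baseline_septal_fraction)
    return (d <= thr) & footprint


def _place_lesions(footprint: np.ndarray, params: SectionParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Dart-thrown disks until the requested footprint coverage is reached."""
    h, w = footprint.shape
    lesions = np.zeros((h, w), dtype=bool)
    target = params.lesion_coverage
    if target <= 0:
        return lesions
    fp_area = footprint.sum()
    mean_r_px = params.lesion_radius_um / params.native_pitch_um
    max_rejections = 5000  # consecutive failed darts => coverage deemed unreachable
    rejections = 0
    while lesions[footprint].sum() / fp_area < target:
        if rejections >= max_rejections:
            raise RuntimeError(
                f"could not reach lesion coverage {target}: "
                f"{max_rejections} consecutive rejected placements"
            )
        r = int(round(np.exp(rng.normal(np.log(mean_r_px), params.lesion_radius_sigma))))
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        # keep focus centres inside parenchyma and out of existing foci (dart throwing)
        if not footprint[cy, cx] or lesions[cy, cx]:
            rejections += 1
            continue
        rejections = 0
        rr, cc = draw_disk((cy, cx), max(r, 2), shape=(h, w))
        lesions[rr, cc] = True
    return lesions


def _place_vessels(footprint: np.ndarray, params: SectionParams,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ring-shaped vessel/bronchus walls plus the exclusion disks covering them."""
    h, w = footprint.shape
    walls = np.zeros((h, w), dtype=bool)
    lumens = np.zeros((h, w), dtype=bool)
    exclusion = np.zeros((h, w), dtype=bool)
    outer_r = params.vessel_diameter_um / 2.0 / params.native_pitch_um
    wall_px = max(2, int(round(0.12 * outer_r)))
    margin_px = int(round(15.0 / params.native_pitch_um))
    for _ in range(params.n_vessels):
        for _try in range(200):
            cy, cx = rng.integers(0, h), rng.integers(0, w)
            if footprint[cy, cx]:
                break
        rr, cc = draw_disk((cy, cx), outer_r, shape=(h, w))
        ring = np.zeros((h, w), dtype=bool)
        ring[rr, cc] = True
        rr, cc = draw_disk((cy, cx), outer_r - wall_px, shape=(h, w))
        inner = np.zeros((h, w), dtype=bool)
        inner[rr, cc] = True
        walls |= ring & ~inner
        lumens |= inner
        rr, cc = draw_disk((cy, cx), outer_r + margin_px, shape=(h, w))
        exclusion[rr, cc] = True
    return walls, lumens, exclusion


def _truth_density_map(truth: np.ndarray, footprint: np.ndarray, exclusion: np.ndarray,
                       params: SectionParams) -> TileDensityMap:
    """Per-tile true densities, using the pipeline's own tiling definition."""
    pitch = params.native_pitch_um
    frac = block_reduce_fraction(BinaryMask(truth, pitch), params.reduction_factor)
    fp_red = block_reduce_fraction(BinaryMask(footprint, pitch), params.reduction_factor)
    ex_red = block_reduce_fraction(BinaryMask(exclusion, pitch), params.reduction_factor)
    inclusion = BinaryMask(
        (fp_red.pixels >= 1.0 - 1e-9) & (ex_red.pixels <= 0),
        frac.pixel_size_um,
        semantics="inclusion",
    )
    grid = make_grid(*frac.shape, params.tile_side_px, frac.pixel_size_um)
    return tile_densities(frac, grid, inclusion, min_inclusion=1.0)


def simulate_section(params: SectionParams) -> SectionBundle:
    """Generate one synthetic section with ground truth; fully seed-determined."""
    rng = np.random.default_rng(params.seed)
    h = int(round(params.height_um / params.native_pitch_um))
    w = int(round(params.width_um / params.native_pitch_um))
    yy, xx = np.ogrid[:h, :w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # elliptical section footprint; the slide margin never falls below 50 um so the
    # footprint-closing morphology cannot bleed to the raster border at any scale
    margin_y = max(0.04 * params.height_um, 50.0) / params.native_pitch_um
    margin_x = max(0.04 * params.width_um, 50.0) / params.native_pitch_um
    ry, rx = h / 2.0 - margin_y, w / 2.0 - margin_x
    if ry <= 0 or rx <= 0:
        raise ValueError("section extent too small for a slide margin")
    footprint = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    septa = _septal_network(h, w, footprint, params, rng)
    lesions = _place_lesions(footprint, params, rng)
    lesion_tissue = lesions & (rng.random((h, w)) < params.lesion_density)
    walls, lumens, exclusion = _place_vessels(footprint, params, rng)

    tissue = np.where(lesions, lesion_tissue, septa)
    tissue = (tissue & ~lumens) | walls
    tissue &= footprint
    achieved = float(lesions[footprint].sum() / footprint.sum())

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = _BG_COLOR
    img[tissue] = _SEPTA_COLOR
    img[lesion_tissue & tissue] = _LESION_COLOR
    img += rng.normal(0.0, params.noise_sd, (h, w, 3))
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth_mask = BinaryMask(tissue, params.native_pitch_um, semantics="tissue")
    excl_mask = BinaryMask(exclusion, params.native_pitch_um, semantics="exclusion")
    fp_mask = BinaryMask(footprint, params.native_pitch_um, semantics="footprint")
    dmap = _truth_density_map(tissue, footprint, exclusion, params)
    return SectionBundle(
        image=SectionImage(pixels, params.native_pitch_um, label=f"sim-{params.seed}"),
        exclusion=excl_mask,
        truth=truth_mask,
        truth_densities=dmap,
        footprint=fp_mask,
        achieved_coverage=achieved,
        params=params,
    )


def _covariates(coverage: np.ndarray, noise: CovariateNoise,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Monotone saturating links from lesion burden to the external readouts.

    The link g(c) = c / (c + 0.10) saturates like the Ashcroft scale ceiling;
    micro-CT HU peak rises with consolidation while compliance (Cdyn), FVC
    and body weight fall, and lung wet weight rises with oedema/fibrosis.
    """
    n = coverage.size
    g = coverage / (coverage + 0.10)
    ashcroft = np.clip(np.round(8.0 * g + rng.normal(0, noise.ashcroft_sd, n)), 0, 8)
    return {
        "ashcroft_score": ashcroft,
        "microct_hu_peak": -480.0 + 500.0 * g + rng.normal(0, noise.microct_sd, n),
        "cdyn": 0.040 * (1.0 - 0.65 * g) + rng.normal(0, noise.cdyn_sd, n),
        "fvc": 1.20 * (1.0 - 0.45 * g) + rng.normal(0, noise.fvc_sd, n),
        "lung_wet_weight": 150.0 * (1.0 + 1.4 * g) + rng.normal(0, noise.lung_weight_sd, n),
        "body_weight": 24.0 - 3.5 * g + rng.normal(0, noise.body_weight_sd, n),
    }


def simulate_study(params: StudyParams | None = None) -> SimulatedStudy:
    """Simulate a full dose-response study and measure Dm/HDFm per animal.

    ``measure="pipeline"`` runs the actual analysis (segmentation of the
    rendered RGB image, reduction, tiling, grading); ``measure="truth"``
    grades the ground-truth density maps directly (fast, noise-free).  The
    HDFm threshold is calibrated from the control group's histograms at the
    study's cutoff.
    """
    params = params or StudyParams()
    groups: list[tuple[str, float, float]] = [("control", 0.0, 0.0)] * params.n_control
    for dose in params.doses:
        groups += [(f"{dose:g}", float(dose), params.dose_to_coverage[dose])] * params.n_per_dose
    n_animals = len(groups)

    ss = np.random.SeedSequence(params.master_seed)
    seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(n_animals + 1)]
    rng_cov = np.random.default_rng(seeds[-1])

    seg_params = SegmentationParams()  # binary_native, Otsu
    records, hists, bundles = [], [], []
    coverages = np.empty(n_animals)
    for i, (group, dose, cov_mean) in enumerate(groups):
        cov = cov_mean
        if cov_mean > 0 and params.coverage_dispersion > 0:
            cov = float(np.clip(
                cov_mean * rng_cov.lognormal(0.0, params.coverage_dispersion), 0.0, 0.95
            ))
        sp = replace(params.section, lesion_coverage=cov, seed=seeds[i])
        bundle = simulate_section(sp)
        if params.measure == "pipeline":
            res = quantify_section(
                bundle.image,
                exclusion=bundle.exclusion,
                seg_params=seg_params,
                reduction_factor=sp.reduction_factor,
                tile_side_px=sp.tile_side_px,
            )
            dmap = res.tile_map
        else:
            dmap = bundle.truth_densities
        hist = histogram(dmap, label=f"animal-{i:02d}")
        hists.append(hist)
        coverages[i] = bundle.achieved_coverage
        records.append({
            "animal_id": f"animal-{i:02d}",
            "group": group,
            "dose": dose,
            "coverage_true": bundle.achieved_coverage,
            "Dm": mean_density(dmap),
            "n_tiles": hist.n_tiles,
        })
        if params.keep_sections:
            bundles.append(bundle)

    control_hists = [h for h, (g, _, _) in zip(hists, groups) if g == "control"]
    calibration = calibrate_threshold(control_hists, cutoff=params.calibration_cutoff)
    table = pd.DataFrame(records)
    table["HDFm"] = [hdf(h, calibration.threshold_class) for h in hists]
    for name, values in _covariates(coverages, params.covariate_noise, rng_cov).items():
        table[name] = values
    cols = ["animal_id", "group", "dose", "coverage_true", "Dm", "HDFm", "n_tiles",
            "ashcroft_score", "microct_hu_peak", "cdyn", "fvc", "lung_wet_weight", "body_weight"]
    return SimulatedStudy(table[cols], calibration, hists, bundles, params)
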