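# pulmotile

Tile-based quantification of pulmonary fibrosis from whole lung section
images.

Histological scoring of lung fibrosis (e.g. the 0–8 Ashcroft scale) is
observer-dependent and usually sampled from a handful of microscopy fields.
`pulmotile` implements an automated, observer-independent alternative for the
bleomycin (BLM) mouse model: it measures **pulmonary tissue density** — the
ratio of tissue area to total area inside each of thousands of small square
**micro-tiles** (~53 µm² at the 3.632 µm/px analysis resolution) laid over
the alveolar parenchyma of an entire Masson-trichrome-stained lung section.

From the per-tile densities *d* ∈ [0, 1] it derives:

- **Dm** — the mean tissue density over all included tiles of a section,
  animal or group;
- a 20-class density histogram (classes of width 0.05), with per-class
  frequencies *f₁…f₂₀*;
- **HDFm** — the high tissue density frequency, Σ *f_k* from a threshold
  class through class 20. The threshold is calibrated on the saline control
  group: it is the lowest class from which every class's mean control
  frequency stays below 1%, so that in healthy parenchyma the mass above it
  is background noise and in treated lungs it is attributable to fibrotic
  foci. HDFm changes over control by several hundred percent where Dm moves
  by tens of percent, which is what makes it the fibrosis-specific index;
- a pseudocolor **2D reconstruction** of the section (light blue = low
  density → yellow = high density) for mapping fibrotic foci;
- a statistics layer: ANOVA + Dunnett (or Kruskal–Wallis + Dunn for ordinal
  readouts) dose-response contrasts against control, and Spearman
  correlations of Dm/HDFm with external readouts (Ashcroft score, micro-CT
  HU peak, dynamic compliance Cdyn, forced vital capacity FVC).

Large bronchi and vessels (diameter > 200 µm) are excluded before tiling,
either via a separate exclusion mask or as pure-white "erased" pixels painted
into the image.

Because no public dataset of such sections exists, the package ships a
synthetic generator (`pulmotile.synthetic_data`) producing lung-like sections
with known ground truth — thin septal networks at a controlled tissue
fraction, dose-dependent fibrotic foci, ring-shaped vessels with exclusion
masks, and covariates monotonically linked to lesion burden — so the entire
pipeline is testable at desk scale.

## Worked example

```python
import pulmotile as pt

# three synthetic saline-control sections, full pipeline
hists = []
for seed in (1, 2, 3):
    bundle = pt.simulate_section(pt.SectionParams(seed=seed))
    res = pt.quantify_section(bundle.image, exclusion=bundle.exclusion,
                              reduction_factor=4, tile_side_px=2)
    print(f"control seed {seed}: n_tiles={res.hist.n_tiles} "
          f"Dm={pt.mean_density(res.tile_map):.4f}")
    hists.append(res.hist)

calib = pt.calibrate_threshold(hists, cutoff=0.01)
print("threshold_class:", calib.threshold_class)

# a fibrotic section (13% of the parenchyma covered by dense foci)
bundle = pt.simulate_section(pt.SectionParams(seed=7, lesion_coverage=0.13))
res = pt.quantify_section(bundle.image, exclusion=bundle.exclusion,
                          reduction_factor=4, tile_side_px=2)
print(f"fibrotic: Dm={pt.mean_density(res.tile_map):.4f} "
      f"HDFm={pt.hdf(res.hist, calib.threshold_class):.4f}")
```

Output:

```
control seed 1: n_tiles=38067 Dm=0.2502
control seed 2: n_tiles=36929 Dm=0.2500
control seed 3: n_tiles=37231 Dm=0.2499
threshold_class: 13
fibrotic: Dm=0.3411 HDFm=0.1474
```

The control sections recover the generator's 25% baseline tissue fraction
almost exactly and calibrate the HDFm threshold at class 13 (densities
≥ 0.60). The fibrotic section raises Dm by ~36% but HDFm by more than
tenfold relative to the control mean (~0.010 → 0.147): the
high-density-frequency index separates fibrosis from healthy parenchyma far
more sharply than the mean density does.

## Command line

```bash
pulmotile simulate  --out sim/ --seed 0            # synthetic study + images
pulmotile quantify  img.tif --pixel-size-um 0.454 --out out/   # histograms, Dm/HDFm, PNG map
pulmotile calibrate out/*_histogram.csv --out calib.json       # control threshold
pulmotile reconstruct out/sec_tiles.csv --out map.png          # pseudocolor rendering
pulmotile stats     study.csv --out stats/                     # dose-response + correlations
```

A YAML config (`--config`) carries pixel pitch, reduction factor, tile side,
segmentation parameters and the calibration cutoff; unknown keys are
rejected. All outputs are deterministic functions of the inputs, the config
and the seed.

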