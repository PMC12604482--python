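# craterscope

Quantitative image analysis of **CRATERs** — pocket-shaped niches on the
tumor–stroma interface where CD8⁺ T cells engage melanoma cells — across the
three imaging settings in which they are measured: 3D confocal stacks of
zebrafish melanoma, 2D RNAscope sections, and multiplexed immunofluorescence
(mIF/CyCIF) of human tumors. It is written for computational biologists and
imaging scientists who need reproducible, unit-calibrated implementations of
these measurements, together with synthetic phantoms that make every stage
testable without any raw microscopy data.

## What it computes

* **3D niche segmentation** (`segmentation3d`). The tumor is segmented by
  Gaussian smoothing, Otsu thresholding and largest-component selection (after
  excluding bright labelled cells found by multiscale Laplacian-of-Gaussian
  blob detection). Craters are extracted with a **black top-hat transform**:
  morphological closing of the binary tumor mask with a 40-voxel cube kernel,
  subtraction of the tumor, then a 2-voxel opening to remove residue,

      craters = open( close(T, K₄₀) \ T , K₂ ),

  which recovers exactly the surface indentations smaller than the kernel.
* **Spatial statistics** (`spatial_stats`). Cells are assigned to
  crater / tumor / outside by exact Euclidean distance transforms; densities
  are reported per region surface area (mm², marching-cubes isosurface);
  crater **coverage** is the crater share of the projected tumor surface and
  the **affinity ratio** is ρ_crater / ρ_tumor. Group comparisons use the
  two-sided Mann-Whitney U test (exact for n ≤ 8 per group) and paired or
  unpaired t tests.
* **RNAscope quantification** (`rnascope`). Maximum-intensity projection;
  a neighbor-count foci filter (keep a focus only if ≥ 2 other foci lie
  within 10 μm); a boundary-corrected Gaussian **KDE** of the retained foci
  whose integral equals the foci count; cell calling as KDE local maxima;
  tumor segmentation with a 15 μm edge band; and per-cell transcript counts
  with percent-positive summaries per zone.
* **Attrition surfaces** (`attrition`). For fragmented tumors, a bivariate
  polynomial z = P(x, y) is fitted to fragment centroids; the degree (2–10)
  is chosen by 5-fold cross-validated RMSE with a one-standard-error
  tie-break; fragments are projected onto the surface and **attrition** is
  the percent of the surface domain left uncovered.
* **Human mIF pipeline** (`mif`). 99th-percentile channel normalization,
  rolling-ball background subtraction, per-cell mean intensities from a
  provided cell label mask, deterministic marker gating, tumor / margin /
  perivascular region logic, a **rule-based crater classifier** (boundary
  location, 20–50 μm size, ≤ 2 collagen fibers, low nuclear density, no
  CD31/CD105 vessels, no αSMA), and **linear density** — craters per cm of
  perivascular-melanocytic boundary (PMB).
* **Annotator concordance** (`concordance`). Instance matching at Jaccard
  index > 0.4, TP/FP/FN, precision, recall, F1 and the mean F1 across
  annotator pairs.
* **Synthetic phantoms** (`synthetic`). Seed-deterministic generators for
  every input above, each with an analytic ground-truth manifest.

## Worked example

```python
from craterscope import synthetic as syn, segmentation3d as s3, spatial_stats as ss
from craterscope.core_io import RegionMaskSet

spec = syn.PhantomSpec(seed=1, pocket_count=4, shape=(48, 160, 160),
                       pocket_diameter_mean=30, pocket_diameter_sd=4,
                       density_ratio=4.0)
img, truth_masks, manifest = syn.make_tumor_phantom(spec)

tumor = s3.segment_tumor(img, "tumor")
seg = s3.segment_craters(tumor)
masks = RegionMaskSet(tumor=tumor, craters=seg.labels, spacing=img.spacing)
cells = ss.assign_cell_regions(manifest.cells.copy(), masks)
rep = ss.region_densities(cells, masks)
print(f"craters: {seg.n_craters}")
print(f"coverage: {rep.coverage_pct:.2f}% (planted {manifest.coverage_pct:.2f}%)")
print(f"affinity ratio: {rep.affinity_ratio:.2f} (planted {spec.density_ratio})")
```

prints

```
craters: 4
coverage: 10.53% (planted 10.04%)
affinity ratio: 3.63 (planted 4.0)
```

i.e. the black top-hat recovers all four planted pockets, the crater share of
the tumor surface is recovered to half a percentage point, and the planted
4:1 crater:tumor CD8 density ratio is recovered within sampling error.

A command-line interface mirrors the library:
`craters simulate | segment3d | stats | rnascope | attrition | mif |
concordance` (see `craters --help`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs every pipeline from scratch on seeded phantoms — 3D segmentation with
coverage/affinity recovery, the RNAscope chain, the attrition fit, the
concordance worked example and the full mIF pipeline — logging each recovered
quantity next to its planted truth, and writes the result JSON to `--out`.

## Further reading

`docs/methods.md` describes the models, parameter choices, numerical
conventions, what the phantoms do and do not emulate, and known limitations.
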