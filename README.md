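# gliaquant

High-content quantification of microglia in mixed glial cultures:
automated counting, proliferation and phagocytosis percentages,
marker-intensity scoring, and rod-like-morphology measurement from
multi-channel fluorescence fields — together with a synthetic image
generator that produces such fields with exact per-cell ground truth.

## The problem

Primary adult human microglia change phenotype when treated with
macrophage colony-stimulating factor (M-CSF): cultures gain microglia,
a larger fraction of them divide (BrdU/Ki67) and phagocytose amyloid-β
cargo, nuclear factors (PU.1, C/EBPβ) and receptors (CSF-1R, IGF-1R,
DAP12) brighten, MHC-II (HLA-DP, DQ, DR) expression drops, and the cells
elongate into "rod-like" bipolar shapes — while the total nucleus count
stays flat.  Quantifying those readouts by eye is slow and subjective;
this package implements the automated image-analysis pipeline as reusable,
tested code, and pairs it with a simulator so every measurement can be
validated against known truth.

## The measurements

Per segmented cell (area *A* px², perimeter *P* px):

- **Shape Factor** `SF = 4πA / P²` — circularity; 1 for a circle,
  → 0 for elongated cells.  *P* is a subpixel contour-length estimate
  (Crofton and raw boundary-walk estimators available).
- **Elliptical Form Factor** `EFF = length / breadth` ≥ 1 — elongation;
  by default the axis ratio of the moment-equivalent ellipse, with a
  max-Feret variant behind a flag.

Cells are isolated by automatic (Otsu) thresholding of the
illumination-flattened CD45-like surface channel; nuclei by threshold +
distance-transform watershed of the Hoechst-like channel; each nucleus is
assigned to the cell it overlaps most.  A cell is *positive* for a marker
when its background-normalized compartment intensity exceeds *k* = 3
robust SDs above background, and *phagocytic* when cargo-positive pixels
cover ≥ 2% of its footprint.  Per-field results are averaged per donor
case; conditions are compared as mean ± SEM across cases with two-sided
Welch t-tests at α = 0.05 (paired mode available).

## Worked example

```sh
python analysis/01_simulate_experiment.py   # 6 cases x 4 fields x 2 conditions
python analysis/02_measure_fields.py
python analysis/03_condition_statistics.py
python analysis/04_validate_recovery.py
```

The measurement step prints per-condition field means:

```
           total_nuclei  cd45_cells  mean_eff  mean_shape_factor
condition
mcsf             97.292      39.125     2.487              0.765
vehicle         101.792      25.542     1.603              0.914
```

i.e. M-CSF fields hold ~1.5× more microglia at an unchanged nucleus count,
and the cells are more elongated (EFF 2.49 vs 1.60) and less round
(SF 0.77 vs 0.91).  The statistics step then reports, per metric, case
means ± SEM and the Welch test, e.g.

```
proliferation_fraction: vehicle 0.06413 ± 0.0076 (n=6) vs mcsf 0.1663 ± 0.018 (n=6); t=-5.211, df=6.74, p=0.00139 *
hla_fraction:           vehicle 0.5519 ± 0.056  (n=6) vs mcsf 0.3101 ± 0.049 (n=6); t=3.249,  df=9.87, p=0.00889 *
```

and the validation step confirms recovery against ground truth
(count errors ≤ 0.2%, all cell IoU ≥ 0.8, EFF error ≈ 0.2%).

The same pipeline is scriptable through the `gliaquant` CLI
(`simulate`, `measure`, `report`, `validate`) with `--config`, `--seed`,
`--out` and `--log-level` flags.

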