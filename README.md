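# ccsquant

Quantification of clathrin-coated structures (CCSs) — pits and plaques —
from single-molecule localization microscopy (SMLM/GSDIM) data and TIRF
time-lapse movies.

Clathrin assembles two kinds of structures on the plasma membrane:
small, curved **clathrin-coated pits** (~100–200 nm, the precursors of
endocytic vesicles) and large, flat **clathrin plaques** (>200 nm in
every direction, near-background density lattices). Conventional light
microscopy cannot tell them apart; super-resolution localization data
can, via explicit morphometric rules. This package implements that
classification and the downstream quantification used to study plaque
biology: per-cell CCS metrics in a peripheral ROI, coordinate-based
colocalization between two channels, tracking of CCS persistence in
live-cell TIRF movies, receptor enrichment at CCSs, EPI/TIRF
internalization ratios, and membrane-translocation biosensor readouts.
It is written for microscopists and image analysts who have localization
tables (e.g. ThunderSTORM exports) or TIRF movie stacks and want
reproducible, scriptable numbers instead of manual scoring.

## The rules and statistics at the core

A localization table is rendered at 20 nm/pixel (normalized-Gaussian or
histogram mode). After segmentation, a cluster with equivalent diameter
d = 2·√(A/π) and brightness ratio ρ (localizations per pixel over the
scattered single-molecule background) is classified

* **pit** iff d ∈ [100, 200] nm, AND (circularity 4πA/P² ≥ 0.7 OR the
  cluster is donut-shaped, i.e. has a hole), AND ρ ≥ 2;
* **plaque** iff the minimum Feret diameter exceeds 200 nm AND ρ < 2;
* otherwise unclassified. Pits embedded in plaques are split out by
  re-thresholding the plaque footprint at 2× background.

Per cell, within a 3 µm-wide peripheral band of the outline:
pit density = (pits with centroid in band) / band area, and
plaque-covered area fraction = (plaque area ∩ band) / band area.

Colocalization uses the coordinate-based colocalization (CBC) score: for
each localization of channel A, the area-normalized neighbour-count
curves D(r_k) = N(r_k)·r_max²/(N(r_max)·r_k²) of both channels are
Spearman-rank-correlated and damped by exp(−d/r_max), d the distance to
the nearest B localization (defaults r_max = 300 nm, 10 radii).
Chromatic aberration is corrected by a least-squares 2D affine fitted to
matched bead coordinates.

Movies are smoothed in time, bleach-corrected by rescaling each frame so
the Otsu signal-minus-background contrast matches frame 0, masked by a
bilateral filter plus iterative local (isodata) thresholding, and
tracked with a Simple LAP linker (squared-displacement assignment,
300 nm/frame maximum for CCSs, 15 µm/frame for nuclei, no gap closing).

Because no reference microscopy dataset ships with the package, the
`synthetic` module generates scenes, bead fields and movies with known
ground truth (structure geometries, lifetimes, recruitment folds), and
the entire test suite validates every stage against that truth.

## Worked example

Simulate a scene with 50 pits and 5 plaques, then classify it:

```sh
$ cat demo.yaml
simulation:
  seed: 42
  n_pits: 50
  n_plaques: 5
$ ccs simulate --config demo.yaml --out demo_bundle
{"n_structures_scene": 55, "n_localizations": 21219, "n_tracks": 20}
$ ccs classify --locs demo_bundle/scene.csv --out demo_results
{"n_pits": 49, "pit_density_per_um2": 0.2143347050754458, "n_plaques": 5,
 "plaque_area_fraction": 0.011862769799277736, "roi_area_um2": 228.61440000000002,
 "background_brightness": 1.0277507302823758}
```

49 of the 50 planted pits are recovered and all 5 plaques are found;
`plaque_area_fraction` says 1.19% of the analyzed area is covered by
plaques, and the background brightness (~1.03 localizations per occupied
20-nm pixel) is the denominator of every brightness ratio.
`demo_results/objects.csv` holds one row per segmented object with all
morphometrics (area, circularity, equivalent diameter, Feret diameters,
hole count, brightness ratio) and the assigned class.

Other sub-commands: `ccs coloc` (CBC with optional bead registration),
`ccs track`, `ccs enrich`, `ccs kymo`, `ccs sensor`, `ccs migrate`, and
`ccs run` for config-driven end-to-end runs. All sub-commands exit 0 on
success, 2 on input/format errors, 3 on parameter errors, 4 on
computation errors.

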