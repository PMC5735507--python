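# wellpat

Quantification of cell patterning on microwell arrays, with a synthetic
ground-truth simulator.

## The problem

Microwell arrays — thousands of shallow cylindrical wells (here 80 µm
inner / 120 µm outer diameter, 20 µm deep, hexagonally packed in a
9 × 9 mm footprint of 2980 wells) — isolate single cells or small groups
for downstream single-cell assays. Seeding cells through a
laser-porated polymer stencil whose pores align with well centres
confines cells to well interiors; peeling the stencil after adhesion
leaves a patterned array. Evaluating how well this works is an image
analysis problem: given a phase-contrast mosaic of the well rings and
fluorescence mosaics of all nuclei (blue) and dead/dying nuclei (red),
measure

- **localization efficiency** — the percentage of cells inside well
  interiors relative to all cells, `100 · n_interior / n_total`;
- **viability** — `100 · (1 − n_dead / n_total)` over cells in wells;
- **well occupancy** — the fraction of wells holding 0, 1, 2, 3 or 4+
  cells, and in particular the **single-cell occupancy**;
- **fold increase** — the mean stencil/no-stencil efficiency ratio
  across seeding densities;

with two-sample significance tests (pooled-variance Student's *t* and
Mann–Whitney *U*) between seeding arms.

The analysis protocol mirrors the original workflow: wells are located
by normalized 2-D cross-correlation (ZNCC) of an annulus template
against the phase channel; 400 wells are sampled uniformly at random
from the ~2980 detections; each nucleus is assigned to the nearest
sampled well by Euclidean centroid distance and called *interior* when
that distance is at most the 40 µm inner radius (the annular lip and
everything beyond count as *exterior*).

Because no raw images from such experiments are publicly deposited,
the package ships a first-class synthetic-scene generator
(`wellpat.scene`) with exact ground truth — hexagonal array geometry,
per-well occupancy models, interior/lip/exterior cell placement, dead
fractions, Gaussian-spot rendering with shot and read noise — so every
pipeline stage is testable and the published summary statistics can be
reproduced as a parameter-recovery exercise.

## Worked example

```python
import wellpat as wp
from wellpat.pipeline import run_scene, DetectionConfig
from wellpat.nuclei import NucleusParams
from wellpat.scene import Optics

layout = wp.build_layout(footprint_um=(4800.0, 1800.0))  # 672-well array
condition = wp.condition_defaults("MDA-MB-231", 100, stencil=True, seed=7)
result = run_scene(layout, condition, DetectionConfig(), NucleusParams(),
                   Optics(), seed=7)

s = result.summary
print(f"condition:                {s.condition}")
print(f"wells detected/sampled:   {result.detections.n_wells}/{s.n_wells_sampled}")
print(f"cells in sampled region:  {s.n_cells_total} ({s.n_cells_interior} interior)")
print(f"localization efficiency:  {s.localization_efficiency_pct:.1f} %")
print(f"viability (interior):     {s.viability_pct:.1f} %")
print(f"single-cell occupancy:    {s.single_cell_occupancy_pct:.1f} %")
occ = s.occupancy_percentages()
print("occupancy 0/1/2/3/4+ (%): " + "/".join(f"{occ[k]:.1f}" for k in sorted(occ)))
```

prints

```
condition:                MDA-MB-231-100K-stencil
wells detected/sampled:   672/400
cells in sampled region:  534 (490 interior)
localization efficiency:  91.8 %
viability (interior):     96.3 %
single-cell occupancy:    33.8 %
occupancy 0/1/2/3/4+ (%): 30.2/33.8/22.5/10.2/3.2
```

The scene was generated with an interior probability of 0.92 and a 3%
dead fraction for this cell line; the pipeline — template matching on
the phase channel, 400-well sampling, nuclei detection on both
fluorescence channels, nearest-well assignment — recovers 91.8%
efficiency and 96.3% viability from the rendered images alone.
Single-cell occupancy fluctuates scene to scene around the generating
31% (binomial noise over 400 wells).

## Command line

```bash
wellpat full --seed 1 -o run_dir          # full bundled study design
wellpat simulate -c config.yaml           # scenes only
wellpat detect-wells run_dir/scenes/...   # per-scene stages
wellpat localize   run_dir/scenes/...
wellpat quantify   run_dir/scenes/...
wellpat report run_dir                    # print the summary table
```

`full` writes `summary.csv` (one row per condition × replicate),
`comparisons.csv` (paired stencil vs. open-substrate *t* and *U* tests)
and `manifest.json` (config hash, seeds, every output file). Identical
configs reproduce identical summaries byte for byte.

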