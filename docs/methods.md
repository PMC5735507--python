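# Methods

This note documents the models behind `wellpat`: what the synthetic
scenes emulate, how each analysis stage works, the defaults and why,
and what passing the test suite does and does not demonstrate.

## Array geometry

Wells are laid out on a hexagonal lattice (row spacing
`pitch·√3/2`, odd rows offset by `pitch/2`), clipped to a rectangular
footprint with a clearance of one outer radius from every edge.
Defaults: inner radius 40 µm, outer radius 60 µm, depth 20 µm
(provenance only — rendering is 2-D), pitch 120 µm, footprint
9 × 9 mm. The reference substrate holds exactly 2980 wells, fewer than
a dense hexagonal fill of that footprint at this pitch (~6400), and
the true arrangement is not documented; `build_layout` therefore
supports `target_well_count`, keeping the first N lattice points in
row-major order. This gives a definite, reproducible 2980-well array
without inventing an unknown arrangement; any statistic computed per
well or per cell is unaffected by which subset is kept.

Coordinates are physical micrometres, origin at the footprint's
top-left corner, x rightward, y downward. Pixel `(i, j)` covers the
half-open square `[j·s, (j+1)·s) × [i·s, (i+1)·s)`; its centre is at
`((j+0.5)·s, (i+0.5)·s)`. The default pixel scale s = 1.625 µm/px is
the 6.5 µm sensor pitch of the sCMOS camera class used for such
imaging divided by the 4× magnification.

## Seeding conditions

A `SeedingCondition` couples a per-well loading model with an
interior probability and a dead fraction.

**Loading.** Stencil arms use explicit occupancy distributions over
{0, 1, 2, 3, 4+} cells per well: the stencil pores act as a sieve, so
counts saturate rather than growing linearly with density. Open
(no-stencil) arms use Poisson loading with mean

    λ = density · volume / reservoir_area · pitch²·√3/2 ,

i.e. the seeded cell number (600 µL at the nominal concentration)
spread uniformly over the 236 mm² reservoir, times the hexagonal
unit-cell area; at 100 K cells/mL this gives λ ≈ 3.17.

**Placement.** Each cell is interior with probability `p_interior`
(uniform over the inner disk); otherwise exterior — half on the
annular lip (40–60 µm), half on the flat substrate within one pitch of
the well centre. The lip/flat split is a declared assumption: both
sub-populations count as "exterior" in every statistic, so the split
is quantification-neutral. Exterior positions are rejection-sampled so
that no exterior cell falls inside any well's inner radius (otherwise
the ground-truth label and the distance-based call could disagree by
construction) and all cells stay inside the footprint. Dead/dying
labels are i.i.d. Bernoulli(0.03 by default).

**Calibrated defaults.** Condition defaults per cell line were set
once, from the published summary statistics, and then frozen:

| cell line  | p_interior (stencil) | p_interior (open) | P(1) stencil |
|------------|----------------------|-------------------|--------------|
| K562       | 0.97                 | — (non-adherent)  | 0.17 at all densities |
| HME1       | 0.82                 | 0.82/3 ≈ 0.273    | 0.22–0.28, peak near 50 K/mL |
| MDA-MB-231 | 0.92                 | 0.92/4 = 0.23     | 0.20/0.26 below, 0.31 at ≥100 K/mL |

The remaining occupancy mass is a plausible monotone-in-density spread
over the other bins; only P(1) (and p_interior) carry published
information. The K562 open arm is modelled as no-data: a handful of
residual cells across the whole array, reflecting a suspension line
that washes off an open substrate.

## Rendering

Four channels share one canvas per scene: a phase-contrast-like
channel with each well drawn as a dark annulus (smooth error-function
edges of 1 µm width) on a mid-grey background; an all-nuclei channel
with every cell as a Gaussian spot; a dead-nuclei channel with only
dead cells; and a live-cytoplasm channel (wider, dimmer spots from
live cells) that is rendered for completeness but never quantified.
The nucleus spot sigma combines the nominal 7 µm nuclear radius with a
2 µm PSF width in quadrature (σ ≈ 4.0 µm): a stained nucleus through a
low-NA 4× objective is adequately a Gaussian blob. Intensities are
fractions of the 16-bit dynamic range (background 5%, nucleus
amplitude 30%, phase background 50%, ring −25%).

Noise is applied last from a seeded generator: shot noise in the
high-count Gaussian approximation N(0, √I) plus Gaussian read noise at
2% of the dynamic range, folded into a single draw
N(0, √(I + r²)). The read-noise default makes detection non-trivial
but leaves both wells and nuclei recoverable at >99%.

Not emulated (deliberately): phase-contrast halo physics, optical
aberrations and field-dependent illumination, 3-D well depth and
defocus, cell clumping as an explicit aggregation process (it enters
only through the occupancy distributions), field-by-field acquisition
and stitching (mosaics are emitted pre-stitched), and nucleus shape
variability. Passing tests therefore demonstrate that the *pipeline*
is correct and unbiased under a faithful geometric model with
realistic noise — not that the detectors would be robust to every
artefact of real microscopy.

## Well detection

The matching template is one noise-free annulus rendered with the
phase-channel conventions (side `2·⌈r_out/s⌉+1` px, centre at the
middle pixel). The score is zero-normalized cross-correlation,

    ncc(i,j) = Σ[(f − f̄_w)(t − t̄)] / √(Σ(f − f̄_w)² · Σ(t − t̄)²),

window mean taken over the template support, values in [−1, 1],
zero-variance windows scored 0 by convention. The fast path computes
the numerator by FFT convolution (float32 above 4 Mpx; ~1e−6 relative
error, far below any threshold) and the window sums by summed-area
tables; a literal double-loop implementation with identical
conventions is kept for verification, and both are tested against an
independent oracle and against scikit-image's `match_template`. The
image is median-padded by half a template so every centre pixel is
scored.

Peaks at or above the NCC threshold (default 0.5 — far above the
background correlation level of noisy flat regions, tolerant of spot
occlusion) are accepted greedily in descending score with non-maximum
suppression at 0.8 × pitch (96 µm: below the pitch so true neighbours
survive, above the outer diameter so side-lobes do not). Score ties
break by row-major position, for determinism. Each accepted peak is
refined to sub-pixel by a separable quadratic fit over its 3 × 3
neighbourhood (clamped to ±0.5 px; skipped at the map border). On a
noise-free full-array render this recovers all 2980 wells with a
maximum centre error of ~0.22 px.

The 400-well analysis subset is drawn uniformly without replacement
with its own seed.

## Nuclei detection and localization

Per channel: Gaussian blur (σ = half the nominal nucleus radius) →
background subtraction (median) → global Otsu threshold → 8-connected
components → splitting → area filter (0.25–4 × the nominal area πr²)
→ intensity-weighted centroids. Two robustness choices on top of the
basic operators:

- the threshold is floored at 4 robust standard deviations of the
  background (MAD-based); with very sparse signal, plain Otsu can
  collapse into the noise mode and flood the mask. Background and MAD
  are estimated on a 4× strided subsample (the image is overwhelmingly
  background).
- touching nuclei: components larger than 1.6 × the lower-quartile
  component area are split by watershed seeded at local intensity
  maxima; pairs so close that their blurred spots fuse into a single
  maximum leave only an area signature and are split geometrically
  into `round(area/typical)` parts by deterministic k-means along the
  component's principal axis. Without the second mechanism, merged
  interior pairs inflate single-cell occupancy by ~3 percentage
  points; with it, detection recall on dense scenes is ~99% and
  centroid RMSE ~0.3 px.

An exactly constant image raises a degenerate-threshold error; a noisy
blank yields zero detections.

Each nucleus is assigned to the nearest well by Euclidean
centroid-to-centroid distance — among the 400 sampled wells, mirroring
the published protocol — with exact-distance ties broken toward the
lowest well id. *Interior* means distance ≤ inner radius, boundary
inclusive (the boundary case is a convention; it affects a vanishing
fraction of cells). Lip and beyond are *exterior*.

**Denominator.** Assigning *every* nucleus in a mosaic among only 400
of ~2980 wells would drag ~87% of cells — those belonging to unsampled
wells — into the exterior tally and make the efficiency statistic
meaningless. The sampling protocol reads as "400 wells with their
surrounding area": the assignment table therefore carries an
`in_sampled_set` flag — true when the nucleus's nearest well over the
*full* detection set is one of the sampled wells — and all summary
statistics restrict to flagged rows. Interior cells always satisfy
this (the inner radius is below half the pitch); exterior cells cross
sampled-region boundaries in both directions symmetrically, so the
restriction is unbiased. The per-nucleus distance is kept as a QC
column. The efficiency denominator uses all blue-channel nuclei
(dead cells included); the red channel is reserved for viability.

## Statistics

- localization efficiency = 100 · interior / total (all-nuclei
  channel, sampled region); undefined (error), not 0, for zero nuclei.
- viability = 100 · (1 − dead/total), restricted by default to well
  interiors; viability + dead-percentage = 100 on the same set.
- occupancy: interior-nucleus counts per sampled well binned to
  {0, 1, 2, 3, 4+} (wells with zero nuclei counted; the open top bin is
  a reporting convention); single-cell occupancy = the 1-bin as a
  percentage of sampled wells.
- fold increase = mean over the matched density grid of the
  stencil/control efficiency ratio; an exact zero control efficiency
  is an undefined-ratio error (the non-adherent-line case).
- Student's t: two-sample pooled-variance by the textbook formula
  (Welch available behind a flag); two-sided p from t(n₁+n₂−2).
- Mann–Whitney U: midranks, U = min(U₁, U₂); exact two-sided p by
  full enumeration of the C(n₁+n₂, n₁) rank assignments when
  n₁+n₂ ≤ 12 with no ties, otherwise the normal approximation with
  midrank tie correction and continuity correction 0.5. The
  approximation tracks the exact p to ~0.015 (worst case) at
  n₁ = n₂ = 6. Significance threshold 0.05, two-sided.

The replicate unit for the paired tests is the per-scene summary
statistic, matching pooling over independent experiments.

## Pipeline and reproducibility

One master seed drives everything; each condition × replicate × stage
draws a named substream (CRC32-hashed key path through
`numpy.random.SeedSequence`), so stages are statistically independent
and reruns are bit-reproducible — the end-to-end determinism test
compares summary CSVs byte for byte. `run_full` writes per-scene
summaries, paired stencil/open t and U tests per cell line × density,
and a manifest (config hash, software version, complete file listing).
Scenes serialize as one 16-bit TIFF per channel, the ground-truth
table as CSV (`%.17g` floats, read back with round-trip parsing, so
write→read is lossless), and a JSON sidecar with layout, condition and
seeds.

## Problem sizes in the reproduction battery

`scripts/acceptance.py` (and the mirrored study-level tests) uses the
full 2980-well array for the three 100 K cells/mL stencil efficiency
estimates (≥2000 cells per scene) and for the clean-render detection
count, and a reduced 672-well array (4800 × 1800 µm, identical pitch,
radii and pixel scale) for the density series behind viability,
occupancy and fold-increase — the 400-well sampling protocol remains
valid there, and every statistic is a per-cell or per-well proportion,
so array size affects only standard errors, not expectations. Three
replicates per condition, seeds derived from the master seed.

## Known limitations

- Tightly overlapping nuclei (closer than ~1.5 spot sigma) are
  resolved by the area-based split, which assumes roughly equal-sized
  nuclei; strongly size-heterogeneous populations would defeat it.
- Detection of cells on well lips relies on centroids; a real analyst
  might call a nucleus straddling the lip differently (any-overlap vs
  centroid is unstated in the source protocol; centroid is adopted).
- The occupancy distributions beyond the single-cell bin are
  plausibility choices, not measurements; only P(1) and the interior
  probabilities are calibrated to published values.
- The Poisson open-substrate loading ignores cell–cell exclusion and
  aggregation, adequate at the densities simulated.
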