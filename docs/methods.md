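# Methods

This note documents the models, parameter choices, numerical conventions,
and limitations behind `wellquant`.

## Problem setting

A lab-on-chip microwell device holds suspension cells (Jurkat-like T
cells, ~15 µm across) in circular wells imaged in brightfield at regular
intervals during perfusion culture. The measurand at each time point is
the **cell-covered area** inside the well, which is converted to an
estimated cell number and aggregated across wells into growth curves. Two
well geometries require different area→count conversions, and the imaging
conditions (label-free, bubbles, chip material in frame) shape the
segmentation design.

## Well geometry and ROI detection

`WellSpec` describes a well as either `flat` (cylindrical, floor diameter
known) or `u_bottom` (the lower half of a prolate spheroid with equatorial
top radius R and polar depth c). Presets: `ibidi` — flat, bottom Ø
800 µm, 21 wells in 3 channels, 45 µL/channel; `pdms` — U-bottom,
R = 750 µm, c = 248 µm, ~150 wells, one 200 µL cistern.

ROI detection runs Canny edges (σ = 2 on the normalized image) into a
circular Hough accumulator over radii within ±`tolerance_frac` (default
20%) of the expected radius. The best accumulator peak wins; exact ties
break to the smallest (y, x, radius) lexicographically, so detection is
deterministic. A peak below `score_threshold` (0.25, the fraction of the
perimeter supported by edges) raises a "well not found" error carrying the
best score. Pixel convention everywhere: 0-based, x = column, y = row; a
pixel belongs to a circle iff its *centre* is inside. `mask_outside`
replaces the exterior with the image's 5th-percentile intensity by
default, imitating dark chip material without hard-coding a brightness.

The pixel scale defaults to 1.6 µm/px, a typical 4× widefield value; it
is a stand-in, not a measured calibration, and every entry point accepts
an explicit scale.

## Synthetic data

The generator emulates the *statistical* structure the analysis relies
on, not the optics:

- **Appearance** — cells are drawn as a bright core (0.85 of full scale)
  inside a dark rim (0.20) on a mid-gray well floor (0.55), with σ = 0.02
  additive Gaussian sensor noise; this reproduces the
  high-local-contrast signature that texture segmentation exploits in
  brightfield. Bubbles are larger disks (default radius 40–90 µm) with a
  near-white interior and a dark shadow ring; they occlude cells under
  them and are never part of the ground-truth cell mask.
- **Placement** — flat wells scatter cells uniformly over the floor;
  U-bottom wells draw centres from a truncated 2-D Gaussian with
  σ = 0.25 R, concentrating colonies centrally as gravity does in a
  curved well. Non-overlapping placement uses bounded rejection sampling
  and raises "well overfull" on failure.
- **Growth** — counts follow n₀·2^(t/T_d) with multiplicative log-normal
  noise of a given CV. Drying is modeled as a one-time collapse: from the
  onset time the count drops to `drying_floor_frac` (default 0.2) of its
  value at onset and growth ceases, with no recovery.
- **Seeding** — per-well initial counts are truncated-normal draws with
  CV 5% for channel-based seeding and 25% for per-well seeding. These
  CVs are calibration knobs chosen to make the two protocols clearly
  distinguishable; no measured dispersion was available to anchor them.

Ground truth carries the exact rendered mask, the true count, the covered
area (mask pixels × pixel area), and the true ROI. Because cell disks are
rasterized by the pixel-centre rule with continuous centres, the expected
pixel count of a disk equals its analytic area; summed over tens of cells
the rasterization error is well under the 3% the counting round-trip
budget allows.

What passing tests on this generator do **not** show: robustness to
focus drift, uneven illumination, debris, cell morphology change, or
motion between frames — real-image performance requires retraining and
revalidation on real annotations. The synthetic segmentation task is
deliberately easier than real brightfield; validation IoUs near 1.0 here
say the pipeline plumbing is correct, not that the classifier generalizes
to a microscope.

## Segmentation

Two backends sit behind one `SegModel` surface.

The **classical baseline** is training-free and deterministic: local
standard deviation in a window of about one cell radius, thresholded by
Otsu *within the ROI core* (the ROI shrunk by one window width, because
the well rim itself is a high-texture closed ring that hole-filling would
otherwise flood), hole-filled so cell halos become solid disks, eroded by
half a window to undo the filter's dilation, and cleaned of objects
smaller than ~20% of a cell's area. The Otsu threshold is floored at 0.05
(unit intensity scale) so pure sensor noise on an empty frame cannot be
split into a phantom cell class.

The **trainable segmenter** is a per-pixel random forest (40 trees, depth
≤ 14) over an 11-feature bank: intensity, Gaussian smoothings at
σ ∈ {1, 2, 4, 8}, gradient magnitude at σ ∈ {1, 2}, a Laplacian at σ = 2,
and local standard deviation in 3/7/15-pixel windows. Features are scaled
by the image dtype's full range rather than per-image min/max, so an
empty or sparse frame keeps the same absolute contrast as a busy one
(per-image stretching was observed to turn the well rim of an empty frame
into false positives). Training subsamples up to 4000 pixels per image,
class-balanced, and is fully seeded; the manifest records the dataset
fingerprint (SHA-256 over pixels and masks), seed, and sampling settings.
Prediction thresholds the forest's per-pixel score at 0.5 and zeroes
everything outside the ROI — no morphological post-processing, so scores
remain interpretable. The multi-scale features are what let the model
separate bubbles (large, smooth, very bright) from cells at similar edge
contrast.

Evaluation: IoU = |A∩B|/|A∪B| with empty/empty defined as 1.0 (perfect
agreement; the definition is otherwise 0/0). IoU is reported per image
and averaged; pooled-pixel IoU would weight large wells more and is not
used. Model-vs-model comparison uses the per-image *absolute* difference
in percent well coverage, reporting mean and sample SD (0 for n = 1).

## Area → count conversion

The single-cell model is a sphere of diameter 15 µm: projected area
π d²/4 = 176.71 µm², volume π d³/6 = 1767.15 µm³. (A 15 µm *radius*
would give a projected area four times larger; 176.71 µm² is consistent
only with d = 15 µm, so the diameter reading is used.)

Flat wells: N = A/176.71 — a monolayer assumption, valid until cells
start stacking near confluence.

U-bottom wells: segmented cluster areas are summed and treated as one
circular colony of radius r = √(ΣA/π) centred at the bottom. The
defining arithmetic is

    h′ = c √(1 − r²/R²)      (gap above the colony)
    h  = c − h′              (colony height)
    V  = π r² h − π r² h³/(3c²)
    N  = V / (π d³/6)

The V formula is kept verbatim as the method's defining arithmetic. It is
*not* the exact volume of the spheroidal cap at intermediate heights: the
exact solid of revolution bounded above by the plane at height h, with
colony radius r tied to h through the spheroid surface, is

    V_exact = π r² h (3c − h) / (3(2c − h)),

available as `colony_volume(..., mode="exact_cap")` for sensitivity
analysis. Both coincide at h = 0 and h = c (where both give the
half-spheroid volume (2/3)πR²c); between them they differ by up to a few
percent. The default reproduces the defining arithmetic; the exact mode
quantifies the approximation.

Numerical conventions: r is clamped to R (with a warning beyond a 1%
overshoot, which overlapping masks can produce); counts are real numbers
internally and rounded to 2 decimals only in CSV output.

## Growth curves

Records are grouped by (channel, time point); the mean is arithmetic and
the SEM uses the sample (n−1) SD divided by √n. A single-well time point
reports SEM 0 and carries a `single_well` flag rather than pretending
precision. Wells missing at a time point (e.g. failed ROI detection)
reduce that point's n with a logged warning.

Collapse detection reports the earliest time the mean falls below
`drop_frac` (default 0.5) of the running maximum *and* never again
exceeds that maximum — a dip with recovery is treated as noise, matching
the no-recovery signature of a dried chip.

Condition comparison is descriptive only (final-time means ± SEM and
fold-change vs a named reference); inferential machinery (mixed-effects
models, multiple-comparison corrections) is intentionally out of scope.

## Self-training

The loop grows a labeled set from a small manual seed: train, predict on
a seeded-random batch of pool images, apply a pluggable corrector
(ground truth in tests; a human in practice), absorb the corrected pairs,
repeat for a fixed number of rounds (no automatic stopping criterion —
none is well defined without a target accuracy). Every absorbed item
records its round, the fingerprint of the model that drafted it, and the
fraction of pixels the corrector flipped; `correction_effort` summarizes
the latter per round as the quantity that falls as the model improves.
With a deterministic corrector the whole loop is seed-reproducible, and
with a ground-truth corrector the final labeled *content* equals direct
full supervision — only provenance differs. Uncertainty-based pool
selection would be a natural extension; random order is the default to
keep the loop unbiased and simple.

## Perfusion budgets

`FlowProtocol` covers static (rate 0), constant (rate > 0), and
intermittent (pulse of `pulse_min` minutes at `rate` every `period_h`
hours) regimens. Per-cycle volume: rate × period (constant) or
rate × pulse (intermittent). Consumption over a horizon integrates
constant flow exactly; intermittent flow counts a pulse iff its start
falls strictly inside the horizon (so a 3 h horizon of a 3 h-period
protocol contains exactly the t = 0 pulse). With equal per-period
volumes, constant and intermittent protocols agree at every whole-period
horizon. Schedules place dispenses at period boundaries and imaging
10 min after each imaging-interval boundary by default, erroring if an
imaging time lands inside a dispense window. Two intermittent presets
exist — 5 min at 10 µL/min every 3 h (per ibidi channel, 50 µL/cycle)
and 20 min at 10 µL/min every 2 h (PDMS device, 200 µL/cycle; it dries
faster because of its larger channel volume).

## Problem sizes in the test suite

Tests run on small wells (floor radius 120 µm → ~175 px frames at
1.6 µm/px) so rendering, Hough detection, and forest training stay at
seconds per case; the counting round-trips use the full-size flat well
(Ø 800 µm). The self-training benchmark uses 7 initial + 60 pool + 10
validation frames over 3 rounds of batch 20. These sizes were chosen as
the smallest that keep the statistical assertions stable across seeds.

## Known limitations

- The area→count conversions assume a fixed spherical cell size; real T
  cells change size upon activation, biasing absolute counts while
  leaving fold-changes largely intact.
- The U-bottom colony model treats scattered clusters as one centred
  colony; sparse non-central cells make it overestimate colony height
  slightly at low coverage.
- The trainable segmenter is a texture classifier, not a deep network;
  it has no shape priors and will not transfer across optical setups
  without retraining.
- Absolute U-bottom counts inherit the uncertainty of the assumed
  single-cell volume; flat-well counts are the better-anchored quantity.
- The drying model is a step collapse; gradual evaporation produces a
  slower decline the detector may flag later than onset.
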