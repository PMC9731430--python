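# Methods

This note documents the models, parameters and design choices behind
chondrotrace: what each stage computes, what the synthetic scenes emulate,
and what passing the validation suite does and does not demonstrate.

## Canonical intensity scale

All thresholds in the package are defined on one scale: background-
subtracted fluorescence in arbitrary units (a.u.), i.e. the value of a
pixel after the grid background estimate has been removed. The synthetic
trace generator emits traces directly on this scale, which is what makes
the default decision-tree thresholds (7, 20, 8, 10, 6, prominence 3)
meaningful verbatim for both real pipelines and synthetic round trips.
Frame-indexed thresholds (7, 50, 100, 120) are interpreted at the long-term
imaging cadence; because published setups of this kind report both 10 s and
20 s frame intervals, the cadence is a free `ScenarioParams.frame_interval`
parameter and the frame thresholds are configuration, not constants.

## Tracking

Localization follows the centroid-tracking tradition: a band-pass filter
(Gaussian smooth, σ = 1 px, minus a boxcar local mean over twice the cell
diameter) suppresses noise and background; local maxima above
`peak_threshold` (default 0.6 a.u.) become candidates; each candidate is
refined by an iteratively re-centered intensity-weighted centroid over a
`locate_diameter` window (default 9 px, matching a ≈13 μm cell at
1.29 μm/px). Two non-standard details matter in crowded, dim fields:

* during refinement, each window pixel is used only by the candidate it is
  nearest to (a Voronoi mask over candidates). Without this, the tail of a
  bright cell 8–9 px away drags a dim cell's centroid into itself and the
  dim cell is lost;
* detections with integrated mass below `min_mass` (default 40 a.u.) are
  discarded; this sits above the clipped-noise mass of empty windows at the
  default camera noise while keeping the dimmest behavior class (composite
  amplitude ≈ 4–5 a.u.) detectable.

Linking is per-frame minimum-total-displacement assignment (Hungarian
algorithm) with displacement capped at `max_link_displacement` (5 px/frame)
for consecutive frames; a lost track stays eligible for `max_gap_frames`
(5) frames and may re-link within `max_gap_displacement` (10 px ≈ one cell
diameter). Gaps whose bracketing detections are within that distance are
filled by linear interpolation and flagged `interpolated`; larger gaps
split the track. After the tissue has relaxed — detected automatically as
the first frame from which the median per-frame track displacement stays
below 0.2 px over a 10-frame window, overridable via
`static_start_frame` — any track that ends is extended at its last position
to the end of the movie and flagged `extended`, so intensities can be read
out for cells that have faded below the detection threshold. Extension is
deliberately one-sided: frames before a track's first detection are never
fabricated, because the early post-impact phase is the moving phase.

## Intensity extraction

Background is estimated per channel and per frame on a `grid × grid`
partition (default 8×8; for a 512×512 frame each region has 4096 px) as the
mean of the `n_lowest` (20) smallest pixel values of the region, and
subtracted. With ~1000 cells of ~10 px diameter in a 512×512 field, the 20
lowest of 4096 pixels are always extracellular, so the estimate tracks
local stain leakage without touching cell interiors. The remainder of a
non-divisible image goes to the last row/column of regions. Traces are the
mean over the 3×3 window centered on the rounded centroid (ties round half
away from zero; windows truncate at borders). Smoothing is a centered
20-frame moving average whose window shrinks to the valid range at the
trace ends (no padding, so no fabricated intensities; even windows lean one
frame backward). The pipeline smooths before both peak and changepoint
extraction; both detectors also accept raw traces.

## Feature extraction

**Peaks.** A sample is a calcium-transient candidate if its topographic
prominence is ≥ `min_prominence` (3 a.u.); its width is measured at half
prominence, and peaks with width/prominence > 10 are rejected as too broad
to be transients. Detection is scipy's peak machinery; the test suite
checks it against a from-first-principles prominence oracle.

**Changepoints.** Traces are segmented by exact dynamic programming over
piecewise-linear fits, minimizing total squared error plus `penalty`
(25 a.u.²) per changepoint, with segments of at least `min_segment_length`
(10) frames. The penalty was calibrated once on synthetic step traces so
that a single ideal step yields one changepoint raw and two after
smoothing (the smoothed step is a ramp with two corners), and is never
re-tuned per trace. A changepoint survives the baseline-drift filter when
its bracketing fitted slopes differ by ≥ `min_slope_difference`
(0.1 a.u./frame) **or** the fitted levels are discontinuous at the boundary
by ≥ `min_level_jump` (1 a.u.). The second clause is necessary: a raw level
shift has equal (zero) slopes on both sides yet is precisely the feature
the detector exists for, while a uniform ramp — pure drift — passes
neither clause and is dropped.

**Statistics.** Min, max, argmax (first maximum), mean, population
variance, range, mean over frames strictly after a configurable frame, and
range after the argmax; plus the cross-channel mean(red − blue).

## Decision tree

The tree is applied per cell, with strict inequalities throughout:

1. blue max > 7 **and** blue argmax < 7 → **A** (elevated from the start).
2. If blue changepoints exist: > 3 changepoints → **L**; else
   mean(red − blue) > 20 → **E**; else if green peaks exist, first peak
   before the first blue changepoint → **H**, after → **G**; else if the
   rise is late (blue argmax > 120 and first changepoint > 100): a green
   changepoint → **F**, none → **D**; else blue peaks → **C**; else range
   after the blue maximum < 8 → **B**; remaining → **A** (a second,
   distinct path to the same label, kept deliberately).
3. No blue changepoints: green peaks → **I**; else blue range > 10 → **B**;
   else red mean after frame 50 < 6 → **K**, otherwise → **J**.

Every comparison reads one fingerprint statistic, so each classification
carries a replayable decision path. "Green changepoint" uses the same
step detector applied to the green channel. Where the tree's prose
admits two readings (≥ vs > at a threshold; which peak "the" green peak
is), this implementation uses strict > and the earliest peak/changepoint,
documented here rather than guessed silently.

The optional benchmark harness wraps external multivariate time-series
classifiers (scikit-learn models over per-channel summary features or
flattened z-scored series) behind a uniform train/predict adapter with a
seeded stratified split; classifier internals are out of scope. Requesting
an unregistered backend raises a capability error rather than silently
skipping.

## Synthetic scenes

The generator emulates the target experiment: a 512×512 px field covering
660×660 μm (1.289 μm/px), hundreds of cells of ≈13 μm diameter rendered as
isotropic Gaussian spots (σ = 2 px; no published PSF, so a plausible
default), a ≈10 s cadence with 300-frame movies as the desk-scale default,
per-channel trace noise of sd 1 a.u., camera noise of sd 0.5 a.u., and a
minimum cell separation of 8 px so that 3×3 extraction windows never
overlap. Twelve trace archetypes (A–L) implement the behavior categories;
their event amplitudes exceed the tree thresholds they trigger by a
2× margin by default, and their event times are placed relative to the
frame-100/120 late-phase boundaries (hence the ≥ 150 frame precondition).
When an impact site is set, death-associated categories (B, C) are placed
within the impact radius (400 μm default) with 0.9 probability and normal
cells (J) outside it, reproducing the spatial segregation such experiments
report; the layout is phenomenological — no strain field is simulated.

Cell motion under `relaxation_drift` is a spatially coherent displacement
field: every cell is displaced radially from the impact (or field) center
with magnitude `amplitude_px` (12 px) decaying over `length_scale_px`
(200 px), a small per-cell jitter (0.5 px), and exponential temporal
relaxation (`decay_frames` = 40). Coherence is deliberate: tissue deforms
as a continuum, so neighboring cells move together; an earlier independent
per-cell drift produced cell-cell collisions that no real tissue shows and
that artificially destroyed tracks.

What the synthetic scenes do **not** emulate: intensity variation across a
cell body (spots are ideal Gaussians), z-drift and focus loss, photobleaching,
stain leakage dynamics beyond a static halo/offset background, segmentation
ambiguity between touching cells, and the heavy class imbalance of real
tissue (the default category weights are uniform so every behavior is
exercised). Consequently the validation figures are upper bounds on real
performance: the decision tree reaches 100% on 1,200 noisy synthetic traces
against a ≥ 81% acceptance bound precisely because the archetypes are
cleanly separated at sd 1 a.u.; on real data the same tree must contend
with intermediate and ambiguous cells.

## Validation figures and problem sizes

`scripts/acceptance.py` recomputes two figures from scratch at the
reference sizes (a few minutes on one CPU):

* **Tracking recovery** — 500 cells, 300 frames, 512×512 px, relaxation
  drift, 5% of detections deleted independently per frame. A cell counts
  as recovered when one track covers all 300 frames within 2 px mean error.
  Note an intrinsic ceiling: a cell whose frame-0 detection is deleted can
  never be recovered under this every-frame metric, because interpolation
  needs an earlier bracket and static extension only acts after the last
  detection — so the expected maximum is ~95% at 5% dropout, and measured
  values sit just below it.
* **Tree accuracy** — 100 traces per category × 12 categories, 300 frames,
  noise sd 1 a.u., smoothing window 20, default tree thresholds; total
  accuracy via the scoring operation (correct/1200).

## Known limitations

* The tracker assumes a single focal plane and near-isotropic spots; no
  3-D tracking or deformable registration.
* Frame-indexed tree thresholds tie the classifier to the acquisition
  cadence; movies at other cadences need rescaled `TreeParams`.
* The changepoint DP is O(n²) in trace length — fine for hours at 10–20 s
  cadence (≤ ~1500 frames), not for the 40 fps short-term mode; the
  short-term calcium analysis is peak-based, not changepoint-based.
* `score` reports per-category accuracy as true positives over truth count
  (recall); categories absent from the truth are undefined (`None`), never
  zero.
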