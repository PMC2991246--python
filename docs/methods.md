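# Methods

This note documents the models, algorithms, parameters and design
choices behind the package, and what the synthetic-data validation does
and does not establish about real movies.

## The simulator: what it emulates

A transport movie is generated as

* a **static autofluorescence texture**: a Gaussian random field
  (smoothing σ = 3 px) scaled to an SD of `texture_amplitude`
  (default 15 intensity units) on a uniform background
  (`background_level`, default 20).  This is the stand-in for the worm
  body structure that drift registration locks onto;
* **particles** arriving by independent homogeneous Poisson processes —
  anterograde at the soma end of the path, retrograde at the tip end —
  at `rate_antero` / `rate_retro` per minute.  Each particle draws one
  base speed from a normal distribution truncated at zero (the
  published summaries give only mean and s.e.m., so a truncated normal
  is the minimal choice; the SD is reconstructed as s.e.m.·√n) and
  keeps it for its whole run: the scoring rule presumes steady-rate
  straight segments, so pausing and speed switching are deliberately
  absent.  An optional piecewise-constant arclength profile multiplies
  the speed locally — the two-segment IFT preset uses multipliers 0.4
  and 1.0 with the junction at 4 µm, mimicking the slower middle-segment
  and faster distal-segment anterograde motors;
* **rendering** as isotropic 2-D Gaussian spots (σ = 0.15 µm) of
  amplitude 80 on a straight path centred in the frame (default
  64 × 256 px at 0.1 µm/px — the pixel size of such 100× acquisitions
  is a convention here, not a published value);
* **stage drift** as an integer 2-D random walk (per-frame step =
  rounded normal with SD `drift_step_px`, default 0.35 for the dendrite
  presets), applied to the whole rendered frame so the registration
  ground truth is exact;
* **noise**: Poisson shot noise on (background + texture + signal) by
  default; Gaussian read noise optional.

Identical (preset, seed) pairs give bit-identical movies and
ground-truth tables.

An observation **campaign** (e.g. "34 minutes of wild type") is
simulated as *n* movies of duration/n minutes with *n* ≈ duration / 4.
Real acquisitions of this kind come in ~1-minute bouts; we use longer
4-minute bouts so that runs censored at movie boundaries (a particle
that enters too late to travel 3 µm before the movie ends) are a small
fraction (~2–3%) of all runs.  Events pool across movies; frequencies
divide by the summed time.

**Not emulated**: photobleaching, camera gain, curved or 3-D dendrite
geometry, anisotropic PSFs, particle pausing/reversal, occlusion beyond
additive intensity.  Passing the synthetic acceptance suite therefore
shows that the *pipeline* recovers known kinematic ground truth at a
realistic SNR and traffic density; it does not certify performance on
real movies with path mistracing, bleaching or bidirectional cargo.

## Registration

The estimator is the definitionally exhaustive scan: for consecutive
frames, evaluate `MSD(d)` over the ROI for every integer displacement
with `|d| ≤ search_radius` (default 6 px in the pipeline) and keep the
minimizer (ties: smaller ‖d‖, then lexicographic).  Offsets chain
consecutively — faithful to registering "two consecutive time slices" —
with the known cost of slow error accumulation on very long movies;
tests bound this by asserting exact recovery of the simulated random
walks at fixture SNR.  Subpixel refinement is intentionally absent
(integer drift ground truth; nothing in the scoring needs it).

Two robustness choices matter in practice:

* the default ROI is the whole frame minus a margin.  Narrow
  texture-only ROIs fail when drift carries the bright moving particles
  into them;
* bright puncta (pixels > median + 6 × 1.4826·MAD, dilated 5 px) are
  masked out of the MSD mean.  Without this, frames with several
  same-direction particles can pull the minimum one pixel along the
  traffic direction — rare per pair (~5%), but chained offsets then
  corrupt every later frame of the movie.  Masking is the automated
  counterpart of a user drawing the ROI over stationary structure.

Translated frames are padded with the movie's background median, so
registration leaves a drift-free movie bit-identical.

## Kymograph

Paths are polylines in pixel coordinates (fractional vertices allowed),
resampled at equal arclength steps (default = one pixel = 0.1 µm).
Each kymograph entry is the **max** (default; robust to ±1 px path
mistracing of punctate cargo — mean is available) of bilinearly
interpolated intensities along a perpendicular segment of half-width
2 px.  Position 0 is the soma end, so anterograde = positive slope.

## Event detection and the 3-µm rule

* **Peak detection.**  Each kymograph column's temporal median is
  subtracted first: stationary structures (texture, cell body) paint
  vertical stripes that would otherwise be detected as zero-velocity
  traces.  Candidates are then per-row local maxima above 5× the robust
  spread (1.4826·MAD) of the flattened kymograph — at 3× the maximum
  operator over the perpendicular segment admits too many shot-noise
  shoulders — at least 0.4 µm apart, with 3-point parabolic subpixel
  refinement.  Thresholds are relative, so detection is invariant under
  global intensity rescaling.
* **Linking.**  Greedy nearest-neighbour, frame by frame: each open
  trace predicts its position (constant-velocity extrapolation once it
  has two points); pairs are accepted by increasing distance within
  `max_jump_um` per elapsed frame, unmatched candidates seed traces, and
  traces close after 2 frames without a match.  `max_jump_um` defaults
  to 1.25 µm/frame: with the wild-type velocity SD implied by the
  published s.e.m. (0.51 µm/s), a 1.0 µm/frame gate would permanently
  exclude the ~4% of particles faster than 2 µm/s; 1.25 covers the
  distribution's practical support at 0.5 s/frame.
* **Stitching and terminus splitting.**  Fragments broken by crossings
  or dropouts are re-joined when their end velocities agree within
  0.3 µm/s and extrapolation meets the next fragment within ~0.5 µm
  (gap ≤ 8 frames).  Conversely, a trace that reverses direction with
  its turning point within 1 µm of a path end is split there: at a
  terminus, one particle leaving and another arriving look like a
  single V-shaped path to a nearest-neighbour tracker, and scoring that
  V as one event would undercount.  Genuine mid-path direction
  switches are *not* split — they remain one path and are scored by the
  longest-segment rule below.  Crossing-trajectory identity assignment
  beyond these rules is out of scope.
* **Steady segments.**  "Steady rate" is operationalized as RMS
  residual ≤ ρ about a least-squares line, ρ = 0.3 µm by default
  (exposed in config; event counts on fixtures are stable for
  ρ ∈ [0.2, 0.5] µm, asserted in the test suite), minimum 4 points.
  Segments grow greedily from seed windows, adjacent runs merge when
  the joint fit stays within ρ, and the boundary between contiguous
  runs is refined locally to the split minimizing total squared
  residual (greedy extension alone overruns a kink by 1–2 points).
* **Scoring.**  A trace yields at most one event: it must contain a
  steady segment whose fitted displacement exceeds 3 µm *strictly*
  (the boundary case of exactly 3.000 µm is excluded); the longest such
  segment (tie → earliest) gives the representative speed (|slope|) and
  direction (sign).  Displacement of the fitted line is used for the
  3-µm measure — identical to path length for a straight segment.

## Statistics

Per direction: sample mean, s.e.m. = sd(n−1)/√n (reported as missing
for n < 2), histograms in 0.2 µm/s bins anchored at 0, and frequency =
events per pooled minute.  Genotype comparisons use Welch's
unequal-variance t test (safer default where only "t test" is known;
two-sided p, Welch–Satterthwaite df), cross-checked against a
permutation test in the suite.  Particles, not animals, are the
statistical unit, consistent with the published n.

Two-segment IFT: every steady segment is assigned middle/distal by mean
position relative to the junction arclength; segments straddling the
junction are split at the observed crossing (points below vs at/above
the junction — splitting by the blended fit's crossing time biases the
distal mean low) and each part refit if it retains 4 points.  Pieces
with fitted displacement under 1 µm are ignored: a velocity needs a
discernible run, and residual near-stationary clutter would bias the
region means.

## Ciliary fluorescence

`total = (voxel volume × count of supra-threshold voxels) × (mean
supra-threshold intensity)` — algebraically the voxel volume times the
summed masked intensity, asserted exactly.  Otsu thresholding is the
default for single stacks; for paired-stack *ratios* a **common
absolute** threshold is used, because a per-stack threshold (Otsu) adapts
to each stack's histogram and biases the comparison.  The simulated
fixture is a uniform ellipsoid (semi-axes 1.2 × 0.9 × 2.2 µm) over
background 2 with amplitude 200 and Poisson noise; the mutant-like stack
scales the signal by 0.26 exactly.  The measured ratio lands near 26.7%
rather than 26.0% because the measured means include the (small) additive
background, which the noiseless ground-truth totals exclude; with
background/amplitude = 1%, this offset stays well inside the comparison
tolerance and was left unmodelled (background-subtraction models are out
of scope).

## Headline-quantity estimation

The acceptance computation (`ciliatransport.acceptance.compute_targets`,
wrapped by `scripts/acceptance.py` and the `accept` CLI command) repeats
each simulated campaign 3 times with independent child seeds and reports
per-campaign mean counts and pooled velocities.  A single 34-minute
campaign's event count is itself a Poisson draw with SD ≈ √134 ≈ 12
events; replicate averaging reduces this Monte-Carlo component of the
estimate without touching any tolerance.

## Numerical conventions and degenerate inputs

0-based pixel coordinates, half-open ROIs; positions in µm, times in s,
frequencies per minute; calibration always from explicit
arguments/config, never TIFF tags.  Degenerate inputs fail loudly:
single-frame movies, zero-length or out-of-frame paths, steps longer
than the path, negative rates/σ/thresholds, junctions outside the path,
mask/stack shape mismatches.  Ties in the MSD scan break toward the
smallest displacement; ties in longest-segment selection toward the
earliest segment.  Movies round-trip losslessly through float32 TIFF.

## Known limitations

Integer-pixel registration only; greedy (not globally optimal) linking;
no crossing disambiguation beyond stitching and terminus splitting; no
per-animal mixed-effects modelling; no multiple-testing correction; the
simulator's idealizations listed above.
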