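# Methods

This note documents the models, estimators and numerical conventions behind
`micromot`, and what validation on the bundled simulator does and does not
establish about real recordings.

## Coordinate and unit conventions

Positions are physical (μm); voxel indices are 0-based and refer to voxel
centers.  Image grids are (t, z, y, x) with square lateral pixels
(dx = dy, 200 or 300 nm in the bundled presets) and a coarser axial step
(dz = 1000 nm).  Frame intervals are 25–60 s.  Velocities are reported in
μm/min throughout; a handful of field studies print directed step velocities
in μm/s, which we treat as a unit inconsistency and do not reproduce.

## The simulator

### Cell geometry

A cell is a soma (disk of area drawn lognormal around the preset median,
σ = 0.30 in log units) plus 3–11 processes: gently curved polylines grown in
~2 μm segments with 6° heading wobble and a ±1.5 μm axial undulation, so the
x-y projected length of each polyline is exact by construction.  One
designated primary receives the cell's "longest process" draw (lognormal,
σ = 0.25 around the preset median); the rest are a random fraction
(0.35–0.85) of it, and secondary branches emerge partway along a parent.
Because the longest path is assigned rather than emergent, the batch median
of the true longest process equals the preset median by construction —
which is what makes morphometry recovery a well-posed test.

Severity presets follow the activation gradient after status epilepticus:
longest-process medians 38.5 / 36 / 31.8 / 26 / 22 μm and soma-area medians
40 / 42 / 55 / 65 / 75 μm² for control / mild / intermediate / intense /
severe; primary-process count is drawn around 6 (alternating 5/6 for
intermediate, giving the 5.5 median; around 7 for severe).  The soma medians
for the intermediate levels are interpolated between the reported control
and activated group means (42.2 and 73.5 μm²), since per-level medians are
not printed anywhere; all other preset centers are reported values.

### Basal scanning

Each tip carries a 1D "territory" coordinate: its distance R(t) to the
process origin, confined to a reflecting band whose width is lognormal
(σ = 0.5 in log units) with median equal to the preset territory scale
(4.18 μm control, 5.38 μm activated), clipped to 1–16 μm — matching the
observed 1–15 μm range.  Per-step speeds are lognormal with arithmetic mean
equal to the preset mean tip velocity (2.38 / 2.46 μm/min) and CV 0.3 (the
source data give only means, so the distributional form is a modeling
convention).  Each step of length s splits into a radial component (50–100 %
of s, direction-persistent, truncated at the band walls) and a tangential
arc carrying the remainder, so the frame-to-frame displacement — the
quantity tip tracking measures — always has length s, while max R − min R
converges to the band width within a 30-min recording.  The walk lives in
the tip's own z-plane with the reference projected into it; this makes the
simulated radial coordinate identical to what projection-based analysis
measures, by design (real z-motion would add a small compressive bias that
the simulator deliberately omits — see Limitations).

### Directed responses

Tips whose initial distance d₀ to the target is within the response radius
re-orient and move straight toward it at a lognormal speed with mean equal
to the preset front speed, stopping at the 2 μm arrival radius.  Two
collective modes:

- **Coordinated (agonist pipette).** A virtual front starts at the farthest
  responder and moves inward at the front speed; each tip starts only when
  the front reaches its own distance, so closer tips start later — the
  staggered-onset behavior seen with purinergic gradients.  Speed CV is 0.02
  (the wave is tight); responder distances span 25–78 μm with the far edge
  at 77.7 ± 2.5 μm, the geometry jointly consistent with the reference
  global velocity (1.30 μm/min control, 2.68 activated) and mean
  time-to-pipette (58.2 and 29.0 min): (77.7 − 2)/1.30 ≈ 58 min.
- **Uncoordinated (laser lesion).** All responders start immediately
  (speed CV 0.1); start distances are normal (26 ± 5 μm) clipped to
  17–35.5 μm inside the 35.8 μm response radius, so the nearest responder
  yields (17 − 2)/3.75 ≈ 4 min to target and the farthest responder sits at
  the response-radius edge.

A fraction of responders aborts: it stops after a sustained approach (at
least ~3.4 steps, so aborted tips still register as "responding") and
retracts to its start.  When `abort_beyond_um` is set, the abort probability
rises logistically (scale 1.5 μm) with start distance, which separates the
responding extent (≈ 35.8 μm) from the arriving extent (≈ 21 μm): distant
responders react but rarely arrive.  `abort_min_radius_um` keeps aborts
outside the measurement annuli so an aborting tip never crosses a ring
twice; this is also the physically sensible regime ("abruptly stopped and
retracted" early in the approach).

### Rendering

Geometry is rasterized by depositing intensity along segments
(amplitude per μm of process, a point deposit per tip, a disk for the soma),
blurred with an anisotropic Gaussian PSF (σ = 0.25 μm lateral, 0.8 μm
axial), offset by a constant background, optionally shifted per frame by a
drift trace (linear interpolation), then corrupted by Poisson shot noise
and Gaussian read noise.  In movie mode the shaft follows its tip (basal:
a straight shaft from the process origin to the current tip; directed: a
finite 2 μm protrusion trailing the tip), so rings see a passing front
rather than an accumulating trail.  Single-plane fields (nz = 1) render as
2D projections.  Everything is reproducible bit-for-bit from the seed.

## Estimators

- **Drift.** Per-frame 2D translation against the first frame by
  cross-correlation of the MIPs (skimage `phase_cross_correlation` with
  `normalization=None`, upsampling ×20).  Plain cross-correlation is
  weighted by the bright static structures (soma, arbor) and is much more
  robust to moving tips than whitened phase correlation (RMSE ~0.08 px vs
  ~0.3 px on moving scenes).  The reference is the first frame, anchoring
  t = 0 to stimulus onset.  Frames with no signal are flagged and their
  shifts interpolated.  Correction resamples with linear interpolation,
  filling uncovered pixels with the frame median.  Rotation and z-drift are
  out of scope.
- **Tracking.** Seeded nearest-local-maximum linking on the lightly smoothed
  (σ = 1 px) registered MIP, greedy global assignment by distance within a
  search radius (default 3.5 μm for basal protocols); contested candidates
  go to the closer tip and the loser's track terminates; tracks are never
  extrapolated.  Local maxima are pixel-quantized (no subpixel refinement);
  at 200 nm pixels this contributes < 1 % to step statistics.
- **Step classification.** θ defaults to 0.5 μm/min ≈ one lateral pixel per
  25-s frame; ties are stationary.  Steps spanning missing frames are
  excluded, not interpolated.
- **Ring velocity.** Annuli of width 2 μm at spacing 5 μm (lesion preset:
  radii 5/10/15 μm, all inside the nearest responder's start distance so
  every responder traverses every ring; agonist preset: radii 10–30 μm).
  Traces are background-subtracted (pre-stimulus mean) and smoothed by a
  centered 3-frame moving average; the peak is the earliest frame attaining
  the smoothed maximum; validity requires prominence ≥ 20 % of the trace's
  dynamic range and a peak away from the trace boundary.  Peak times are
  quantized at frame resolution — deliberately, to keep the estimator
  identical to its maxima-based definition — so each pairwise velocity
  carries a one-frame quantization error (up to ~25 % of a single pair for
  the lesion geometry); averaging over pairs and runs brings recovered means
  within a few percent.  Non-monotonic peak pairs are dropped with a
  warning; experiments with fewer than 3 valid peaks are invalid, mirroring
  the ≥ 3-peak inclusion rule.
- **Morphometry.** The "magic wand" is seeded region growing on the lightly
  smoothed MIP with tolerance 50 % of the seed-to-background contrast — the
  half-maximum contour, which is unbiased for a blurred sharp-edged soma
  (a tighter 35 % tolerance undersizes the soma by ~7 %).  The seed
  intensity is a windowed median so a process crossing over the soma in the
  projection cannot inflate the threshold.  Skeletonization thresholds with
  the triangle method (robust when thin processes occupy a tiny fraction of
  voxels, where Otsu collapses onto the soma) and applies 3D thinning.
  Primary processes are connected components of the tube mask crossing an
  annulus 4–6 px outside the soma (clear of the soma's blurred halo).  The
  longest process is found on the skeleton graph (26-connected, 3D edge
  weights) from soma-adjacent roots via Dijkstra, and its length is reported
  on the x-y projection of that path using corrected chain-code weights
  (0.948 straight / 1.343 diagonal per pixel, Dorst–Smeulders), which
  removes the ~5–8 % staircase overestimate of naive per-step lengths.
- **Statistics.** The normality screen is a one-sample KS test against a
  Gaussian with the sample's own mean and SD, without the Lilliefors
  correction — this mirrors the stated procedure literally and is
  conservative (it accepts Gaussianity too readily), which we document
  rather than correct.  Measured type-I error of the auto-selected unpaired
  comparison on Gaussian nulls at n = 30 is ≈ 0.048.  All tests are
  two-sided; no multiple-testing correction.  Mann–Whitney uses the exact
  null for small tie-free samples and matches full enumeration.

## Problem sizes

The test suite and the acceptance script size each experiment so the whole
validation runs in minutes on one CPU: basal tracking batches use 10 cells
(~90 tips, 8-min movies at Δt = 45 s); territory batches 20–24 cells of
30-min trajectories at Δt = 30 s; agonist estimates 2–6 rendered runs of
24 tips; lesion estimates 4–9 runs of 20 tips; the morphology gradient 90
cells per severity level.  These sizes put median/mean sampling error well
inside the recovery tolerances; larger batches change nothing but the error
bars.

## What validation on the simulator shows — and what it does not

Passing recovery tests shows the estimator chain is correct and unbiased
*under the simulator's assumptions*: straight-line or 1D-radial tip motion,
Gaussian PSF with Poisson/read noise, pure-translation drift, shafts that
follow their tips, and fronts of near-uniform speed.  Real recordings add
z-motion through the projection (compressing radial measures), non-rigid
tissue deformation, photobleaching, autofluorescence, and densely
overlapping arbors from neighboring cells.  Two measured artifacts already
visible at simulator density are documented rather than hidden: tracked
batch mean velocity runs ~2 % below truth because tips in close encounters
merge into one intensity peak (fast tips are lost slightly more often), and
ring estimates inherit frame-quantization scatter.  Neither artifact is
corrected post hoc; both shrink with sparser scenes or finer sampling.

## Known limitations

- No rotation/affine/deformable registration; no 3D (z) drift correction.
- Tracking requires seeds; there is no automatic tip detection, lineage or
  branching-event analysis, and no cell-body tracking (somata are static on
  these time scales).
- The simulator has no amoeboid/phagocytic end-state, no cell-body
  migration, and no optical realism beyond Gaussian PSF + shot/read noise.
- The ring estimator assumes the front passes each ring once; oscillatory
  re-entry would need kymograph-style analysis, which is out of scope.
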