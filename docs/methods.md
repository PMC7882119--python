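# Methods

This note documents the models, estimation procedures, and numerical
choices behind `dualmlc`, and what the synthetic validation does and
does not demonstrate.

## Leaf-end model

The collimator is a dual-layer stacked-and-staggered MLC: two banks of
1 cm (at isocenter) leaves at 38.9 and 47.9 cm from the source, the
distal layer offset half a leaf width in Y, giving 0.5 cm effective
resolution over a 28 × 28 cm² maximum field.  Effective tip positions
are an affine-plus-quadratic map of the nominal position:

    X_left  = x_nom − Offset + Gain·x_nom − Curvature·x_nom²
    X_right = x_nom + Offset + Gain·x_nom + Curvature·x_nom²

`x_nom` here is the signed nominal position (central axis at zero).
This is the reading under which the isolation properties hold exactly:
the dosimetric offset ΔX_D = Offset + Curvature·x² is independent of
Gain, and the midpoint shift ΔX_MP = Gain·x is independent of Offset
and Curvature.  Those two invariants are what the commissioning
strategy exploits, and they are enforced as property tests.

Parameters are uniform across leaf rows (all leaves share one width and
end shape) and shared between the two layers, which is how the model is
optimized in practice — a single parameter set describes the machine.

### Defaults

| parameter | default | units | origin |
| --- | --- | --- | --- |
| Offset | +0.007 | cm | commissioned value for this machine class |
| Gain | 0.0 | – | slope test insignificant |
| Curvature | 0.0 | cm⁻¹ | off-axis trend at experimental-error level |
| tip width | 0.0 | cm | profiles insensitive for this tall, flat-ended leaf |
| layer transmission | 0.0047 | – | standard single-layer value |
| T&G width | 0.05 | cm | bar-pattern match |
| dynamic min gap | 0.06 | cm | conservative delivery floor |
| max leaf speed | 5 | cm/s | machine limit |
| max gantry speed | 12 | deg/s | machine limit |
| min MU/deg | 0.1 | MU/deg | deliverability floor for arc segments |
| source sigma (X, Y) | 0.075, 0.090 | cm | penumbra match |
| d_max | 1.3 | cm | 6 MV FFF beam |

## Fluence model

Each layer is an infinitely thin attenuator: open = 1, under leaf = T,
and two half-thickness zones at √T — a tip zone of width `tip_width`
just behind each tip (a thinned rounded end attenuates with half the
exponent), and tongue-and-groove strips of width `tng_width` where a
closed leaf's side protrudes into an open neighbor row.  The √T value
for both zones is a modeling choice (the half-height argument); where a
tip zone and a T&G strip overlap at a corner, the minimum transmission
wins.

Leaf edges are anti-aliased by area-weighted pixel coverage, so
sub-grid leaf motion changes fluence continuously.  One subtlety
matters quantitatively: the two layers' tips usually coincide in x, and
averaging each layer over a pixel *before* multiplying squares the
partial coverage (a pixel 57% open would contribute 0.57² instead of
0.57), which systematically eats ~h/6 of effective gap width per edge —
enough to destroy sweeping-gap intercepts at the 0.1 mm level.  Dynamic
accumulation therefore rasterizes the *product*: within each 0.5 cm
effective band (cut at every row border of either layer) both layers'
profiles are piecewise constant, so the pixel average of their product
is computed exactly on merged breakpoints.  T&G strips are applied
afterwards as multiplicative √T corrections with fractional coverage.

Dynamic sequences are integrated by linear interpolation between
control points with sub-steps of at most the grid spacing of leaf
travel.  With the sub-step equal to the pixel size, the discrete time
sum of pixel coverages integrates exactly one period of the sampling
ripple per pixel, so uniform sweeps are reproduced without quantization
bias — the default sub-step (0.1 cm) is chosen to match the default
grid for this reason.

## Dose engine

The engine is a deliberately simple relative-dosimetry chain:
anisotropic Gaussian source blur (source sigmas projected through the
mid-layer distance to the measurement plane), geometric magnification
by (SSD + depth)/SAD, an analytic depth-dose factor (linear build-up to
d_max = 1.3 cm, exponential beyond, fixed so PDD(10 cm) = 0.63), and an
optional mild monotone output-factor curve on the equivalent square
(4·Area/Perimeter = 2ab/(a+b)).  The PDD shape and output curve are
configuration, not science: virtual measurements and model calculations
share them, so they cancel in every relative comparison the pipeline
makes.  Field edges of the unflattened beam are located at the
inflection point of the penumbra — the extremum of the centered first
difference, refined by quadratic interpolation of the derivative peak;
profiles with no distinct extremum (linear ramps) or several separated
equal extrema raise an ambiguity error rather than guessing.

Most sessions measure at 10 cm depth and 90 cm SSD, which places the
measurement plane at the isocenter distance: magnification is unity and
plane coordinates coincide with nominal leaf coordinates.

## Virtual lab

The synthetic-data module replaces the physical linac with a hidden
`GroundTruth` (true parameters + noise level + seed).  Sessions are
pure functions of (ground truth, arguments); all randomness flows from
explicit integer streams, so identical seeds give identical readings.

* **Sweeping gaps** — 2–20 mm gaps traversing an 8 cm window around
  chamber positions 0, ±3, 5, 10, 12, 13 cm; Farmer chamber as a 2.3 cm
  line average along Y; one closed-field leakage record per position and
  a static 10 × 10 cross-calibration reference.  Combinations the ±14 cm
  leaf travel cannot sweep fully across the chamber (wide gaps at 13 cm
  off-axis) are omitted rather than half-measured.
* **Abutting fields** — two 2 × 4 cm² fields meeting at 0 or ±10 cm,
  scanned in X with an 0.08 cm diode kernel, each normalized to its own
  opening center, summed, three noisy runs averaged.
* **Complementary bars** — alternate rows open/closed on one layer (the
  other retracted), scanned in Y; the summed pair exposes T&G dips at
  that layer's leaf borders (1 cm apart per layer; the two layers'
  borders interleave at 0.5 cm).
* **Slit edges** — 2 cm slits at seven off-axis centers; the two
  field-edge inflections give the pair midpoint, hence ΔX_MP(x_nom),
  the Gain isolator.  For a slit of width w the measured slope is
  Gain + Curvature·w, so slits are kept narrow.
* **Modulated plans** — per technique (VMAT: 60 control points over
  354°; sliding-window VMAT: monotone sweeps; sliding-window IMRT: nine
  fixed angles × 8-point sweeps), with smoothly modulated MU densities
  and per-row aperture widths, validated against the kinematic limits
  (leaf speed, dynamic gap, MU/deg).  Each plan carries two chamber
  points — isocenter plus a low-dose point chosen so the noise-free
  ratio is 0.4–0.8 — and 581–1009 cylindrical-array samples at 10.5 cm
  radius.  Plan doses are computed as a single composite fluence (the
  phantoms are uniform and doses relative, so gantry dependence is
  ignored dosimetrically; angles are kept for kinematics only), and
  array detectors are projected onto the dose plane at lateral offset
  10.5·sin φ with no depth-dependent attenuation.  Target modulation
  (default 6 MU/cGy, valid range 1.5–10) sets the aperture width
  heuristically; the realized value is checked, and unreachable targets
  are refused.

Noise is multiplicative lognormal, default SD 0.5% (typical chamber
repeatability), one independent draw per record.

What the generator does *not* emulate: detector energy response and
field-size corrections, interleaf leakage beyond the T&G strips,
off-axis spectral softening, gantry-angle-dependent attenuation, EPID
or log-file dosimetry.  Because the commissioning fits use the same
forward engine as the generator, noise-free recovery tests demonstrate
the correctness and identifiability of the estimation procedures, not
the physical fidelity of the engine; on a real machine the model-error
floor would be higher.

## Estimation pipeline

`run_commissioning` proceeds from isolating experiments to fine-tuning:

1. **Transmission** — √(mean closed-field leakage / 10×10 reference);
   the configured standard value is retained, the measurement confirms
   it.
2. **T&G width** — RMS match of summed bar profiles over a candidate
   grid.
3. **Gain** — OLS slope of ΔX_MP vs x_nom with a two-sided t-test;
   the slope is accepted only at p < 0.05, otherwise Gain = 0.
4. **DLG** — OLS of (reading − leakage) vs gap width per position; the
   DLG is the negative of the fit line's x-intercept.  For a flat tip it
   equals 2·Offset; a stacked tip zone inflates it only by ≈ 2·tip_width·T
   (the two layers' √T zones multiply back to T), which is why tip width
   matters so little for this collimator.
5. **Offset, RMS variant** — readings cross-calibrated to dose against
   the calculated 10×10 reference (leakage not subtracted), RMS% against
   model calculations minimized over a candidate grid with parabolic
   refinement of the three best.  Near the optimum the RMS is V-shaped,
   so the parabolic vertex can be biased by up to ~0.002 cm when the
   truth falls between grid points; the modulated-plan scan supersedes
   this value anyway.
6. **Curvature** — quadratic OLS of DLG/2 vs position; the quadratic
   coefficient is accepted only beyond 3× its standard error (a strong
   quadratic term would add large off-axis offsets), else 0.  The 3·SE
   rule is this package's sharpening of what is otherwise a judgment
   call.
7. **Offset, final** — for each candidate offset, mean local percent
   difference (calculated − measured)/measured over all chamber points;
   the x-intercept of the straight-line fit is the accepted Offset.
   This value wins over the sweep-based estimates.

All fits are ordinary least squares with standard parametric
uncertainties; every `FitResult` records the estimate, diagnostics, the
decision, and the rule that produced it, and the report is
deterministic given sessions and configuration.

## Gamma analysis

γ(p) is the minimum over reference points r of
√((ΔD/Δd_tol)² + (|p−r|/DTA)²), with Δd_tol scaled by the reference
maximum (global) or by the local reference dose (local), and points
below 10% of the reference maximum excluded.  The reference is linearly
resampled at DTA/10; for each evaluated point the gamma at the nearest
resampled node is an upper bound, and any candidate farther than
(bound · DTA) cannot lower the minimum, so restricting the search to
that radius is exact, not approximate.  The implementation is verified
point-for-point (≤ 1e-6) against an independent exhaustive search over
the full resampled grid.  Array comparisons evaluate measured detector
doses at detector coordinates against the calculated reference map
(rather than interpolating measurements).  Confidence limits are
mean ± 1.96·(sample SD) for error distributions and mean − 1.96·SD
(capped at 100) for passing rates; alongside the raw limits a
"paper-style" value truncated toward zero at one decimal is emitted,
matching the convention used when such limits are quoted.

## Problem sizes and runtime

The standard study — chosen as this package's default experimental
design — uses all seven sweep positions (gaps 2–20 mm), three abutting
junctions, one bar session, seven slit centers, and 15 modulated plans
(5 per technique, 30 chamber points), on a 0.1 cm fluence grid (0.05 cm
for scanned profiles).  A full commissioning run takes a few minutes on
one CPU; the noisy-recovery study keeps the plans fixed and redraws
measurement noise per replicate, so the per-candidate model doses are
computed once.

## Known limitations

* Offset, Gain and Curvature are shared between layers; per-layer
  asymmetries are not identifiable from the implemented sessions.
* Curvature estimation leans on per-position DLG/2 values; with
  tip_width > 0 the DLG carries a small tip-zone bias that would leak
  into the quadratic term on rounded-tip machines.
* The staggered-field construction of sub-leaf-width apertures exposes
  the Y shift as a parameter but does not resolve what the optimal
  value is for a real machine.
* The cylinder-to-plane projection of the array flattens entrance/exit
  geometry; passing rates on the virtual array validate the comparison
  machinery, not array dosimetry.
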