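# dualmlc

Dosimetric commissioning toolkit for a ring-gantry linac with a
dual-layer stacked-and-staggered multileaf collimator (MLC).

When a treatment planning system is commissioned independently of the
machine vendor, the leaf-end model of the MLC must be estimated from
measurements: rounded or thinned leaf tips make the *dosimetric* field
edge sit beyond the *nominal* leaf position, and errors of a few
hundredths of a millimetre per edge accumulate into percent-level dose
errors in modulated (IMRT/VMAT) deliveries.  `dualmlc` implements that
whole commissioning analysis as a reusable, tested pipeline — with a
virtual machine in place of the physical linac, so the estimation
procedures can be validated by parameter recovery against a hidden
ground truth.

## The model

Effective leaf-tip positions follow a three-parameter algebra (lengths
in cm, isocenter plane, IEC 61217, x positive to the right in
beam's-eye view for both banks):

```
X_left  = x_nom − Offset + Gain·x_nom − Curvature·x_nom²
X_right = x_nom + Offset + Gain·x_nom + Curvature·x_nom²
```

For an opposed pair planned at the same `x_nom`, the dosimetric offset
`ΔX_D = (X_right − X_left)/2 = Offset + Curvature·x_nom²` moves the
dosimetric edge, while the midpoint shift
`ΔX_MP = (X_left + X_right)/2 − x_nom = Gain·x_nom` moves the pair
midpoint.  Gain never affects `ΔX_D`; Offset and Curvature never affect
`ΔX_MP` — so each parameter has an isolating experiment:

| parameter | isolating measurement | estimator |
| --- | --- | --- |
| layer transmission | closed-field leakage | reading ratio vs open 10×10 |
| T&G width | complementary bar patterns | RMS profile match |
| Gain | field-edge midpoints vs `x_nom` | OLS slope + significance test |
| Offset (initial) | sweeping gaps (2–20 mm) | DLG x-intercept / RMS dose fit |
| Curvature | off-axis `ΔX_D` trend | quadratic term vs 3× its SE |
| Offset (final) | modulated-plan chamber doses | x-intercept of mean %diff vs Offset |

Each leaf layer is an infinitely thin attenuator (open = 1, under leaf
= T ≈ 0.47%, tip zone and tongue-and-groove strips = √T); the two
stacked layers multiply, a Gaussian primary source blurs the fluence,
and an analytic depth-dose factor turns it into relative dose.  The
evaluation layer provides gamma analysis (global/local normalization,
10% threshold), per-detector local dose errors, and mean ± 1.96·SD
confidence limits.

## Worked example

```python
from dualmlc import GroundTruth, fit_dlg
from dualmlc.virtual_lab import gen_sweep_session

gt = GroundTruth(noise_sd=0.0, seed=1)          # hidden truth: Offset +0.007 cm
session = gen_sweep_session(gt, positions=(0.0,))
res = fit_dlg(session)
d = res.diagnostics["per_position"][0.0]
print(f"DLG = {res.estimate:.3f} mm  (R^2 = {d['r_squared']:.6f})")
```

prints

```
DLG = 0.140 mm  (R^2 = 1.000000)
```

The dosimetric leaf gap of a flat-tipped leaf pair is twice the
leaf-end offset — the virtual machine was built with Offset = +0.007 cm,
and the sweeping-gap analysis returns exactly 2 × 0.07 mm.

The same workflow is available from the shell:

```
dualmlc simulate --seed 7 --out sessions/
dualmlc commission --sessions sessions/ --out report.json
dualmlc report --report report.json
```

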