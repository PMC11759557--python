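# cdtikit

Postprocessing toolkit for **cardiac diffusion tensor imaging (cDTI)**:
from short-axis diffusion-weighted image stacks and gradient tables,
through quality control and overdetermined tensor fitting, to helix-,
transverse- and sheetlet-angle maps and summary reports checked against
consensus normal ranges. A synthetic left-ventricular phantom generator
with exact ground truth makes every stage testable without any acquired
data.

It is written for imaging scientists and cardiology researchers setting
up or validating a cDTI analysis pipeline: the phantom tells you whether
your chain of corrections, fits and angle conventions returns exactly
what was put in.

## The model

Diffusion weighting attenuates the magnitude image mono-exponentially,

```
S = S0 · exp(−b · gᵀ D g)
```

where `D` is the 3×3 symmetric diffusion tensor (mm²/s), `g` the unit
encoding direction and `b` the diffusion weighting (s/mm²). For the
stimulated-echo (STEAM) sequence the monopolar b-value is

```
b = γ² δ² G² (Δ − δ/3)
```

with gradient duration `δ`, amplitude `G` and diffusion time `Δ` spanning
one cardiac cycle — so beat-to-beat RR variability changes the realized
b frame by frame, and the fitter can re-evaluate each frame's `b` at its
own RR interval before building the design.

`D` is estimated per voxel by linear least squares on
`log S_i = log S_ref + row_i · vec(D)` over every surviving frame
(repeats are observations, never averaged; the intercept is estimated
because STEAM has no true b=0 image). From its eigensystem
`λ1 ≥ λ2 ≥ λ3`, `e1..e3`:

- **MD** = (λ1+λ2+λ3)/3, **FA** = √(3/2)·‖λ−MD‖/‖λ‖,
  **mode** = 3√6·det(Ã/‖Ã‖) with Ã = D − MD·I;
- **HA** (helix angle): elevation of e1's wall-tangent projection out of
  the imaging plane, positive toward the right-handed subendocardial
  helix;
- **TA** (transverse angle): in-plane tilt of e1 off the circumferential
  direction;
- **E2A** (sheetlet angle): angle of e2's projection in the
  radial/cross-myocyte plane, quoted as |E2A| ∈ [0°, 90°];
- **HAT** (helix-angle transmurality): OLS slope of the transmural HA
  profile, normally ≈ −1°/% wall depth.

Local wall coordinates {R radial, C circumferential, L longitudinal} and
transmural depth (0% endo → 100% epi) are derived from endo/epi contours.

## Worked example

Simulate the default phantom — an annular LV cross-section with a linear
+50°→−50° transmural helix profile, sheetlet angle 62°, eigenvalues
(1.6, 0.9, 0.59)×10⁻³ mm²/s, one b=50 frame plus twelve b=450 frames —
and run the full report:

```
$ cdti simulate --out phantom
phantom written to phantom (10 files)

$ cdti report --dwi phantom/dwi.nii.gz --bval phantom/dwi.bval \
              --bvec phantom/dwi.bvec --contours phantom/contours.txt \
              --out report --sequence STEAM --phase systole
# cdtikit QC report
attenuation_reduction: 0.3303 (band 0.30-0.50) => PASS
rejected_frames: []
...
# consensus-range flags
md: value=0.00103 status=in_range rule=typical range ('md', 'STEAM', 'any') reference=(0.0008, 0.0012)
fa: value=0.464755 status=in_range rule=typical range ('fa', 'STEAM', 'systole') reference=(0.43, 0.51)
ha_range: value=99.9995 status=in_range rule=typical range ('ha_range', 'any', 'any') reference=(95.0, 110.0)
hat: value=-0.999995 status=in_range rule=mean±2SD ('hat', 'any', 'any') reference=(-1.12, -0.88)
```

Reading the numbers: the b=50→450 signal drop is 33% (inside the 30–50%
quality band); the recovered mean diffusivity 1.03×10⁻³ mm²/s and FA
0.465 equal the phantom prescription; the helix-angle range (100°) and
transmurality (−1.00°/% depth) match the prescribed ±50° linear profile.
`report/` additionally contains MD/FA/mode/HA/TA/E2A NIfTI maps and
rendered PNGs (HA on a cyclic color scale wrapping at ±90°), a summary
CSV, and an acquisition-parameter reporting manifest.

Other subcommands: `cdti qc` (attenuation check, outlier frames,
registration), `cdti fit` (tensor + scalar maps, `--wls`, `--rr-file`),
`cdti maps` (angle maps only).

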