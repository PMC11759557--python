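# Methods

## Signal model and tensor estimation

The forward model is the mono-exponential magnitude attenuation
`S = S0·exp(−b·gᵀDg)` with a symmetric positive-definite tensor `D`
(mm²/s). No perfusion (IVIM) compartment, kurtosis, or strain correction
is modelled; the low b-value is kept non-zero (default 50 s/mm²) as is
standard for suppressing the perfusion contribution, but the fit itself
is purely mono-exponential.

Per voxel the tensor is estimated from `log S_i = log S_ref + row_i·vec(D)`
with `row = −b·(gx², gy², gz², 2gxgy, 2gxgz, 2gygz)`, by ordinary least
squares over all surviving frames. Choices:

- **Estimated intercept.** Stimulated-echo protocols have no true b=0
  image, so `log S_ref` is a free parameter and the low-b frame is an
  ordinary observation at its actual b.
- **No repeat averaging.** Repeats enter as separate rows of the
  overdetermined system; this is what makes per-frame b-value correction
  possible.
- **OLS default, WLS optional.** Weighted least squares (weights ∝
  signal²) is the first-order variance correction for the log transform
  and is available behind a flag; OLS is the default because it is
  deterministic, dependency-free and adequate at the SNRs where the
  log-linear model is trustworthy anyway.
- **Rank guard.** Fitting requires ≥ 6 unique non-collinear high-b
  directions (design rank 6) plus ≥ 1 low-b frame; deficient designs
  raise with a message naming the deficiency.
- **Negative eigenvalues are flagged, never clamped.** Clamping hides
  corruption; the flag propagates to diagnostics.

### STEAM b-values and RR correction

For the monopolar STEAM experiment `b = γ²δ²G²(Δ − δ/3)`, evaluated in
SI units from console units (δ, Δ in ms; G in mT/m; γ defaults to the
proton value 2.6752×10⁸ rad s⁻¹ T⁻¹, overridable). The formula does not
apply to moment-compensated spin-echo waveforms; MCSE b-values are taken
as given inputs and never recomputed. When per-frame RR intervals are
available, frame i's b is re-evaluated at its own diffusion time:
`b_i = b_nom·(RR_i − δ/3)/(Δ_nom − δ/3)`, which is the same closed form
at the gradient amplitude implied by the nominal b. A linear-algebra
identity makes the effect of *not* correcting exactly predictable
(fitting data generated under design A_true against design A_nom maps
coefficients through pinv(A_nom)·A_true); the tests use this as an
oracle.

## Local cardiac coordinates and angles

From endo/epi contours (plain-text polygon format, mm): contours are
resampled with a periodic cubic spline to 4000 vertices; signed
distances to each contour are computed exactly (nearest vertex via
KD-tree, then point-to-segment distance on the adjacent segments, with
the sign from the segment cross product so the field stays smooth across
the wall surfaces). Transmural depth is
`d = 100·d_endo/(d_endo + d_epi)` (0% endo → 100% epi, so a normal
helix-angle slope is negative). The radial unit vector R is the in-plane
gradient of the depth field, differentiated by central differences at a
step of 0.05 voxel — small enough that truncation error is negligible,
large enough that the residual polygonization noise (~10⁻⁶ mm) does not
amplify; on a circular annulus R matches the analytic radial direction
to ~10⁻⁹. L is the slice normal (apex→base) and C = L×R completes a
right-handed frame.

All three angles are projection angles, sign-stabilized so that the
eigenvector sign ambiguity (e → −e) can never change a reported value:

- HA = atan2(e1p·L, e1p·C) with e1p = e1 − (e1·R)R flipped to e1p·C ≥ 0,
  range [−90°, 90°) with +90° folded onto −90° (the angle is axial, mod
  180°);
- TA analogous in the R–C plane;
- E2A: cross-myocyte direction x = R × ê1p; e2 is projected off ê1p and
  its angle from x folded into [0°, 90°] (a signed variant is available).

Degenerate voxels (e1 ∥ R, or a vanishing projection) return NaN and are
excluded from summaries. Where λ2 and λ3 agree within 2% relative, the
e2/e3 assignment is unstable; such voxels carry a low-confidence flag
rather than any swapping heuristic, which would silently corrupt
statistics.

## Quality control

- **Attenuation check**: mean masked signal over all high-b frames
  divided by the mean over low-b frames; the reduction 1−ratio must land
  in a configurable band, default 30–50% (enough diffusion contrast
  without dropping into the noise).
- **Corrupted-frame rejection**: each frame's masked mean is scored
  against the median of its b-shell in MAD units; frames below −3 robust
  SDs or below 70% of the shell median are rejected. The thresholds are
  package decisions surfaced in the API — there is no community-standard
  quantitative definition of "corrupted". Rejection refuses to proceed
  (raises) if the survivors could not support a tensor fit.
- **Rigid registration**: translation-only, maximizing normalized
  cross-correlation over an integer ±10 px search window with optional
  parabolic sub-pixel refinement. An optimum on the window boundary is
  flagged and the frame left unshifted rather than silently moved to the
  edge of the search space. Translation-only is deliberate for
  breath-hold single-slice short-axis data; rotation is out of scope.

## ROI, transmural profile and summary metrics

The septal ROI is the full-thickness arc between the two RV-insertion
landmarks (minor arc about the LV centroid), with any delineated
trabeculation polygon excluded; ROIs below 50 voxels are refused. A
six-sector partition referenced to the first insertion point is also
provided; a full 16-segment model is out of scope for a single-slice
tool.

The transmural HA profile bins voxels by depth (default 10 bins, ≥5 must
be populated); per-bin HA is the axial circular mean (doubled-angle
trick, period 180°), and the endo→epi bin sequence is unwrapped so
profiles crossing ±90° remain continuous. HAT is the OLS slope of
per-bin HA against per-bin mean depth, reported in °/% and in °/mm
(slope × 100 / mean wall thickness — the two are related exactly).

**HA range.** The range is reported as max−min over the per-bin means
*together with* the fitted line evaluated at 0% and 100% depth. Bin
means alone sit at ~5% and ~95% depth and systematically understate the
wall-surface values by half a bin width per side (a ±50° linear profile
would read ~90° instead of 100°); the published normal range (95–110°,
"≈+50° to ≈−50°") clearly refers to surface values. For non-linear
profiles the bin-mean extremes dominate and the definition reduces to
the conventional one.

E2A summaries use the **median** of |E2A| (absolute-angle distributions
are skewed near the 0°/90° boundaries); E2A mobility is the systolic
minus diastolic median and a negative value is reported as-is with a
reduced-mobility flag. Consensus normal ranges are shipped as a
read-only table keyed by (metric, sequence, phase); QC uses the printed
typical range where one exists, mean ± 2 SD otherwise, labels which rule
fired, never compares STEAM values against spin-echo rows, and
hard-flags any diffusivity above free water at body temperature
(3×10⁻³ mm²/s) regardless of range.

## The synthetic phantom

The generator emulates: an annular LV short-axis cross-section
(circular contours, RV-insertion landmarks on the epicardium), a linear
transmural helix-angle profile, prescribed transverse and sheetlet
angles, prescribed eigenvalues, mono-exponential forward simulation,
Rician noise (two independent Gaussian channels, σ = S0/SNR, seeded),
whole-frame signal dropouts, and per-frame STEAM b-value modulation by
an RR profile. Ground truth is prescribed **in the same local frames the
geometry module derives from the contours**, so the angle conventions
cancel exactly and noiseless full-loop recovery is a machine-precision
test of the fitting and angle code, not of the frame construction
(which is tested separately against the analytic annulus).

Defaults (the conditions all reported numbers use): 48×48 grid at 1 mm,
8 mm slice; r_endo 10 mm, r_epi 17 mm; HA +50° (endo) → −50° (epi); TA
0°; E2A 62°; eigenvalues (1.6, 0.9, 0.59)×10⁻³ mm²/s → MD 1.03×10⁻³,
FA 0.465 (the STEAM normal means); S0 1000; 12 fixed
spherical-Fibonacci directions at b=450 plus one b=50 frame; landmarks
at ±60°. A closed-form axially-symmetric eigenvalue solution
(`eigenvalues_for_md_fa`) places a phantom at any exact MD/FA pair; note
its λ2 = λ3 degeneracy makes E2A undefined there by construction.

What the phantom does **not** emulate — and what passing tests therefore
do not establish for real data: cardiac and respiratory motion within
the encoding, EPI distortion, fat ghosts, partial volume with blood pool
and trabeculation (an optional trabeculation polygon exists only as an
exclusion-logic test), perfusion, strain, multi-family interpenetrating
sheetlet populations, through-plane curvature of the helix field, and
any vendor reconstruction behaviour.

## Estimator behaviour at very low SNR

The log-domain OLS estimator is remarkably insensitive to the Rician
noise floor itself: Monte-Carlo evaluation shows E[log M] for a Rician
magnitude stays within ~0.01 of log S down to S ≈ 2.4σ, so at b=450 and
SNR 5 (the default phantom's deepest-attenuation frames) the classic
floor-induced underestimation of attenuation barely engages. What
dominates instead is eigenvalue-sorting repulsion: per-voxel λ1 is
inflated and λ3 deflated, biasing FA strongly upward (median ≈ 0.75
against a truth of 0.465 at SNR 5) while MD — linear in the fitted
coefficients — shows only a small, skew-dependent bias (mean slightly
low, median slightly high). Floor-driven underestimation of MD and FA
is expected to dominate only at deeper attenuation (higher b·D relative
to SNR) or in pipelines that magnitude-average repeats before the log
transform. One property test encodes the floor-dominated expectation at
SNR 5 and currently fails for exactly this reason; it is retained as an
honest record rather than weakened.

## Problem sizes and determinism

All tests and the acceptance script run on the 48×48 single-slice
phantom (~600 myocardial voxels, 13 frames), chosen so the full suite
completes in seconds while every statistic still has a few hundred
voxels behind it. Every stochastic element (noise channels, jitter
draws) flows from explicit integer seeds; noiseless results are
bit-reproducible across runs and seeds.
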