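# Methods

This note documents the statistical models, forward simulation and
numerical choices behind `f19mri`, and what its synthetic tests do and do
not demonstrate about real acquisitions.

## Magnitude-noise model and corrected SNR

Magnitude reconstruction of complex MR data makes the voxel noise
non-Gaussian.  With one receive channel the magnitude M of a voxel with
true signal S and per-channel Gaussian noise σ follows a Rician law; with
a two-element quadrature probe combined by root-sum-of-squares it follows
a noncentral chi law with d = 4 degrees of freedom.  Two consequences
matter for SNR work:

1. **Noise floor.** E[M] > S everywhere, with E[M]/σ → √(π/2) ≈ 1.2533
   (d = 2) or ≈ 1.8800 (d = 4) as S → 0: weak signals are biased upward.
2. **Background std shrinkage.** The std of a signal-free background is
   not σ but c_σ·σ, with the closed forms c_σ = √(2 − π/2) ≈ 0.6551
   (Rician) and ≈ 0.6824 (4-DOF chi), obtained from the first two moments
   of the central chi distribution.

The corrected estimator takes the measured ROI mean (or voxel value) s_m
and background std σ_m, forms σ = σ_m/c_σ, and solves the mean equation

    E[M | S, σ] = s_m

for S, reporting SNR = S/σ.  The mean function is evaluated through
Kummer's confluent hypergeometric function,

    E[M]/σ = √2 · Γ(k+3/2)/Γ(k+1) · ₁F₁(−1/2; k+1; −a²/2),  a = S/σ,

with k = channels − 1.  It is strictly increasing in a, so the inversion
is a bracketed Brent root-find on [0, s_m/σ] with absolute tolerance
1e−8 (in σ-units).  Measurements at or below the zero-signal mean have no
nonnegative solution and are reported as SNR 0 with a `flagged_subfloor`
marker rather than a negative root.

For whole maps the scalar root-find is replaced by linear interpolation on
a dense tabulation of the mean function (spacing 0.005 in a, up to
E[M]/σ = 60) and, above that, by the asymptotic inverse
S/σ = √(r² − (d−1)), whose relative error falls off as (d−1)²/r⁴.  The
residual deviation of the corrected value from the naively rescaled ratio
is ≈ (d−1)/(2r²): about 0.2% at r = 20 for Rician data and under 0.5% for
both models by r ≈ 25–30.

Two c_σ conventions are exposed.  `printed` (default) uses the
constants common in the quantitative ¹⁹F literature, 0.655 and 0.687;
`derived_closed_form` uses the exact values 0.6551 and 0.6824.  The
printed chi constant differs from the exact 4-DOF value by ≈0.7% and its
derivation is not stated in the literature we follow; both conventions are
computed side by side in benchmark reports, and the configured one feeds
the headline numbers.

ROI mode averages magnitudes first and then corrects the mean (matching
the convention of reporting one SNR per tube from a central ROI covering
~90% of the cross-section's pixels); map mode corrects voxelwise.  The
central ROI is the largest disc concentric with the region centroid whose
enclosed in-region pixel count does not exceed the requested fraction;
discretization leaves a ring of a few percent.

Background std uses the n−1 sample variance and warns below 100 voxels
(configurable).  A background mask overlapping a provided signal mask
warns but still computes, since the contract that the background is
signal-free belongs to the caller.

## Double-angle flip-angle mapping

For fully relaxed acquisitions (TR ≫ T1; the bench protocols use TR up to
20 s) at nominal angles α and 2α, the signal ratio depends only on the
local flip angle: FA = acos(SI_2α / 2 SI_α), by sin 2x = 2 sin x cos x.
Any receive profile multiplies both images identically and cancels — the
map is receive-independent, which the tests verify by construction.

Numerical choices:

- The intensity ratio is clipped to [−1, 1] before acos; noise can push it
  outside.  Clipped voxels are retained and flagged.
- Voxels with SI_α below `signal_floor` are invalid (NaN); a practical
  floor is 5× the background σ of the α image.
- Magnitude inputs fold angles beyond 90° (the true signed 2α-signal is
  negative there); the simulator can emit signed rasters for exact
  inversion over (0°, 180°).  Maps are reported both raw and normalized
  to a nominal 90° (×90/α).

Error conditioning: propagating magnitude noise through acos amplifies by
1/sin FA, so at per-voxel SNR 20 the per-voxel scatter is ≈1° near FA 70°
but ~4–5° near FA 30–40°.  Recovery claims at SNR 20 are therefore stated
for the Monte-Carlo mean over many voxels (bias well under 2° everywhere
in 30–120°), with per-voxel ±2° holding in the well-conditioned range
(FA ≳ 55° with the doubled-angle image above SNR 20).  This is a property
of the double-angle method itself, not of this implementation.

Profiles are extracted along any raster axis (by index or tag, the depth
axis being tagged `depth`), as a single center line or the mean of a
lateral band (default 3 lines per lateral axis, NaN-aware); positions are
voxel-size spaced in mm.  Both aggregations are provided because published
profile plots rarely state which was used.

## Spins-per-voxel calibration

Atoms per voxel is pure dimensional analysis:
N = c·10⁻³ [mol/L] × V_voxel [L] × n_F × N_A, with n_F = 20 for PFCE.
Two atom counts quoted in the original cryoprobe study exceed this formula
by a consistent ≈4.3× under their stated concentrations and voxel sizes;
since the convention behind them is not stated, they are retained only as
reference metadata (`REPORTED_ATOM_COUNTS`) and never enter computation.

The sensitivity model is strictly proportional, SNR = k·N.  The default
fit (`log_proportional`) fixes the exponent at one and estimates
log k = mean(log SNR − log N), weighting each decade equally, which is the
appropriate estimator for a unit-slope line on a log-log calibration
spanning decades; `linear_origin` (OLS through the origin) is available
and weights the largest N most.  A free-exponent power-law fit is provided
purely as a proportionality diagnostic and never feeds gain computation.
The residual spread is reported as the geometric std of SNR/(kN).

Gain = k_A/k_B; detection limit = cutoff/k (cutoff 2 by default, the level
below which images stop being sharply defined).  Profile comparison
resamples both profiles onto the finer grid over their overlap, takes the
ratio where the reference is positive, and reports the maximum ratio with
its depth plus the first downward crossing of ratio 1 (linearly
interpolated; a ratio exactly 1 at the first sample counts, and a ratio
that never comes down to 1 yields no crossover).

## Scan-time accounting

TA = TR × ceil(phase-encode steps / ETL) × averages, with ETL = 1 for
FLASH and the 2nd×3rd matrix axes as phase steps for 3D scans.  Partial
echo trains cost a full TR (hence ceil; e.g. 65×65 steps at ETL 33 → 129
shots).  Zero-fill matrices are metadata only.  Durations render to the
nearest second/minute/hour or an "H h MM min" form, matching console
output.  `reference_protocols()` carries five published protocol listings
with their reported times; four reproduce to within the rendering
granularity, while the 3D FLASH listing computes to ≈2.0 h against a
reported 6 h 3 min and is flagged inconsistent rather than forced.

## Synthetic acquisitions

The generator emulates the three bench setups: a uniform
high-concentration cylinder (radius 7.75 mm by default, approximating a
33% trifluoroethanol syringe), a single row of 4-mm-I.D. NMR tubes holding
the PFCE dilution series 25/50/100/200/400/600 mM behind a 0.75 mm spacer,
and a seeded field of ellipsoidal blobs.  Membership is by voxel center —
no partial-volume anti-aliasing — and depth is measured from the coil face
plus spacer.

Forward model per voxel:

    S = signal_per_atom × N_atoms × B1rx(depth) × sin(FA(depth)),
    FA(depth) = flip_nominal × reference_power_scale × B1tx(depth),

with B1tx = B1rx ≡ 1 for the volume coil and exp(−depth/λ) for the
transceive surface coil.  Defaults: λ = 3.3 mm, chosen so the normalized
FA falls below 5% of its surface value by ≈10 mm (the depth range over
which measured surface-coil FA maps collapse to zero), and
reference_power_scale = 1.69 ≈ 152/90, mimicking the over-flipped surface
region that results from calibrating pulse power for useful depth.  RARE
echo-train amplitude modulation is not modeled — the first-echo sin(FA)
response is used for both sequences, since none of the estimators under
test depend on echo weighting; optional T1/T2 saturation factors exist but
are off for the fully relaxed bench protocols.  Channel noise is added as
independent Gaussians on the real and imaginary parts of each channel and
combined root-sum-of-squares, making the voxel law exactly Rician or
4-DOF noncentral chi; identical seeds give bit-identical rasters.

Not emulated: k-space artifacts (ghosting, Gibbs ringing, motion),
spatially varying noise from accelerated reconstruction, partial-volume
rims, T2 blur along RARE echo trains, a physical loop-coil field map, and
anatomical realism.  Passing tests therefore demonstrate the correctness
of the estimators under their stated noise models, not robustness to those
real-world effects — users of real data must still supply clean background
masks and artifact screening.

## Two-coil benchmark workflow

`run_benchmark` simulates both arms on the dilution-series phantom,
estimates per-tube SNR via the 90% central-disc ROI against an eroded
signal-free background (4-voxel margin), fits the proportional slope per
arm on tubes above the noise floor, and reports gain and detection limits
under both c_σ conventions; optionally it also acquires the uniform
cylinder per arm, builds corrected-SNR depth profiles (3-voxel-halfwidth
mean band) and reports peak gain, peak depth and crossover.  Per-stage
seeds are drawn from the single config seed and recorded in the report, so
a re-run reproduces the report exactly.  Noiseless arms (σ = 0) have no
background to calibrate against; they propagate raw ROI means as
arbitrary-unit signals, which leaves slope ratios — the quantity of
interest — exact.

Default study conditions (chosen once): 0.25 mm in-plane voxels, 1.2 mm
slice, tubes at a common depth; arm signal scales 4.8e−15 and 3.0e−16
per atom with unit noise σ, giving a true sensitivity ratio of 16 with the
weakest tube near SNR 7 — a regime where slope recovery within 10% is
expected from the tube-count and noise level.  These sizes keep the full
suite and the acceptance script in the seconds range while leaving
Monte-Carlo errors far below the asserted tolerances (bias checks use
10⁵ voxels; noise-constant checks 10⁶).

## Known limitations

- The printed-vs-derived chi constant discrepancy (0.687 vs 0.6824) is
  unresolved upstream; both are carried, clearly labeled.
- Published atom counts retained as metadata are internally inconsistent
  with the dimensional formula (≈4.3×) and are not reconciled.
- The double-angle mapper folds FA > 90° for magnitude inputs; use the
  signed-simulation path when unfolded angles matter.
- Acquisition-time arithmetic assumes Cartesian interleaved single-package
  2D and full 3D phase-encode loops; exotic orderings are out of scope.
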