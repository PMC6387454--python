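# Methods

This note documents the models implemented in `uspiorelax`, the numerical
choices behind the fitters, what the synthetic-data generators emulate (and
deliberately do not), and the problem sizes the test suite and
`scripts/acceptance.py` use.

## Signal models

All models operate on longitudinal relaxation rate `r1` (s⁻¹), effective
transverse rate `r2star` (s⁻¹), equilibrium signal `s0` (arbitrary units,
absorbing proton density and receive sensitivity) and flip-angle scale `k`
(actual/nominal flip-angle ratio; spatially varying through B1 inhomogeneity
and the slab excitation profile).  Times are seconds internally; YAML/dict
configs accept milliseconds via `*_ms` keys.

**sGRE (Ernst equation).**  Ideal spoiling is assumed, and T2\* decay at the
echo time is neglected — the protocol's sGRE echoes are 2.3–2.5 ms, where
exp(−R2\*·TE) is a near-constant factor absorbed into `s0` and irrelevant to
R1 estimation.

**IR-sGRE.**  A non-selective adiabatic-quality inversion is assumed perfect
(`Mz → −Mz`).  Three steady-state descriptions are provided:

1. *Simplified*: the readout train is assumed not to perturb the recovery;
   `S = s0 (1 − 2e^{−R1·TI_eff} + e^{−R1·TR}) / (1 + e^{−R1·TR}) sin(kβ)`.
2. *Brix (pulse-by-pulse)*: one TR cycle is inversion → free recovery to the
   train → N pulses of angle kβ spaced by τ, each multiplying Mz by cos(kβ)
   and followed by recovery over τ → free recovery to the next inversion.
   Every segment is an affine map on Mz, so the periodic steady state is the
   fixed point of the composed affine cycle; the repeated pulse–recovery
   segment is composed in closed form by a geometric series.  A brute-force
   fixed-point iteration of the same recursion is retained purely as a test
   oracle (`irsgre_signal_brix_iterative`), and the two agree to 1e−10
   relative.
3. *Deichmann (effective relaxation)*: during the train Mz relaxes toward an
   effective equilibrium `M0* = M0(1−Eτ)/(1−Eτ cos kβ)` with effective rate
   `R1* = R1 − ln(cos kβ)/τ`; the cycle is closed by periodicity.  Because
   `exp(−R1*τ) = cos(kβ)·Eτ` exactly, this closed form coincides with the
   pulse-by-pulse solution at pulse boundaries; the two implementations
   differ only in how the train window and the residual post-train delay are
   segmented, and agree far inside the 0.5 %-of-s0 contract verified by the
   tests.  Both capture the train's saturation of Mz that the simplified
   model ignores.

`TI_eff` is the inversion-to-k-space-centre time.  With linear slice
ordering the centre line is acquired at the train midpoint, so the signal is
read just before pulse `readout_index = ceil(N/2)` (configurable).  The
train length defaults to 80 (72 slice encodes × 11.1 % oversampling).  A
"TI to train start" convention is representable by setting
`readout_index = 1`; note that for the long-TI preset (TR 1.19 s, TI 1.0 s)
that reading is geometrically impossible — the train would overrun TR — which
is why the inversion-to-centre convention is the default.

An important feature of the model family: the absolute discrepancy between
the simplified and pulse-by-pulse predictions grows with r1 from tissue-like
values up to a peak (≈3.9 s⁻¹ for the long-TI preset) and then shrinks
again, since both models converge to `s0·sin(kβ)` once relaxation completes
between pulses.  The discrepancy at blood-like r1 (4.7 s⁻¹) remains several
times the white-matter value, which is the regime that matters for
post-contrast blood measurements.

**ME-sGRE.**  Mono-exponential decay `S_i = S_TE0·exp(−R2*·TE_i)`; `r2star`
is unconstrained in sign.

**IR-SE.**  `S = s0(1 − 2e^{−R1·TI} + e^{−R1·TR})`, signed or magnitude.
The refocusing chain is treated as ideal and B1-independent — this sequence
plays the role of gold standard.

## Fitting

The fitters are scikit-learn-style estimators (`fit(X)` over an
`(n_voxels, n_measurements)` array, fitted attributes with trailing
underscores); `fit_despot1_hifi` and friends are single-voxel functional
wrappers, and `fit_volume` maps any estimator over the in-mask voxels of
co-registered stacks after correcting each for its scanner intensity scale.
All fits are deterministic; unfitted voxels carry the NaN sentinel.

* **DESPOT1-HIFI** minimises the sum of squared signal differences over
  (s0, r1, k) with a trust-region-reflective solver, all three parameters
  constrained positive.  Initialisation: `s0` from the strongest measurement
  back-projected through sin(β) at k = 1; `r1 = 1 s⁻¹`; `k = 1`; one
  fallback multi-start over `r1 ∈ {0.3, 1, 3}` on non-convergence.
  Tolerances 1e−10, 500 iterations.  Two numerical guards that never bind in
  the physical range: `r1 ≤ 1000 s⁻¹`, and `k` bounded just below where the
  train flip reaches 90° (≈18 at a 5° nominal flip), where the
  effective-relaxation model is undefined.  The solver evaluates compiled
  plain-math closures of the signal models; a test pins them to the
  reference array implementations at 1e−10.
* **VFA** is the linearised regression of `S/sin β` on `S/tan β` (slope
  `E1`), optionally refined by nonlinear least squares with k ≡ 1 (default
  on; identical on noiseless data).  Distinct flip angles are required.
* **R2\*** excludes data points with intensity below
  `noise_floor_factor × noise_sigma` (default 3σ; σ supplied or estimated
  from a background region), then fits unconstrained, initialised by a
  signal-weighted log-linear regression and refined by Levenberg–Marquardt;
  `method='loglinear'` stops after the regression (fast mode).  Voxels
  retaining fewer than `min_echoes` (default 2) points are flagged not-fit
  rather than raising.  Caveat established by the Monte-Carlo tests: the
  exclusion rule only reduces the mean bias magnitude when several echoes
  genuinely sit in the Rician floor (r2\* ≳ 120 s⁻¹ at first-echo SNR 30
  with the 4.6–41.5 ms echo train — a post-contrast venous-blood-like
  regime); with milder decay the data-dependent truncation slightly
  *increases* bias, so the threshold should not be applied blindly.
* **IRSE** profiles `s0` out analytically on a coarse `r1` grid (0.05–20 s⁻¹,
  geometric) to select a starting point — and, for magnitude data, the
  polarity pattern among all sign assignments with a single zero-crossing
  along sorted TIs — then refines with one Levenberg–Marquardt fit.

Degenerate inputs: all-zero voxels raise in the single-voxel API and become
NaN in array fits; empty ROI medians return NaN with a logged count of
excluded sentinel voxels.

## Digital phantom

`nine_syringe_spec` emulates a multi-compartment test object: a 3×3 grid of
cylinders with r1 from 0.3 to 4.5 s⁻¹ (white matter through post-contrast
blood) and companion r2\* values, in a short-T1 bath (r1 = 2.2 s⁻¹ — a
synthetic stand-in; the physical bath's relaxation is not characterised
here).  The k field is a second-order in-plane polynomial times a cosine
slab-profile taper, defaults spanning roughly k ∈ [0.79, 1.0]; zero
coefficients give k ≡ 1.  Acquisitions are forward-simulated with the
pulse-by-pulse model for IR-sGRE, the Ernst equation for sGRE (feeding the
echo-train amplitude for ME-sGRE), and the ideal IR-SE model; noise is
Gaussian or Rician (default), seeded, with `sigma_for_snr` setting σ from
the mean foreground signal of the first measurement.

Not modelled, by design: k-space sampling and partial-volume mixing, T2\*
decay within the sGRE/IR-sGRE echo (consistent with the fitted models),
slice-profile and imperfect-inversion effects, magnetisation transfer,
in-flow effects, and B0-related R2\* artefacts.  Passing phantom tests
therefore demonstrates correctness of the estimation chain under the stated
signal models, not robustness to every scanner non-ideality.

## Synthetic cohort

`simulate_uspio_cohort` draws per-subject, per-region, per-timepoint median
rates under an intravascular generative model: tissue
`Δr1(t) = cbv·Δr1_blood(t) + uptake(t)` and
`Δr2*(t) = c·(cbv·Δr1_blood(t) + uptake(t))`, with `uptake ≡ 0` under the
blood-pool-only hypothesis.  Blood r2\* is never generated or used —
intra-vessel R2\* depends on vessel geometry and orientation in ways that
make it unusable for normalisation — and r1 is not measured at the one-month
timepoint (medians are NaN there), mirroring the study design the generator
emulates; at one month the agent is assumed eliminated (`Δr1_blood = 0`).

Defaults (`svd_cohort_spec`) and their rationale, fixed once a priori:
baseline r1/r2\* per region at patient-cohort-typical values (e.g. WM
1.090/19.3, GM 0.825/19.1 s⁻¹; blood r1 0.526 s⁻¹); blood Δr1 3.146 s⁻¹
post-infusion and 4.139 s⁻¹ at 24 h (one-third dose, then full dose);
CBV fractions WM 0.008, GM 0.024, WMH 0.015, SL 0.0125; Δr2\*/Δr1 coupling
c = 90 (between the WM- and GM-implied ratios; a single scalar cannot
reproduce both, reflecting genuine tissue dependence); between-subject
spread 15 % (CoV) on cbv and on blood Δr1, 0.035 / 1.0 s⁻¹ SD on r1 / r2\*
baselines; measurement noise on ROI medians 0.003 s⁻¹ (tissue r1, medians
over thousands of voxels), 0.010 s⁻¹ (blood r1, small ROI), 0.10 s⁻¹
(r2\*).  These produce per-subject ΔR1,norm CoVs around 20–40 %, cleaner
than typical in-vivo spread — the generator models biological variation and
median noise, not segmentation or registration error.

Because a single 12-subject draw of the group-mean ΔR1,norm has a sampling
SD of 5–8 % of the true CBV, recovery is assessed on the *expected* group
mean, averaged over 100 seeded replicates, alongside the fraction of
replicates in which the post-vs-24 h paired difference is non-significant.

## Statistics

Paired two-sided t-tests with pairwise NaN dropping; zero-variance
differences are resolved analytically (all-equal pairs → t = 0, p = 1;
constant nonzero shift → t = ±∞, p = 0) rather than propagating 0/0.
Linear regression and Pearson correlation via ordinary least squares.
Coefficients of variation use the population SD (ddof = 0): CoV of
{1, 2, 3} is 40.8 %.  Raw p-values are reported without multiplicity
correction; between-tissue comparisons are computed for all region pairs.
No automatic outlier exclusion is performed anywhere — per-ROI
distributions are reported for manual review.

## Problem sizes

Chosen so the whole suite and the acceptance script each run in seconds on
one CPU: signal-model comparisons on 1200-point r1 grids; noiseless
recovery on a 12-point (r1, k) grid; the R2\* Monte Carlo on 1000 voxels ×
8 echoes; the cohort study on 100 replicates of 12 subjects × 5 regions ×
4 timepoints; the phantom validation on a 24×24×10 grid (≈840 fitted
voxels, ≈90–96 per compartment) at SNR 50, comparing compartment-mean HIFI
R1 against IRSE R1 via pooled standard errors.

## Known limitations

* The Deichmann-style and Brix implementations share the same discrete
  backbone, so their mutual agreement validates the transcription, not two
  independent derivations; the fixed-point iteration is the independent
  oracle.
* The noise-floor threshold is a declared default (3σ), not estimated per
  dataset; its benefit is regime-dependent (see above).
* The cohort generator draws medians directly rather than simulating full
  images per subject; map-level effects (registration error, segmentation
  contamination, partial volume) are outside its scope.
* Registration, brain extraction and tissue segmentation are out of scope;
  volumes must be supplied co-registered (congruence is enforced, never
  resampled).
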