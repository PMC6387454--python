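# uspiorelax

Quantitative MRI relaxometry for tracking ultrasmall superparamagnetic
iron-oxide (USPIO) contrast agents — such as ferumoxytol — in the brain.

USPIO particles shorten T1, T2 and T2\*, so serial mapping of the relaxation
rates R1 = 1/T1 and R2\* = 1/T2\* before and after infusion quantifies where
the agent goes: immediately post-infusion it is confined to the blood pool,
and at later timepoints any *extra* tissue change signals parenchymal uptake
(inflammatory cells, blood–brain-barrier leak).  The package implements the
full analysis chain for such studies, aimed at MR physicists and imaging
scientists working on small vessel disease and neuroinflammation:

* **B1-insensitive R1 mapping (DESPOT1-HIFI).**  Volumetric R1 at 3 T from
  three spoiled-gradient-echo (sGRE) scans at different flip angles plus two
  inversion-prepared sGRE (IR-sGRE) scans, fitted jointly per voxel for
  (s0, R1, k), where k is the actual/nominal flip-angle ratio.  The sGRE
  signal follows the Ernst equation

      S = s0 · (1 − E1) sin(kβ) / (1 − E1 cos(kβ)),   E1 = exp(−R1·TR),

  and the IR-sGRE signal is modelled three ways: a *simplified* closed form
  that ignores the readout train, the *Deichmann* effective-relaxation closed
  form (R1\* = R1 − ln cos(kβ)/τ), and the full *Brix* pulse-by-pulse
  periodic steady state.  The simplified model is adequate at tissue R1 but
  fails at post-contrast blood R1 (≈4–5 s⁻¹), which is why the model choice
  is exposed everywhere.
* **Variable-flip-angle (VFA) fitting** with k fixed at 1, reproducing the
  standard method's bias under B1 inhomogeneity for comparison.
* **R2\* mapping** from 8-echo mono-exponential decay,
  S_i = S_TE0 · exp(−R2\*·TE_i), unconstrained, with exclusion of data
  points below a noise-floor threshold (default 3σ) to limit Rician bias at
  long echo times.
* **IRSE gold standard.**  Inversion-recovery spin-echo R1 fitting with
  polarity restoration for magnitude images, used to validate the joint fit.
* **Synthetic data.**  A digital nine-compartment phantom (R1 0.3–4.5 s⁻¹,
  smooth B1/slab-profile k field, Gaussian or Rician noise) and a synthetic
  patient cohort in which tissue changes arise from a prescribed cerebral
  blood volume (CBV) fraction and blood ΔR1 — so every pipeline stage is
  testable without scanner data.
* **Uptake metrics and statistics.**  ROI medians, blood-normalised changes

      ΔR1,norm = ΔR1 / ΔR1,blood,   ΔR2*,norm = ΔR2* / ΔR1,blood,

  which immediately post-infusion approximate (respectively, are proportional
  to) the CBV fraction; paired t-tests, Δ R2\*-on-ΔR1 regression and
  coefficients of variation.

## Worked example

Simulate a 12-subject cohort with GM-like CBV 0.024 and WM-like CBV 0.008
and no parenchymal uptake, then estimate CBV from the blood-normalised R1
changes:

```python
from uspiorelax import (
    svd_cohort_spec, simulate_uspio_cohort, normalized_change_table, cohort_stats,
)

spec = svd_cohort_spec(n_subjects=12, seed=42)
table = simulate_uspio_cohort(spec)          # tidy subject x region x timepoint
changes = normalized_change_table(table)     # per-subject normalised changes
print(
    changes[changes.timepoint != "1month"]
    .groupby(["region", "timepoint"], observed=True)["delta_r1_norm"]
    .agg(["mean", "std"]).round(4)
)
```

```
                    mean     std
region timepoint
GM     24h        0.0233  0.0042
       post       0.0231  0.0040
SL     24h        0.0129  0.0012
       post       0.0129  0.0017
WM     24h        0.0082  0.0020
       post       0.0081  0.0022
WMH    24h        0.0136  0.0018
       post       0.0135  0.0030
```

The group means recover the prescribed blood volume fractions (GM 0.024,
WM 0.008, WMH 0.015, SL 0.0125), and — because the generative model is
intravascular-only — the post and 24 h values agree, the null pattern that
distinguishes blood-pool contrast from parenchymal uptake.  Cohort
inference runs the same way:

```python
rep = cohort_stats(table)
gm24 = rep["regions"]["GM"]["timepoints"]["24h"]
# GM r1 24h vs baseline: t=14.5, p=1.7e-08
# GM delta_r1_norm CoV: 17%
```

The same pipeline is scriptable from the shell:

```sh
uspiorelax simulate-phantom --preset nine_syringe --seed 7 --snr 50 --out-dir phantom/
uspiorelax fit-r1 --data-dir phantom/ --model deichmann --out-dir maps/
uspiorelax fit-irse --data-dir phantom/ --out-dir gold/
uspiorelax roi-stats --map maps/r1.nii.gz --labels phantom/labels.nii.gz --out roi.csv

uspiorelax simulate-cohort --seed 1 --out cohort.csv
uspiorelax uptake --table cohort.csv --out changes.csv
uspiorelax report --table cohort.csv --out-json stats.json
```

Volumes are NIfTI-1 with a JSON sidecar carrying the sequence parameters and
scanner intensity scale; cohort tables are tidy CSV.

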