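# Methods

## Scoring model

The package computes the Sequential Organ Failure Assessment (SOFA) score
— six organ sub-scores, each 0–4, summed to 0–24 — with the respiratory
sub-score calculated under seven interchangeable strategies. The
non-respiratory rows use the original SOFA thresholds: coagulation by
platelet count (150/100/50/20 ×10³/µL), liver by bilirubin
(1.2/2.0/6.0/12.0 mg/dL), cardiovascular by mean arterial pressure
(<70 mmHg) and vasopressor dose category, CNS by Glasgow Coma Scale
(15/13–14/10–12/6–9/<6), and renal by creatinine (1.2/2.0/3.5/5.0 mg/dL).
Renal scoring uses creatinine only; urine output is not an input. Inputs
are assumed to be pre-aggregated worst-in-24h values.

"Respiratory support", both as the gate on PF-based scores 3–4 and as the
+1 bonus in the SpO₂-threshold rule, means any oxygen delivery beyond room
air.

### The conventional method and its ambiguity

"Impute missing PaO₂ as normal" can mean two things: impute the *value*
(PaO₂ = 100 mmHg, then score the PF ratio with the patient's actual FiO₂)
or impute the *score* (respiratory = 0). The default is value imputation,
which preserves FiO₂ information: a ventilated patient on FiO₂ 0.8 with a
missing gas still scores PF = 125 → 3. The score-zero variant is available
as `ConvImputation.SCORE_ZERO`.

### SpO₂ → PaO₂ estimators

The piecewise rule is exact at its knots (100 %→100 mmHg, 90 %→60,
80 %→45) and halves the SpO₂ value below 80 %; SpO₂ = 80 is assigned to
the upper segment so the estimator is continuous on [80, 100]. The Hill
estimator PaO₂ = (27.8^2.81 · s/(1 − 0.99 s))^(1/2.8) is one reading of a
typographically ambiguous published formula; the reading was chosen
because it is a proper dissociation-curve inversion (nominal P50
27.8 mmHg), reproduces the classic 90 % → ≈60 mmHg anchor (59.8), and
stays finite at full saturation (≈146 mmHg) thanks to the 0.99 shrink in
the denominator. It is isolated in one function so an alternative reading
can be swapped in. Note the unequal exponents (2.81 inside, 1/2.8
outside) mean the curve's value at s/(1−0.99 s) = 1 is 27.8^(2.81/2.8) ≈
28.13 mmHg, not exactly 27.8.

No cap is applied at high SpO₂ (no truncation at 97 %): neither estimator
is clipped at the top of its range.

### FiO₂ from delivery device

The device/flow → FiO₂ table is a reconstruction of standard bedside
conversion values (room air 0.21; nasal cannula +0.04/L up to 6 L;
simple mask 0.40/0.50/0.60 by flow band; non-rebreather 0.21+0.10/L
within [0.60, 0.90]; high-flow and ventilator circuits report their set
FiO₂ directly). It is explicitly a reconstruction, not a published
reference table, and can be overridden with a four-column CSV lookup
(`device, flow_lpm_min, flow_lpm_max, fio2`). Out-of-band simple-mask
flows clamp to the nearest band.

## Evaluation machinery

AUROC is computed by midranks (ties count ½), identical to the pairwise
estimator P(score_case > score_control) + ½P(tie); with integer SOFA
scores ties are ubiquitous, so midranks are not optional. Variance and
the paired two-score test use DeLong's structural components: per-case
means of the pairwise kernel over controls (V₁₀) and vice versa (V₀₁),
with

z = (AUC₁ − AUC₂) / √(var₁ + var₂ − 2 cov),

two-sided p from the standard normal. A difference with (numerically)
zero variance — e.g. identical score vectors — is reported as degenerate
with p = 1 rather than a 0/0. No multiple-testing correction is applied
across the six method-vs-conventional contrasts.

The default AUROC interval is the DeLong normal interval, clipped to
[0, 1]. A `binomial_style` alternative (Hanley–McNeil
binomial-assumption variance) is provided because "exact binomial CI for
an AUROC" is not a standard construction; neither is claimed to be
anything other than what it is.

Per-score-level mortality uses Clopper–Pearson exact binomial intervals
(via `statsmodels`, cross-checked in the tests against the beta-quantile
closed form). Calibration bands are plain nonstratified case-resampling
bootstrap percentile intervals (default 100 replicates); replicates in
which a score level does not appear are excluded from that level's
percentiles, and a single-replicate run is flagged degenerate. The
bootstrap seed is a required, manifest-logged parameter.

## Synthetic cohort generator

One latent severity factor z ~ N(0,1) drives every channel. This is a
deliberate simplification — real cohorts have multi-morbidity structure —
but one factor suffices to exercise every scoring path and, critically,
the severity-dependent missingness that makes the method comparison
interesting.

| channel | model | default | targets |
|---|---|---|---|
| mortality | Bernoulli(expit(−4.4499 + 2.0 z)) | 4.9 % | ED infection cohort mortality |
| PaO₂ measured | Bernoulli(expit(−0.3743 + 1.8 z)) | 44 % measured | 56 % missing; measured subgroup ≈9 % vs missing ≈1.4 % mortality |
| true PaO₂ | clamp(75 − 16 z − 8·expit(2(z−1.5)), 35, 110) mmHg | — | SpO₂ quartiles ≈ 92/95/97 % |
| SpO₂ | Severinghaus(supported PaO₂) + N(0, 1.5²), clipped [50, 100], 0.1 % resolution | noise 1.5 pts | oximeter error |
| oxygen therapy | severity cutpoints 1.2/1.6/1.8/1.91 → cannula/mask/non-rebreather/ventilator | ≈11 % supported, ≈2.8 % ventilated | escalation prevalence |
| observed PaO₂ | supported PaO₂ · exp(N(0, 0.15²)) | σ = 0.15 | one-time ABG sampling error |
| organ labs | monotone (log-)linear transforms of z + noise | see `CohortConfig.organ_coeffs` | lab medians/IQRs of an ED cohort |

The logistic intercepts were calibrated by Gaussian quadrature against
their target marginal rates before any simulation was run; they are not
free parameters.

Two physiologic choices deserve comment because the comparison's outcome
depends on them:

- **True PaO₂ is primary; SpO₂ is derived** through the forward
  Severinghaus curve S = 100/(23400/(P³+150P)+1) plus noise. The SpO₂→PaO₂
  estimators are therefore evaluated against inputs generated by a
  *different* curve family than either estimator — their errors are
  realistic, not circular.
- **The blood gas is a noisy one-time snapshot** (multiplicative error,
  σ = 0.15 on the log scale) while SpO₂ represents the worst of
  continuous monitoring, and **oxygen therapy raises PaO₂ only weakly**
  ((FiO₂/0.21)^0.3 — patients sick enough to need support have
  shunt-limited physiology). Together these encode the clinical reality
  that a single ABG drawn at an arbitrary moment is a weaker severity
  readout than continuous oximetry. They are what make SpO₂-for-all
  scoring (methods A/C/E) match or beat the conventional strategy in the
  default cohort, mirroring what is observed in real ED data.

What the generator does *not* emulate: comorbidity-specific mortality,
infection-focus structure, time-varying vitals, oximeter bias by skin
pigmentation or perfusion, or any follow-up beyond in-hospital death.
Passing tests on this cohort therefore demonstrate correctness of the
scoring/evaluation machinery and qualitative behavior under
severity-dependent missingness — not quantitative performance on any real
population.

### Reproducibility mechanics

All randomness flows from counter-based Philox streams keyed by the seed,
with a fixed block of 8 normal and 5 uniform variates per patient: the
same seed reproduces the cohort exactly, and growing n appends patients
without perturbing earlier ones. Pipeline artifacts are fully determined
by (input CSV, run configuration); each run writes a manifest with the
seed, a SHA-256 configuration hash, and the package version, and reruns
are byte-identical.

## Numerical and edge-case choices

- SpO₂ is accepted in percent everywhere; fractions are internal.
- Domain errors (SpO₂ ∉ (0, 100], PaO₂ ≤ 0, FiO₂ ∉ [0.21, 1]) raise
  `ValueError` rather than clipping.
- The SpO₂-threshold score caps at 4 after the support bonus.
- Missing PaO₂ in CSVs is an empty cell only; `0` is a (rejected) value,
  not a missing marker.
- Pipeline CSV floats are written with `%.10g` so determinism does not
  depend on platform float-repr details.
- Exit codes: 0 success, 2 validation failure, 3 statistical degeneracy
  (single outcome class).

## Problem sizes

The default cohort is n = 15,000 (the scale of a two-year single-center
ED sample). The test suite uses n = 2,000 for shared fixtures, the full
n = 15,000 cohort for calibration and direction checks, and n = 50,000
for the generator self-consistency check against the quadrature oracle;
the null-calibration test of the paired DeLong test uses 2,000 replicates
at n = 200.

## Known limitations

- The Hill-formula reading is one interpretation of an ambiguous source;
  the original reference should be consulted before relying on its exact
  values (the function is isolated for exactly this reason).
- The FiO₂ table is a reconstruction; institutional tables differ, hence
  the CSV override.
- Single-factor severity means all organ scores are positively coupled;
  discordant multi-organ presentations are under-represented.
- The generator's AUROCs (~0.84–0.87) are higher than typically reported
  for respiratory SOFA in real cohorts — one latent factor with clean
  monotone loadings is an easier discrimination problem than reality.
  Direction-of-difference conclusions transfer; absolute AUROCs do not.
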