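# Methods

`dikidetect` implements a two-stage laboratory-trigger algorithm for
detecting drug-induced kidney injury (DIKI) signals in pediatric inpatient
EHR data, together with a synthetic data generator that makes every stage
testable against known ground truth. This note records the model, the
parameters that matter, the numerical choices, and what the simulation
evidence does and does not show.

## Renal-function model and the DIKI trigger

Renal function is assessed from serum creatinine (SCr, µmol/L) through the
height-independent full-age-spectrum eGFR:

    eGFR = 107.3 × (1 − e^(−Age/0.5)) / (SCr / Q)

where Q(age, sex) is the median SCr of healthy children, a sex-specific
quartic in age (years). A measurement *triggers* when SCr > 130 µmol/L
(strict) or when eGFR falls outside the age-banded pediatric reference
interval: 33–84 (3–6 months), 57–122 (6–12 m), 78–132 (12–15 m), 84–150
(15–24 m), 83–143 (24 m–18 y). Bands are half-open on the right and tile
[3 months, 18 years) exactly; ages between 28 days and 3 months have no
band, so only the SCr rule applies there — the 3–6-month band is never
extrapolated downward. The trigger threshold of 130 is read in µmol/L (a
creatinine of 130 mmol/L is six orders of magnitude beyond physiology).

"Outside the reference interval" is implemented literally as either side
of the band; `egfr_abnormal_direction: below_only` restricts it to reduced
filtration, the clinically expected direction.

**The girls' quartic.** With the fourth-order coefficient −0.00993 the
girls' polynomial becomes non-positive above ≈8.5 years, which cannot be a
working formula for a pediatric population reaching 18. `dikidetect`
evaluates the coefficients it is given and raises an explicit domain error
on a non-positive Q — never a silent NaN. Two coefficient sets ship:
`QCoefficients.printed()` (the default) and `QCoefficients.corrected()`,
which reads the term as −0.000993; the corrected girls' curve reaches
Q(18) ≈ 64 µmol/L, in line with reference values for adolescent girls, and
is the set the synthetic presets use, because the printed set cannot cover
girls over the full age span. Both are configuration, not code.

## Stage 1 — screening suspected drugs

Per hospitalization record: keep records with ≥2 SCr tests whose first
result (T1) is non-triggering, drop records carrying any kidney-disease
diagnosis code, and mark records with a later triggering result as DIKI
events (T2 = first such report time). Drugs administered during the
observation window are tallied per drug as b = users, a = users with an
event; a drug is *suspected* when a/b > 0.10 and b > 2000 (both strict).

Decisions where the procedure is under-determined:

- **Group-1 window.** T2 exists only for event records. For non-event
  records the drug-extraction window closes at the last SCr report time —
  the last moment renal status is observed — configurable to discharge.
- **Window intersection** is closed: an administration [first, last]
  counts when first ≤ window-end and last ≥ T1.
- **Threshold provenance.** 0.10 is a configured default justified by the
  intravenous-solvent calibration report (solvents do not injure kidneys,
  so their a/b estimates the background event ratio); it is reported, not
  re-derived, because the threshold is a judgment sited above that range.
- Ratios are reported at 2 decimal places; comparisons use unrounded
  values. "Initial result within range" uses the full trigger (SCr and
  eGFR rules).

## Stage 2 — retrospective matched cohorts

For each suspected drug, an exposed cohort (received the drug; ≥1 SCr test
strictly before and after first administration; most recent
pre-administration result non-triggering; no kidney-disease code; the
nephroprotectant rule below) and an unexposed cohort (never received the
drug; ≥2 tests; initial result non-triggering; same further rules) are
built. Outcome = any trigger after first administration (exposed) or after
the initial test (unexposed); ascertainment ends at discharge.

The nephroprotectant rule: records with an abnormal result are excluded if
a kidney-protecting drug started before the first abnormal report; records
without one are excluded if they received a kidney-protecting drug at any
point. Records exposed to several suspected drugs stay in each drug's
exposed cohort (drugs are analyzed one at a time) and are flagged
`co_exposed` for sensitivity analyses.

Propensity scores come from a logistic model of exposure on four
confounders — age (years), sex, admission time (fractional years since
2009-01-01; laboratory platforms drift over calendar time) and main
diagnosis (categorical, grouped by a 3-character code prefix to control
cardinality). Matching is greedy 1:4 nearest-neighbor without replacement,
exposed members processed in seeded random order, with a caliper of 0.1 on
the raw propensity scale (configurable to a logit-SD caliper); exposed
members with no in-caliper candidate are dropped and reported, so the
unexposed:exposed size ratio is ≤ 4 with equality when matching completes.
The matched fraction and standardized mean differences before/after
matching are exported as diagnostics.

The association is estimated by unconditional logistic regression of the
outcome on exposure; `adjusted=true` (default) also includes the four
covariates, because matched analyses of this design typically retain the
confounders and the crude 2×2 ratios demonstrably do not reproduce
adjusted estimates. Wald 95% CIs on the log-OR scale, two-sided p-values,
Benjamini–Hochberg adjustment across exactly the drugs analyzed in the
run. Signal rule: positive ⇔ the 95% CI lower bound exceeds 1 (strict).
A zero cell in the unadjusted 2×2 falls back to the Haldane–Anscombe 0.5
correction with a warning. Zero-variance covariates are dropped before
fitting; a covariate that separates the groups raises an error naming it.

## Synthetic worlds

The generator emulates the statistical structure the pipeline consumes,
not hospital physiology. Per record: age ~ U(0.1, 18) years, sex 46%
female, admission uniform over 2009–2020, stay = 2 d + lognormal(1.6, 0.5)
days, a main diagnosis from a small code list, kidney-disease codes at 3%
prevalence. Each formulary drug is assigned independently with a
configurable probability (optionally age-dependent — the confounding
knob). A latent DIKI event is drawn from a logistic model:
logit P = logit(0.07) + Σ_exposed log(true OR) + age term, so the injected
OR is the exact conditional estimand of stage 2. SCr values are
multiplicative-lognormal noise (σ = 0.08) around Q(age, sex); event
records get an abnormal time T2 after the earliest exposure start and
≈3-fold elevated values from T2 on (lognormal shift 1.1, sd 0.15).
Trajectories are piecewise-constant; no kinetics, dosing, or
multi-admission histories are modelled.

The baseline 0.07 and noise 0.08 were calibrated once so that the
*observed* background trigger ratio — latent events plus noise triggers
plus contributions of co-prescribed effective drugs — places the solvent
a/b range at ≈0.085–0.095, just below the 0.10 screening threshold, the
regime the threshold was designed for.

Presets:

- `paper_like` (default n = 50,000): nine screened drugs with injected ORs
  {1.61, 1.06, 1.07, 1.35, 1.49, 1.01, 1.36, 1.13, 1.17}, two intravenous
  solvents (55%/45% exposure, OR 1), a nephroprotectant, an external drug,
  and three background drugs. Test-drug exposure rises mildly with age
  (slope 0.08/y) and so does DIKI risk (0.06/y), so crude screen ratios of
  effective drugs sit clearly above the solvent background — the structure
  real trigger tallies show — while matching recovers the injected
  conditional OR.
- `null_world` (n = 20,000): six test drugs, all OR 1.
- `confounded` (n = 40,000): a null drug whose exposure rises steeply with
  age (slope 0.15/y) under age-dependent risk (0.09/y), plus a clean null
  drug.

What passing simulations do **not** show about real data: the generator
has no confounding by indication beyond age, no drug–drug interactions,
no dose–response, no informative test ordering (clinicians test sicker
children more), and independent exposures. Estimates on the synthetic
worlds are mildly attenuated toward the null by residual outcome
misclassification (noise triggers) and by effective co-medication in the
comparator pool; both phenomena exist in real EHR data too, and power
statements here do not transfer to settings with stronger unmeasured
confounding.

## Validation studies (computed by the test suite / acceptance script)

- **Arithmetic**: the stage-1 tally reproduces reference screen ratios at
  2 d.p., and the suspected-drug criteria select all nine reference rows.
- **Oracles**: the unadjusted logistic exposure OR equals the 2×2
  cross-product to ≥6 significant figures on random tables; BH matches an
  independent step-up implementation; the matcher equals a brute-force
  greedy re-implementation on small instances.
- **Recovery**: across 20 replicates of `paper_like` at 50,000 records,
  drugs with injected OR ≥ 1.35 pass the screen and come out positive in
  ≥90% of drug-replicates; in `null_world` the 95% CI misses 1 at the
  nominal 5% rate (±2 SE) and the positive-signal rate stays below its
  one-sided bound; in `confounded` the crude OR of the null drug exceeds
  1.2 while the matched OR returns to 1 ± 0.1. The type-I study runs
  stage-2 estimation directly on the null drugs: under the null no drug
  passes the a/b > 0.10 gate, by design, so the screening stage would
  leave nothing to measure.

Problem sizes (50,000 records × 20 replicates for power; 20,000 × 20 for
type I; 40,000 × 3 for confounding) are the package's chosen simulation
scale: large enough that per-drug cohorts reach the several-thousand range
of real screens while a full study completes on a laptop in minutes.

## Known limitations

- The record (hospitalization) is the unit of analysis; patients with
  multiple admissions contribute independent records.
- No conditional logistic regression for matched sets, IPTW, or
  disproportionality statistics; the caliper is not adaptive.
- Reference-interval units are taken as the units the eGFR formula yields
  (conventionally mL/min/1.73 m²); no conversion is applied.
- Diagnosis codes are opaque strings matched exactly or by prefix; no
  terminology system is assumed.
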