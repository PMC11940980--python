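# Methods

This note documents the analytic model the package implements, the
synthetic-data generator it is validated against, and the numerical and
design choices made where conventions were genuinely open.

## 1. Analysis model

### Key dates and eligibility

The pipeline operates on four tables (patients, enrollment spans,
medical claims, pharmacy claims) plus a drug dictionary mapping codes to
therapeutic classes (ICI, platinum, non-platinum chemotherapy, targeted,
VEGF/anti-angiogenic, SCLC-predominant, other). Three anchor dates are
derived per patient: the lung-cancer diagnosis date (earliest C34-coded
claim, any diagnosis position, within the study window), the secondary-
malignancy date (earliest C77–C79 claim on or after diagnosis; the code
set is configurable), and the index date (first systemic anticancer
therapy on or after the secondary-malignancy date). Claims data define
one further ambiguity: the study description uses "index date" both for
the metastasis date and for the 1L start. Here the metastasis date
anchors eligibility sequencing and the 1L SACT start is *the* index
date used for baseline lookback, outcomes and costs.

The eligibility cascade is ordered, and each patient is labelled with
the first criterion failed, which makes attrition decrements additive.
The targeted-therapy exclusion applies anywhere in the study period and
never counts ICIs or VEGF agents; the SCLC exclusion uses only
SCLC-predominant agents (topotecan, lurbinectedin) — etoposide, which
is also used in NSCLC, is classed as non-platinum chemotherapy.
Continuous enrollment requires medical *and* pharmacy coverage of every
day in [Dx − 180, index + 30]; the gap tolerance defaults to 0 days
(strictest reading) and is configurable.

### Line-of-therapy engine

Runout dates: pharmacy fills run out at fill date + days supply − 1;
infused drugs carry no days supply on claims, so they run out at
service date + a per-drug default of 21 days (the dominant cycle
length), configurable per drug. The regimen is the set of canonical
agents (substitution groups collapsed) starting within the 30-day
window [start, start + 29]. After the window, claim dates are evaluated
in order with the gap rule first: a start ≥ 60 days after the line's
maximum runout advances the line regardless of drug identity; the
advancement date is the new claim's start either way, so rule order
affects only the recorded end reason. Maintenance absorption is an
editable map: pemetrexed on a platinum backbone, ICI continuation on an
ICI or platinum backbone, bevacizumab on a chemotherapy backbone;
absorbed episodes extend the line's runout anchor but do not join the
regimen used for classification. A maintenance drug appearing *inside*
the 30-day window joins the regimen (the window rule is unconditional).

Classification maps the regimen's classes to seven categories: ICI
mono/dual (1–2 ICIs only), ICI + platinum chemotherapy, ICI +
non-platinum chemotherapy, platinum mono/combination (no ICI),
non-platinum monotherapy, non-platinum combination, and other. VEGF
agents are transparent when any chemotherapy is present; VEGF-only and
VEGF + ICI-only regimens fall to "other", as do regimens containing
targeted agents and ICI-only sets of three or more.

### Outcomes

All durations are inclusive day counts; months = days / 30.4375. The
day-count conventions (both ends inclusive; "day before" boundaries for
next-line truncation) are centralized in `duration_table`,
`ttnt_table` and `sact_period_table`. First-line duration ends at the
earliest of the line's maximum runout, the day before the second line,
or the end of follow-up (enrollment end, study end, or death); ends
imposed by follow-up or study end are censored, death counts as an
event. The pooled and per-category duration distributions are estimated
with the Kaplan–Meier product-limit estimator (lifelines); the median
is the smallest observed event time with S(t) ≤ 0.5, with no
interpolation, and is undefined if S never reaches 0.5. Mean TTNT is an
unadjusted arithmetic mean over patients with an observed second line.

### PPPM utilization and costs

The costing window (SACT period) runs from index to the earliest of
max runout + 30 days, the day before the second line, or follow-up end.
Utilization counts by setting: outpatient and ED visits are distinct
service dates (a drug administration and a facility claim on the same
day are one visit), inpatient admissions are maximal runs of adjacent
inpatient dates (an ED visit that leads to an admission counts in both
settings), pharmacy utilization is fill counts. Costs are paid amounts
multiplied by CPI(reference year)/CPI(service year) using the bundled
annual medical-care CPI series (reference year 2022), summed per
patient per setting; oncology drug administrations are outpatient
claims, so drug costs ride with the outpatient setting. Per-patient
values are divided by observed months first and then averaged
(ratio-of-patient-means, not pooled ratio). A claim is NSCLC-related if
any diagnosis position carries a C34 code or its drug is a lung-cancer
medication (any SACT class plus a configurable supportive list).

The baseline table flags nine comorbidities, metastasis sites and
smoking history (nicotine-dependence codes, known to under-ascertain
true smoking history) from claims in [index − 180, index − 1], and
computes the NCI-adapted Charlson index as a configurable weighted sum
over flagged conditions, never scoring the lung cancer itself.

## 2. Synthetic-data generator

The generator emulates the study conditions: a 2016–2023 study window
with 1L starts from 2020, the published first-line category mix (47.0%
ICI+platinum, 26.4% platinum mono/combo, 19.7% ICI mono/dual, remainder
spread over the minor categories), age ~ N(71.7, 8.6²) at index, 51.8%
male, 85.5% Medicare Advantage, comorbidity prevalences from the
published baseline table, a log-normal diagnosis-to-treatment delay
(median 1.5 months), and PPPM targets of 6.6 outpatient visits, 0.12
admissions, 0.11 ED visits, and $28,045/$3,412 outpatient/inpatient
cost. The published cost total of $32,215 leaves a $758 remainder that
the generator splits ED $254 / pharmacy $504; the pharmacy fill rate
(1.5 PPPM) and per-category duration medians are likewise package
choices, documented here because the source reports only a pooled
median (4.2 months) and a category range (2.7–6.5).

Mechanically, every emitted stream is rule-consistent with the LOT
engine: regimen drugs recur every 21 days with 21-day runouts (no
internal gap can reach 60 days), substitutions and maintenance are the
only within-line variations, and a second line is realized as a drug
that is neither in nor absorbable into the first-line regimen. The
generator's ground-truth table therefore *is* the correct output of the
algorithm, and the engine is required to recover it exactly (this
oracle-equivalence property is asserted at full scale in the test
suite).

Calibration is exact in expectation, not tuned:

- **Durations.** Intended 1L duration is log-normal (log-SD 0.55) with
  per-category medians {ICI+PBCT 4.6, PBCT 2.7, ICI mono/dual 6.5,
  ICI+non-PBCT 5.5, non-PBCT mono 2.7, non-PBCT combo 2.7, other 4.0}
  months, rescaled so the share-weighted mixture median solves (by
  Brent's method on the mixture CDF) to the 4.2-month target. Durations
  are realized as whole cycles, so the derived median snaps to the
  21-day grid (126 days = 4.14 months); acceptance tolerances carry a
  0.25-month band for this discretization.
- **Censoring.** Disenrollment is exponential past index + 31 days and
  *independent* of treatment duration, with its mean solved so the
  expected fraction disenrolling mid-line equals 0.25. An earlier
  design truncated enrollment uniformly within the treatment interval;
  that ties the censoring time to the event time, violates the
  product-limit estimator's independent-censoring assumption, and
  demonstrably biased the KM median upward by a full cycle, so it was
  replaced. Study-end censoring adds naturally on top (total censored
  ≈ 32% at defaults).
- **TTNT.** The delay from 1L runout to the 2L start is exponential; a
  second line sampled beyond the patient's follow-up is simply never
  observed (no claims, no truth entry). Naively setting the delay mean
  would therefore bias the observed mean TTNT low, so the mean is
  solved (Brent) such that the *expected observed* mean — integrating
  the fit probability patient by patient — equals 8.0 months. A
  consequence of follow-up truncation is that the observed 2L share
  (~14%) is below the nominal 40% second-line probability.
- **Visits and costs.** Outpatient visit dates are the cycle dates plus
  extra dates Poisson-drawn with rate (target × category multiplier ×
  months − cycle dates), making the expected distinct-date rate exactly
  the target; admissions use non-adjacent block placement so stays
  never merge; ED dates are sampled without replacement. Paid amounts
  are log-normal with mean-targeting parameterization (location =
  ln(mean) − σ²/2, σ = 1) per event, times a patient-level log-normal
  frailty of mean 1 (σ = 1) that reproduces the heavy cost tails
  (SD ≈ 1.4 × mean). Per-event means are target PPPM / event rate, so
  every cost target is exact in expectation. Amounts are written in
  nominal dollars (deflated by the CPI series), so the pipeline's
  inflation adjustment is exercised non-trivially. The NSCLC-related
  share of extra outpatient dates is solved so the pooled related
  fraction equals 74%.
- **Ineligible injection.** Eight roles each violate exactly one
  cascade criterion (no metastasis, no SACT, pre-2020 index, enrollment
  hole, SCLC agent between Dx and SM, targeted claim after index,
  pre-Dx metastasis, age < 18) at 1% apiece; the cohort stage must
  reproduce the injected per-criterion counts exactly.

What the generator does **not** emulate: realistic NDC/HCPCS coding
breadth, comorbidity-correlated costs or durations, per-category cost
multipliers (cost differences across categories follow visit rates
only, so the ICI-combination cost premium of the source is not
reproduced at category level), dose/units, death events, or a
calibrated NCI-CCI distribution (the score is computed but its mean is
not targeted). Passing tests therefore demonstrate correctness of the
*algorithms* under rule-consistent inputs and recovery of pooled
calibration targets — not robustness to the coding noise, claim-line
fragmentation and adjudication artifacts of real extracts, which the
reader should validate separately.

## 3. Numerical conventions and degenerate inputs

- Dates are ISO calendar dates; all arithmetic is integer days since
  epoch; no time zones.
- Enrollment spans merge when overlapping or abutting (next start ≤
  previous end + 1 + tolerance); merging preserves covered days.
- Duration day counts are inclusive at both ends; a 21-day cycle
  starting at index yields duration 21 × (number of cycles).
- The KM median convention (smallest event time with S ≤ 0.5) uses a
  1e-12 absolute tolerance on the 0.5 comparison.
- Ties between a pharmacy fill and an infusion on the index date are
  immaterial (minimum over the union).
- Empty datasets flow through every stage: zero-row tables, an
  attrition table of zeros, and header-only outputs.
- Malformed rows (unparseable dates, negative paid amounts, invalid
  settings, days supply < 1, duplicate or orphan ids) are rejected and
  counted per (table, reason); unresolvable drug codes are fatal
  because they could hide systemic therapy.
- Claims postdating death or disenrollment are tolerated (dirty-data
  reality); the engine bounds lines by follow-up instead of trusting
  claim streams to stop.

## 4. Problem sizes used by the test suite

Unit and property tests run on hand-built patients and a shared
400-patient generated cohort; the end-to-end suite runs one full-size
cohort (15,659 patients, seed 42), which generates in ~11 s and flows
through the complete pipeline in ~25 s on one CPU. The acceptance
script regenerates everything from scratch at the same size. The
product-limit estimator is cross-checked against a from-scratch naive
risk-set implementation on 100 random censored samples (n ≤ 50), and
substitution invariance is asserted by swapping cisplatin/carboplatin
claims for 1,000 randomly chosen patients.
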