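# Methods

## Phenotype definition

Systemic inflammation (SI) is an eligible C-reactive protein (CRP)
measurement ≥ 2 mg/L (inclusive).  Eligibility removes CRP values whose
elevation plausibly reflects something other than chronic vascular
inflammation:

| rule | excluded when | window semantics |
|---|---|---|
| pre-ASCVD | test date strictly before the first ASCVD diagnosis | a test on the diagnosis day is retained |
| active infection | value > 20 mg/L (strict), or an antibiotic/antiviral prescription at *p* with *p* ∈ [*t* − 60, *t* + 7] days | both ends inclusive |
| immunosuppressant | prescription at *p* with 0 ≤ *t* − *p* < 90 days | "less than 3 months after": far end exclusive, one-sided |
| active cancer | malignancy diagnosis (non-melanoma skin cancer excepted) at *d* with 0 ≤ *t* − *d* < 1095 days | far end exclusive |

Calendar-unit windows are fixed-day approximations (2 months = 60 d,
3 months = 90 d, 3 years = 1095 d, 12 months = 365 d, 18 months = 548 d),
all configurable.  Rules are labelled in the order above — each raw CRP
receives exactly one label, so label counts reconcile with the raw count —
but retention is the conjunction, so ordering cannot change the retained
set.

Eligible measurements within 90 days are grouped greedily: the earliest
ungrouped measurement anchors a group absorbing everything dated within
[anchor, anchor + 90 d]; the grouped value is the geometric mean of the
members.  The anchor's date is carried as the record date.  Greedy
anchoring is deterministic and invariant to input order; whether the
original analysis dated a group at its first member, last member or mean
date is not documented anywhere we know of, so the anchor-date choice is an
explicit assumption here.  A CRP of exactly 0 mg/L is rejected at parse
time (assay floor; the geometric mean is undefined at zero).

The index date is the anchor of the patient's first grouped record.  The
cohort comprises patients with ≥ 1 ASCVD diagnosis, no chronic-infection
diagnosis ever (HIV, tuberculosis, viral hepatitis), age ≥ 18 at index, and
≥ 1 eligible grouped CRP.  The attrition flowchart reports ASCVD
identification, the chronic-infection exclusion, the ≥ 1-CRP step and the
final cohort; because age eligibility is anchored at the index date (which
only exists once eligibility has run), the under-18 exclusion is applied
between the last two steps rather than in the second.

## Renal classification

eGFR always comes from the 2021 CKD-EPI creatinine refit (no race term):
`142 · min(Scr/κ,1)^α · max(Scr/κ,1)^−1.200 · 0.9938^age · 1.012[female]`,
κ = 0.7/0.9 and α = −0.241/−0.302 for females/males.  It is computed on
the fly from stored creatinine (age taken at the measurement date), keeping
the equation a single source of truth.

CKD at a reference date: stage ≥ 3 diagnosis code on/before the date, OR
most recent prior eGFR < 60, OR most recent prior UACR ≥ 30 mg/g.
"Most recent prior" is current-status semantics, matching a
point-prevalence design; an `egfr_any_historical` switch provides the
any-value-ever alternative, and both are tested.  Whether the original
analysis required the KDIGO chronicity criterion (two qualifying values
≥ 90 days apart) is unstated; single-measurement semantics is implemented.
Status is `no-CKD` only when at least one eGFR-evaluable creatinine exists;
with neither creatinine nor a CKD diagnosis the status is `unknown` and the
patient forms a third stratum (never silently merged).  Stage uses the
KDIGO eGFR bands — < 15, [15, 30), [30, 60) — plus stage 1/2 for
eGFR ≥ 60 with UACR ≥ 30; a diagnosis code without any eGFR stages as
`unknown`.

## Prevalence estimands

All three are numerator/denominator proportions with Wilson 95% intervals
(the artifact reports intervals even though observational summaries often
omit them; Wilson behaves well near 0 and 1).  Point prevalence keeps
patients alive at the cutoff (no death date, or one after it) with a
grouped CRP anchored in the prior 548 days, judging SI on the most recent
such record (`point_any_in_window` switches to "any in window").
Zero-denominator strata are undefined and omitted — never reported as 0.
Stratum numerators and denominators always sum to their parent's, and the
period numerator contains the index numerator by construction; both
properties are enforced in tests.  The sensitivity analysis recomputes all
estimands after dropping patients with any inflammatory/rheumatoid
diagnosis before index.

## Characterization

Baseline labs/vitals: most recent value in [index − 548 d, index) — a
measurement on the index day is outside the window.  Smoking and SES use
the most recent observation on or before index, with no lookback cap.
Comorbidities: any matching code strictly before index; the cancer
comorbidity requires the code > 1095 days before index (more recent codes
make the CRP itself ineligible).  Drug exposure: [index − 365 d, index)
pre-index, (index, index + 365 d] post-index; the index day belongs to
neither, avoiding double-counting.  Group comparisons default to
chi-squared (categorical), Welch t (approximately normal), and Wilcoxon
rank-sum (skewed: CRP, UACR, triglycerides); the source analysis never
names its tests, so these defaults are assumptions, flagged in the table
footer.  No multiple-testing correction is applied; p-values are
descriptive.

## Code lists

ICD-9 and ATC are prefix-hierarchical, so concepts are sets of code
prefixes with `startswith` semantics (adding a prefix can only enlarge the
matched set).  The shipped lists in `codes.py` are illustrative defaults,
not validated phenotypes; any concept can be overridden in the `code_lists`
configuration section.

## Synthetic-data generator

The generator emulates the structure the pipeline assumes, with exported
ground truth for recovery tests.  What it does model:

* log-normal baseline CRP per CKD stratum — medians 2.9 (CKD) / 2.2
  (non-CKD) mg/L, marginal log-sd 1.03 (from an IQR of 1.2–4.8 around a
  median of 2.4: ln(4.8/1.2)/(2·0.6745)) — split into a per-patient random
  intercept (sd 0.7) and within-patient noise, because CRP tracks a
  patient's chronic inflammatory state; baseline values are drawn truncated
  at 20 mg/L so values above the infection cap arise only from infection
  episodes;
* sparse irregular testing (0.25 tests/year after the first ASCVD
  diagnosis; CRP is not routine in primary care), with 15% of patients
  carrying an additional pre-ASCVD test;
* infection episodes (0.15/year) that emit an antibiotic prescription and
  force every CRP test inside the episode's eligibility window above
  20 mg/L, flagged in ground truth, so the engine's recall is testable;
* CKD induced mechanistically: target eGFR drawn per true stage with a
  safety margin from the 15/30/60 edges, inverted through the 2021 equation
  into creatinine (±1.5% noise), UACR ≥ 30 for stage-1/2 patients and < 30
  for non-CKD patients; 6% of patients carry no renal data at all and are
  expected to classify `unknown`;
* demographics near the target population (age 71 ± 12 at first ASCVD,
  57% male, 32% CKD), comorbidity/drug-class prevalences near the published
  marginals, an annual mortality hazard of 4%, and SES/smoking fields.

Ground truth records each patient's true stratum and a true
SI-at-first-eligible indicator computed from the un-inflated post-ASCVD
values with an independently coded copy of the 90-day geometric-mean
bookkeeping.  With trigger processes disabled the pipeline's view of the
data coincides with the generator's, so index-SI recovery is exact up to
classification of patients lacking renal data; acceptance tests assert
recovery within three binomial standard errors on 50,000 patients.

What it does **not** model: treatment response, realistic coding noise,
seasonal infection patterns, correlation between CKD and age/comorbidities
beyond the CRP stratum means, or informative CRP testing (testing is
independent of patient state).  Passing recovery tests therefore
demonstrates the correctness of the pipeline's logic under the stated
assumptions — not the realism of any particular prevalence figure for a
real population.

## Problem sizes and numerics

Tests run the generator at 250–5,000 patients (20 seeds for trigger-recall)
and one 50,000-patient cohort for parameter recovery; the acceptance script
uses 20,000 patients.  All window arithmetic is in whole days on epoch day
numbers; interval membership uses sorted-array bisection, checked
record-for-record against an O(n·m) pairwise oracle.  Geometric means are
computed as exp(mean(log)); grouped CRP values are rounded to 0.01 mg/L at
generation so file round-trips are exact.  Degenerate inputs: empty strata
are omitted; a constant variable yields a missing p-value; an empty cohort
yields an all-zero flowchart.

## Known limitations

* Fixed-day approximations of calendar-unit windows can differ from
  calendar-month arithmetic by up to two days around month boundaries.
* No distinction between standard and high-sensitivity CRP assays (the
  source data does not record it).
* The default code lists are illustrative; results on real data depend
  entirely on locally validated lists.
* Single-measurement CKD semantics (no chronicity requirement) may
  overestimate CKD relative to KDIGO-strict definitions.
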