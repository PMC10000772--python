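# Methods

## Setting and data model

The package analyzes four longitudinal tables linked by an anonymous
patient ID, mirroring the administrative flows of an Italian Local Health
Unit: demographics (birth date, sex, enrollment interval, death, optional
transfer-out date), pharmacy dispensations (ATC code, date, packages ×
units, cost), hospital discharges (admission/discharge dates, ICD-9-CM
diagnoses, DRG code and tariff) and outpatient services (date, type,
tariff). All monetary values are euros from the payer's perspective;
internally money is held in integer cents so item costs always sum to
totals exactly.

## Cohort construction

Adults (≥18 years at the first ART dispensation) with at least one `J05A*`
dispensation in the inclusion window (default 2015-01-01 – 2019-12-31) are
screened. Exclusions, applied in order: a single ART dispensation ever; any
gap between consecutive ART dispensations above 365 days; a transfer-out
flag in demographics. The index date is the first TAF-containing
dispensation in the window; follow-up runs to the end of enrollment (death
truncates it). A patient is *naive* when no ART dispensation falls in the
half-open look-back `[index − 365 d, index)` — a same-day dispensation never
voids naive status — otherwise a *switcher*. The regimen subtype is fixed by
the index dispensation's ATC: the four complete fixed-dose combinations
(`J05AR18/19/20/22`) are single-tablet regimens, while TAF alone
(`J05AF13`) and the FTC/TAF backbone (`J05AR17`) imply concomitant third
agents, i.e. multi-tablet regimens. Later MTR→STR changes do not relabel.

Baseline comorbidities (depression, respiratory disease, renal failure,
alcohol/drug abuse, cardiovascular disease, cancer, diabetes, dyslipidemia,
HBV/HCV, hypertension) are flagged from any matching ATC or ICD-9-CM code
in the look-back year. The code lists in `config.py` are deliberately
configuration, not constants: claims studies differ in their operational
definitions, and the shipped defaults are a conventional, editable choice.
The comorbidity score is a Charlson index on look-back discharge diagnoses
using a compact Deyo ICD-9-CM category table, hierarchical (metastatic
disease supersedes non-metastatic malignancy, severe supersedes mild liver
disease, complicated supersedes uncomplicated diabetes), with the HIV/AIDS
item weighted 0 — in an all-HIV cohort the infection itself must not
contribute to the comorbidity burden.

Two age-class systems are stored per patient: <36 / 36–55 / >55 for
characterization tables and ≤50 / 51–65 / >65 for the cost model.

## Adherence (PDC)

Each dispensation supplies `n_packages × units_per_package` days of
therapy, i.e. once-daily dosing — the modern ART convention. Coverage is
the carry-forward union of supply intervals: a refill starts at its
dispensation date or at the end of the previous supply, whichever is later,
so early refills bank stock rather than being discarded. Day 0 is the index
date; all intervals are half-open; PDC = 100 × covered days / window days,
capped at 100 (the cap matters only under oversupply). The default window
is the fixed 365-day first year (truncated at death, with the patient
flagged censored); the same machinery serves any window length. Adherence
flags use strict inequalities (PDC > 95, PDC > 85) and the three strata
partition [0, 100] as ≤80, (80, 95], >95 — the middle stratum is taken as
(80, 95] so no value is unassigned.

A consequence worth stating: PDC is computed on TAF-class coverage over the
full window for every patient, so patients who switch away from TAF or
discontinue mid-year are mechanically low-PDC. Cohort-level "adherent"
shares therefore mix adherence behavior with persistence; the per-patient
target-PDC recovery tests condition on persistent patients for exactly this
reason.

## Persistence, switch, discontinuation

The evaluation window is the last quarter of the first follow-up year, days
[274, 365) after index (for censored patients, the last quarter of the
available follow-up). *Discontinued*: no ART dispensation date in the
window. *Persistent*: a TAF-class dispensation date in the window.
*Switched*: ART but no TAF in the window; the switch date is the first
non-TAF ART dispensation after the last TAF dispensation. The three labels
are exhaustive and mutually exclusive by construction. Two documented rule
switches exist: `persistence_rule="coverage_in_window"` counts a
dispensation whose supply interval overlaps the window (not just its date),
and `quarter_basis="all_followup"` evaluates the last quarter of all
available follow-up instead of year 1. Defaults are date-in-window and
first-year; both alternatives are tested.

## Resource use and costs

Five items per patient and window: ART dispensations (HIV-related drugs),
non-ART dispensations, HIV-related hospitalizations (DRG 488/489/490),
other hospitalizations (unknown DRGs fall here, logged), outpatient
services. Windows: `first_year` (fixed 365 days, person-years = 1, patients
who die or exit before day 365 are excluded — means are over alive
patients) and `all_followup` (exact person-years = days/365.25, patients
who die during follow-up excluded). Outlier handling is a single pass on
the analysis population before any stratification: compute mean and sample
SD (ddof = 1) of annualized total cost, drop patients strictly above
mean + 3·SD, never re-iterate. Stratified tables report per-item mean/SD
and Welch two-sample p-values for two-group comparisons.

## Inference

Non-ART cost = annual total minus annual HIV-drug cost. The cost model is a
gamma GLM with identity link — variance proportional to the squared mean,
coefficients in EUR — with predictors adherence stratum (reference ≤80),
age class (reference ≤50) and the Charlson score as a continuous integer.
Zero responses are shifted by EUR 1 by default (`zero_rule="exclude"` is
the alternative) since the gamma family requires positivity. Fitting is
IRLS (statsmodels) started from the OLS solution to keep early iterations
in the positive-mean region; convergence tolerance 1e-10, at most 200
iterations; non-positive fitted means raise rather than silently returning
estimates, because the identity link offers no positivity guarantee. The
test suite cross-checks the IRLS solution against direct numerical
minimization of the gamma deviance (BFGS with analytic gradient) to 1e-6 —
valid because gamma-GLM coefficient estimates do not depend on the
dispersion. Group comparisons use Welch's unequal-variance t-test; with
zero variance in both groups and equal means the p-value is defined as 1.

## Synthetic-claims generator

The generator is first-class, tested code that defines the study
conditions, not a tuning dial. Defaults encode the reference cohort's
margins: 2658 ART patients of which ~45% TAF-treated (≈1198), 71.6% male,
age 48.6 ± 11 y truncated to [19, 90], comorbidity prevalences between 1.3%
(renal failure) and 19.5% (hypertension), STR share 57.1% and naive share
39.9% among TAF patients, persistence/switch/discontinuation planted at
78.5 / 17.5 / 4.0%, and a per-patient target-PDC mixture with 83.3% of mass
above 0.95 and 90.6% above 0.85. HIV-admission intensities differ by
persistence label (0.088 vs 0.102 admissions/person-year, per-admission
tariff means EUR 2448 vs 5996), which plants the persistence-dependent
HIV-hospitalization cost gap the cost analysis is meant to detect.

Mechanics, per patient (randomness is split with
`numpy.random.SeedSequence`: patient *i* uses child stream *i* of the
master seed, so any patient is reproducible in isolation and tables are
byte-identical across runs):

- Refills follow a renewal process: each 30-day supply is followed by a
  geometric number of uncovered days with mean `30·(1−p)/p`, which makes
  the long-run covered fraction equal the target PDC *p* (floored at 0.05).
- Persistent patients refill through the whole follow-up; if the gap
  process leaves the last quarter of year 1 without a dispensation date,
  one refill is placed there. Without this guarantee, low-target patients
  would be misclassified at a few-percent rate and ground-truth labels
  would not be recoverable; the price is a slight upward bias of realized
  PDC for low-target persistent patients.
- Switch-labelled patients stop TAF at a uniform day in [90, 240] and start
  a non-TAF combination 10–60 days later (continuing into the last
  quarter); discontinuation-labelled patients stop all ART at a uniform day
  in [90, 240], safely before day 274.
- Experience switchers carry a monthly non-TAF refill history through the
  look-back year ending 5–40 days before index; naive patients have none.
- Comorbidity evidence is emitted in the look-back year as drug
  dispensations (75% of the time, when the condition has an ATC signature)
  or as a hospitalization with the matching ICD-9-CM diagnosis; cancer
  evidence is metastatic 15% of the time.
- Non-ART drugs (10/PY), other admissions (0.05/PY), outpatient services
  (8/PY) and HIV admissions are Poisson; all tariffs and costs are gamma
  with per-item shape/scale (EUR). Drug-acquisition costs per ART
  dispensation are high-shape (low variance) gamma with mean ≈ EUR 640,
  which makes ART ≈ 70% of total spending.
- Mortality is exponential at 0.01/PY (censoring deaths), 1% of patients
  transfer out (exercising the exclusion rule), and dispensation pack sizes
  are 1 × 30 units. Pack size and refill cadence are stated assumptions of
  the generator, not facts about any real extraction.

### What the generator does and does not emulate

It reproduces marginal demographics, comorbidity prevalences, regimen mix,
planted utilization labels, and gamma-tailed cost structure — enough for
classification, accounting and recovery properties to be meaningful. It
does **not** model correlation between adherence and regimen type or
experience (real STR users are more adherent), seasonal or calendar trends
in costs, regional tariff heterogeneity, dose changes, or informative
censoring; passing tests therefore demonstrate correctness of the
algorithms under known conditions, not that real-world effect sizes will
match.

## Numerical and design choices

- Half-open day arithmetic everywhere; day 0 = index date.
- PDC denominator fixed at 365 days for first-year analyses (full
  follow-up for all-follow-up analyses); "days of therapy" has no other
  self-consistent reading that keeps the three status labels disjoint.
- Interval union is cross-checked against an independent day-by-day
  inventory simulation (bank supply, consume one unit per covered day);
  the two agree exactly on random streams, including pre-index
  dispensations (ignored) and window truncation.
- Outlier trim is single-pass by design; re-iterating would change the
  estimand.
- The GLM reference classes are adherence ≤80 and age ≤50.
- Inclusion-year strata use the calendar year of the index date, so each
  patient belongs to exactly one year; an "active-in-year" view would
  overlap years and break the disjoint-strata requirement of cost
  comparisons.
- Problem sizes in the test suite (cohorts of 400–5000, 20-seed recovery
  runs, 1000 oracle streams) were chosen as the smallest sizes at which the
  binomial/SE-based checks have comfortable margins.

## Known limitations

- ICD-9-CM only; no ICD-10 mapping.
- The Charlson table is compact (prefix-based); borderline codes in rare
  categories may differ from full published implementations.
- Identity-link gamma fits can fail on designs where negative linear
  predictors are attainable; the package surfaces this as an error rather
  than switching links silently.
- Indirect and out-of-pocket costs are out of scope; only payer-reimbursed
  flows are modeled.
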