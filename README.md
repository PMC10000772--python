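# artclaims

Drug-utilization and direct healthcare-cost analysis of antiretroviral
therapy (ART) from linked administrative-claims tables, focused on
tenofovir-alafenamide (TAF)-based regimens, with a synthetic-claims
generator so the whole pipeline runs end-to-end with known ground truth and
no access to real payer data.

## Who this is for

Pharmacoepidemiologists and health-economics analysts working with
administrative databases of the kind Italian Local Health Units maintain:
a demographic registry, a pharmacy-dispensation flow (ATC codes, packages,
costs), a hospital-discharge flow (ICD-9-CM diagnoses, DRG and tariff) and
an outpatient-services flow, all linked by an anonymous patient ID. The
package implements the standard analysis battery for such data:

- **Cohort construction** — screen adults (≥18 y) with ART (ATC `J05A*`)
  dispensations in an inclusion window; exclude patients with a single
  dispensation, an inter-dispensation gap > 12 months, or a transfer out of
  the catchment area; index at the first TAF-containing dispensation
  (`J05AF13`, `J05AR17`–`J05AR22`); label regimens single- vs multi-tablet
  (STR/MTR) and prior-therapy status naive vs switcher on a half-open
  365-day look-back; flag ten baseline comorbidities and score a modified
  Charlson index (Deyo ICD-9-CM mapping, HIV item weighted 0).
- **Adherence** — proportion of days covered,
  `PDC = 100 · covered days / days in window`, from a carry-forward union of
  supply intervals (early refills bank supply); adherent at the strict
  thresholds PDC > 95% and PDC > 85%, stratified ≤80 / (80, 95] / >95.
- **Persistence** — judged on the last quarter of the first follow-up year
  (days [274, 365) after index): *discontinued* if no ART dispensation in
  the window, *persistent* if a TAF dispensation is present, otherwise
  *switched* (ART without TAF); changes between TAF products are not
  switches.
- **Costs** — five annualized items (HIV drugs, other drugs, HIV
  hospitalizations = DRG 488/489/490, other hospitalizations, outpatient
  services), cent-exact accounting, single-pass mean + 3·SD outlier trim,
  stratified by persistence / adherence / inclusion year with Welch
  comparisons.
- **Inference** — a gamma GLM with identity link for annual non-ART cost,
  `E[y] = β₀ + β·adherence + β·age-class + β·CCI`, fitted by IRLS so
  coefficients read directly as EUR differences.

## Worked example

```python
import artclaims as ac

cfg = ac.GeneratorConfig(n_patients=500, seed=7)
tables = ac.generate_cohort_tables(cfg)          # 4 linked tables + truth
spec = ac.CohortSpec()
res = ac.build_cohort(tables, spec)
print(res.attrition)
util = ac.compute_utilization(res.cohort, tables, spec)
print(ac.summarize_utilization(util, res.cohort).round(1))
```

prints

```
{'screened': 500, 'excluded_single_prescription': 1, 'excluded_transfer': 4,
 'art_retained': 495, 'taf_cohort': 226}
   group   n  adherent_95_pct  adherent_85_pct  persistent_taf_pct  persistent_any_art_pct  persistent_pct  switched_pct  discontinued_pct
 overall 226             65.0             71.7                81.0                    95.6            81.0          14.6               4.4
     MTR  96             67.7             75.0                84.4                    96.9            84.4          12.5               3.1
     STR 130             63.1             69.2                78.5                    94.6            78.5          16.2               5.4
   naive  84             69.0             72.6                84.5                    96.4            84.5          11.9               3.6
switcher 142             62.7             71.1                78.9                    95.1            78.9          16.2               4.9
```

Of 500 generated ART patients, 495 survive the exclusion rules and 226 form
the TAF cohort. 81% are persistent (TAF dispensing in the last quarter of
year 1), 95.6% stay on *some* ART, and the persistent + switched +
discontinued shares sum to 100 by construction. Note that `adherent_95_pct`
is computed over the full fixed 365-day window for *everyone*, so patients
who switch or discontinue mid-year necessarily sit in the low-PDC strata.

Continuing with costs:

```python
costs = ac.tally_resources(res.cohort, tables, spec)      # first year
trimmed = ac.exclude_outliers(costs)                      # mean + 3·SD trim
lab = util.set_index('patient_id')['status'].eq('persistent') \
          .map({True: 'persistent', False: 'non_persistent'})
print(ac.stratify_costs(trimmed.retained, lab).round(1))
```

gives mean annual HIV-hospitalization costs of EUR 289 (persistent, n=182)
vs EUR 588 (non-persistent, n=42) — the generator plants a higher
HIV-admission rate and tariff for non-persistent patients, and the pipeline
recovers the gap.

The same stages are available from the shell:

```bash
artclaims simulate --out data/ --seed 1 --n-patients 1000
artclaims run --data data/ --out run/
```

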