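# dyadscan

Case-control **family-history transmission-pattern analysis** with a
verifiable synthetic-cohort simulator.

Given a per-subject cohort table (case/control status, sex, parental
dementia history, parental birthplaces, APOE genotype, covariates and
optional CSF biomarkers), dyadscan provides:

* **Dyad analysis** — for each parent-category × offspring-sex dyad
  (father→son, mother→daughter, …) the exposure ("affected parent")
  2×2 table, risk/odds ratios with Wald CIs, and pairwise dyad contrasts
  through the relative ratio Φ with a normal-deviate z test
  (`z = ln(Φ) / sqrt(v₁ + v₂)`), used to probe X-/Y-linked transmission.
  Subjects with both parents affected are excluded from these univariate
  tables.
* **Consanguinity proxy** — a same-birthplace flag for the parental pair
  (exact string equality after casefold/trim/diacritic stripping;
  neighbouring but distinct places count as different), group descriptives
  and APOE-homozygosity comparisons by birthplace concordance.
* **Regression stages** — OLS endophenotype models (age of onset, CSF
  Aβ42, t-tau, p-tau) in female cases with CSF data, and a logistic AD-risk
  model (sex, age, education, APOE ε4 carriership, same-town flag) fitted
  by an in-house IRLS with deviance trace and Nagelkerke R².
* **Synthetic cohorts** — a generative model with X-linked, Y-linked,
  autosomal-recessive/consanguinity and null scenarios: Mendelian
  transmission, X-inactivation attenuation (λ), inbreeding-inflated
  homozygosity (`q² + F·q(1−q)`), logistic liability shared between parents
  and offspring, and case/control ascertainment (controls unaffected and
  older than 75).
* **Calibration harness** — Monte-Carlo type-I-error / power estimation of
  the dyad-comparison test on any scenario preset.

## Input format

CSV or TSV, UTF-8, header row, `NA` for missing (never blank — "no" and
"unknown" are distinct answers). Mandatory columns: `subject_id`,
`status` (case/control), `sex`, `age_at_assessment`, `paternal_history`,
`maternal_history` (yes/no/unknown), `father_birthplace`,
`mother_birthplace`. Optional: `age_of_onset`, `education`,
`year_of_birth`, `n_siblings`, `siblings_with_dementia`, `apoe`
(e.g. `e3/e4`), `csf_abeta42`, `csf_ttau`, `csf_ptau`, `age_at_lp`.
The machine-readable schema ships as `src/dyadscan/schema.json`
(`dyadscan schema` prints it).

## CLI

```bash
# simulate a cohort (presets: null, x_linked, y_linked,
# recessive_consanguinity, paperlike)
dyadscan simulate --scenario paperlike --seed 42 --out synth.tsv

# eligibility filters + audit log
dyadscan filter --input synth.tsv --out filtered.tsv --log filters.json

# dyad-comparison matrix (TSV mirroring the published layout + JSON twin)
dyadscan dyads --input synth.tsv --mode rr --variance woolf --out matrix.tsv

# group descriptives / regressions
dyadscan describe --input synth.tsv --grouping case_vs_control --out desc.json
dyadscan models --input synth.tsv --which both --out fits.json

# full pipeline (simulate or ingest; all reports + run log)
dyadscan run --scenario paperlike --seed 1 --out-dir out/

# Monte-Carlo calibration of the dyad test
dyadscan calibrate --scenario null --alpha 0.05 --reps 2000 --seed 1
```

Exit codes: 0 ok, 2 validation error, 3 degenerate statistics. Existing
outputs are never overwritten without `--force`.

## Python API

```python
from dyadscan import (
    read_cohort, apply_control_eligibility, dyad_matrix, TABLE2_SPECS,
    fit_endophenotype_models, fit_ad_logistic,
    scenario_preset, generate_cohort, calibrate,
)

cohort = apply_control_eligibility(read_cohort("cohort.tsv"))
matrix = dyad_matrix(cohort, TABLE2_SPECS, mode="risk_ratio")
print(matrix.to_frame())
```

Φ is a ratio of **risk ratios** by default (matching the published
tables); odds-ratio mode and both variance rules (`paper_literal`,
`pooled_woolf`) are available — for odds ratios the two rules coincide
algebraically (the Woolf identity, covered by tests).

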