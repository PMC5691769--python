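# cohortsom

Nutritional cohort subtyping pipeline: from a per-participant cohort table
(demographics, anthropometry, biochemistry, three-day food-group intakes,
derived nutrients, socio-economic categories, baseline/follow-up anemia
status) to age-matched case-control subsets, a correlation-network-matched
training set, a self-organizing-map (SOM) subtyping of nutritional profiles
with bootstrap subgroup statistics, univariate anemia associations, and
iron-fortified soy sauce what-if scenarios. A seeded synthetic-cohort
generator with ground-truth subgroup labels makes every stage testable
without access to the original (undeposited) survey data.

## Modules

| Module | Purpose |
| --- | --- |
| `cohortsom.synthetic` | Seeded synthetic cohorts: four nutritional archetypes (bundled defaults from the published subgroup profile), sex-specific hemoglobin, archetype-specific 5-year anemia incidence, covariate-shifted loss to follow-up |
| `cohortsom.cohort` | Cohort schema, CSV I/O with validation, derived flags (anemia 130/120 g/L, low iron 20/12 mg/day, obesity, hypertension, diabetes, IDF-2005 metabolic syndrome), income encoding, per-sex height calibration |
| `cohortsom.matching` | Greedy age-balanced control selection per sex stratum; greedy nearest-neighbour training-set pairing in standardized module-PC space with balance testing |
| `cohortsom.network` | Sex-weighted Spearman correlation network, maximum spanning forest on absolute weights, agglomerative modularity modules, per-module PC1/PC2 scores |
| `cohortsom.stats` | Age residualization, sex-stratified testing with Fisher combination, number-weighted descriptives, Benjamini-Hochberg FDR, adjusted logistic models, epidemiological rate helpers |
| `cohortsom.som` | Within-sex rank normalization, batch SOM (Gaussian neighborhood, shrinking radius), BMU assignment, map colorings, K contiguous subgroups, 10,000-rep bootstrap summaries |
| `cohortsom.fortification` | Added iron per mg/mL fortification level (soy sauce at 1.12 g/mL) and per-subgroup low-iron prevalence deltas |
| `cohortsom.reference` | Printed study counts and the subgroup profile table used as defaults |

## CLI

```bash
cohortsom generate --n 2500 --seed 1 --out cohort.csv --truth truth.csv
cohortsom derive --in cohort.csv --out derived.csv
cohortsom match --mode case-control --in derived.csv --out match.json
cohortsom univariate --in derived.csv --match match.json --out table.csv
cohortsom network --in derived.csv --out-prefix net
cohortsom som train --in derived.csv --out model.json --seed 0
cohortsom som evaluate --in derived.csv --model model.json --out membership.csv
cohortsom som summary --in derived.csv --membership membership.csv --out summary.csv
cohortsom fortify --in derived.csv --membership membership.csv --level 4.0 --out scenario.csv
```

`generate` also accepts `--config cfg.yaml` (keys: `n_participants`,
`seed`, `female_fraction`, `age_range`, `hb_mean_sd_by_sex`,
`ferritin_lognormal_params`, `loss_to_followup`, `trait_correlations`,
`archetypes`).

## Data notes

- Hemoglobin is g/L internally (anemia below 130 g/L men / 120 g/L women,
  strict); readers accept `hemoglobin_unit="g/dL"`.
- Low iron intake: below 20 mg/day for women aged 18-49, below 12 mg/day
  otherwise (strict).
- Income levels encode to 1000 / 3500 / 5000 Yuan/person.
- The cohort CSV column dictionary is documented in
  `cohortsom/cohort.py` (`REQUIRED_COLUMNS`, `OPTIONAL_COLUMNS`,
  `CATEGORICAL_VOCABS`).
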