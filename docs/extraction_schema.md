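# Input schemas

All inputs are UTF-8 delimited text (comma by default) with a header
row. `metaepi validate` checks them and lists every violation with row,
column and rule; validation never modifies the files.

## Study-level table (`studies.csv`)

One row per experimental arm (comparison) inside a meta-analysis.

| column | required | meaning |
|---|---|---|
| `ma_id` | yes | meta-analysis identifier; must exist in `mas.csv` |
| `study_id` | yes | study identifier (cluster key for the robust analysis) |
| `arm_id` | yes | arm identifier; (`ma_id`, `study_id`, `arm_id`) must be unique |
| `smd` | with `var`/CI | standardized mean difference as published |
| `var` | one of three | sampling variance of the SMD |
| `ci_low`, `ci_high` | one of three | 95% Wald CI of the SMD |
| `mean_t, sd_t, n_t, mean_c, sd_c, n_c` | one of three | arm-level summaries; SMD (Hedges' g) computed from them |
| `rob_<characteristic>` | optional | risk-of-bias rating: `low`, `high`, `unclear`, `not_assessed`/`NA` (case-insensitive, normalized) |
| `shared_control` | optional | flag; informational |

Exactly one effect-size source is used per row, resolved in the order
explicit `var` → CI → arm summaries (a row with both `var` and a CI
keeps `var` and logs a warning).

The ten `rob_` characteristics: `randomization`, `baseline_similarity`,
`allocation_concealment`, `random_housing`, `blinding_caregivers`,
`blinding_model`, `random_outcome_assessment`, `blinding_assessors`,
`attrition`, `selective_reporting`.

## Meta-analysis table (`mas.csv`)

One row per meta-analysis.

| column | required | meaning |
|---|---|---|
| `ma_id` | yes | identifier |
| `expected_direction` | yes | `benefit_positive`, `benefit_negative` or `unclear` |
| `design` | optional | `therapeutic` or `pathophysiology` (stratification) |
| `topic` | optional | free text |

## Review-level table (for `metaepi summarize`)

One row per systematic review; columns are the audit variables
(categorical levels, `True`/`False` indicator columns for multi-select
items, numeric columns for counts/impact factors). A TOML table spec
declares, per output table, the variables, their kind
(`categorical`/`multiselect`/`numeric`) and an optional nested
`denominator` column ("among those reporting X"); every output cell
carries its own count and denominator.
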