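# metaepi

Two-step meta-epidemiological analysis of preclinical meta-analyses:
does the risk of bias of animal studies change the effect sizes they
report?

## The problem

Systematic reviews with meta-analyses of preclinical (animal) studies
pool standardized mean differences (SMDs) from many small experiments.
If poorly conducted studies — no randomization, no blinding, unexplained
attrition — systematically report larger effects, the pooled results of
those reviews are inflated. Meta-epidemiology quantifies this: for each
methodological characteristic (rated *low*, *high* or *unclear* risk of
bias per study, following the SYRCLE items for animal research), it asks
whether studies at high/unclear risk report different SMDs than studies
at low risk, across a whole corpus of meta-analyses.

## The model

The package implements the standard two-step approach:

**Step 1 — within each meta-analysis.** SMDs are first aligned so a
positive value means benefit in the expected direction. For one
characteristic, each experimental arm is labelled x = 1 (study rated
high or unclear) or x = 0 (low). A random-effects meta-regression

y_i = β₀ + β₁·x_i + u_i + ε_i,  u_i ~ N(0, τ²_res),  ε_i ~ N(0, v_i)

is fitted by weighted least squares with weights 1/(v_i + τ²_res)
(τ²_res by REML, DerSimonian–Laird selectable). The slope β₁ is the
**difference in standardized mean difference (DMSD)**: high/unclear
minus low. A meta-analysis is eligible if it has ≥ 3 rated studies with
at least one in each group.

**Step 2 — across meta-analyses.** The per-meta-analysis DMSDs are
pooled by random-effects meta-analysis with weights 1/(se²_k + τ²),
provided at least 10 meta-analyses are eligible for the characteristic;
otherwise the characteristic is skipped. A positive pooled DMSD means
studies at high or unclear risk of bias report larger effects.

**Sensitivity analysis.** Multiple arms of one study are dependent
(shared animals, shared control group). The robust variant replaces the
step-1 standard errors by CR2 cluster-robust (sandwich) estimates
clustered on study, with Satterthwaite degrees of freedom.

Because the extraction datasets behind published analyses of this kind
are rarely public, the package ships a calibrated synthetic-data
generator (`metaepi.synthetic`) that emulates the corpus structure —
63 meta-analyses, median 9 studies each, multi-arm studies sharing
split control groups, median per-meta-analysis I² ≈ 77%, realistic
rating prevalences — with a known injected bias effect δ, so every
pipeline stage is testable against ground truth.

## Worked example

```python
from metaepi import MetaEpidemiologyModel, SimulationConfig, simulate_dataset

cfg = SimulationConfig(delta={"randomization": 0.3})   # inject a bias effect
studies, mas, truth = simulate_dataset(cfg, seed=42)   # 63 MAs, 1221 arms
res = MetaEpidemiologyModel(studies, mas).fit()
print(res.summary())
```

```
Meta-epidemiological analysis: difference in SMD (high/unclear vs low risk of bias)
======================================================================================
Characteristic                  DMSD              95% CI   I2 (%)   MAs   Arms
--------------------------------------------------------------------------------------
randomization                   0.36        [0.17, 0.56]     42.1    62   1213
baseline_similarity            -0.26       [-0.60, 0.09]     50.1    38    408
allocation_concealment          0.12       [-0.32, 0.55]     54.2    33    491
random_housing                  0.58       [-0.37, 1.53]     70.5    10    169
blinding_caregivers            -0.29       [-1.06, 0.48]     24.1    12    132
blinding_model                    --                  --       --    --     --  skipped: 6 eligible meta-analyses (minimum 10)
random_outcome_assessment      -0.44       [-1.01, 0.13]      6.2    13    166
blinding_assessors             -0.18       [-0.42, 0.05]     43.7    56    928
attrition                      -0.01       [-0.29, 0.27]     50.9    50    767
selective_reporting             0.14       [-0.15, 0.44]     45.3    44    454
======================================================================================
Positive DMSD: larger effect sizes in studies at high or unclear risk of bias.
```

The injected δ = 0.3 on randomization is recovered (pooled DMSD 0.36,
CI excluding 0), while the other characteristics — where no bias effect
was injected — scatter around zero with CIs covering 0. `blinding_model`
is skipped: too few meta-analyses have both rating groups for it, the
same reason several characteristics cannot be evaluated in real corpora.
`res.to_frame()`, `res.per_ma_frame()` and `res.plot_forest()` expose
the results as DataFrames and a forest plot; `res["randomization"]`
returns the per-characteristic result with its per-meta-analysis DMSDs.

The same analysis runs from the shell:

```bash
metaepi simulate --seed 42 --out data/
metaepi run --studies data/studies.csv --mas data/mas.csv --out results/
metaepi run --studies data/studies.csv --mas data/mas.csv --robust --out results_robust/
```

Descriptive audit tables (counts with explicit denominators, medians
with quartiles, stratified by review design) live in
`metaepi.descriptives`; the input schemas are documented in
`docs/extraction_schema.md`.

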