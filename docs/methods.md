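# Methods

## Effect sizes

Arm-level summaries are converted to standardized mean differences with
the pooled-SD denominator; Hedges' small-sample correction
J = 1 − 3/(4·(n_t + n_c − 2) − 1) is applied by default (`bias_corrected`
flag gives Cohen's d), since preclinical groups are small (5–15 animals)
and published reviews predominantly report g. The sampling variance is
the usual large-sample form (n_t + n_c)/(n_t·n_c) + smd²/(2(n_t + n_c)),
evaluated at the corrected SMD. When only a confidence interval is
available, the variance is ((ci_high − ci_low)/(2·z))²; the interval is
assumed normal (Wald) — t-based intervals are not auto-detected, a
stated simplification since source reviews rarely say which they used.

Direction alignment multiplies all SMDs of a meta-analysis by −1 when
the expected direction of benefit is negative, so that a positive SMD
always means benefit. Meta-analyses whose expected direction is unclear
are excluded with a logged reason by default; setting
`unclear_direction_policy = "pooled_sign"` instead aligns by the sign of
the meta-analysis's own pooled random-effects estimate (a pragmatic
fallback that slightly biases those SMDs toward positivity, hence not
the default).

Control groups shared by k experimental arms are split by floor
division of n_control; remainder animals are dropped. This is
conservative and reproducible; splitting fails (degenerate-input error)
if fewer than 2 control animals per arm would remain.

## Meta-analytic core

τ² is estimated by REML (bounded scalar minimisation of the restricted
negative log-likelihood on [0, 10·var(y)], absolute tolerance 1e−8,
deterministic, truncated at zero) or by the DerSimonian–Laird moments
formula, generalised to a design matrix for meta-regression
(Raudenbush's estimator). REML is the default — less biased for τ² —
with DL retained for comparability with older meta-epidemiological
work. Cochran's Q and I² = max(0, (Q − df)/Q)·100 always use
fixed-effect weights. Confidence intervals are Wald (normal quantile)
by default; Hartung–Knapp (t quantile with variance rescaling) is
selectable for step-2 pooling. If all sampling variances are zero the
core raises a validation error rather than pooling.

The binary-moderator meta-regression is weighted least squares of
effects on [1, x] with weights 1/(v_i + τ²_res); its slope is the DMSD.
The cluster-robust variant works on the weight-transformed scale (the
working model treats 1/(v_i + τ²_res) as inverse variances, making the
problem OLS after multiplying by √w): CR2 applies the bias-reduced
adjustment A_j = (I − H_jj)^(−1/2) per cluster and reports Satterthwaite
degrees of freedom computed under the working model; CR0/CR1 are
selectable. Agreement with R's metafor (pooling, τ² by DL and REML,
moderator slope and its standard error) is verified in the test suite
on a fixed small dataset.

## Two-step pipeline

Ratings are dichotomized with high and unclear grouped as exposed —
unclear ratings overwhelmingly reflect non-reporting, and grouping them
with high risk is the convention for this design — and arms without a
rating are excluded from that characteristic only. Eligibility (≥ 3
rated studies, both groups represented at study level) and the
≥ 10-eligible-meta-analyses threshold are config constants `min_studies`
and `min_mas`. The step-1 regression unit is the experimental arm;
within-study dependence is deliberately ignored in the primary analysis
and addressed by the CR2 sensitivity analysis clustered on study (a
meta-analysis whose arms all come from one study is excluded there and
logged). Step-2 weights are 1/(se²_k + τ²) with no additional
meta-analysis-size weighting. Arms are processed in a deterministic
sort order so results are exactly invariant to input row order. Skipped
characteristics are results, not errors: `run_all` always returns ten
rows and the CLI exits 0.

## Synthetic corpus

The generator draws, for meta-analysis k, study s and arm a:
θ_k ~ N(μ, τ²_between), η_ks ~ N(θ_k, τ²_within),
true_ksa = η_ks + Σ_c δ_c·1[exposed_c], and the observed SMD from
N(true, v) with v the SMD variance at the drawn group sizes. Ratings
and the study-level effect are assigned per study — arms of one study
inherit both — which is what induces the within-study correlation the
robust sensitivity analysis targets; ratings are independent across
characteristics except through δ (a stated simplification; real rating
correlations are unknown). `confounded_mode` couples exposure
probability and group size to stress-test the estimator.

Default calibration, chosen to emulate the audited corpus and then
frozen: 63 meta-analyses; studies per meta-analysis from a discretized
lognormal with median 9 (σ = 0.7, minimum 3 — a uniform distribution
cannot have both the observed median and the observed range); 70/20/10%
of studies with 1/2/3 arms, multi-arm studies sharing a floor-split
control; μ = 0.8 (typical magnitude of beneficial preclinical SMDs);
τ_between = 0.4; group sizes uniform on [5, 15] animals; half the
meta-analyses measured on a benefit-negative scale; per-characteristic
rating prevalences matching the published audit (e.g. randomization
rated for every study with 53% low risk; random housing 96% high or
unclear among the third of studies rated). τ_within was calibrated by
pilot simulation against the corpus median per-meta-analysis I² of 77%:
pilots gave median I² of 64% at τ_within = 0.85, 76% at 1.15 and 79.5%
at 1.3; the default is τ_within = 1.2 (median I² ≈ 77.5%). δ defaults
to zero for every characteristic — the generator's null is the
pipeline's null.

Monte-Carlo studies in the tests and the acceptance script use reduced
problem sizes (single simulated characteristic, single-arm studies,
K = 20–50 meta-analyses, 200–1000 replicates), chosen as the smallest
designs whose Monte-Carlo error is well below the tolerances being
checked.

## What the synthetic tests do and do not show

Passing recovery/coverage/permutation tests shows the estimator
correctly measures an additive, rating-linked shift under the
generator's assumptions: normal random effects, ratings independent of
effect size except through δ, correctly recorded expected directions
and known sampling variances. Real corpora violate several of these —
rating quality varies across reviews, ratings correlate with each other
and with study size, SMD variances are estimated, and whole reviews
sometimes assign all studies the same rating (which the eligibility
rule then excludes). The tests validate the machinery, not the
substantive conclusion of any particular corpus.

## Known limitations

- **Mild CI undercoverage.** With δ = 0.3 injected, K = 50
  meta-analyses of 20 studies, the 95% Wald CI of the pooled DMSD
  covers the truth in ≈ 92–93% of replicates. Two mechanisms: step-1
  standard errors condition on the estimated residual τ² and are
  treated as known in step 2 (inherent to the standard two-step
  procedure), and the SMD sampling variance grows with the effect, so
  exposed (shifted) studies are slightly down-weighted, attenuating the
  pooled DMSD by about 0.02. Hartung–Knapp step-2 intervals do not
  materially improve this at K = 50 (measured ≈ 92%). Users should
  treat borderline CIs accordingly.
- The pooled-sign fallback for unclear directions is weakly
  self-confirming and is off by default.
- CR2 with Satterthwaite df assumes the working covariance model on the
  transformed scale; with very few clusters per meta-analysis the df
  can be small and the robust CIs wide — by design.
- Quantiles in descriptive tables use linear interpolation and
  percentages round half-up to one decimal, matching common printed
  tables; other software may differ in the last digit.
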