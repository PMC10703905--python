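# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices and the known limitations of `transomics`. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## The three-stage model

### Stage 1 — feature-level association

For each omics feature x and each outcome, a fixed-effect regression with
covariate adjustment (age in years, sex, weight in kg, height in cm, plus
one standard-normal technical covariate per omics layer when present) and a
cluster-robust sandwich variance grouped on `family_id`:

| outcome        | response                     | model                         | p-value reference |
|----------------|------------------------------|-------------------------------|-------------------|
| `cac_present`  | CAC > 0 (binary)             | logistic                      | t(G−1) Wald       |
| `cac_score`    | log CAC score, CAC>0 subset  | linear (OLS)                  | t(G−1) Wald       |
| `mi_prevalent` | prevalent MI (binary)        | logistic                      | t(G−1) Wald       |
| `mi_incident`  | time to MI, prevalent cases excluded | Cox PH (Breslow ties) | t(G−1) Wald       |

G is the number of family clusters. Cluster-robust fixed-effect fits stand
in for GEE (binary), linear mixed models (continuous) and pedigree-clustered
Cox formulations: for exchangeable family clusters the estimand is the same,
no working-correlation or variance-component specification is needed, and
per-feature fitting at genome scale avoids the convergence pathologies of
mixed models. The continuous response is log-transformed by default
(`log_transform=False` turns it off) because the Agatston scale is strongly
right-skewed.

Small-sample corrections: the linear model uses the CR2 (Bell–McCaffrey)
leverage adjustment — cluster residuals premultiplied by (I − H_gg)^{−1/2} —
which empirically holds the Wald test within ~0.005 of the nominal 0.05
level at a few hundred clusters, where the plain CR1 multiplier runs near
0.06. Logistic uses G/(G−1)·(n−1)/(n−k) (matching statsmodels GLM cluster
SEs exactly), Cox uses the Lin–Wei score-residual sandwich with G/(G−1).
All three fitters are batched: shared covariate block, one feature column
per model, solved simultaneously with vectorised linear algebra
(Frisch–Waugh for OLS, batched Newton for logistic and the Breslow partial
likelihood). statsmodels (`cov_type="cluster"`) and lifelines
(`cluster_col`) reproduce the estimates to ≈1e-6 and the SEs to ≤5% (exact
for OLS-CR1 and GLM) in `tests/test_association.py`.

Degenerate fits — constant features, (quasi-)separation (|per-SD
coefficient| > 15), non-convergence, singular information — are flagged and
reported with p = 1 rather than dropped, so gene-level collapsing never
loses a gene silently. Features are z-scored internally (results rescaled),
making fits and the separation guard invariant to affine feature rescaling.

### Stage 2 — min-p gene summary

A gene's association per omics is the minimum p-value over its features;
ties break on the lexicographically smallest feature id. No per-gene
multiplicity correction is applied, which biases toward feature-rich genes;
under the null with k features per gene the median gene-level p is
1 − 0.5^(1/k) (≈ 0.067 at k = 10), a property the tests verify through the
collapsing code.

### Stage 3 — robust rank aggregation

Per outcome, each omics' gene list is sorted by min-p and truncated to the
top fraction (default 0.05) of its universe of N_o tested genes, count
⌈0.05·N_o⌉, ties on gene id. A gene at 1-based rank k gets normalized rank
k/N_o; genes absent from a truncated list get rank 1 (least informative),
with N_o held at the full universe size so truncation never changes the
score of a gene inside all lists. With the rank vector sorted ascending,

    beta_k = I_{r_(k)}(k, n−k+1)   (regularized incomplete beta),

the probability that the k-th smallest of n iid uniform ranks is ≤ r₍ₖ₎,
and the trans-omic score is rho = min(n · min_k beta_k, 1). The Bonferroni
factor over the n order statistics makes rho a valid, conservative
p-value-like quantity: under three independent uniform lists the measured
P(rho ≤ α) is ≈ 0.006/0.022/0.037 at α = 0.01/0.05/0.10 (2000 genes × 500
replicates). The uncorrected min β is emitted alongside (`min_beta`) since
either convention is defensible; a Monte-Carlo shuffling oracle
(`permutation_oracle`, ≥10⁴ sorted-uniform draws) exists purely as an
independent check of the closed form (agreement < 0.005 at 10⁶ draws).

Genes present in no truncated list are omitted from the output (they would
all tie at rho = 1). Reports: per-outcome top-N tables (default N = 10) and
the set of genes appearing in ≥ 2 of the four per-outcome top-100 lists.

## The synthetic cohort

The generator emulates the marginal structure of a mid-2000s US
observational cohort of ~3100 adults with familial clustering:

* **Families**: sizes drawn uniformly from 1–6 (or an exact `n_families`
  partition); relatedness enters through (a) a shared-parent genotype
  construction — two latent binomial(2, MAF) parents per family, each child
  dosage the sum of one Bernoulli(parent dosage/2) transmission per parent,
  keeping the marginal mean at exactly 2·MAF while correlating siblings —
  and (b) an N(0, 0.5²) family random intercept on every outcome's linear
  predictor (`family_intercept_sd`, set 0 to disable).
* **Omics**: genotype dosages (MAF ~ U(0.05, 0.5)); methylation beta values
  logit-normal (per-feature mean logit ~ N(0, 2), within-feature SD 0.8);
  expression log-normal (log-mean ~ N(1, 0.5), SD 0.5). One standard-normal
  technical covariate per omics loads 0.1 on the methylation logit and the
  expression log scale (batch-effect stand-in; the specific technical
  covariates of real platforms are not modelled).
* **Covariates**: age ~ N(57, 10²) clipped to 30–90; 48.9% female; sex-
  specific height/weight normals; fixed covariate coefficients per outcome
  with epidemiologically signed effects (older age, male sex, higher weight
  increase risk).
* **Outcomes**: CAC presence from a logistic model whose intercept is
  solved by root-finding so the expected prevalence hits the target
  (default 45.2%); CAC score log-normal around log 67.8 with log-SD 2.40
  (solved from a log-normal with quartiles 10.8 and 274.9), generated only
  for the CAC-positive subset with its linear predictor centred within that
  subset so the median stays on target; prevalent MI logistic at 2.1%;
  incident MI exponential with marginal rate 0.00235/person-year, scaled by
  planted log-hazards and the family intercept, the scalar hazard level
  re-solved so hazard heterogeneity does not depress the expected event
  count; censoring = min(exponential dropout solved to give a mean 8.2-year
  follow-up, administrative horizon 9.2 years). Prevalent-MI samples carry
  no incident time and are excluded from the Cox risk set.
* **Planted effects**: a `PlantedEffect` names a gene, a per-omics loading
  and a per-outcome effect; the product multiplies the *z-scored* causal
  feature (the gene's first feature in each listed omics) in the outcome's
  linear predictor. Per-SD effects make "matched effect sizes" across omics
  layers well-defined. A concordant effect lists all three omics, a
  discordant one a strict subset.

Everything is a deterministic function of `(config, seed)`; fixtures
round-trip losslessly through TSV (shortest-roundtrip float printing,
round-trip parsing), and identical configs produce byte-identical files.

What the generator does **not** emulate: linkage disequilibrium and real
pedigree inheritance, imputation uncertainty, probe chemistry, non-random
missingness, and population stratification. Passing tests therefore show
that the pipeline is correct and calibrated under exchangeable-cluster,
independence-across-genes conditions — not that it is robust to real-data
confounding.

## Validation studies and problem sizes

Run by the test suite and `scripts/acceptance.py`:

* **Beta-score oracle**: 100 random n=3 rank vectors vs 10⁶-draw sorted-
  uniform Monte-Carlo; max |Δ| observed ≈ 0.001 (bound 0.005).
* **Null rho coverage**: 2000 genes × 3 uniform lists × 500 reps.
* **Type-I error**: four independent null cohorts of n = 500 with 1000
  features each (pooled), binary on genotype vs CAC presence, continuous on
  methylation vs log CAC score, Cox on genotype vs incident MI with the
  incidence raised so ~60 events occur per cohort (the study-scale rate
  would yield ~10 at n = 500). Pooling over cohorts shrinks the Monte-Carlo
  error of the estimate; the per-feature level being estimated is unchanged.
* **Effect recovery**: 200 single-gene cohorts of n = 2000,
  `family_intercept_sd=0` so the planted conditional coefficient is the
  estimand (an unmodelled cluster intercept would attenuate the marginal
  logistic/Cox coefficient through non-collapsibility); the regressed
  feature is z-scored so the per-unit estimate equals the planted per-SD
  value. Recovered ≈ 0.504 for log-odds 0.5, ≈ 0.501 for log-HR 0.5,
  ≈ 0.303 for slope 0.3.
* **Concordance premise**: 50 cohorts of n = 2500, 2000 genes, one feature
  per gene per omics, 30 concordant + 30 single-omics genes at per-SD
  log-odds 0.25 on CAC presence. The effect size is set so the attenuated
  per-feature Wald statistic is ≈ 3 after the ~120 planted latent effects
  inflate the linear predictor variance (logistic non-collapsibility);
  top-100 recovery ≈ 0.91 (concordant) vs ≈ 0.47 (single-omics).
* **Pipeline determinism/cardinality**: a 350-sample, 100-gene end-to-end
  run, twice, byte-compared; artifact counts 12 + 12 + 4 + 4 + 1.

These sizes keep the full validation under ~10 minutes on one CPU while
leaving each estimate's Monte-Carlo error well inside its acceptance band.

## Numerical choices and edge cases

* Logistic/Cox Newton: warm start at the covariates-only fit, convergence
  when the max coefficient update < 1e-10 (logistic) / 1e-9 (Cox), updates
  clipped at ±5 per Cox step, linear predictors clipped at ±30 (logistic) /
  ±100 (Cox) inside exp/expit.
* The Cox design carries no intercept (the baseline hazard absorbs it);
  covariates are centred for conditioning.
* p-values are floored at the smallest positive double and capped at 1.
* `truncate_top_fraction` uses ⌈fraction·N⌉; all orderings break ties on
  ids, so every output is reproducible.
* Binary outcomes with a single class, survival data with zero events, and
  continuous analyses with fewer than (covariates + 3) usable samples raise
  errors; per-feature pathologies degrade to flagged rows instead.

## Limitations

* The cluster-robust approximation targets exchangeable within-family
  correlation; it does not model kinship-graded covariance, and no genomic
  control or inflation-factor correction is applied.
* The min-p summary favours feature-rich genes (documented above); region
  tests (SKAT/burden) are out of scope.
* The trans-omic score's Bonferroni correction is conservative; exact joint
  distributions of the order statistics are not computed.
* Feature→gene assignment is taken as an explicit input map; the package
  performs no genomic-coordinate arithmetic.
* Pathway enrichment and literature annotation of top genes are out of
  scope; report tables accept an optional user-supplied annotation join.
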