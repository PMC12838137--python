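# Methods

## Scope and data model

`envgp` models within-environment genotype means from multi-environment
trials. A record carries a genotype id, an environment id (site ×
harvest year), an experimental-series label and a yield value in Q/ha.
Genotypes are inbred lines (fully homozygous, dosage codes 0/2) or
single-cross hybrids whose SNP profiles are the mean of the parental
profiles, so heterozygous calls (code 1) occur only in hybrids.

## Genomic kernels and distances

Markers are filtered for missingness (default ≤ 0.5), monomorphism and
minor allele frequency (default ≥ 0.01); surviving missing calls are
replaced by the rounded per-marker mean dosage. This mean imputation is
a deliberate simplification — haplotype-based imputation is out of
scope — and is exact for the package's own synthetic data, which are
complete.

* `GRM_a` is VanRaden method 1, `W W′ / 2Σ p_j (1−p_j)` with `W` the
  allele-frequency-centered dosages. For a panel of fully inbred lines
  its mean diagonal is ≈ 2 (inbreeding), for hybrids ≈ 1.
* `GRM_d` uses the orthogonal dominance coding
  {0 → −2p², 1 → 2p(1−p), 2 → −2(1−p)²} normalized by `Σ(2p_j(1−p_j))²`.
  In an all-inbred panel the dominance coding degenerates to a function
  of the additive coding and `GRM_d` is strongly confounded with
  `GRM_a`/`GRM_aa`; dominance variance is only well identified when
  hybrids (heterozygotes) are present.
* `GRM_aa` is the Hadamard square of `GRM_a` scaled to unit mean
  diagonal.
* All kernels receive a 1e-8 diagonal jitter and must pass symmetry
  (1e-10) and minimum-eigenvalue (≥ −1e-8) checks.

Rogers distance is the mean per-locus allele-frequency distance
(`mean |c_x − c_y| / 2`), 0 for identical genotypes, 1 for opposite
homozygotes. Genomic duplicates are pairs with distance < 0.03 (the
theoretical F6 full-sib distance); grouping is by single linkage
(transitive closure), each group mapped to its lexicographically
smallest id. Windowed F_st uses the Weir–Cockerham (1984) estimator with
half-open 1-based base-pair windows of 299,999 bp stepped by 29,999 bp
per chromosome and a ratio-of-sums weighting across windows. Windows are
in base pairs (physical positions), not marker indices.

## Environment kernels

Daily weather (27 variables) is averaged per calendar month over the
growing season from 1 October of the sowing year to 31 August of the
harvest year — 11 months, hence 297 environment variables (EVs) per
environment, ordered variable-major with October first. EVs are
z-scored per column across environments. The linear kernel is
`ERM_l = EV EV′ / mean(diag)`; the non-linear kernel is
`exp(−dist(EV)/θ)` mean-diagonal normalized with Euclidean `dist` and
`θ` defaulting to the median off-diagonal distance. The exponent is
negative: the positive-exponent form diverges with distance and cannot
be a similarity kernel, so the package implements the standard
exponential (Gaussian-family) kernel. Year and site kernels (`YRM`,
`SRM`) apply the linear construction to EV rows averaged across sites
(respectively years); with a single site `YRM` coincides with `ERM_l`
(and symmetrically for `SRM`).

## The mixed-model machinery

Every model is a `ModelSpec`: an intercept (plus optional fixed factors
or covariates), a list of random terms, and a residual grouping. A
random term is either

* an **iid level term** (identity kernel over its observed levels),
* a **correlated level term** (a labeled kernel over levels), or
* a **Hadamard row term**, whose row covariance is the element-wise
  product of per-column kernel expansions
  (`C_ij = K_E[e_i, e_j] · K_G[g_i, g_j]`), computed on phenotype rows
  so unbalanced data need no special casing.

### Gibbs sampler

Fitting is Bayesian. Variance components carry scaled-inverse-χ² priors
with `df₀ = 5` and scale set so the prior mode splits the phenotypic
variance equally among terms plus residual (mirroring the R²-based
defaults of common Bayesian whole-genome regression software). Fixed
effects have flat priors. Defaults are `nIter = 3000`, `burnIn = 500`,
`thin = 5` — desk-scale settings; the study-scale reference settings are
`nIter = 15000`, `burnIn = 2000`. Effective sample sizes per variance
chain are reported (initial-positive-sequence estimator).

Correlated terms are sampled as one blocked draw per sweep: writing a
term's contribution as `B u` with `u ~ N(0, K σ²_t)` and whitening
`u = K^{1/2} Q q` where `Q` diagonalizes `K^{1/2} B′B K^{1/2}` (computed
once per fit), the full conditional of `q` has a *diagonal* precision
`Φ/σ²_e + I/σ²_t`, so each sweep costs two matrix–vector products per
term. This is exact blocked Gibbs, not an approximation. Eigenvalues
below 1e-10 of the maximum are dropped; the corresponding directions
carry no data and have posterior-mean zero.

Identity-kernel terms use the conditional independence of level effects
given the residual: vectorized per-level updates that also support
heterogeneous residual variances. Heterogeneous residuals (one σ²_e per
environment, pooled for environments with < 10 records) are only needed
by the heritability model, whose terms are all iid; combining them with
correlated terms raises `NotImplementedError`.

Known mixing limitation: posterior means of *individual effects* mix
slowly along the intercept ↔ genetic-mean ridge (the fitted values do
not). Oracle-comparison tests therefore use long thin-1 chains; variance
components and predictions are unaffected at default settings.

### Prediction

Predictions for new rows are posterior-mean kernel projections: a
correlated term contributes `K[new, train] K[train]⁺ û`; because test
rows carry no data this equals the exact posterior mean under the joint
kernel over train ∪ test labels. Identity-kernel terms contribute
exactly zero for unseen levels — this is why the baseline model M_1 has
structurally zero prediction ability for new genotypes.

### Variance accounting

A term's **explained variance** is `σ²_t · (mean diag C − mean C)` of
its realized row covariance `C` — the expected sample variance its
contribution adds to the phenotype. This centered scale (rather than the
mean diagonal alone) makes shares comparable across kernels with very
different correlation structure (e.g. `ERM_nl`, whose off-diagonals are
large) and matches the generator's calibration exactly.

### Oracle

`blup_oracle` solves the mixed model exactly for supplied variance
components via the marginal covariance
`V = Σ σ²_t C_t + R` (GLS for fixed effects,
`û_t = σ²_t C_t V⁻¹(y − Xβ̂)` for random terms). It serves as the
deterministic reference for the sampler and as a fast path when
variances are known.

### BLUEs, heritability, repeatability

Across-environment BLUEs treat genotype as fixed and environment as
random: variance components are first estimated on the all-random
companion model by Gibbs sampling, then the genotype-fixed system is
solved exactly once by sparse normal equations. Duplicates are collapsed
to canonical ids for fitting and estimates copied back to members. A
disconnected genotype–environment incidence graph is an error (the
components are listed).

The heritability model decomposes hybrids into female/male general
combining ability and specific combining ability, with material type
and series fixed, everything else random and per-environment residuals.
Entry-mean broad-sense heritability uses
`H² = σ²_G / (σ²_G + σ²_G×E/n̄_E + σ̄²_e/n̄_E)` with `n̄_E` the harmonic
mean number of environments per genotype and `σ̄²_e` the mean
per-environment residual variance; for hybrids
`σ²_G = σ²_GCA_F + σ²_GCA_M + σ²_SCA` and the interaction sum
analogously. The formula is the package's choice of the standard
entry-mean form.

Genomic repeatability fits `y = μ + g_a + e` per environment and reports
explained additive variance over total. With one record per genotype the
two variances separate only through the kernel's eigenstructure; under
the df₀ = 5 equal-split prior the posterior-mean ratio has a floor of
roughly 0.3 for a pure-noise trait (verified to be the converged
posterior, not a mixing artifact). Values should therefore be read
comparatively — a genuine signal pushes the ratio above 0.9 — rather
than as unbiased point estimates near zero.

## Validation geometries

* **Five-fold** (over canonical genotypes, duplicates never split): 10
  runs × 5 folds = 50 evaluations; within a run, fold predictions are
  stacked before correlating.
* **Scenario**: the training set stacks 1..6 whole experimental series,
  the test set is one held-out series; all (train-subset, test-series)
  combinations are enumerated, subsampled with the seed beyond 50.
  Prediction ability is per split.
* **Quadrant**: environments with more than 50 genotypes are kept;
  per run `round(0.33 n)` genotypes and environments are declared new,
  partitioning observed cells into quadrants; training is a random 80%
  of quadrant 1, cv1 tests the remaining 20% and cv2–cv4 the full
  quadrants 2–4. Sampling of "new" genotypes is unstratified by series
  (a flag could stratify; the unstratified choice is the default).
* **Leave-one-environment-out**: one run per environment; a genotype
  enters the test set only with ≥ 3 records elsewhere; environments
  with no eligible genotype are reported.

Prediction ability is the Pearson correlation per test-set environment;
run means average over environments. Groups with < 3 pairs or
degenerate *observed* values are skipped. Groups whose *predictions*
are constant while observations vary are recorded as r = 0: the
correlation is undefined, but a constant prediction provably carries no
ranking information, and this is the reporting convention that makes
the baseline model's null structure a measurable 0 rather than a
missing value. Model comparisons are paired by run: mean percent
difference, paired t statistic and two-sided p value at threshold 0.05.

## G×E patterns, clustering and EV importance

The G×E pattern of a genotype panel is obtained by fitting
`ŷ = μ + genotype + environment + e` (independent random effects) to a
complete predicted genotype × environment matrix and taking residuals.
Because random-effect shrinkage leaves a fraction `1 − λ` of each main
effect in the residual, the residual matrix is then orthogonalized
exactly against the row and column indicator spaces (double centering);
this guarantees the defining property of the pattern matrix — zero
row/column means — and is algebraically identical to double-centering
the predictions themselves. The fit supplies the decomposition
provenance (μ, main effects).

Environments are clustered on the first two principal coordinates of
the Euclidean distances between pattern columns, with K-means
(k-means++, 50 restarts, seeded). `k = "auto"` scans 2..n/min_size and
takes the best mean silhouette subject to every cluster holding at
least `min_size` environments (3 by default; the study also reports a
9-cluster solution with ≥ 6 environments each — both reachable through
`min_size`), with the SSE elbow curve reported alongside. Tree
similarity uses the Pearson correlation of cophenetic distances (raw
heights; only linear rescaling leaves it invariant).

EV importance uses a gradient-boosted tree classifier
(learning_rate 0.1, n_estimators 3000, max_depth 30 as reference
settings; tests use fewer trees since desk-scale problems saturate far
earlier). Accuracy is assessed by repeated stratified 5-fold × 3 CV
(random_state 1); the final model trains on an 80/20 split with
early stopping (100 rounds, multiclass log-loss) and gain importances
are scaled to [0, 1] (or normalized to sum 1) and aggregated per
variable (mean over months) and per month.

## Selection of enviromically adapted genotypes

The reference set is the top 7% of genotypes by BLUE plus a random 3%
of the remainder (ceiling rounding; seeded). Per environment, the
enviromically adapted set is the top 10% by predicted yield (ceiling;
ties broken by id). Selection gain of a set in an environment is its
mean predicted yield minus the reference-set mean; the boost is the
adapted gain minus the gain of the 50 overall top performers (ranked by
BLUE; ranking by mean prediction is available behind a flag), and
boost / 0.32 Q ha⁻¹ yr⁻¹ converts to equivalent years of breeding
progress. Environment-wise, the adapted gain can never be below the
overall gain on the same prediction column (the top-k subset maximizes
the k-subset mean) — this is asserted, while the *comparative* claim
(positive mean boost) only holds when G×E variance is present. The
study's absolute yield thresholds (101 and 60–100 Q/ha) are expressed
as quantile-equivalent fractions because synthetic yields have an
arbitrary scale.

## The synthetic-data generator

The generator is first-class, tested code. It emulates:

* elite inbred lines in experimental-series blocks, plus an optional
  divergent subpopulation drawn from shifted allele frequencies (a
  gene-bank stand-in) assigned to the last series;
* hybrids from an incomplete factorial (a seeded sample of the
  female × male lattice; an explicit error if the factorial density
  cannot yield the requested hybrid count);
* exact genomic duplicates under new identifiers;
* daily weather per site-year: 27 variables over a 335-day season
  (1 Oct – 31 Aug, leap days dropped), each variable = its natural-scale
  mean + site + year + site×year effects (SDs as multiples of the
  variable's own SD) + day noise. Packaged means/SDs are plausible
  central-European values; no attempt is made to mimic seasonal cycles,
  autocorrelation or cross-variable physics;
* phenotypes `y = μ + u_E + u_a + u_d + u_aa + u_GE + e` with each
  component drawn from the corresponding kernel (environment effects
  from `ERM_nl`, G×E from the Kronecker product of `ERM_nl` and
  `GRM_a`) by Cholesky with 1e-8 jitter. Kernels are normalized to unit
  *centered* scale and each drawn component is rescaled to its exact
  target variance, so configured shares are exact shares of total
  phenotypic variance — without the rescaling, the few effective
  degrees of freedom of the strongly correlated environment kernel
  made realized shares fluctuate far beyond the generator's contract.
  Observed cells are a seeded subsample of the grid (`sparsity`);
* genotype × site growth-parameter tables with a configurable heritable
  fraction (default 0.15, reflecting the weak heritability of
  crop-growth-model parameters), optionally kernel-structured.

One global seed fans out by fixed offsets (+1 population, +2 weather,
+3 phenotypes, +4 growth parameters); identical configurations are
byte-identical. The relative magnitude of environment main effects is
configurable (default share 0.20) since it is a free parameter of the
study design.

What passing tests on these data do **not** show: robustness to linkage
disequilibrium and realistic marker ascertainment, to non-Gaussian
trait architecture (major genes, skew), to spatial field trends, or to
weather measurement artifacts — the generator matches the models'
assumptions by design, which is precisely what makes recovery tests
well-posed.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale chosen as the
package's own benchmark conditions: the baseline-null benchmark uses
500 genotypes × 20 environments with 20 quadrant runs; variance-component
recovery uses 800 genotypes (400 lines + 400 hybrids so dominance is
identified) across 6 environments at 60% sparsity over 5 seeds; model
ordering uses 250 genotypes × 12 environments over 20 paired runs.
MCMC settings in tests are 1200–2000 iterations with proportional
burn-in, which the recovery results show to be sufficient at these
sizes. Degenerate inputs are errors, not NaNs: empty marker panels
after QC, missing season months, disconnected incidence graphs,
undersized clusters. All eigen-decompositions clip eigenvalues at zero
after the 1e-8 jitter; ties in top-k selections break lexicographically
by id; "33%"-style fractions use `round()` for sampling counts and
`ceil()` for top-k set sizes.
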