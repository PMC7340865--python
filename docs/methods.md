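# Methods

This note documents the statistical procedures implemented in `methylgsz`,
the modelling assumptions behind them, the tunable parameters that matter,
and the numerical and design choices a maintainer should know about.

## Overview

The package implements a complete smoking–methylation analysis chain for
Illumina 450K-style whole-blood data:

1. **Preprocessing** — detection-rate and blacklist probe filters,
   sex-chromosome removal, beta/M conversion, control-probe principal
   components as batch surrogates.
2. **EWAS** — per-CpG ordinary least squares of M-values on smoking status
   plus covariates, with genomic-inflation diagnostics and
   Benjamini–Hochberg FDR.
3. **Gene proxy scores** — collapsing per-CpG statistics to one signed
   score per gene.
4. **Gene Set Z-score (GSZ) analysis** — a threshold-free competitive gene
   set test with a permutation null and an extreme-value asymptotic
   p-value.
5. **Region analysis** — rank-sum comparison of per-sample mean
   methylation across gene-region and CpG-island-relation categories.
6. **Synthetic data** — a seeded generator with planted ground truth that
   defines the study conditions under which the pipeline is validated.

## Per-CpG model

Methylation beta values are mapped to M-values, `M = log2(beta/(1-beta))`,
which are approximately homoscedastic and suit a linear model. For each
probe the model is

    M ~ smoking + age + sex + BMI + cell proportions + chip + array
        position + control-probe PCs                      (model 1)
    model 2 = model 1 + alcohol use + socioeconomic status

Cell proportions enter as five of the six leukocyte fractions (CD8T, CD4T,
NK, B, monocytes; granulocytes are dropped because the six sum to one).
Chip and array position enter as treatment-coded factors. Model 2 uses
listwise deletion over its extra covariates, so its sample size is smaller
when those covariates are partially missing. The design matrix is checked
for rank deficiency and offending columns are named in the error.

OLS is solved in closed form for all probes at once against the shared
design matrix (coefficients `M X (X'X)^-1`, standard errors from per-probe
residual sums of squares). A test asserts equality with statsmodels' OLS
per probe on a small fixture, so the vectorized path is cross-checked
against an independent implementation.

Inflation is summarized by the genomic inflation factor
`lambda = median(t^2) / F^-1_chi2(1)(0.5)` with the exact chi-square
median 0.4549364…; `lambda ≈ 1` indicates calibrated tests.

FDR uses step-up Benjamini–Hochberg. `bh_adjust(p, m_total)` accepts a
total test count larger than the vector length, which is what lets the
published top-site FDR column be recomputed from a printed subset of
p-values: when the subset is the global head of the p-value ranking,
subset ranks equal global ranks and the arithmetic is exact up to printed
rounding.

## Gene proxy score

Each gene's score is the signed t-statistic of the CpG with the largest
absolute t among the probes annotated to it. Ties break toward the smaller
p-value, then the lexicographically smaller probe id, so results are
deterministic. The max-|t| proxy favours genes with one strong site over
genes with diffuse weak signal; this matches the intended use (feeding a
competitive rank test), but the number of probes per gene modulates the
null distribution of the proxy — which is why significance is assessed
competitively against other genes measured on the same platform rather
than against a parametric null.

## Gene Set Z-score

Genes are ranked by score (descending). For a set of size `m` in a
universe of `N` scored genes, let `X_k` be the sum of member scores among
the top `k`. Under the competitive null — the membership is a uniformly
random m-subset of the ranks, i.e. sampling without replacement —

    E[X_k]   = p * S_k,                       p = m/N
    Var[X_k] = p(1-p) * [ Q_k - (S_k^2 - Q_k)/(N-1) ]

with `S_k, Q_k` the running sum and sum of squares of the ranked scores.
Both profiles are computed in O(N). The early positions of the variance
profile are noisy, so the variance core is smoothed with an exponentially
weighted moving average along the ranking (`var_smooth = 0.5`, the weight
of the current position) and floored by `var_floor_frac = 0.01` times the
pooled score variance. The GSZ statistic is the maximum of the
standardized running deviation `(X_k - E[X_k]) / sqrt(Var_k + floor)` over
all `k`, taken over both ranking directions and floored at zero; the
attaining direction is reported as `high` (enrichment toward high scores)
or `low`. Because the maximum is taken over the whole profile, no
per-gene significance threshold is involved.

**Permutation null.** Each set is compared against `B = 100` random
same-size memberships drawn from a random stream keyed by the analysis
seed and the set's name. Keying by name makes results invariant to the
order sets are listed in, and drawing each set's null independently keeps
the Monte Carlo error of the per-set p-values independent across sets — a
single shared permutation batch would shift every p-value in the same
direction whenever that batch happened to be extreme, which ruins
calibration diagnostics computed across sets. The empirical p-value is
`(1 + #{null >= observed}) / (B + 1)`.

**Asymptotic p-value.** The null of a maximum statistic is extreme-value
shaped, so a fitted extreme-value distribution interpolates far beyond the
1/(B+1) resolution of the empirical p. The default family is the
generalized extreme value (GEV) fitted by maximum likelihood: the
permutation distribution of the GSZ maximum is markedly more right-skewed
than the Gumbel's fixed shape allows, so a Gumbel fit underestimates the
upper tail and over-rejects null sets, while the GEV's free shape
parameter keeps the rejection rate at nominal 0.05 inside its binomial
band (asserted in the calibration tests and reported by the reproduction
script). A `gumbel` option (one fewer parameter, method-of-moments start
`scale = sd*sqrt(6)/pi`, `location = mean - 0.5772*scale`) is retained for
users who prefer the classical fit. Degenerate nulls (zero variance) fall
back to the empirical p-value with a warning; fitted p-values are floored
at machine epsilon.

FDR over sets runs within each category when category labels are present
in the GMT file, else globally.

## Region analysis

Probes are grouped by gene-region annotation (TSS200, TSS1500, 5'UTR,
1stExon, Body, 3'UTR) and by CpG-island relation collapsed to four levels
(Island; N/S shore → Shore; N/S shelf → Shelf; OpenSea). A probe
annotated to several gene regions contributes once to each. Per sample
and category the mean beta is computed, and smokers are compared to never
smokers with the Wilcoxon rank-sum test: exact enumeration when the
pooled sample is ≤ 25 without ties, otherwise the normal approximation
with midranks, tie-corrected variance and continuity correction
(`scipy.stats.mannwhitneyu` backs the computation; the reported W is the
rank-sum of the first group). Direction is the sign of the smoker median
minus the never-smoker median. The ten category means share the same
samples and are strongly correlated, so their p-values are reported
nominally, with a clearly labelled BH column as a secondary aid.

## Synthetic data generator

The generator emulates a whole-blood 450K experiment at desk scale. Per
probe `i` and sample `j`, on the M scale:

    M_ij = base_i + a_i (age_j - mean) + x_i sex_j
           + sum_c c_ic (prop_jc - mean_c) + l_i u_chip(j)
           + smoking_j delta_i + Normal(0, noise_sd_m)

`base_i` is the logit2 of a Beta draw whose parameters depend on the
island relation (islands hypomethylated, Beta(2,8); shores intermediate,
Beta(4.5,5.5); shelves/open sea hypermethylated, Beta(7,3)), reproducing
the canonical bimodal beta distribution. Chip scores `u` are injected
into both the methylation and the control-probe matrix, so control-probe
PCs genuinely recover the batch component the EWAS adjusts for. Planted
effects are additive M-shifts in smokers, so a planted delta equals the
expected regression coefficient downstream.

Default conditions (chosen once as the study design the package targets):
125 samples with 21 active smokers; 20,000 probes over 5,000 genes
(Poisson(3) probes per gene, 25% intergenic, intergenic probes open sea);
150 gene sets of 10–40 genes; 20 planted CpGs with a 1.0 M-unit shift; one
planted coherent set (`set_0001`) whose member genes' probes carry a
milder 0.2 M-unit shift; residual noise 0.5 M-units; six chips with batch
offsets of SD 0.1 M-units; covariate effect spreads of 0.01 M-units/year
(age), 0.05 (sex) and 0.5 (cell fractions); and 16 of 125 samples missing
alcohol/SES, so the extended model runs on 109 samples. All stages draw
from seeded, stage-separated random streams; the same configuration and
seed reproduce every output byte-identically.

**What the generator does not emulate:** probe-level measurement error
profiles of the two Illumina chemistry types, spatial chip artefacts,
genuine LD-like correlation between neighbouring CpGs (probes are
independent given the sample covariates), population stratification,
age–smoking confounding, and real genomic coordinates (positions are
arbitrary). Passing tests therefore demonstrate statistical correctness
and calibration of the procedures under a realistic covariance structure,
not robustness to every artefact of real arrays.

## Numerical choices

- Beta values are clamped to `[1e-6, 1 - 1e-6]` before the logit; M-values
  generated by the synthetic model are clipped to ±19 so the beta/M round
  trip is exact to floating precision.
- Control-probe PCs come from an SVD of the column-centred matrix; each
  component's sign is fixed so its loading sum is positive. A rank-deficient
  control matrix yields zero-filled trailing components with a warning.
- Gene proxy tie-break: larger |t|, then smaller p, then probe id.
- GSZ ranking tie-break: equal scores order by gene name.
- The GSZ statistic is floored at zero (a set concentrated mid-list can
  otherwise produce a negative maximum). The direction label is the sign
  of the set's terminal deviation (total member score minus expectation):
  the terminal deviation enters the maxima of both directional profiles,
  so comparing the two maxima would be a coin flip for mean-shifted sets.
  Sets with negligible mean shift are labelled by the larger profile
  maximum, ties toward `high`.
- Degenerate inputs (all scores equal, empty regions, single-group
  comparisons) warn or raise typed `DataError`s rather than returning NaN.
- Seeds derived from a master seed use CRC32 mixing and stay below 2^31.

## Problem sizes

The test suite and the reproduction script run the full chain at reduced
sizes chosen to keep a complete validation run on one CPU in minutes:
calibration experiments use 2,500 null probes, 700 genes and 200 sets at
B = 100; recovery experiments use the full default 20,000-probe
configuration; determinism checks use 1,500 probes. These sizes are large
enough that the asymptotics the methods rely on (normal rank-sum
approximation, extreme-value fit, BH step-up) operate in their intended
regime.

## Known limitations

- The max-|t| gene proxy makes no size adjustment for the per-gene probe
  count; competitive testing absorbs this only insofar as the tested sets
  resemble random draws from the same gene universe.
- The GEV asymptotic p-value is a fit to B = 100 permutation scores; its
  extreme tail (p far below 1/B) is an extrapolation, and the null
  rejection rate it yields, while inside the nominal binomial band, tends
  to sit slightly above 0.05 (the reproduction script reports the measured
  rate). Rank ordering of sets is unaffected (rank concordance with the
  empirical p exceeds 0.9 in the calibration tests).
- Region-level comparisons are unadjusted for covariates by design
  (they summarize raw methylation); confounded designs will show
  confounded region differences.
- Model 2's listwise deletion assumes covariates are missing completely
  at random.
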