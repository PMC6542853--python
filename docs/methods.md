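# Methods

## The model

`comboseq` analyses a 2×2 factorial treatment design: four conditions
(vehicle, treatment A, treatment B, combined A+B), each with at least two
— by default three — biological replicates, measured as a genes × samples
matrix of read counts. Counts for gene *g* in sample *j* are modelled as
negative binomial,

    K_gj ~ NB(mean = s_j * q_gc(j),  variance = mu + alpha_g * mu^2)

where `s_j` is a per-sample size factor, `q_gc` the condition mean on the
normalized scale, and `alpha_g` the gene-wise dispersion. The GLM uses the
natural-log link with `log s_j` as a fixed offset, one factor with four
levels and the vehicle as reference; base-2 conversion happens only at
reporting. All four contrasts of interest (A vs vehicle, B vs vehicle,
combo vs vehicle, combo vs B) are linear combinations of the coefficients
of this single fit, which makes them internally consistent by
construction.

The scientific quantity built on top of the fit is the **expected additive
effect**: per gene, the sum of the two single-treatment log₂ fold-changes.
Under exact additivity on the log scale the combined-treatment log₂
fold-change equals this sum; the package quantifies departure from
additivity by ordinary least squares of observed on expected over three
gene subsets (union of the single-treatment DE sets, their intersection,
and the combination-only genes). The combination-only regression uses the
single-treatment fold-change *estimates* for genes that are not
significant in the single treatments — the estimates exist regardless of
significance, and excluding them would make that subset's regression
undefined.

## Estimation pipeline

**Size factors** are median-of-ratios: reference genes are those with no
zero count in any sample; each sample's factor is the median over
reference genes of `count / geometric mean across samples` (midpoint
convention for even reference sets). If no gene is positive everywhere the
estimator refuses rather than silently switching to a pseudo-reference;
factors can always be supplied explicitly.

**Dispersion** is estimated per gene. A method-of-moments start is taken
from the pooled within-condition residual variance of normalized counts;
the estimate is then refined by maximizing the negative-binomial
likelihood with the condition means profiled out (plug-in group means of
normalized counts) and the Cox–Reid adjustment `-0.5*logdet(XᵀWX)` added.
The CR term is the standard correction for the downward bias that
profiling four means out of twelve observations would otherwise induce;
for the saturated one-factor design it reduces to
`0.5 * Σ_c log Σ_{j∈c} w_j` up to an alpha-free constant. The
maximization is a vectorized golden-section search on log alpha over
[1e-8, 10]; estimates within a decade of the lower bound are snapped to it
and flagged `FLOOR` (the likelihood is numerically flat there), failures
fall back to the moment estimate (`MOM`), everything else is flagged
`MLE`. No shrinkage toward a mean-dispersion trend, no outlier refitting,
no independent filtering and no fold-change shrinkage are performed: the
goal is a transparent, calibrated test, not bit-compatibility with any
particular external pipeline.

**IRLS**: Fisher scoring with working weights `w = mu/(1 + alpha*mu)`,
initialized from group means, at most 50 iterations, convergence when the
largest coefficient change drops below 1e-8, coefficients capped at ±30 on
the natural-log scale. The coefficient covariance is `(XᵀWX)⁻¹` at the
final fit. Genes where a contrast group is all zeros (complete
separation), or where IRLS did not converge, fall back to a flagged
pseudo-mean group-ratio estimate (+0.5 on the normalized scale) with a
delta-method standard error — never an exception.

**Wald tests** use `t = log2fc / se` referred to a **t distribution with
residual degrees of freedom** (samples minus conditions; 8 at triplicate
scale). The asymptotic normal reference ignores that the per-gene
dispersion entering the standard error was itself estimated with those few
degrees of freedom; measured on global-null simulations at the package's
default conditions the normal reference gives empirical type-I error
≈ 0.08 at nominal 0.05 and routinely produces spurious BH discoveries,
while the t reference gives ≈ 0.047 and a clean null — the familiar
estimated-variance correction from small-sample linear modelling, adopted
here deliberately.

**Multiple testing** is Benjamini–Hochberg, applied separately within each
contrast, over the genes passing the expression filter (total raw count ≥
`min_total_count`, default 10; filtered genes keep their fold-change
estimate but get missing adjusted p). DE selection is strict:
`padj < alpha`, default 0.05.

**Attenuation** is operationalized as: among the genes DE for B vs
vehicle, those whose combo-vs-B contrast is significant — BH applied
within the candidate set only — with sign opposite to the B-vs-vehicle
fold-change. Strict sign opposition (rather than `|combined| < |B|`) keeps
the rule free of an arbitrary magnitude threshold; the rule is isolated in
one documented operation (`comboseq.attenuation`) so alternatives can be
swapped in. Note that a gene truly regulated by *both* agents in opposite
directions is genuinely attenuated under this definition even when the
interaction term is zero: with additive truth the combo-vs-B effect equals
betaA. Null operating characteristics are therefore assessed on
simulations whose B-regulated candidates carry `betaA = 0`.

**Concordance percentages** use round-half-up for the concordant share and
define the discordant share as its complement, so the pair always sums to
100 (436/800 → 55% / 45%, not 55/46 or 54/45).

**Comparative Cₜ**: technical replicates are averaged on the Ct scale per
(sample, gene), then per (condition, gene); per housekeeper h,
`ΔCt = Ct_target − Ct_h`, `ΔΔCt = ΔCt_condition − ΔCt_reference`,
`fc_h = 2^(−ΔΔCt)`. Normalization is performed independently against each
housekeeper and the per-housekeeper fold-changes are combined by the
arithmetic mean (averaging the normalized expression values themselves);
the geometric mean — equivalent to averaging ΔΔCt — is available behind
`average="geometric"`. Fold-changes are invariant to any global Ct shift
of a sample, and the reference condition's fold-change is exactly 1.

## The simulator and what it does (not) emulate

`SimulationParams` defaults describe the study conditions the package is
built around: ~15,000 expressed genes, 4 conditions × 3 replicates,
regulated fractions 2329/15000 (A only), 994/15000 (B only) and 800/15000
(both), matching the motivating factorial experiment's Venn marginals.
Effect magnitudes |beta| are uniform on [0.5, 3] log₂ units with
independent ±1 signs (so induced and repressed genes split ~50/50, as
observed); baseline means are log-normal with median 300 counts and
sigma_log 1.5, and dispersions log-normal with median 0.02 and sigma_log
0.8 — deep bulk RNA-seq of a homogeneous cell line in triplicate.
Library-size factors are log-normal with sigma_log 0.15 unless supplied.
The interaction gamma defaults to a point mass at zero (exactly additive
truth); `gamma_sd > 0` adds normal interactions to regulated genes, and
truth tables can be edited directly for targeted scenarios (e.g. full
cancellation, `gamma = −betaB`). One global seed drives two independent
generator streams (truth, counts), so counts can be regenerated from an
edited truth table reproducibly.

The simulator deliberately omits several features of real data: no
GC/length biases, no batch effects, no correlation between genes, no
outlier samples, no mean-dispersion trend. Passing tests therefore
demonstrate that the estimators and the additivity statistic behave
correctly *under the stated model*; they do not certify robustness to
artefacts the model excludes.

## Problem sizes and tolerances used in validation

The validation suite measures: additivity-regression recovery on a purely
additive simulation of 5,000 genes (slope within [0.9, 1.1], intercept
within [−0.1, 0.1], r² > 0.90 on the union subset); type-I error on a
2,000-gene global null (within [0.035, 0.065] at nominal 0.05) and
realized null FDR averaged over 20 seeds (≤ 0.10); dispersion recovery at
200 replicates (Poisson truth below 0.02; alpha = 0.1 recovered within
[0.07, 0.13]); attenuation false-positive fraction ≤ 0.10 on additive
truth with B-only candidates and ≥ 80% detection of full-cancellation
genes (|betaB| ≥ 2, mean ≥ 200, 200 of 1,000 candidates); and exact
reproduction of the hand-computable size-factor, BH and ΔΔCt examples.
Published r² values from the motivating study's deposited dataset are not
reproduced here — they require the original accession and a bit-compatible
upstream pipeline — which is why the additivity criteria are stated as
parameter-recovery properties on simulations with known truth instead.

## Known limitations

- Gene-wise dispersions without moderation are noisy at triplicate scale;
  the t reference compensates at the testing level, but interval estimates
  for individual fold-changes remain approximate.
- The observed-vs-expected regression inherits errors-in-variables
  attenuation: the expected additive effect is itself estimated, so slopes
  slightly below 1 (~0.96 at the default conditions) are expected even
  under exact additivity.
- The attenuation rule is one of several defensible operationalizations;
  it is exposed as a single swappable operation.
- The four-level condition factor is fixed; designs with extra arms,
  covariates or time courses are out of scope.
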