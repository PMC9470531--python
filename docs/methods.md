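# Methods

This note documents the generative models, estimators, parameter defaults
and numerical choices in `famliab`, and what the synthetic validation does
and does not establish about real data.

## Liability-threshold family simulator

**Model.** Parents draw independent standard-normal polygenic scores
(PGS); the population PGS variance is normalized to 1. A child's PGS is
`N(midparent, 1/2)`: under additive inheritance the within-family
(segregation) variance is half the population variance, which is what
makes the child-minus-midparent deviation a clean null under no selection.
High-impact de novo counts are Poisson — not Bernoulli — so multi-variant
carriers exist; each variant independently hits a DD gene (a constrained
gene robustly associated with severe developmental disorders) with
probability `p_dd_gene`, and the carrier class takes precedence DD >
nonDD > none. Liability is

```
L = a * PGS + b * n_dnm + b_dd_extra * 1[any DD variant] + e,
e ~ N(0, 1 - a^2),
```

and diagnosis occurs when `L > Phi^-1(1 - K_sex)`. The simulator operates
at the score level for trios; per-SNP structure exists only in the
genotype panel, because the pTDT and association stages need only
score-level structure.

**Defaults** (units: liability SD unless noted):

| parameter | default | rationale |
|---|---|---|
| `a` | sqrt(0.1) | a PGS explaining ~10% of liability, typical of current autism scores |
| `b` | 1.0 | a strong per-variant shift, consistent with the large relative risks of high-impact variants |
| `mu_dnm` | 0.05 | a few percent of children carry a high-impact variant before ascertainment; ascertainment enriches this toward the ~10% seen in probands |
| `K_male`, `K_female` | 0.0276, 0.0084 | total prevalence 1.8% split at a 3.3:1 male:female ratio assuming equal sex frequencies |
| `p_dd_gene` | 0.3 | roughly a third of carriers are DD-gene carriers |
| `b_dd_extra` | 0.3 | DD-gene variants are more penetrant |
| `stoppage` | 0.3 | reproductive stoppage probability after an affected child; not calibrated (see below) |

Families plan two children; stoppage truncates the sibship after an
affected first child. Under `affected_proband` ascertainment the first
affected child is the proband. Sibling records only exist for families
with at least two children.

**What the simulator does not model**: linkage disequilibrium, population
structure, imputation error, assortative mating, diagnostic bias beyond
the threshold difference, or a quantitative split between stoppage and
parental underdiagnosis as causes of sibling undertransmission — the two
knobs (`stoppage`, thresholds) exist but their relative contribution is
deliberately left uncalibrated. Passing tests therefore show that the
*estimators* behave correctly under a clean additive liability model, not
that real cohorts satisfy that model.

**Phenotypes.** The 0–7 count of co-occurring developmental disabilities
and the milestone ages (months) are NB2 draws with log links; the default
log-rate coefficients (0.31 per de novo variant and −0.037 per PGS SD for
the disability count; −0.012 / −0.0125 per PGS SD for age of walking /
first words) are the effect sizes this class of study reports, so
refitting the corresponding quasi-Poisson / negative-binomial models on a
large synthetic cohort recovers them — an estimator-recovery check, not a
claim about real effect sizes. The count is distributed over seven binary
condition indicators (uniform weights) so leave-one-out analyses have
real columns to drop. The count cap at 7 binds rarely at the default
baseline mean (~1.2) and introduces a small downward bias (<1 SE at
n = 50,000) in recovery fits. IQ is a latent normal with a PGS loading
and a per-variant shift of 0.5 latent SD (~7.5 IQ points); the
intellectual-disability flag is IQ < 70. Factor scores are multivariate
normal with a two-block (social / non-social) correlation structure by
default plus a small PGS-linked component.

**Genotype panel.** SNPs are in Hardy–Weinberg proportions at MAFs
uniform on (0.05, 0.5); all m SNPs are causal with normal effects scaled
to the target h². Binary phenotypes threshold the liability at
`Phi^-1(1-K)`; case-control panels are built by rejection sampling until
the requested case fraction is met, mirroring full ascertainment with a
case:control ratio capped at 1.

## pTDT

The default deviation is `(child - midparent) / SD(midparent)` with the
sample (n−1) SD computed within the analysed stratum — the pTDT
literature convention, and invariant to affine rescaling of the raw
score. A second mode standardizes child and parents by the pooled
parental mean/SD first; it is provided because "standardized by the
parental mean and standard deviation" is genuinely ambiguous between the
two readings, and the two differ only by a scale factor close to
`SD(midparent)/SD(parents) ~ sqrt(1/2)`. The one-sample test uses t (not
normal) for finite-n correctness; stratum contrasts use the normal Z
contrast conventionally reported. Multi-proband families are treated as
independent trios by default (family IDs are retained for clustering, and
the association battery offers cluster-robust SEs).

## Association battery

Continuous predictors are z-scored so coefficients are per-SD; binary
indicators stay on their natural scale. Count outcomes are fitted both as
overdispersed Poisson (Pearson-χ²/df scaling of the covariance — the
quasi-Poisson variance assumption, linear in the mean) and as maximum
likelihood NB2 (variance quadratic in the mean); `auto_count` keeps the
family with the lower residual deviance. Family relatedness is handled by
cluster-robust standard errors rather than random intercepts: a moment
approximation chosen so that the whole battery stays within a single GLM
framework; it is an approximation of a mixed model, documented as such.
Benjamini–Yekutieli is applied within each battery (one outcome set), the
appropriate correction under the arbitrary dependence of highly
correlated phenotypes. BY and the GLMs come from statsmodels; the IVW
pooling, Cochran's Q and I² are implemented here and frozen against
worked-example arithmetic in the tests.

## Heritability

The estimator is Haseman–Elston regression — the slope of pairwise
phenotype cross-products on GRM entries over distinct pairs, with an
intercept — rather than REML: the moment estimator is transparent,
dependency-free, and consistent for the observed-scale variance ratio,
which is the quantity the liability conversion consumes. Standard errors
come from a delete-one-block jackknife over 20 equal individual blocks
(configurable); deleting a block removes every pair touching it. The GRM
standardizes by sample allele frequencies and drops monomorphic SNPs.

The liability conversion multiplies the observed-scale case-control
estimate by `K^2(1-K)^2 / (z^2 P(1-P))`; at `K = P = 0.5` this is π/2
exactly, a useful closed-form anchor. The conversion corrects for
ascertainment through P; residual small-sample bias of HE+conversion at
K = 0.02, truth 0.3, is below the 0.05 acceptance band used here (mean
over 20 seeds ≈ 0.30). Known limitation: no covariate adjustment (the
full PCGC-with-covariates correction is out of scope), so equivalence
with likelihood methods is claimed only for the covariate-free case. The
bivariate cross-product variant is exposed but flagged experimental (no
jackknife SE).

Subgroup prevalences: a factor-score subtype defined by > +1 SD carries
the normal upper-tail mass `1 - Phi(1) = 15.87%` of the total prevalence;
an F1>F2-type split is exactly 50% by exchangeability; carrier subgroups
multiply by an external share; sex-specific prevalences follow from a
male:female ratio r as `K_m = 2rK/(1+r)`, `K_f = 2K/(1+r)` under equal
sex frequencies. `K_total = 1` is admitted so the same function reports
raw shares.

## Variant filtering

Thresholds are applied exactly as conventionally printed and strictly:
LOEUF < 0.37 (the most-constrained decile), MPC > 2; boundary values
(MPC = 2.0, LOEUF = 0.37) do not qualify and are pinned in tests.
Structural variants count as high-impact whenever they overlap a
constrained gene, with no deletion/duplication distinction. The DD gene
list is a plain text file of symbols, so sensitivity lists (e.g. a
DDG2P-style superset) are drop-in replacements. Missing LOEUF
annotations cannot satisfy the constraint rule; such variants are
excluded with a warning count — a package policy for a case the
literature leaves unspecified. Chromosome labels accept both `21` and
`chr21`; `X`/`Y` fail the autosome restriction.

## Psychometrics

Factor models enter as fitted loading tables; rotation and DWLS fitting
on polychorics are out of scope because the reusable computation is the
scoring and the decision metrics, not the SEM optimizer. Thurstone
regression scores use `Sigma^-1 Lambda Phi` weights with
`Sigma = Lambda Phi Lambda' + diag(theta)`; items are treated as
standardized continuous, a documented divergence from ordinal-DWLS
scoring whose practical closeness is untested here. Hierarchical omega
and ECV use the standard bifactor sums. The Jennrich (1970) chi-square
for equality of two correlation matrices is implemented from the original
formula (`tr(Z^2)/2 - dg(Z)' S^-1 dg(Z)`); its null calibration (mean ≈
df) is verified by simulation, and a 2×2 case is frozen against hand
arithmetic. The Wilcoxon rank-sum uses the normal approximation with tie
correction.

## Power simulation

Per replicate, a mediator responds to the fixed de novo design vector,
and the outcome correlates with the standardized mediator at target r; the
outcome is then regressed on the de novo count and power is the rejection
fraction at α = 0.05 over B = 1,000 replicates (Wilson 95% CI). The
de novo effect on the mediator is configurable so meta-analytic carrier
effects can be plugged in. At r = 1 the Monte-Carlo power matches the
noncentral-t analytic power for the induced correlation; at r = 0 it
matches α. The 80% crossing is linearly interpolated on the grid and
reported as NaN when never reached.

## Problem sizes

The validation suite uses: 20 replicate genotype panels of n = 2,000 ×
m = 1,000 for heritability recovery; 1,000 null cohorts of 500 families
for pTDT calibration; 5,000 ascertained cases for the overtransmission
and anticorrelation checks; 50 replicate cohorts of 20,000 families for
the sex-differential contrasts; and B = 1,000 replicates for power.
These sizes put the Monte-Carlo error of each quantity well below the
band it is judged at while keeping a full run in the minutes range.
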