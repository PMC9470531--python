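# famliab

Family-based liability-threshold simulation and the trio statistics that go
with it.

Large autism family cohorts are analysed with a recurring set of tools:
polygenic transmission disequilibrium tests (pTDT), regression batteries
relating polygenic scores (PGS) and high-impact de novo variants to
phenotypes, inverse-variance-weighted (IVW) meta-analysis across cohorts,
case-control SNP heritability with liability-scale conversion, and bifactor
decision metrics for phenotype factor models. Access to the underlying
cohorts is restricted, which makes the *machinery* hard to test and reuse.
`famliab` packages that machinery together with a synthetic family simulator
that reproduces the statistical structure of such cohorts, so every analysis
stage can be exercised, calibrated and validated end to end without any data
access.

## The model

Each child in a simulated family has latent liability

```
L = a * PGS_child + b * n_dnm (+ b_dd_extra if a DD-gene variant) + e,
e ~ N(0, 1 - a^2)
```

with `PGS_child ~ N(midparent, 1/2)` (additive Mendelian segregation around
the midparental mean), `n_dnm ~ Poisson(mu)` high-impact de novo variants,
and diagnosis when `L` exceeds the sex-specific threshold
`Phi^-1(1 - K_sex)`. Reproductive stoppage and proband ascertainment
distort the sampled families the way recruitment distorts real cohorts —
which is exactly what the pTDT and the carrier/PGS anticorrelation detect.

Key statistics implemented on top of this:

- **pTDT**: per-trio deviation `(PGS_child - midparent) / SD(midparent)`,
  one-sample t-test, stratified contrasts via two-sided Z-tests, relative
  risks with delta-method CIs.
- **Association battery**: Gaussian / logistic / quasi-Poisson /
  negative-binomial GLMs (lower-residual-deviance choice for counts),
  cluster-robust SEs for within-family relatedness, Benjamini–Yekutieli
  correction, and IVW meta-analysis with Cochran's Q and I².
- **SNP heritability**: GCTA-style GRM, Haseman–Elston regression with a
  block jackknife, and the liability-scale conversion
  `h2_liab = h2_obs * K^2 (1-K)^2 / (z^2 P (1-P))` with prevalence scans
  and subgroup prevalence derivations.
- **Variant filtering**: high-impact = damaging consequence or MPC>2
  missense or structural variant, in a LOEUF<0.37 autosomal gene; carrier
  classes `DD` / `nonDD` / `none` against a supplied DD gene list.
- **Psychometrics**: Thurstone regression factor scores, hierarchical
  omega and explained common variance for bifactor layouts, Jennrich and
  Fisher-z correlation contrasts, Wilcoxon rank-sum tests.
- **Power**: simulation-based power for de novo effects on core features
  mediated through associated features, over a grid of mediator-outcome
  correlations.

## Worked example

```python
import numpy as np
from famliab import (
    LiabilityParams, simulate_trio_cohort, ptdt_deviation, ptdt_test,
)

params = LiabilityParams(n_families=60000, seed=202)  # proband-ascertained
cohort = simulate_trio_cohort(params)
probands = cohort[(cohort.role == "proband") & cohort.affected]
res = ptdt_test(ptdt_deviation(probands))
print(f"n={res.n} mean={res.mean_deviation:.3f} se={res.se:.3f} p={res.p:.2e}")
```

prints

```
n=2994 mean=0.471 se=0.019 p=3.88e-124
```

Affected probands carry ~0.48 midparent-SD more polygenic liability than
their midparental expectation — overtransmission detected by the pTDT, of
the kind real trio cohorts show. In an *unascertained* cohort
(`ascertain="none"`) the same statistic is null-calibrated: the mean
deviation is within Monte-Carlo error of zero and the test rejects at the
nominal 5% rate.

The same cohort feeds the rest of the pipeline, e.g. regressing carrier
status on PGS among cases (negative, ascertainment-induced) or writing
`trios.tsv` / `variants.tsv` for the CLI:

```sh
famliab simulate --config cfg.yaml --seed 7 --out cohort/
famliab ptdt --trios cohort/trios.tsv --stratify sex --out ptdt.tsv
famliab filter-variants --variants cohort/variants.tsv \
    --dd-genes cohort/dd_genes.txt --out carriers.tsv
```

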