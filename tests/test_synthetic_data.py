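"""Generator correctness: segregation, ascertainment, determinism, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famliab import (
    EmptyCohortError,
    LiabilityParams,
    ParameterError,
    PhenotypeParams,
    simulate_genotype_panel,
    simulate_phenotypes,
    simulate_trio_cohort,
)
from famliab.assoc_meta import AssocSpec, fit_association


def test_segregation_null_mean_and_variance():
    """Without selection, child minus midparent has mean 0 and variance 1/2."""
    params = LiabilityParams(
        n_families=1000, seed=7, a=0.0, b=0.0, mu_dnm=0.0,
        K_male=0.999999, K_female=0.999999, ascertain="none", stoppage=0.0,
    )
    cohort = simulate_trio_cohort(params)
    dev = cohort["pgs_child"] - cohort["midparent"]
    mc_se = np.sqrt(0.5 / len(dev))
    assert abs(dev.mean()) < 3 * mc_se
    assert abs(dev.var(ddof=1) - 0.5) < 0.05


def test_same_seed_identical_tables():
    params = LiabilityParams(n_families=500, seed=42)
    a = simulate_trio_cohort(params)
    b = simulate_trio_cohort(LiabilityParams(n_families=500, seed=42))
    pd.testing.assert_frame_equal(a, b)


def test_midparent_invariant(null_cohort):
    expected = 0.5 * (null_cohort["pgs_father"] + null_cohort["pgs_mother"])
    assert np.allclose(null_cohort["midparent"], expected)


def test_carrier_class_consistent_with_counts(null_cohort):
    none = null_cohort[null_cohort["carrier_class"] == "none"]
    carriers = null_cohort[null_cohort["carrier_class"] != "none"]
    assert (none["n_dnm"] == 0).all()
    assert (carriers["n_dnm"] > 0).all()
    dd = null_cohort[null_cohort["carrier_class"] == "DD"]
    assert (dd["n_dnm_dd"] > 0).all()


def test_ascertainment_anticorrelation():
    """Selecting on diagnosis makes carrier cases PGS-poorer than non-carrier cases."""
    params = LiabilityParams(
        n_families=50000, seed=9, a=np.sqrt(0.1), b=3.0, mu_dnm=0.05,
        K_male=0.02, K_female=0.02, ascertain="affected_proband",
    )
    cohort = simulate_trio_cohort(params)
    cases = cohort[cohort["affected"] & (cohort["role"] == "proband")]
    carrier = cases[cases["carrier_class"] != "none"]["pgs_child"]
    noncarrier = cases[cases["carrier_class"] == "none"]["pgs_child"]
    t, p = stats.ttest_ind(carrier, noncarrier)
    assert carrier.mean() < noncarrier.mean()
    assert p < 0.05


def test_population_pgs_carrier_independence():
    """In the unselected population, PGS and carrier status are uncorrelated."""
    params = LiabilityParams(
        n_families=20000, seed=10, a=np.sqrt(0.1), b=1.0, mu_dnm=0.1,
        ascertain="none",
    )
    cohort = simulate_trio_cohort(params)
    carrier = (cohort["carrier_class"] != "none").astype(float)
    r = np.corrcoef(cohort["pgs_child"], carrier)[0, 1]
    assert abs(r) < 3.0 / np.sqrt(len(cohort))


def test_sex_threshold_affected_females_higher_pgs(ascertained_cohort):
    """With K_f < K_m, affected females carry more polygenic liability."""
    cases = ascertained_cohort[ascertained_cohort["affected"]]
    f = cases[cases["sex"] == "F"]["pgs_child"]
    m = cases[cases["sex"] == "M"]["pgs_child"]
    se = np.sqrt(f.var(ddof=1) / len(f) + m.var(ddof=1) / len(m))
    assert f.mean() - m.mean() > 0
    assert (f.mean() - m.mean()) / se > 2


def test_unaffected_sibling_undertransmission(ascertained_cohort):
    """Unaffected siblings show non-positive mean transmission deviation."""
    from famliab import ptdt_deviation

    sibs = ascertained_cohort[
        (ascertained_cohort["role"] == "sibling") & ~ascertained_cohort["affected"]
    ]
    dev = ptdt_deviation(sibs)
    assert dev.mean() <= 3.0 / np.sqrt(len(dev))


def test_stoppage_truncates_sibships():
    base = dict(n_families=20000, a=0.3, b=0.0, mu_dnm=0.0, K_male=0.05,
                K_female=0.05, ascertain="none")
    no_stop = simulate_trio_cohort(LiabilityParams(seed=3, stoppage=0.0, **base))
    full_stop = simulate_trio_cohort(LiabilityParams(seed=3, stoppage=1.0, **base))
    assert len(full_stop) < len(no_stop)
    # with full stoppage no affected first child has a later sibling
    first_aff = full_stop[(full_stop["child_id"].str.endswith("C1")) & full_stop["affected"]]
    fams = set(first_aff["family_id"])
    second = full_stop[full_stop["child_id"].str.endswith("C2")]
    assert fams.isdisjoint(set(second["family_id"]))


def test_invalid_parameters_rejected():
    with pytest.raises(ParameterError):
        LiabilityParams(n_families=100, seed=0, a=1.2).validate()
    with pytest.raises(ParameterError):
        LiabilityParams(n_families=100, seed=0, K_male=0.0).validate()
    with pytest.raises(ParameterError):
        LiabilityParams(n_families=100, seed=0, mu_dnm=-1).validate()


def test_empty_cohort_error():
    params = LiabilityParams(
        n_families=50, seed=1, a=0.0, b=0.0, mu_dnm=0.0,
        K_male=1e-9, K_female=1e-9, ascertain="affected_proband",
    )
    with pytest.raises(EmptyCohortError):
        simulate_trio_cohort(params)


def test_phenotype_coefficient_recovery():
    """Refitting the count models recovers the generative coefficients."""
    cohort = simulate_trio_cohort(
        LiabilityParams(n_families=52000, seed=17, ascertain="none")
    )
    probands = cohort[cohort["role"] == "proband"].head(50000)
    ph = simulate_phenotypes(probands, PhenotypeParams(dd_gene_extra=0.0), seed=18)
    res = fit_association(
        ph,
        AssocSpec(outcome="dd_count", predictors=["n_dnm", "pgs_child"],
                  family="quasipoisson", standardize=False),
    ).set_index("term")
    assert abs(res.loc["n_dnm", "beta"] - 0.31) < 2 * res.loc["n_dnm", "se"]
    assert abs(res.loc["pgs_child", "beta"] - (-0.037)) < 2 * res.loc["pgs_child", "se"]
    walk = fit_association(
        ph,
        AssocSpec(outcome="age_walk_mo", predictors=["pgs_child"],
                  family="negative_binomial", standardize=False),
    ).set_index("term")
    assert abs(walk.loc["pgs_child", "beta"] - (-0.012)) < 2.5 * walk.loc["pgs_child", "se"]


def test_null_phenotype_model_calibrated():
    """With all effects zero, carrier status is non-significant in >=90% of replicates."""
    null = PhenotypeParams(
        beta_dnm_dd=0.0, beta_pgs_dd=0.0, dd_gene_extra=0.0,
        beta_pgs_walk=0.0, beta_dnm_walk=0.0, beta_pgs_words=0.0, beta_dnm_words=0.0,
    )
    cohort = simulate_trio_cohort(
        LiabilityParams(n_families=600, seed=13, mu_dnm=0.3, ascertain="none")
    )
    probands = cohort[cohort["role"] == "proband"]
    hits = 0
    n_rep = 100
    for k in range(n_rep):
        ph = simulate_phenotypes(probands, null, seed=1000 + k)
        res = fit_association(
            ph,
            AssocSpec(outcome="dd_count", predictors=["n_dnm"],
                      family="quasipoisson", standardize=False),
        )
        if res["p"].iloc[0] < 0.05:
            hits += 1
    assert hits <= 0.10 * n_rep


def test_factor_independence_under_identity_phi():
    params = PhenotypeParams(factor_phi=np.eye(6), factor_h2=np.zeros(6))
    cohort = simulate_trio_cohort(
        LiabilityParams(n_families=5200, seed=14, ascertain="none")
    )
    ph = simulate_phenotypes(cohort[cohort["role"] == "proband"], params, seed=15)
    cols = [f"factor{i}" for i in range(1, 7)]
    corr = ph[cols].corr().to_numpy()
    off = corr[np.triu_indices(6, 1)]
    assert np.all(np.abs(off) < 3.0 / np.sqrt(len(ph)))


def test_bad_factor_phi_rejected(null_cohort):
    phi = np.full((6, 6), 1.0)  # rank-1, not PD
    with pytest.raises(ParameterError):
        simulate_phenotypes(
            null_cohort.head(50), PhenotypeParams(factor_phi=phi), seed=1
        )


def test_genotype_panel_determinism_and_hwe():
    a = simulate_genotype_panel(300, 200, h2=0.3, seed=21)
    b = simulate_genotype_panel(300, 200, h2=0.3, seed=21)
    assert np.array_equal(a.dosages, b.dosages)
    assert np.array_equal(a.phenotype, b.phenotype)
    assert set(np.unique(a.dosages)) <= {0.0, 1.0, 2.0}
    # sample frequencies track the generative MAFs
    p_hat = a.dosages.mean(axis=0) / 2
    assert np.corrcoef(p_hat, a.freqs)[0, 1] > 0.95


def test_genotype_panel_binary_ascertainment():
    panel = simulate_genotype_panel(
        400, 100, h2=0.3, binary=True, K=0.02, case_fraction=0.5, seed=22
    )
    assert panel.phenotype.mean() == pytest.approx(0.5)
    assert panel.dosages.shape == (400, 100)


def test_genotype_panel_domain_errors():
    with pytest.raises(ParameterError):
        simulate_genotype_panel(100, 10, maf_range=(0.0, 0.6))
    with pytest.raises(ParameterError):
        simulate_genotype_panel(100, 10, h2=1.5)
    with pytest.raises(ParameterError):
        simulate_genotype_panel(100, 10, binary=True, K=None)
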