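"""Reproducible study-condition experiments.

Each function runs one of the package's headline Monte-Carlo analyses at
its standard conditions (cohort sizes, effect sizes, replicate counts) and
returns plain dictionaries of summary numbers.  They are what the
acceptance script and the calibration tests execute; the sizes are chosen
to resolve each quantity's Monte-Carlo error well below the tolerance it
is judged at.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from famliab.assoc_meta import AssocSpec, fit_association
from famliab.heritability import estimate_h2_liability, subgroup_prevalence
from famliab.ptdt import ptdt_deviation, ptdt_test
from famliab.synthetic_data import (
    LiabilityParams,
    simulate_genotype_panel,
    simulate_trio_cohort,
)


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 100003 + k) % (2**31 - 1)


def heritability_recovery(
    seed: int = 0,
    n_seeds: int = 20,
    n: int = 2000,
    m: int = 1000,
    h2: float = 0.3,
    K: float = 0.02,
    case_fraction: float = 0.5,
) -> dict:
    """Liability h2 recovery: binary panels, HE regression, Lee conversion.

    Simulates ``n_seeds`` fully ascertained case-control panels (true
    liability-scale h2, prevalence K, case proportion ``case_fraction``),
    estimates observed-scale h2 by Haseman-Elston regression on the GRM
    and converts to the liability scale.
    """
    estimates, ses = [], []
    for k in range(n_seeds):
        panel = simulate_genotype_panel(
            n=n,
            m=m,
            h2=h2,
            binary=True,
            K=K,
            case_fraction=case_fraction,
            seed=_sub_seed(seed, k),
        )
        est = estimate_h2_liability(panel, K=K)
        estimates.append(est.h2_liab)
        ses.append(est.se_liab)
    estimates = np.asarray(estimates)
    ses = np.asarray(ses)
    return {
        "true_h2": h2,
        "mean_h2_liab": float(estimates.mean()),
        "estimates": estimates,
        "ses": ses,
        "abs_error": float(abs(estimates.mean() - h2)),
        "n_within_3se": int(np.sum(np.abs(estimates - h2) <= 3.0 * ses)),
        "n_seeds": n_seeds,
    }


def ptdt_null_calibration(
    seed: int = 0, n_cohorts: int = 1000, n_families: int = 500, alpha: float = 0.05
) -> dict:
    """Type-I error of the pTDT over unascertained null cohorts."""
    rejections = 0
    for k in range(n_cohorts):
        params = LiabilityParams(
            n_families=n_families, seed=_sub_seed(seed, k), ascertain="none"
        )
        cohort = simulate_trio_cohort(params)
        probands = cohort[cohort["role"] == "proband"]
        res = ptdt_test(ptdt_deviation(probands))
        if res.p < alpha:
            rejections += 1
    return {
        "rejection_rate": rejections / n_cohorts,
        "n_cohorts": n_cohorts,
        "alpha": alpha,
    }


def ptdt_ascertained(seed: int = 0, n_probands: int = 5000) -> dict:
    """pTDT overtransmission in ascertained probands (a^2 = 0.1)."""
    params = LiabilityParams(
        n_families=320000, seed=seed, ascertain="affected_proband"
    )
    cohort = simulate_trio_cohort(params)
    probands = cohort[(cohort["role"] == "proband") & cohort["affected"]].head(
        n_probands
    )
    res = ptdt_test(ptdt_deviation(probands))
    return {"mean_deviation": res.mean_deviation, "se": res.se, "p": res.p, "n": res.n}


def carrier_pgs_anticorrelation(seed: int = 0, n_cases: int = 5000) -> dict:
    """Regression of carrier status on PGS among ascertained cases.

    With positive PGS and de novo liability effects, selecting on
    diagnosis induces a negative PGS-carrier association among cases even
    though the two are independent in the population.
    """
    params = LiabilityParams(
        n_families=280000,
        seed=seed,
        a=np.sqrt(0.1),
        b=3.0,
        mu_dnm=0.05,
        K_male=0.02,
        K_female=0.02,
        ascertain="affected_proband",
    )
    cohort = simulate_trio_cohort(params)
    cases = cohort[(cohort["role"] == "proband") & cohort["affected"]].head(n_cases)
    data = cases.assign(carrier=(cases["carrier_class"] != "none").astype(int))
    res = fit_association(
        data,
        AssocSpec(outcome="carrier", predictors=["pgs_child"], family="binomial"),
    )
    row = res.iloc[0]
    return {"beta": float(row["beta"]), "se": float(row["se"]), "p": float(row["p"]), "n": int(row["n"])}


def sex_differential_replicates(
    seed: int = 0, n_reps: int = 50, n_families: int = 20000
) -> dict:
    """Female-vs-male case PGS and pTDT contrasts under K_f < K_m.

    Sex-specific prevalences come from a total prevalence of 1.8% split at
    a male:female ratio of 3.3:1.  For each replicate cohort the mean
    case PGS and the mean pTDT deviation are compared between sexes; the
    counts of replicates with the female value above the male value feed
    a sign test.
    """
    K_m, K_f = subgroup_prevalence("sex_ratio", K_total=0.018, ratio=3.3)
    wins_pgs = wins_ptdt = 0
    diffs_pgs, diffs_ptdt = [], []
    for k in range(n_reps):
        params = LiabilityParams(
            n_families=n_families,
            seed=_sub_seed(seed, k),
            K_male=K_m,
            K_female=K_f,
            ascertain="affected_proband",
        )
        cohort = simulate_trio_cohort(params)
        cases = cohort[(cohort["role"] == "proband") & cohort["affected"]]
        females = cases[cases["sex"] == "F"]
        males = cases[cases["sex"] == "M"]
        if len(females) < 2 or len(males) < 2:
            continue
        d_pgs = females["pgs_child"].mean() - males["pgs_child"].mean()
        d_ptdt = ptdt_deviation(females).mean() - ptdt_deviation(males).mean()
        diffs_pgs.append(d_pgs)
        diffs_ptdt.append(d_ptdt)
        wins_pgs += d_pgs > 0
        wins_ptdt += d_ptdt > 0
    n_eff = len(diffs_pgs)
    p_pgs = float(stats.binomtest(wins_pgs, n_eff, alternative="greater").pvalue)
    p_ptdt = float(stats.binomtest(wins_ptdt, n_eff, alternative="greater").pvalue)
    return {
        "n_reps": n_eff,
        "wins_pgs": int(wins_pgs),
        "wins_ptdt": int(wins_ptdt),
        "sign_p_pgs": p_pgs,
        "sign_p_ptdt": p_ptdt,
        "mean_diff_pgs": float(np.mean(diffs_pgs)),
        "mean_diff_ptdt": float(np.mean(diffs_ptdt)),
    }
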