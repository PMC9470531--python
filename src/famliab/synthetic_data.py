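"""Synthetic family cohorts under a liability-threshold model.

The generator emulates the statistical structure of large autism trio
cohorts: each family contributes parental polygenic scores (PGS), children
whose PGS segregate around the midparental mean with half the population
variance, Poisson-distributed high-impact de novo variant counts, and a
latent liability

    L = a * PGS_child + b * n_dnm (+ b_dd_extra if a DD-gene variant) + e,

with ``e ~ N(0, 1 - a**2)`` so that the PGS explains ``a**2`` of the
residual (non-de-novo) liability variance.  A child is affected when L
exceeds the sex-specific threshold ``Phi^{-1}(1 - K_sex)``.  Reproductive
stoppage and proband-based ascertainment distort the sampled families the
way recruitment distorts real cohorts.

Downstream phenotypes (counts of co-occurring developmental disabilities,
motor/language milestone ages, IQ bins, six correlated factor scores) are
generated from generalized-linear models whose default coefficients are the
effect sizes this class of study reports, so that refitting the models on
the synthetic cohort recovers them.

A per-SNP genotype panel (Hardy-Weinberg sampling at random MAFs with an
additive polygenic architecture) supports the heritability pathway; trio
simulation itself is score-level by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ParameterError(ValueError):
    """A simulation parameter is outside its admissible domain."""


class EmptyCohortError(RuntimeError):
    """Ascertainment removed every simulated family."""


#: The seven binary co-occurring developmental disability indicators.
DD_CONDITIONS = (
    "dd_id_gdd",
    "dd_language",
    "dd_learning",
    "dd_motor",
    "dd_mutism",
    "dd_social_pragmatic",
    "dd_speech_articulation",
)

_ASCERTAIN_MODES = ("affected_proband", "proband_plus_unaffected_sibling", "none")


@dataclass
class LiabilityParams:
    """Parameters of the liability-threshold trio generator.

    Parameters
    ----------
    n_families : int
        Families simulated before ascertainment.
    seed : int
        RNG seed; a single stream drives the whole cohort.
    a : float
        Liability loading of the standardized autism PGS (variance
        explained ``a**2``).  Default ``sqrt(0.1)``, i.e. a PGS explaining
        10% of liability, typical of current autism scores.
    b : float
        Liability shift per high-impact de novo variant, in liability-SD
        units.
    mu_dnm : float
        Expected high-impact de novo count per child (Poisson rate).
    K_male, K_female : float
        Sex-specific population prevalences.  Defaults derive from a total
        prevalence of 1.8% split at a 3.3:1 male:female ratio.
    p_dd_gene : float
        Probability that a simulated high-impact variant hits a gene
        associated with severe developmental disorders (a "DD gene").
    b_dd_extra : float
        Additional liability shift when at least one variant is in a DD
        gene.
    stoppage : float
        Probability that a family has no further children after an
        affected child (reproductive stoppage).
    ascertain : str
        One of ``affected_proband``, ``proband_plus_unaffected_sibling``
        or ``none``.
    """

    n_families: int
    seed: int
    a: float = 0.31622776601683794
    b: float = 1.0
    mu_dnm: float = 0.05
    K_male: float = 0.0276
    K_female: float = 0.0084
    p_dd_gene: float = 0.3
    b_dd_extra: float = 0.3
    stoppage: float = 0.3
    ascertain: str = "affected_proband"

    def validate(self) -> None:
        if self.n_families <= 0:
            raise ParameterError("n_families must be positive")
        if not (0.0 <= self.a**2 < 1.0):
            raise ParameterError(
                f"a^2 must lie in [0, 1) for positive residual variance, got a={self.a}"
            )
        for name, K in (("K_male", self.K_male), ("K_female", self.K_female)):
            if not (0.0 < K < 1.0):
                raise ParameterError(f"{name} must lie in (0, 1), got {K}")
        if self.mu_dnm < 0:
            raise ParameterError("mu_dnm must be non-negative")
        if not (0.0 <= self.p_dd_gene <= 1.0):
            raise ParameterError("p_dd_gene must lie in [0, 1]")
        if not (0.0 <= self.stoppage <= 1.0):
            raise ParameterError("stoppage must lie in [0, 1]")
        if self.ascertain not in _ASCERTAIN_MODES:
            raise ParameterError(
                f"ascertain must be one of {_ASCERTAIN_MODES}, got {self.ascertain!r}"
            )


def _default_factor_phi() -> np.ndarray:
    # Two blocks of three factors (social / non-social) with higher
    # within-block than between-block correlation.
    phi = np.full((6, 6), 0.25)
    for block in (slice(0, 3), slice(3, 6)):
        phi[block, block] = 0.5
    np.fill_diagonal(phi, 1.0)
    return phi


@dataclass
class PhenotypeParams:
    """Generative coefficients for the downstream phenotype models.

    Count outcomes use a log link: the number of co-occurring developmental
    disabilities (0-7) responds to the de novo count with ``beta_dnm_dd``
    (default 0.31) and to the autism PGS with ``beta_pgs_dd`` (default
    -0.037); milestone ages in months respond to the PGS with
    ``beta_pgs_walk``/``beta_pgs_words`` (defaults -0.012 / -0.0125).
    Overdispersion is negative-binomial with the given ``*_dispersion``
    (NB2 alpha).  ``dd_gene_extra`` adds a log-rate shift for DD-gene
    carriers on counts and milestones, reproducing the more severe
    developmental profile of that carrier class.
    """

    beta_dnm_dd: float = 0.31
    beta_pgs_dd: float = -0.037
    dd_intercept: float = 0.1
    dd_dispersion: float = 0.3
    beta_pgs_walk: float = -0.012
    beta_dnm_walk: float = 0.08
    walk_intercept: float = float(np.log(13.0))
    walk_dispersion: float = 0.05
    beta_pgs_words: float = -0.0125
    beta_dnm_words: float = 0.08
    words_intercept: float = float(np.log(16.0))
    words_dispersion: float = 0.15
    dd_gene_extra: float = 0.2
    factor_phi: np.ndarray = field(default_factory=_default_factor_phi)
    factor_h2: np.ndarray = field(default_factory=lambda: np.full(6, 0.05))
    # (PGS loading on latent IQ, per-variant IQ shift in latent SD, ID cutoff)
    iq_model: tuple = (0.25, 0.5, 70.0)

    def validate(self) -> None:
        phi = np.asarray(self.factor_phi, dtype=float)
        if phi.shape != (6, 6):
            raise ParameterError("factor_phi must be 6x6")
        if not np.allclose(phi, phi.T):
            raise ParameterError("factor_phi must be symmetric")
        if not np.allclose(np.diag(phi), 1.0):
            raise ParameterError("factor_phi must have unit diagonal")
        try:
            np.linalg.cholesky(phi)
        except np.linalg.LinAlgError as exc:
            raise ParameterError("factor_phi must be positive-definite") from exc
        for name in ("dd_dispersion", "walk_dispersion", "words_dispersion"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        h2 = np.asarray(self.factor_h2, dtype=float)
        if h2.shape != (6,) or np.any(h2 < 0) or np.any(h2 > 1):
            raise ParameterError("factor_h2 must be six values in [0, 1]")


@dataclass
class GenotypePanel:
    """An additive-dosage SNP panel with known generative truth."""

    dosages: np.ndarray  # (n, m) values in {0, 1, 2}
    freqs: np.ndarray  # generative allele frequencies, length m
    effects: np.ndarray  # per-SNP effects on the standardized genotype scale
    phenotype: np.ndarray  # quantitative values or 0/1 case status
    h2: float  # true (liability-scale, if binary) heritability
    binary: bool
    K: Optional[float] = None  # population prevalence when binary
    ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if self.ids is None:
            self.ids = [f"I{i + 1:06d}" for i in range(self.dosages.shape[0])]


def simulate_trio_cohort(params: LiabilityParams) -> pd.DataFrame:
    """Simulate a family cohort under the liability-threshold model.

    Each family draws two parents with standard-normal PGS and up to two
    children whose PGS are ``N(midparent, 1/2)`` (additive Mendelian
    segregation).  Reproductive stoppage truncates the sibship after an
    affected first child with probability ``params.stoppage``.  Under
    ``affected_proband`` ascertainment only families with at least one
    affected child are retained, the first affected child becoming the
    proband; ``proband_plus_unaffected_sibling`` additionally requires an
    unaffected sibling; ``none`` keeps every family (first child labelled
    proband).

    Returns a DataFrame with one row per retained child, including both
    parents' scores, the midparental mean, de novo counts, carrier class
    and affection status.  Deterministic under a fixed seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_families

    father = rng.normal(size=n)
    mother = rng.normal(size=n)
    midparent = 0.5 * (father + mother)

    shape = (n, 2)
    pgs = midparent[:, None] + rng.normal(scale=np.sqrt(0.5), size=shape)
    is_male = rng.random(shape) < 0.5
    n_dnm = rng.poisson(params.mu_dnm, size=shape)
    n_dnm_dd = rng.binomial(n_dnm, params.p_dd_gene)
    has_dd = n_dnm_dd > 0

    resid_sd = np.sqrt(1.0 - params.a**2)
    liability = (
        params.a * pgs
        + params.b * n_dnm
        + params.b_dd_extra * has_dd
        + rng.normal(scale=resid_sd, size=shape)
    )
    thr = np.where(is_male, stats.norm.isf(params.K_male), stats.norm.isf(params.K_female))
    affected = liability > thr

    stop = rng.random(n) < params.stoppage
    exists = np.ones(shape, dtype=bool)
    exists[:, 1] = ~(affected[:, 0] & stop)

    aff1 = affected[:, 0]
    aff2 = affected[:, 1] & exists[:, 1]
    proband_slot = np.where(aff1, 0, np.where(aff2, 1, -1))

    if params.ascertain == "none":
        keep_family = np.ones(n, dtype=bool)
        proband_slot = np.zeros(n, dtype=int)
    elif params.ascertain == "affected_proband":
        keep_family = proband_slot >= 0
    else:  # proband_plus_unaffected_sibling
        sib_slot = 1 - proband_slot
        has_unaffected_sib = (proband_slot >= 0) & exists[
            np.arange(n), np.clip(sib_slot, 0, 1)
        ] & ~affected[np.arange(n), np.clip(sib_slot, 0, 1)]
        keep_family = has_unaffected_sib

    if not keep_family.any():
        raise EmptyCohortError(
            "ascertainment removed every simulated family; "
            "increase n_families or relax the ascertainment mode"
        )

    fam_idx = np.nonzero(keep_family)[0]
    rows = []
    for slot in (0, 1):
        mask = exists[fam_idx, slot]
        fa = fam_idx[mask]
        rows.append(
            pd.DataFrame(
                {
                    "_fam": fa,
                    "_slot": slot,
                    "sex": np.where(is_male[fa, slot], "M", "F"),
                    "affected": affected[fa, slot],
                    "pgs_child": pgs[fa, slot],
                    "pgs_father": father[fa],
                    "pgs_mother": mother[fa],
                    "midparent": midparent[fa],
                    "n_dnm": n_dnm[fa, slot],
                    "n_dnm_dd": n_dnm_dd[fa, slot],
                    "role": np.where(proband_slot[fa] == slot, "proband", "sibling"),
                }
            )
        )
    out = pd.concat(rows, ignore_index=True).sort_values(["_fam", "_slot"], kind="stable")
    out["family_id"] = [f"F{i + 1:06d}" for i in out["_fam"]]
    out["child_id"] = [f"F{i + 1:06d}_C{s + 1}" for i, s in zip(out["_fam"], out["_slot"])]
    out["carrier_class"] = np.where(
        out["n_dnm_dd"] > 0, "DD", np.where(out["n_dnm"] > 0, "nonDD", "none")
    )
    out = out.drop(columns=["_fam", "_slot"]).reset_index(drop=True)
    front = [
        "family_id",
        "child_id",
        "role",
        "sex",
        "affected",
        "pgs_child",
        "pgs_father",
        "pgs_mother",
        "midparent",
        "n_dnm",
        "n_dnm_dd",
        "carrier_class",
    ]
    return out[front]


def _draw_nb(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Draw NB2 counts with Var = mu + alpha * mu^2 (Poisson when alpha=0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_phenotypes(
    cohort: pd.DataFrame, params: Optional[PhenotypeParams] = None, seed: int = 0
) -> pd.DataFrame:
    """Attach downstream phenotypes to a simulated cohort.

    Adds the 0-7 count of co-occurring developmental disabilities (and its
    seven binary components), negative-binomial milestone ages (months),
    an IQ bin with an intellectual-disability flag, six correlated factor
    scores with a PGS-linked heritable component, and ten null principal
    components usable as covariates.
    """
    if len(cohort) == 0:
        raise ParameterError("cohort is empty")
    if params is None:
        params = PhenotypeParams()
    params.validate()
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)
    pgs = out["pgs_child"].to_numpy(dtype=float)
    n_dnm = out["n_dnm"].to_numpy(dtype=float)
    is_dd_carrier = (out["carrier_class"] == "DD").to_numpy()

    # count of co-occurring developmental disabilities (0-7)
    log_mu = (
        params.dd_intercept
        + params.beta_dnm_dd * n_dnm
        + params.beta_pgs_dd * pgs
        + params.dd_gene_extra * is_dd_carrier
    )
    dd_count = np.minimum(_draw_nb(rng, np.exp(log_mu), params.dd_dispersion), 7)
    out["dd_count"] = dd_count
    # distribute the count over the seven indicator conditions
    ranks = np.argsort(rng.random((n, len(DD_CONDITIONS))), axis=1).argsort(axis=1)
    indicators = ranks < dd_count[:, None]
    for j, name in enumerate(DD_CONDITIONS):
        out[name] = indicators[:, j].astype(int)

    # milestone ages (months)
    log_walk = (
        params.walk_intercept
        + params.beta_pgs_walk * pgs
        + params.beta_dnm_walk * n_dnm
        + params.dd_gene_extra * 0.5 * is_dd_carrier
    )
    out["age_walk_mo"] = _draw_nb(rng, np.exp(log_walk), params.walk_dispersion)
    log_words = (
        params.words_intercept
        + params.beta_pgs_words * pgs
        + params.beta_dnm_words * n_dnm
        + params.dd_gene_extra * 0.5 * is_dd_carrier
    )
    out["age_words_mo"] = _draw_nb(rng, np.exp(log_words), params.words_dispersion)

    # IQ: latent z-scale with PGS loading and per-variant shift
    pgs_iq, shift, id_cutoff = params.iq_model
    resid = np.sqrt(max(0.0, 1.0 - pgs_iq**2))
    latent = pgs_iq * pgs - shift * n_dnm + rng.normal(scale=resid, size=n)
    iq = 90.0 + 15.0 * latent
    out["iq"] = iq
    out["id_flag"] = iq < id_cutoff
    out["iq_bin"] = np.digitize(iq, [40, 55, 70, 80, 90, 100, 110, 120, 130]) + 1

    # six factor scores: PGS-linked heritable part plus correlated residual
    h2 = np.asarray(params.factor_h2, dtype=float)
    chol = np.linalg.cholesky(np.asarray(params.factor_phi, dtype=float))
    eps = rng.normal(size=(n, 6)) @ chol.T
    factors = np.sqrt(h2)[None, :] * pgs[:, None] + np.sqrt(1.0 - h2)[None, :] * eps
    for j in range(6):
        out[f"factor{j + 1}"] = factors[:, j]

    for j in range(10):
        out[f"pc{j + 1}"] = rng.normal(size=n)
    return out


# -- annotated de novo variants ------------------------------------------------

_DAMAGING_CONSEQUENCES = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_loss",
    "start_loss",
)

_N_DD_GENES = 200
_N_NONDD_GENES = 600


def dd_gene_list() -> list[str]:
    """Gene symbols the simulator treats as DD (severe developmental disorder) genes."""
    return [f"DDG{i + 1:04d}" for i in range(_N_DD_GENES)]


def simulate_variant_annotations(
    cohort: pd.DataFrame, seed: int = 0, benign_rate: float = 1.0
) -> pd.DataFrame:
    """Emit an annotated de novo variant table consistent with a cohort.

    Each child's ``n_dnm`` high-impact variants are written with
    annotations that satisfy the high-impact rule (damaging consequence or
    MPC>2 missense or structural variant, LOEUF<0.37, autosomal), with
    ``n_dnm_dd`` of them in DD genes.  Background variants failing at
    least one rule (low MPC, unconstrained gene, benign consequence, sex
    chromosome, or missing annotation) are added at ``benign_rate`` per
    child, so that re-filtering the table recovers the cohort's carrier
    structure exactly (with ``autosomes_only=True``).
    """
    rng = np.random.default_rng(seed)
    dd_genes = dd_gene_list()
    nondd_genes = [f"CONS{i + 1:04d}" for i in range(_N_NONDD_GENES)]
    tolerant_genes = [f"TOL{i + 1:04d}" for i in range(800)]
    rows: list[dict] = []

    def _high_impact_row(child: str, dd: bool) -> dict:
        gene = rng.choice(dd_genes if dd else nondd_genes)
        kind = rng.random()
        if kind < 0.6:
            cons = _DAMAGING_CONSEQUENCES[rng.integers(len(_DAMAGING_CONSEQUENCES))]
            mpc = np.nan
        elif kind < 0.9:
            cons = "missense_variant"
            mpc = float(rng.uniform(2.01, 4.0))
        else:
            cons = "structural_variant"
            mpc = np.nan
        return {
            "individual_id": child,
            "gene": gene,
            "chrom": str(rng.integers(1, 23)),
            "consequence": cons,
            "mpc": mpc,
            "loeuf": float(rng.uniform(0.03, 0.36)),
        }

    def _benign_row(child: str) -> dict:
        mode = rng.random()
        if mode < 0.3:  # missense below the MPC threshold, constrained gene
            return {
                "individual_id": child,
                "gene": rng.choice(nondd_genes),
                "chrom": str(rng.integers(1, 23)),
                "consequence": "missense_variant",
                "mpc": float(rng.uniform(0.0, 1.99)),
                "loeuf": float(rng.uniform(0.03, 0.36)),
            }
        if mode < 0.6:  # damaging consequence in an unconstrained gene
            return {
                "individual_id": child,
                "gene": rng.choice(tolerant_genes),
                "chrom": str(rng.integers(1, 23)),
                "consequence": _DAMAGING_CONSEQUENCES[
                    rng.integers(len(_DAMAGING_CONSEQUENCES))
                ],
                "mpc": np.nan,
                "loeuf": float(rng.uniform(0.38, 1.8)),
            }
        if mode < 0.8:  # benign consequence
            return {
                "individual_id": child,
                "gene": rng.choice(tolerant_genes),
                "chrom": str(rng.integers(1, 23)),
                "consequence": "other",
                "mpc": np.nan,
                "loeuf": float(rng.uniform(0.03, 1.8)),
            }
        if mode < 0.9:  # would be high-impact but on a sex chromosome
            return {
                "individual_id": child,
                "gene": f"XL{rng.integers(1, 200):04d}",
                "chrom": "X",
                "consequence": "stop_gained",
                "mpc": np.nan,
                "loeuf": float(rng.uniform(0.03, 0.36)),
            }
        # missing LOEUF annotation: excluded with a warning downstream
        return {
            "individual_id": child,
            "gene": rng.choice(tolerant_genes),
            "chrom": str(rng.integers(1, 23)),
            "consequence": "stop_gained",
            "mpc": np.nan,
            "loeuf": np.nan,
        }

    for child, k, k_dd in zip(cohort["child_id"], cohort["n_dnm"], cohort["n_dnm_dd"]):
        for j in range(int(k)):
            rows.append(_high_impact_row(child, dd=j < int(k_dd)))
        for _ in range(rng.poisson(benign_rate)):
            rows.append(_benign_row(child))
    return pd.DataFrame(
        rows, columns=["individual_id", "gene", "chrom", "consequence", "mpc", "loeuf"]
    )


def simulate_genotype_panel(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    h2: float = 0.3,
    binary: bool = False,
    K: Optional[float] = None,
    case_fraction: Optional[float] = None,
    seed: int = 0,
) -> GenotypePanel:
    """Simulate an additive SNP panel with known heritability.

    SNPs are drawn in Hardy-Weinberg proportions at MAFs uniform on
    ``maf_range``; all m SNPs are causal with standardized effects summing
    to variance ``h2``.  Quantitative phenotypes add ``N(0, 1 - h2)``
    noise.  Binary phenotypes threshold the liability at
    ``Phi^{-1}(1 - K)``; when ``case_fraction`` is given the panel is
    ascertained (rejection sampling) until it holds that proportion of
    cases, mimicking a case-control design.
    """
    if n <= 0 or m <= 0:
        raise ParameterError("n and m must be positive")
    if not (0.0 <= h2 <= 1.0):
        raise ParameterError("h2 must lie in [0, 1]")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ParameterError("maf_range must lie within (0, 0.5]")
    if binary and (K is None or not (0.0 < K < 1.0)):
        raise ParameterError("binary panels require K in (0, 1)")

    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=m)
    effects = rng.normal(size=m)
    effects *= np.sqrt(h2 / np.sum(effects**2)) if h2 > 0 else 0.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    noise_sd = np.sqrt(1.0 - h2)

    def _chunk(size: int) -> tuple[np.ndarray, np.ndarray]:
        X = rng.binomial(2, p, size=(size, m)).astype(np.float64)
        g = ((X - 2.0 * p) / denom) @ effects
        liab = g + rng.normal(scale=noise_sd, size=size)
        return X, liab

    if not binary:
        X, liab = _chunk(n)
        return GenotypePanel(X, p, effects, liab, h2, binary=False)

    thr = stats.norm.isf(K)
    if case_fraction is None:
        X, liab = _chunk(n)
        return GenotypePanel(X, p, effects, (liab > thr).astype(float), h2, True, K)

    n_cases = int(round(n * case_fraction))
    n_controls = n - n_cases
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    got_cases = got_controls = 0
    chunk = max(2000, int(2.0 * n_cases / max(K, 1e-6) / 10))
    guard = 0
    while got_cases < n_cases or got_controls < n_controls:
        X, liab = _chunk(chunk)
        case_mask = liab > thr
        if got_cases < n_cases:
            take = X[case_mask][: n_cases - got_cases]
            cases.append(take)
            got_cases += len(take)
        if got_controls < n_controls:
            take = X[~case_mask][: n_controls - got_controls]
            controls.append(take)
            got_controls += len(take)
        guard += 1
        if guard > 1000:  # pragma: no cover - defensive
            raise RuntimeError("ascertainment failed to accumulate enough cases")
    X = np.vstack(cases + controls)
    y = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    order = rng.permutation(n)
    return GenotypePanel(X[order], p, effects, y[order], h2, True, K)
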