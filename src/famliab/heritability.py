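"""SNP heritability: GRM construction, Haseman-Elston regression and
liability-scale conversion.

The genetic relationship matrix (GRM) is the standardized-genotype inner
product ``G_ij = (1/m) sum_m (x_im - 2 p_m)(x_jm - 2 p_m) / (2 p_m (1 - p_m))``
with sample allele frequencies by default.  Observed-scale SNP
heritability is the slope of the phenotype cross-products ``y_i * y_j`` on
``G_ij`` over distinct pairs (Haseman-Elston regression, a moment
estimator in the PCGC family), with a delete-one-block jackknife over
individuals for standard errors.

Case-control estimates on the observed 0/1 scale are converted to the
liability scale with the ascertainment-aware transformation

    h2_liab = h2_obs * K^2 (1-K)^2 / (z^2 * P * (1-P)),

where K is the population prevalence, P the sample case proportion and
``z = phi(Phi^{-1}(1-K))`` the normal density at the threshold.  A
prevalence scan recomputes the conversion over a grid of K, and subgroup
prevalences are derived for factor-defined subtypes (upper-tail mass
beyond +1 SD), exchangeable split-half subtypes, carrier subgroups, and
sex-specific prevalences from a total prevalence and a male:female ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GRM:
    """Genetic relationship matrix with its individual IDs and SNP count."""

    values: np.ndarray  # (n, n) symmetric
    ids: Sequence[str]
    m: int


@dataclass
class HeritabilityEstimate:
    """Observed- and liability-scale SNP heritability."""

    h2_obs: float
    se_obs: float
    K: Optional[float]
    P: Optional[float]
    z: Optional[float]
    h2_liab: Optional[float]
    se_liab: Optional[float]
    method: str = "HE"


def compute_grm(
    dosages: np.ndarray,
    freqs: Optional[np.ndarray] = None,
    ids: Optional[Sequence[str]] = None,
) -> GRM:
    """GCTA-style GRM from an additive dosage matrix (individuals x SNPs).

    Monomorphic SNPs (sample frequency 0 or 1) are dropped with a log
    message.  Passing ``freqs`` overrides the sample allele frequencies
    used for centring and scaling.
    """
    X = np.asarray(dosages, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D dosage matrix with at least 2 individuals")
    n, m = X.shape
    p = np.asarray(freqs, dtype=float) if freqs is not None else X.mean(axis=0) / 2.0
    keep = (p > 0.0) & (p < 1.0)
    dropped = int(m - keep.sum())
    if dropped:
        logger.info("dropped %d monomorphic SNP(s)", dropped)
    if not keep.any():
        raise ValueError("all SNPs are monomorphic")
    Xk, pk = X[:, keep], p[keep]
    Z = (Xk - 2.0 * pk) / np.sqrt(2.0 * pk * (1.0 - pk))
    G = Z @ Z.T / keep.sum()
    if ids is None:
        ids = [f"I{i + 1:06d}" for i in range(n)]
    return GRM((G + G.T) / 2.0, list(ids), int(keep.sum()))


def _pair_regression(g: np.ndarray, q: np.ndarray) -> float:
    """Slope of cross-products q on relatedness g, with intercept."""
    g = np.asarray(g, dtype=float)
    q = np.asarray(q, dtype=float)
    var = g.var()
    if var == 0:
        raise ValueError("zero variance in off-diagonal relatedness")
    return float(np.cov(g, q, bias=True)[0, 1] / var)


def he_regression(
    y: np.ndarray, grm: GRM, n_blocks: int = 20
) -> tuple[float, float]:
    """Haseman-Elston SNP heritability with a block-jackknife SE.

    The phenotype is standardized internally, so the slope estimates the
    observed-scale variance ratio directly.  The jackknife deletes
    ``n_blocks`` contiguous blocks of individuals (all pairs touching the
    block) and uses the usual delete-one-block variance formula.
    """
    yv = np.asarray(y, dtype=float)
    n = yv.size
    if n != grm.values.shape[0]:
        raise ValueError("phenotype length must match GRM size")
    sd = yv.std(ddof=1)
    if sd == 0:
        raise ValueError("phenotype has zero variance")
    yv = (yv - yv.mean()) / sd

    iu, ju = np.triu_indices(n, k=1)
    g = grm.values[iu, ju]
    q = yv[iu] * yv[ju]
    h2 = _pair_regression(g, q)

    n_blocks = min(n_blocks, n)
    block_of = np.floor(np.arange(n) * n_blocks / n).astype(int)
    pair_block_i, pair_block_j = block_of[iu], block_of[ju]
    estimates = []
    for b in range(n_blocks):
        mask = (pair_block_i != b) & (pair_block_j != b)
        estimates.append(_pair_regression(g[mask], q[mask]))
    estimates = np.asarray(estimates)
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((estimates - estimates.mean()) ** 2)))
    return h2, se


def liability_multiplier(K: float, P: float) -> float:
    """The observed-to-liability conversion factor K^2(1-K)^2 / (z^2 P(1-P))."""
    if not (0.0 < K < 1.0) or not (0.0 < P < 1.0):
        raise ValueError("K and P must lie strictly inside (0, 1)")
    z = stats.norm.pdf(stats.norm.isf(K))
    return float(K**2 * (1.0 - K) ** 2 / (z**2 * P * (1.0 - P)))


def observed_to_liability(h2_obs: float, K: float, P: float) -> float:
    """Convert an observed-scale case-control h2 to the liability scale."""
    if h2_obs < 0:
        raise ValueError("h2_obs must be non-negative")
    return h2_obs * liability_multiplier(K, P)


def prevalence_scan(
    h2_obs: float, K_grid: Sequence[float], P: float
) -> pd.DataFrame:
    """Liability-scale conversions across a grid of assumed prevalences."""
    grid = np.asarray(list(K_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("K_grid is empty")
    rows = [
        {
            "K": float(K),
            "multiplier": liability_multiplier(K, P),
            "h2_liab": observed_to_liability(h2_obs, K, P),
        }
        for K in grid
    ]
    return pd.DataFrame(rows)


def subgroup_prevalence(
    kind: str,
    K_total: float,
    share: Optional[float] = None,
    ratio: Optional[float] = None,
):
    """Derive a subgroup prevalence from the total prevalence.

    - ``factor_sd``: subtype defined by a factor score more than 1 SD above
      the mean of a normal distribution; the subgroup holds the upper-tail
      mass ``1 - Phi(1)`` (~15.9%, conventionally printed as 16%) of the
      total prevalence.
    - ``split_half``: subtype defined by one factor exceeding another;
      exchangeability gives exactly half the total prevalence.
    - ``carrier_share``: multiply the total prevalence by an externally
      estimated carrier share.
    - ``sex_ratio``: split the total prevalence into (K_male, K_female)
      from a male:female ratio r, assuming equal sex frequencies:
      K_m = 2 r K / (1 + r), K_f = 2 K / (1 + r).
    """
    if not (0.0 < K_total <= 1.0):
        raise ValueError("K_total must lie in (0, 1]")
    if kind == "factor_sd":
        return float((1.0 - stats.norm.cdf(1.0)) * K_total)
    if kind == "split_half":
        return 0.5 * K_total
    if kind == "carrier_share":
        if share is None or not (0.0 < share < 1.0):
            raise ValueError("carrier_share requires share in (0, 1)")
        return float(share * K_total)
    if kind == "sex_ratio":
        if ratio is None or ratio <= 0:
            raise ValueError("sex_ratio requires a positive male:female ratio")
        K_m = 2.0 * ratio * K_total / (1.0 + ratio)
        K_f = 2.0 * K_total / (1.0 + ratio)
        return float(K_m), float(K_f)
    raise ValueError(f"unknown subgroup kind {kind!r}")


def estimate_h2_liability(
    panel, K: Optional[float] = None, n_blocks: int = 20
) -> HeritabilityEstimate:
    """GRM + Haseman-Elston + liability conversion in one call.

    ``panel`` is a :class:`~famliab.synthetic_data.GenotypePanel` (or any
    object with ``dosages`` and ``phenotype``).  For binary panels the
    observed-scale estimate is converted to the liability scale using the
    supplied K (defaulting to the panel's generative K) and the sample
    case proportion P.
    """
    grm = compute_grm(panel.dosages)
    h2_obs, se_obs = he_regression(panel.phenotype, grm, n_blocks=n_blocks)
    binary = bool(getattr(panel, "binary", False))
    if not binary:
        return HeritabilityEstimate(h2_obs, se_obs, None, None, None, None, None)
    K = K if K is not None else panel.K
    if K is None:
        raise ValueError("binary panels require a population prevalence K")
    P = float(np.mean(panel.phenotype))
    mult = liability_multiplier(K, P)
    z = stats.norm.pdf(stats.norm.isf(K))
    return HeritabilityEstimate(
        h2_obs,
        se_obs,
        float(K),
        P,
        float(z),
        max(0.0, h2_obs) * mult,
        se_obs * mult,
    )


def he_bivariate(
    y1: np.ndarray, y2: np.ndarray, grm: GRM
) -> tuple[float, float, float]:
    """Experimental: bivariate Haseman-Elston genetic correlation.

    Regresses symmetrized cross-trait products on relatedness to obtain
    the genetic covariance, then divides by the geometric mean of the two
    univariate slopes.  Returned as ``(rg, cov_g, se_placeholder)``; no
    jackknife SE is computed.  Interpret with caution.
    """
    a = np.asarray(y1, dtype=float)
    b = np.asarray(y2, dtype=float)
    a = (a - a.mean()) / a.std(ddof=1)
    b = (b - b.mean()) / b.std(ddof=1)
    n = a.size
    iu, ju = np.triu_indices(n, k=1)
    g = grm.values[iu, ju]
    cov_g = _pair_regression(g, 0.5 * (a[iu] * b[ju] + b[iu] * a[ju]))
    h1 = _pair_regression(g, a[iu] * a[ju])
    h2 = _pair_regression(g, b[iu] * b[ju])
    if h1 <= 0 or h2 <= 0:
        return float("nan"), cov_g, float("nan")
    return cov_g / np.sqrt(h1 * h2), cov_g, float("nan")
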