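"""Factor-model decision metrics, factor scoring and correlation contrasts.

Factor models enter as fitted loading tables (items x factors), factor
correlations and uniquenesses; fitting itself (rotation, DWLS on
polychorics) is out of scope.  Provided here are Thurstone regression
factor scores, the bifactor decision indices omega-hierarchical and
explained common variance (ECV), the Jennrich chi-square test for
equality of two correlation matrices, Fisher-z contrasts of two
correlations, Wilcoxon rank-sum contrasts, and grouped factor-score
summaries (means, CIs, Cohen's d, clustered correlation ordering).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class FactorModel:
    """Loadings (items x factors), factor correlations, uniquenesses.

    ``general`` optionally holds the general-factor loading column of a
    bifactor layout; for bifactor models ``phi`` is the identity.
    """

    loadings: np.ndarray
    phi: Optional[np.ndarray] = None
    uniquenesses: Optional[np.ndarray] = None
    general: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        n_items, n_factors = self.loadings.shape
        if self.phi is None:
            self.phi = np.eye(n_factors)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (n_factors, n_factors):
            raise ValueError("phi must be square with one row per factor")
        if self.general is not None:
            self.general = np.asarray(self.general, dtype=float).ravel()
            if self.general.size != n_items:
                raise ValueError("general loading column must have one entry per item")
        if self.uniquenesses is None:
            lam_g = self.general if self.general is not None else 0.0
            common = np.einsum(
                "if,fg,ig->i", self.loadings, self.phi, self.loadings
            ) + np.square(lam_g)
            self.uniquenesses = 1.0 - common
        self.uniquenesses = np.asarray(self.uniquenesses, dtype=float).ravel()
        if self.uniquenesses.size != n_items:
            raise ValueError("need one uniqueness per item")
        if np.any(self.uniquenesses < -1e-8):
            raise ValueError("uniquenesses must be non-negative")


def regression_factor_scores(items, model: FactorModel) -> np.ndarray:
    """Thurstone regression factor scores for standardized items.

    Weights are ``Sigma^{-1} Lambda Phi`` with the model-implied
    covariance ``Sigma = Lambda Phi Lambda' + diag(theta)``; scores are
    ``X @ weights``.  A numerically singular Sigma raises, naming items
    with (near-)zero uniqueness as the usual culprits.
    """
    X = items.to_numpy(dtype=float) if isinstance(items, pd.DataFrame) else np.asarray(
        items, dtype=float
    )
    lam, phi, theta = model.loadings, model.phi, model.uniquenesses
    sigma = lam @ phi @ lam.T + np.diag(theta)
    cond = np.linalg.cond(sigma)
    if not np.isfinite(cond) or cond > 1e12:
        suspects = np.nonzero(theta < 1e-10)[0].tolist()
        raise np.linalg.LinAlgError(
            f"model-implied covariance is singular (cond={cond:.2e}); "
            f"items with zero uniqueness: {suspects}"
        )
    weights = np.linalg.solve(sigma, lam @ phi)
    return X @ weights


def _require_bifactor(model: FactorModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if model.general is None:
        raise ValueError("bifactor metrics need a general-factor loading column")
    return model.general, model.loadings, model.uniquenesses


def omega_hierarchical(model: FactorModel) -> float:
    """Hierarchical omega: general-factor share of total score variance.

    ``omega_h = (sum lam_g)^2 / [(sum lam_g)^2 + sum_k (sum_i lam_ik)^2
    + sum theta]``.
    """
    lam_g, lam, theta = _require_bifactor(model)
    gen = np.sum(lam_g) ** 2
    group = float(np.sum(np.sum(lam, axis=0) ** 2))
    return float(gen / (gen + group + np.sum(theta)))


def ecv(model: FactorModel) -> float:
    """Explained common variance of the general factor.

    ``ECV = sum lam_g^2 / (sum lam_g^2 + sum_ik lam_ik^2)``.
    """
    lam_g, lam, _ = _require_bifactor(model)
    gen = float(np.sum(lam_g**2))
    total = gen + float(np.sum(lam**2))
    return gen / total if total > 0 else 0.0


def jennrich_test(
    R1: np.ndarray, n1: int, R2: np.ndarray, n2: int
) -> tuple[float, int, float]:
    """Jennrich (1970) chi-square test for equality of two correlation matrices.

    With the pooled matrix ``R = (n1 R1 + n2 R2)/(n1 + n2)``,
    ``c = n1 n2 / (n1 + n2)`` and ``Z = sqrt(c) R^{-1} (R1 - R2)``, the
    statistic is ``tr(Z^2)/2 - dg(Z)' S^{-1} dg(Z)`` where
    ``S = I + R * R^{-1}`` (elementwise product), with
    ``df = p (p - 1) / 2``.
    """
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    p = R1.shape[0]
    if R1.shape != (p, p) or R2.shape != (p, p):
        raise ValueError("R1 and R2 must be square and of equal dimension")
    for R in (R1, R2):
        if not np.allclose(R, R.T, atol=1e-8) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("inputs must be correlation matrices")
    if n1 <= p or n2 <= p:
        raise ValueError("sample sizes must exceed the matrix dimension")
    c = n1 * n2 / (n1 + n2)
    R = (n1 * R1 + n2 * R2) / (n1 + n2)
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("pooled correlation matrix is not positive-definite") from exc
    Rinv = np.linalg.inv(R)
    Z = np.sqrt(c) * Rinv @ (R1 - R2)
    S = np.eye(p) + R * Rinv
    dg = np.diag(Z)
    chi2 = float(0.5 * np.trace(Z @ Z) - dg @ np.linalg.solve(S, dg))
    df = p * (p - 1) // 2
    return chi2, df, float(stats.chi2.sf(chi2, df))


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sided Fisher z-test for equality of two independent correlations."""
    for r in (r1, r2):
        if not (-1.0 < r < 1.0):
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test, normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = ranks[:n1].sum()
    mu = n1 * (n2 + n1 + 1) / 2.0
    n = n1 + n2
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return 0.0, 1.0
    z = (w - mu) / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def _cluster_order(corr: np.ndarray) -> np.ndarray:
    """Leaf order from average-linkage clustering of 1 - r distances."""
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    return np.asarray(hierarchy.leaves_list(link))


def factor_summaries(
    scores: pd.DataFrame, grouping: Optional[pd.Series] = None
) -> dict:
    """Per-group summaries of factor scores.

    Returns a dict with ``means`` (per group: mean, 95% t-CI, n per
    factor), ``cohens_d`` (pairwise pooled-SD d between the first two
    groups, when two or more groups exist) and ``correlations`` (Pearson
    interfactor correlation matrix, rows/columns ordered by hierarchical
    clustering of 1 - r distances).
    """
    cols = list(scores.columns)
    if grouping is None:
        grouping = pd.Series(["all"] * len(scores), index=scores.index)
    grouping = pd.Series(grouping, index=scores.index)

    mean_rows = []
    for level, sub in scores.groupby(grouping):
        for col in cols:
            vals = sub[col].dropna().to_numpy(dtype=float)
            n = vals.size
            mean = float(vals.mean()) if n else np.nan
            if n >= 2:
                half = stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n)
                lo, hi = mean - half, mean + half
            else:
                lo = hi = np.nan  # CI undefined for a single observation
            mean_rows.append(
                {"group": level, "factor": col, "n": n, "mean": mean, "lo": lo, "hi": hi}
            )
    means = pd.DataFrame(mean_rows)

    levels = list(dict.fromkeys(grouping))
    d_rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            g1 = scores[grouping == levels[i]]
            g2 = scores[grouping == levels[j]]
            for col in cols:
                a, b = g1[col].dropna(), g2[col].dropna()
                if len(a) < 2 or len(b) < 2:
                    continue
                pooled = np.sqrt(
                    ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                    / (len(a) + len(b) - 2)
                )
                d = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
                d_rows.append(
                    {
                        "group1": levels[i],
                        "group2": levels[j],
                        "factor": col,
                        "cohens_d": float(d),
                    }
                )
    cohens_d = pd.DataFrame(d_rows)

    corr = scores[cols].corr().to_numpy()
    order = _cluster_order(corr) if len(cols) > 2 else np.arange(len(cols))
    ordered = [cols[i] for i in order]
    correlations = pd.DataFrame(
        corr[np.ix_(order, order)], index=ordered, columns=ordered
    )
    return {"means": means, "cohens_d": cohens_d, "correlations": correlations}
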