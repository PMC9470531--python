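"""Association batteries, multiple-testing correction and IVW meta-analysis.

Genetic predictors (polygenic scores, de novo counts, carrier flags) are
regressed against cohort phenotypes with configurable covariates using the
generalized linear model appropriate to each outcome: Gaussian for
standardized quantitative traits, logistic for binary traits,
quasi-Poisson (Pearson-scaled Poisson) or negative-binomial for
overdispersed counts, with an automatic choice keeping the family with the
lower residual deviance.  Continuous predictors are standardized so the
coefficients are on a per-SD scale.  Within-family relatedness is handled
with cluster-robust standard errors.  P-values across a battery are
corrected with Benjamini-Yekutieli false discovery rates, and per-cohort
estimates are pooled by inverse-variance-weighted (IVW) meta-analysis with
Cochran's Q and I-squared heterogeneity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

_FAMILIES = ("gaussian", "binomial", "quasipoisson", "negative_binomial", "auto_count")


@dataclass
class AssocSpec:
    """One regression of the battery."""

    outcome: str
    predictors: Sequence[str]
    covariates: Sequence[str] = field(default_factory=tuple)
    family: str = "gaussian"
    cohort: str = "cohort"
    cluster: Optional[str] = None  # column of grouping ids for robust SEs
    standardize: bool = True

    def validate(self, data: pd.DataFrame) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        missing = [
            c
            for c in [self.outcome, *self.predictors, *self.covariates]
            if c not in data.columns
        ]
        if missing:
            raise KeyError(f"columns absent from data: {missing}")


@dataclass
class MetaResult:
    """IVW-pooled effect with heterogeneity statistics."""

    beta: float
    se: float
    p: float
    q_stat: float
    i2: float  # percentage in [0, 100]
    k: int


def _standardize(col: pd.Series) -> pd.Series:
    vals = col.astype(float)
    if vals.nunique() <= 2:  # leave binary indicators on their natural scale
        return vals
    sd = vals.std(ddof=1)
    return (vals - vals.mean()) / sd if sd > 0 else vals * 0.0


def fit_association(data: pd.DataFrame, spec: AssocSpec) -> pd.DataFrame:
    """Fit one battery regression and return per-term coefficient rows.

    Returns a DataFrame with one row per predictor term: ``term, beta,
    se, p, n, cohort, family_used, converged``.  For ``auto_count`` both a
    quasi-Poisson and a negative-binomial model are fitted and the family
    with the lower residual deviance is kept.  Non-convergence or
    separation is flagged on the rows rather than silently dropped.
    """
    spec.validate(data)
    cols = [spec.outcome, *spec.predictors, *spec.covariates]
    if spec.cluster:
        cols.append(spec.cluster)
    frame = data[cols].dropna()
    n = len(frame)
    if n < 20:
        raise ValueError(f"need at least 20 complete cases, got {n}")

    y = frame[spec.outcome].to_numpy(dtype=float)
    X = pd.DataFrame(index=frame.index)
    for term in [*spec.predictors, *spec.covariates]:
        series = frame[term]
        if series.dtype == object or series.dtype == bool:
            series = pd.Series(
                pd.factorize(series)[0].astype(float), index=frame.index, name=term
            )
        X[term] = _standardize(series) if spec.standardize else series.astype(float)
    X = sm.add_constant(X)

    fit_kwargs: dict = {}
    if spec.cluster:
        fit_kwargs = {
            "cov_type": "cluster",
            "cov_kwds": {"groups": frame[spec.cluster]},
        }

    family_used = spec.family
    converged = True
    if spec.family == "gaussian":
        res = sm.OLS(y, X).fit(**fit_kwargs)
    elif spec.family == "binomial":
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit(**fit_kwargs)
            mu = res.fittedvalues
            if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
                converged = False  # (quasi-)separation
        except Exception:
            res = model.fit(maxiter=25, **fit_kwargs)
            converged = False
    elif spec.family == "quasipoisson":
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(scale="X2", **fit_kwargs)
    elif spec.family == "negative_binomial":
        res, converged = _fit_negbin(y, X, fit_kwargs)
    else:  # auto_count: lower residual deviance wins
        qp = sm.GLM(y, X, family=sm.families.Poisson()).fit(scale="X2", **fit_kwargs)
        nb, nb_ok = _fit_negbin(y, X, fit_kwargs)
        if nb_ok and _nb_deviance(y, X, nb) < qp.deviance:
            res, family_used = nb, "negative_binomial"
        else:
            res, family_used = qp, "quasipoisson"

    rows = []
    for term in spec.predictors:
        rows.append(
            {
                "term": term,
                "beta": float(res.params[term]),
                "se": float(res.bse[term]),
                "p": float(res.pvalues[term]),
                "n": n,
                "cohort": spec.cohort,
                "outcome": spec.outcome,
                "family_used": family_used,
                "converged": bool(converged),
            }
        )
    return pd.DataFrame(rows)


def _fit_negbin(y, X, fit_kwargs):
    """ML negative-binomial fit; returns a GLM-NB refit at the ML alpha."""
    converged = True
    try:
        ml = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
        try:
            alpha = float(ml.params["alpha"])
        except (KeyError, IndexError, TypeError):
            alpha = float(np.asarray(ml.params)[-1])
    except Exception:
        alpha, converged = 1.0, False
    alpha = max(alpha, 1e-8)
    res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit(
        **fit_kwargs
    )
    if not res.converged:
        converged = False
    return res, converged


def _nb_deviance(y, X, res) -> float:
    return float(res.deviance)


def by_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted q-values.

    The BY procedure inflates the Benjamini-Hochberg adjustment by
    ``c(m) = sum_{k=1..m} 1/k``, making it valid under arbitrary
    dependence among the tests — appropriate for highly correlated
    phenotype batteries.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def ivw_meta(betas: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """Fixed-effect inverse-variance-weighted meta-analysis.

    Weights are ``w_i = SE_i^-2``; the pooled effect is the weighted mean
    with ``SE_meta = sqrt(1 / sum w_i)`` and a normal p-value.
    Heterogeneity is summarized by Cochran's
    ``Q = sum w_i (beta_i - beta_meta)^2`` and
    ``I2 = max(0, (Q - (k-1)) / Q) * 100``.
    """
    b = np.asarray(list(betas), dtype=float)
    s = np.asarray(list(ses), dtype=float)
    if b.size == 0:
        raise ValueError("need at least one study")
    if b.shape != s.shape:
        raise ValueError("betas and ses must have equal length")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = s**-2.0
    beta = float(np.sum(b * w) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = float(np.sum(w * (b - beta) ** 2))
    k = b.size
    i2 = float(max(0.0, (q - (k - 1)) / q) * 100.0) if q > 0 else 0.0
    return MetaResult(beta, se, p, q, i2, k)


def run_battery(
    data: pd.DataFrame, specs: Sequence[AssocSpec], adjust: bool = True
) -> pd.DataFrame:
    """Fit every spec and (optionally) BY-adjust p-values within the battery."""
    frames = [fit_association(data, spec) for spec in specs]
    out = pd.concat(frames, ignore_index=True)
    if adjust:
        out["q"] = by_adjust(out["p"].to_numpy())
    return out


def meta_by_term(results: pd.DataFrame) -> pd.DataFrame:
    """IVW-pool battery rows across cohorts, per (outcome, term)."""
    rows = []
    for (outcome, term), grp in results.groupby(["outcome", "term"]):
        m = ivw_meta(grp["beta"], grp["se"])
        rows.append(
            {
                "outcome": outcome,
                "term": term,
                "beta": m.beta,
                "se": m.se,
                "p": m.p,
                "q_stat": m.q_stat,
                "i2": m.i2,
                "k": m.k,
            }
        )
    return pd.DataFrame(rows)


def leave_one_out_dd(
    data: pd.DataFrame, dd_columns: Sequence[str], spec: AssocSpec
) -> pd.DataFrame:
    """Leave-one-out refits over the seven developmental disability indicators.

    Each refit recomputes the 0-6 summed count after excluding one of the
    seven binary condition columns and reruns the battery regression on
    it.  Returns exactly seven rows labelled by the excluded condition.
    """
    dd_columns = list(dd_columns)
    if len(dd_columns) != 7:
        raise ValueError(f"expected exactly 7 condition columns, got {len(dd_columns)}")
    missing = [c for c in dd_columns if c not in data.columns]
    if missing:
        raise KeyError(f"condition columns absent from data: {missing}")
    rows = []
    for excluded in dd_columns:
        kept = [c for c in dd_columns if c != excluded]
        work = data.copy()
        work["_loo_count"] = work[kept].sum(axis=1)
        sub_spec = AssocSpec(
            outcome="_loo_count",
            predictors=spec.predictors,
            covariates=spec.covariates,
            family=spec.family,
            cohort=spec.cohort,
            cluster=spec.cluster,
            standardize=spec.standardize,
        )
        res = fit_association(work, sub_spec)
        res.insert(0, "excluded", excluded)
        rows.append(res)
    return pd.concat(rows, ignore_index=True)
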