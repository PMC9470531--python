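"""Polygenic transmission disequilibrium tests (pTDT).

Under Mendelian segregation a child's polygenic score is centred on the
midparental mean, so in unselected families the child-minus-midparent
deviation has expectation zero.  Systematic overtransmission in affected
children is evidence that the score indexes liability.  This module
computes per-trio deviations under two standardization conventions, the
one-sample test on their mean, two-stratum Z contrasts, PC
residualization of raw scores, and 2x2 relative risks for carrier-status
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PTDTResult:
    """Mean transmission deviation in one stratum."""

    stratum: str
    n: int
    mean_deviation: float
    se: float
    p: float
    mode: str
    degenerate: bool = False


@dataclass
class ContingencyTable2x2:
    """Counts (exposed-event, exposed-nonevent, unexposed-event, unexposed-nonevent)."""

    a: int
    b: int
    c: int
    d: int


def residualize_pgs(pgs: np.ndarray, covariates: Optional[np.ndarray] = None) -> np.ndarray:
    """Least-squares residuals of a score on covariates (plus intercept).

    With no covariates this is mean-centering.  Zero-variance covariate
    columns or collinear designs are rejected, naming the offending
    columns.
    """
    y = np.asarray(pgs, dtype=float)
    if covariates is None or np.size(covariates) == 0:
        return y - y.mean()
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("pgs and covariates must have matching rows")
    zero_var = np.nonzero(X.std(axis=0) == 0)[0]
    if zero_var.size:
        raise ValueError(f"covariate column(s) {zero_var.tolist()} are constant")
    design = np.column_stack([np.ones_like(y), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify collinear columns by incremental rank
        collinear = []
        kept = design[:, :1]
        for j in range(X.shape[1]):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                collinear.append(j)
            else:
                kept = cand
        raise ValueError(f"rank-deficient covariates; collinear column(s) {collinear}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def ptdt_deviation(
    trios: pd.DataFrame,
    mode: str = "midparent_sd",
    score_child: str = "pgs_child",
    score_father: str = "pgs_father",
    score_mother: str = "pgs_mother",
) -> np.ndarray:
    """Per-trio transmission deviations.

    ``midparent_sd`` (the pTDT literature convention) divides the
    child-minus-midparent difference by the sample SD of the midparent
    distribution, making the deviation invariant to affine rescaling of
    the raw score.  ``parental_pooled`` first standardizes child and
    parents by the pooled parental mean and SD and then differences.
    Incomplete trios are dropped (count reported via the returned array's
    length).
    """
    cols = [score_child, score_father, score_mother]
    complete = trios.dropna(subset=cols)
    n_dropped = len(trios) - len(complete)
    if n_dropped:
        import logging

        logging.getLogger(__name__).info("dropped %d incomplete trios", n_dropped)
    if len(complete) < 2:
        raise ValueError("need at least 2 complete trios to standardize")
    child = complete[score_child].to_numpy(dtype=float)
    father = complete[score_father].to_numpy(dtype=float)
    mother = complete[score_mother].to_numpy(dtype=float)
    midparent = 0.5 * (father + mother)
    if mode == "midparent_sd":
        sd = midparent.std(ddof=1)
        if sd == 0:
            raise ValueError("midparent distribution has zero variance")
        return (child - midparent) / sd
    if mode == "parental_pooled":
        pooled = np.concatenate([father, mother])
        mu, sd = pooled.mean(), pooled.std(ddof=1)
        if sd == 0:
            raise ValueError("pooled parental distribution has zero variance")
        child_z = (child - mu) / sd
        mid_z = (midparent - mu) / sd
        return child_z - mid_z
    raise ValueError(f"unknown mode {mode!r}")


def ptdt_test(deviations: np.ndarray, stratum: str = "all", mode: str = "midparent_sd") -> PTDTResult:
    """One-sample t-test of mean transmission deviation against zero."""
    d = np.asarray(deviations, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 deviations")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        return PTDTResult(stratum, n, mean, 0.0, np.nan, mode, degenerate=True)
    se = sd / np.sqrt(n)
    t = mean / se
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return PTDTResult(stratum, n, mean, se, p, mode)


def compare_strata(res1, res2) -> tuple[float, float]:
    """Two-sided Z-test for a difference between two independent strata.

    Accepts :class:`PTDTResult` objects or ``(mean, se)`` tuples.
    """
    m1, s1 = (res1.mean_deviation, res1.se) if isinstance(res1, PTDTResult) else res1
    m2, s2 = (res2.mean_deviation, res2.se) if isinstance(res2, PTDTResult) else res2
    if s1 <= 0 or s2 <= 0:
        raise ValueError("both strata need positive standard errors")
    z = (m1 - m2) / np.sqrt(s1**2 + s2**2)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p


def relative_risk(table: ContingencyTable2x2) -> tuple[float, tuple[float, float]]:
    """Relative risk with a delta-method (log-scale) 95% CI.

    No continuity correction is applied: a zero event cell is an error.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("both exposure margins must be positive")
    if a == 0 or c == 0:
        raise ValueError("zero event cell; relative risk undefined without correction")
    rr = (a / (a + b)) / (c / (c + d))
    se_log = np.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
    lo = float(np.exp(np.log(rr) - 1.96 * se_log))
    hi = float(np.exp(np.log(rr) + 1.96 * se_log))
    return float(rr), (lo, hi)


def stratified_ptdt(
    trios: pd.DataFrame,
    by: Sequence[str] = (),
    mode: str = "midparent_sd",
    score_child: str = "pgs_child",
) -> pd.DataFrame:
    """pTDT per stratum of one or more grouping columns, plus overall.

    Standardization (midparent SD or pooled parental moments) is computed
    within each stratum's families.
    """
    results = []

    def _one(label: str, sub: pd.DataFrame) -> None:
        if len(sub) < 2:
            return
        dev = ptdt_deviation(sub, mode=mode, score_child=score_child)
        results.append(ptdt_test(dev, stratum=label, mode=mode))

    _one("all", trios)
    if by:
        for keys, sub in trios.groupby(list(by), observed=True):
            if not isinstance(keys, tuple):
                keys = (keys,)
            label = ",".join(f"{c}={k}" for c, k in zip(by, keys))
            _one(label, sub)
    return pd.DataFrame(
        {
            "stratum": [r.stratum for r in results],
            "n": [r.n for r in results],
            "mean_deviation": [r.mean_deviation for r in results],
            "se": [r.se for r in results],
            "p": [r.p for r in results],
            "mode": [r.mode for r in results],
        }
    )
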