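"""Simulation-based power for mediated de novo variant effects.

The design mirrors power analyses in which the effect of a de novo burden
on a core feature is assumed to act entirely through an associated feature
(the mediator): per replicate, a mediator responds to the de novo count
with a configurable effect, a simulated outcome correlates with the
(standardized) mediator at a target correlation r, and the outcome is then
regressed on the de novo count.  Power is the fraction of replicates with
p below alpha; a curve over a grid of r reports where (if anywhere) power
crosses 80%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PowerSpec:
    """One power computation.

    Parameters
    ----------
    r : float
        Target correlation between the mediator and the simulated outcome.
    n : int
        Sample size per replicate.
    beta_med : float
        Generative effect of the de novo count on the mediator (per
        variant, in mediator SD units before restandardization).
    B : int
        Monte-Carlo replicates (default 1,000).
    alpha : float
        Test level (default 0.05).
    seed : int
        RNG seed.
    """

    r: float
    n: int
    beta_med: float = 0.3
    B: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not (-1.0 <= self.r <= 1.0):
            raise ValueError("|r| must not exceed 1")
        if self.B < 1:
            raise ValueError("B must be at least 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n < 4:
            raise ValueError("n must be at least 4")


def simulate_mediated_power(
    spec: PowerSpec, dnm_counts: Optional[np.ndarray] = None
) -> tuple[float, tuple[float, float]]:
    """Monte-Carlo power with a Wilson 95% CI.

    ``dnm_counts`` fixes the de novo design vector across replicates (as
    when re-using an observed cohort's counts); when omitted, counts are
    drawn once from Poisson(0.15).  A degenerate (constant) design is an
    error.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if dnm_counts is None:
        dnm = rng.poisson(0.15, size=spec.n).astype(float)
        # re-draw in the (vanishingly unlikely) all-equal corner
        while np.all(dnm == dnm[0]):
            dnm = rng.poisson(0.15, size=spec.n).astype(float)
    else:
        dnm = np.asarray(dnm_counts, dtype=float)
        if dnm.size != spec.n:
            raise ValueError("dnm_counts length must equal spec.n")
    if np.all(dnm == dnm[0]):
        raise ValueError("degenerate de novo counts: all values equal")

    n, B = spec.n, spec.B
    mediator = spec.beta_med * dnm[:, None] + rng.normal(size=(n, B))
    med_std = (mediator - mediator.mean(axis=0)) / mediator.std(axis=0, ddof=0)
    outcome = spec.r * med_std + np.sqrt(1.0 - spec.r**2) * rng.normal(size=(n, B))

    x = dnm - dnm.mean()
    sxx = float(np.sum(x**2))
    yc = outcome - outcome.mean(axis=0)
    slope = x @ yc / sxx
    rss = np.sum(yc**2, axis=0) - slope**2 * sxx
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, slope / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - 2)

    hits = int(np.sum(pvals < spec.alpha))
    power = hits / B
    # Wilson score interval
    z = stats.norm.ppf(0.975)
    denom = 1.0 + z**2 / B
    centre = (power + z**2 / (2 * B)) / denom
    half = z * np.sqrt(power * (1 - power) / B + z**2 / (4 * B**2)) / denom
    return float(power), (float(centre - half), float(centre + half))


def power_curve(
    r_grid: Sequence[float],
    spec: PowerSpec,
    dnm_counts: Optional[np.ndarray] = None,
    threshold: float = 0.8,
) -> tuple[pd.DataFrame, float]:
    """Power over a grid of mediator-outcome correlations.

    Returns ``(table, crossing)`` where the table has one row per r with
    its power and CI, and ``crossing`` is the linearly interpolated r at
    which power first reaches ``threshold`` (NaN when never reached).
    The grid must be non-empty, within [0, 1] and sorted.
    """
    grid = np.asarray(list(r_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("r_grid is empty")
    if np.any((grid < 0) | (grid > 1)) or np.any(np.diff(grid) < 0):
        raise ValueError("r_grid must be an ordered grid within [0, 1]")
    rows = []
    for i, r in enumerate(grid):
        sub = PowerSpec(
            r=float(r),
            n=spec.n,
            beta_med=spec.beta_med,
            B=spec.B,
            alpha=spec.alpha,
            seed=spec.seed + i,
        )
        power, (lo, hi) = simulate_mediated_power(sub, dnm_counts=dnm_counts)
        rows.append({"r": float(r), "power": power, "lo": lo, "hi": hi})
    table = pd.DataFrame(rows)

    crossing = float("nan")
    pw = table["power"].to_numpy()
    above = np.nonzero(pw >= threshold)[0]
    if above.size:
        j = int(above[0])
        if j == 0:
            crossing = float(grid[0])
        else:
            r0, r1 = grid[j - 1], grid[j]
            p0, p1 = pw[j - 1], pw[j]
            crossing = float(r0 + (threshold - p0) * (r1 - r0) / (p1 - p0))
    return table, crossing
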