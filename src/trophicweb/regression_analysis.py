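"""Quantile regression of log total interaction strength on topology.

Whether strongly interacting species are also the topologically
prominent ones is asked with quantile regression: the natural log of a
species' total interaction strength is regressed on each unweighted
property (trophic level, degree, omnivory, trophic similarity) at the
0.25, 0.50 and 0.75 quantiles, so relationships confined to the upper
or lower envelope of the scatter are not averaged away.  Slope
uncertainty comes from a case-resampling bootstrap: percentile
confidence intervals and a two-sided sign-based p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .topology_metrics import SpeciesMetrics

TAUS = (0.25, 0.5, 0.75)
PROPERTIES = ("trophic_level", "degree", "omnivory", "trophic_similarity")


@dataclass(frozen=True)
class QuantileFit:
    property_name: str
    tau: float
    slope: float
    intercept: float
    slope_p: float
    slope_ci: tuple[float, float]
    n_boot: int
    n: int

    @property
    def significant(self) -> bool:
        return self.slope_p < 0.05


def pinball_loss(y: np.ndarray, fitted: np.ndarray, tau: float) -> float:
    """Check loss ρ_τ summed over observations."""
    u = y - fitted
    return float(np.sum(u * (tau - (u < 0))))


def quantile_fit(x, y, tau: float) -> tuple[float, float]:
    """Fit one conditional quantile line, returning (slope, intercept).

    Minimizes the pinball loss Σ ρ_τ(y − a − b·x) via iteratively
    reweighted least squares; deterministic for fixed inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.all(x == x[0]):
        raise ValueError("x is constant; slope is unidentifiable")
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    exog = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.QuantReg(y, exog).fit(q=tau, max_iter=5000)
    intercept, slope = float(res.params[0]), float(res.params[1])
    return slope, intercept


def bootstrap_slope(
    x,
    y,
    tau: float,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, tuple[float, float]]:
    """Case-resampling bootstrap inference for the quantile slope.

    Resamples (x, y) pairs with replacement ``n_boot`` times, refits,
    and reports the percentile 95% CI plus the two-sided p-value
    ``2 · min(P(b ≤ 0), P(b ≥ 0))``.  Resamples with constant x are
    redrawn (at most 10·n_boot attempts in total).
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = x.size
    slopes = np.empty(n_boot)
    filled = 0
    attempts = 0
    while filled < n_boot:
        if attempts > 10 * n_boot:
            raise RuntimeError("too many degenerate bootstrap resamples")
        attempts += 1
        idx = rng.integers(0, n, size=n)
        xb = x[idx]
        if np.all(xb == xb[0]):
            continue
        slopes[filled], _ = quantile_fit(xb, y[idx], tau)
        filled += 1
    ci = (float(np.percentile(slopes, 2.5)), float(np.percentile(slopes, 97.5)))
    p_low = float(np.mean(slopes <= 0))
    p_high = float(np.mean(slopes >= 0))
    p = min(1.0, 2.0 * min(p_low, p_high))
    return p, ci


def run_property_regressions(
    metrics: dict[str, SpeciesMetrics],
    taus: tuple[float, ...] = TAUS,
    properties: tuple[str, ...] = PROPERTIES,
    n_boot: int = 1000,
    seed: int = 0,
) -> list[QuantileFit]:
    """Regress ln(total IS) on each property at each quantile.

    Species with zero total interaction strength cannot enter the log
    response; they are dropped with a warning.
    """
    usable = {s: m for s, m in metrics.items() if m.total_is > 0}
    dropped = sorted(set(metrics) - set(usable))
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} species with zero total interaction "
            f"strength from regressions: {', '.join(dropped[:10])}"
            + ("..." if len(dropped) > 10 else ""),
            stacklevel=2,
        )
    if len(usable) < 3:
        raise ValueError(
            f"only {len(usable)} species with positive total interaction "
            "strength; need at least 3"
        )
    order = sorted(usable)
    y = np.log([usable[s].total_is for s in order])
    fits: list[QuantileFit] = []
    master = np.random.SeedSequence(seed)
    for pi, prop in enumerate(properties):
        x = np.array([float(getattr(usable[s], prop)) for s in order])
        for ti, tau in enumerate(taus):
            slope, intercept = quantile_fit(x, y, tau)
            p, ci = bootstrap_slope(
                x, y, tau, n_boot=n_boot,
                seed=np.random.SeedSequence(seed, spawn_key=(pi, ti)),
            )
            fits.append(
                QuantileFit(
                    property_name=prop,
                    tau=tau,
                    slope=slope,
                    intercept=intercept,
                    slope_p=p,
                    slope_ci=ci,
                    n_boot=n_boot,
                    n=len(order),
                )
            )
    return fits


def regression_table(fits: list[QuantileFit]) -> pd.DataFrame:
    """One row per (property, tau)."""
    rows = [
        {
            "property": f.property_name,
            "tau": f.tau,
            "slope": f.slope,
            "intercept": f.intercept,
            "p": f.slope_p,
            "ci_lo": f.slope_ci[0],
            "ci_hi": f.slope_ci[1],
        }
        for f in fits
    ]
    return pd.DataFrame(
        rows, columns=["property", "tau", "slope", "intercept", "p", "ci_lo", "ci_hi"]
    )
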