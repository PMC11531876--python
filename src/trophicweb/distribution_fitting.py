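"""Maximum-likelihood fits of candidate models to interaction strengths.

The per-link median interaction strengths are pooled into one sample
and fitted to six candidate families — exponential, gamma, log-normal,
normal, power law and uniform — by maximum likelihood; the best model
is the one minimizing AIC = 2k − 2·loglik.  Food webs typically show
many weak and few strong links, which the gamma (shape < 1) and
log-normal families capture; the normal and uniform candidates act as
null references even though their support is not restricted to
positives.

The power law is a continuous Pareto with ``xmin`` fixed at the sample
minimum and the exponent from its closed-form ML estimate; no xmin
search is performed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MODELS = ("exponential", "gamma", "lognormal", "normal", "powerlaw", "uniform")

#: Number of free parameters per candidate family.
N_PARAMS = {
    "exponential": 1,
    "gamma": 2,
    "lognormal": 2,
    "normal": 2,
    "powerlaw": 1,   # xmin fixed at min(values)
    "uniform": 2,
}


@dataclass(frozen=True)
class FitResult:
    """One model's ML fit: parameters, log-likelihood and AIC."""

    model: str
    params: dict[str, float]
    loglik: float
    aic: float
    n: int
    error: str | None = None

    @property
    def k(self) -> int:
        return N_PARAMS[self.model]

    @property
    def ok(self) -> bool:
        return self.error is None and math.isfinite(self.aic)


def _check_values(values: np.ndarray, model: str) -> None:
    if values.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in input")
    if model in ("exponential", "gamma", "lognormal", "powerlaw") and not np.all(
        values > 0
    ):
        raise ValueError(f"{model} fit requires strictly positive values")


def fit_model(values, model: str) -> FitResult:
    """Fit one candidate family by maximum likelihood.

    Degenerate inputs (zero sample variance) cannot support the
    two-parameter continuous families; those fits come back flagged
    with ``error`` set and infinite AIC so that selection skips them.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    x = np.asarray(values, dtype=float)
    _check_values(x, model)
    n = x.size
    degenerate = bool(np.all(x == x[0]))

    if degenerate and model != "exponential":
        return FitResult(
            model=model, params={}, loglik=math.inf, aic=-math.inf, n=n,
            error="degenerate input (zero variance)",
        )

    if model == "exponential":
        rate = 1.0 / float(np.mean(x))
        loglik = n * math.log(rate) - rate * float(np.sum(x))
        params = {"rate": rate}
    elif model == "gamma":
        shape, _, scale = stats.gamma.fit(x, floc=0)
        loglik = float(np.sum(stats.gamma.logpdf(x, shape, loc=0, scale=scale)))
        params = {"shape": float(shape), "rate": 1.0 / float(scale)}
    elif model == "lognormal":
        logs = np.log(x)
        mu = float(np.mean(logs))
        sigma = float(np.std(logs))  # ML: ddof=0
        if sigma == 0:
            return FitResult(model, {}, math.inf, -math.inf, n,
                             error="degenerate input (zero log-variance)")
        loglik = float(np.sum(stats.lognorm.logpdf(x, sigma, scale=math.exp(mu))))
        params = {"meanlog": mu, "sdlog": sigma}
    elif model == "normal":
        mu = float(np.mean(x))
        sigma = float(np.std(x))
        loglik = float(np.sum(stats.norm.logpdf(x, mu, sigma)))
        params = {"mean": mu, "sd": sigma}
    elif model == "powerlaw":
        xmin = float(np.min(x))
        s = float(np.sum(np.log(x / xmin)))
        if s == 0:
            return FitResult(model, {}, math.inf, -math.inf, n,
                             error="degenerate input (all at xmin)")
        # Continuous Pareto: pdf = (a-1)/xmin * (x/xmin)^(-a), a = 1 + n/s.
        a = 1.0 + n / s
        loglik = n * math.log((a - 1.0) / xmin) - a * s
        params = {"alpha": a, "xmin": xmin}
    elif model == "uniform":
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi == lo:
            return FitResult(model, {}, math.inf, -math.inf, n,
                             error="degenerate input (zero-width support)")
        loglik = -n * math.log(hi - lo)
        params = {"min": lo, "max": hi}

    aic = 2 * N_PARAMS[model] - 2 * loglik
    return FitResult(model=model, params=params, loglik=loglik, aic=aic, n=n)


def fit_all(values, models: tuple[str, ...] = MODELS) -> list[FitResult]:
    """Fit every candidate family to the same sample."""
    return [fit_model(values, m) for m in models]


def select_best(fits: list[FitResult]) -> FitResult:
    """Minimum-AIC model among usable fits.

    Ties (|ΔAIC| < 1e-9) break toward fewer parameters, then toward the
    lexicographically first model name.  All fits must share the same
    sample size, else the AICs are not comparable.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to select between")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits cover different sample sizes: {sorted(ns)}")
    usable = [f for f in fits if f.ok]
    if not usable:
        raise ValueError("no usable (non-degenerate) fits to select from")
    best = min(usable, key=lambda f: (f.aic, f.k, f.model))
    near = [f for f in usable if abs(f.aic - best.aic) < 1e-9]
    if len(near) > 1:
        best = min(near, key=lambda f: (f.k, f.model))
    return best


def delta_aic_table(fits: list[FitResult]) -> pd.DataFrame:
    """One row per model: k, loglik, aic, ΔAIC and JSON-encoded params."""
    usable = [f for f in fits if f.ok]
    best_aic = min(f.aic for f in usable) if usable else math.nan
    rows = []
    for f in sorted(fits, key=lambda f: (not f.ok, f.aic)):
        rows.append(
            {
                "model": f.model,
                "k": f.k,
                "loglik": f.loglik if f.ok else math.nan,
                "aic": f.aic if f.ok else math.nan,
                "delta_aic": (f.aic - best_aic) if f.ok else math.nan,
                "params_json": json.dumps(f.params, sort_keys=True),
            }
        )
    return pd.DataFrame(
        rows, columns=["model", "k", "loglik", "aic", "delta_aic", "params_json"]
    )
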