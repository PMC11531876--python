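"""Per-link interaction-strength estimation from body masses.

The per-capita effect of a consumer on a resource is estimated from
allometry alone::

    IS = alpha * xR * mR / mC

where ``alpha`` is the consumer's search rate (area or volume scanned
per unit time), ``xR`` the resource density, and ``mR``/``mC`` the
resource and consumer body masses in grams.  Both ``alpha`` and ``xR``
follow power laws of body mass whose coefficients differ with the
dimensionality of the interaction: a planar (2D, benthic-style) search
space scales differently from a volumetric (3D, pelagic-style) one.

Uncertainty in the regression exponents is propagated by Monte Carlo:
each replicate draws one exponent per scaling law and dimensionality
from Normal(point estimate, standard error) and applies it to every
link, so the per-link samples share the exponent draws within a
replicate — the uncertainty lives in the globally estimated regressions,
not in individual links.  Sampled interaction strengths are
right-skewed (log-normal-like), so the per-link median is the central
tendency reported downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .foodweb_core import (
    UNSET,
    FoodWeb,
    FoodWebError,
    MOVEMENT_2D,
    MOVEMENT_3D,
    TrophicLink,
    _VALID_MOVEMENTS,
)


class EstimationError(FoodWebError):
    """Raised when a link's interaction strength cannot be estimated."""


@dataclass(frozen=True)
class ScalingCoefficients:
    """Power-law coefficients for search rate and resource density.

    Intercepts are on the natural scale of the power law
    (``value = intercept * mass ** exponent``); ``*_se`` are the
    standard errors of the exponents used for Monte-Carlo propagation.
    """

    search_rate_intercept_2D: float
    search_rate_exponent_2D: float
    search_rate_exponent_se_2D: float
    search_rate_intercept_3D: float
    search_rate_exponent_3D: float
    search_rate_exponent_se_3D: float
    density_intercept_2D: float
    density_exponent_2D: float
    density_exponent_se_2D: float
    density_intercept_3D: float
    density_exponent_3D: float
    density_exponent_se_3D: float

    def __post_init__(self) -> None:
        for name in (
            "search_rate_exponent_se_2D",
            "search_rate_exponent_se_3D",
            "density_exponent_se_2D",
            "density_exponent_se_3D",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def search_rate_params(self, dim: str) -> tuple[float, float, float]:
        """(intercept, exponent, se) of the search-rate law for ``dim``."""
        if dim == MOVEMENT_2D:
            return (self.search_rate_intercept_2D, self.search_rate_exponent_2D,
                    self.search_rate_exponent_se_2D)
        if dim == MOVEMENT_3D:
            return (self.search_rate_intercept_3D, self.search_rate_exponent_3D,
                    self.search_rate_exponent_se_3D)
        raise ValueError(f"unknown dimensionality {dim!r}")

    def density_params(self, dim: str) -> tuple[float, float, float]:
        """(intercept, exponent, se) of the density law for ``dim``."""
        if dim == MOVEMENT_2D:
            return (self.density_intercept_2D, self.density_exponent_2D,
                    self.density_exponent_se_2D)
        if dim == MOVEMENT_3D:
            return (self.density_intercept_3D, self.density_exponent_3D,
                    self.density_exponent_se_3D)
        raise ValueError(f"unknown dimensionality {dim!r}")

    def without_uncertainty(self) -> "ScalingCoefficients":
        """Copy with all exponent standard errors set to zero."""
        kwargs = {f.name: getattr(self, f.name) for f in self.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        for k in list(kwargs):
            if k.endswith("_se_2D") or k.endswith("_se_3D"):
                kwargs[k] = 0.0
        return ScalingCoefficients(**kwargs)


def load_coefficients(path: str | Path | None = None) -> ScalingCoefficients:
    """Load scaling coefficients from YAML.

    Without ``path``, the packaged defaults (the Pawar-style 2D/3D
    search-rate and density regressions) are used.
    """
    if path is None:
        text = (resources.files("trophicweb") / "data" / "scaling_coefficients.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    try:
        return ScalingCoefficients(
            search_rate_intercept_2D=float(raw["search_rate"]["2D"]["intercept"]),
            search_rate_exponent_2D=float(raw["search_rate"]["2D"]["exponent"]),
            search_rate_exponent_se_2D=float(raw["search_rate"]["2D"]["se"]),
            search_rate_intercept_3D=float(raw["search_rate"]["3D"]["intercept"]),
            search_rate_exponent_3D=float(raw["search_rate"]["3D"]["exponent"]),
            search_rate_exponent_se_3D=float(raw["search_rate"]["3D"]["se"]),
            density_intercept_2D=float(raw["density"]["2D"]["intercept"]),
            density_exponent_2D=float(raw["density"]["2D"]["exponent"]),
            density_exponent_se_2D=float(raw["density"]["2D"]["se"]),
            density_intercept_3D=float(raw["density"]["3D"]["intercept"]),
            density_exponent_3D=float(raw["density"]["3D"]["exponent"]),
            density_exponent_se_3D=float(raw["density"]["3D"]["se"]),
        )
    except (KeyError, TypeError) as exc:
        raise EstimationError(f"malformed coefficients config: {exc}") from exc


def classify_dimensionality(consumer_movement: str, resource_movement: str) -> str:
    """Interaction dimensionality from the two endpoints' movement spaces.

    The search space is planar (2D) when both species move in 2D or when
    a 3D consumer hunts 2D prey (a pelagic predator striking the
    benthos); it is volumetric (3D) when both move in 3D or when a 2D
    consumer captures 3D prey (a benthic predator reaching into the
    water column).  In short: the *resource's* movement space decides.
    """
    for value in (consumer_movement, resource_movement):
        if value not in _VALID_MOVEMENTS:
            raise ValueError(f"unknown movement {value!r}")
    return resource_movement


def search_rate(
    mC: float,
    dim: str,
    coeffs: ScalingCoefficients,
    exponent_override: float | None = None,
) -> float:
    """Consumer search rate ``alpha = intercept * mC ** exponent``.

    ``exponent_override`` substitutes a Monte-Carlo exponent draw for
    the point estimate.
    """
    if not mC > 0:
        raise EstimationError(f"consumer mass must be > 0, got {mC}")
    intercept, exponent, _ = coeffs.search_rate_params(dim)
    if exponent_override is not None:
        exponent = exponent_override
    # np.power keeps the scalar path bit-identical to the vectorized
    # Monte-Carlo path (Python's ** can differ in the last ulp).
    return float(intercept * np.power(mC, exponent))


def resource_density(
    mR: float | None,
    dim: str,
    coeffs: ScalingCoefficients,
    empirical_density: float | None = None,
    exponent_override: float | None = None,
) -> float:
    """Resource density ``xR``: empirical when known, allometric otherwise.

    An empirical density is returned unchanged — observed abundances
    carry no regression-exponent uncertainty, so the Monte-Carlo
    override does not touch them.
    """
    if empirical_density is not None:
        return empirical_density
    if mR is None or not mR > 0:
        raise EstimationError(
            f"resource density needs a positive mass or an empirical value (mR={mR})"
        )
    intercept, exponent, _ = coeffs.density_params(dim)
    if exponent_override is not None:
        exponent = exponent_override
    return float(intercept * np.power(mR, exponent))


def interaction_strength_value(alpha: float, xR: float, mR: float, mC: float) -> float:
    """Per-capita interaction strength ``IS = alpha * xR * mR / mC``."""
    for name, value in (("alpha", alpha), ("xR", xR), ("mR", mR), ("mC", mC)):
        if not value > 0:
            raise EstimationError(f"{name} must be > 0, got {value}")
    return alpha * xR * mR / mC


PASS = "pass"


def mass_independent_policy(
    link: TrophicLink, web: FoodWeb, *, unit_consumer_mass: bool = False
) -> tuple[float, float, float] | str:
    """Effective (mR, mC, xR) for links whose resource is mass-independent.

    Macroalgae, sponges, necromass and detritus are consumed in
    proportion to the consumer's effort, not to their own mass or
    density, so the resource terms collapse to unity: mR = 1, xR = 1.
    With the default policy the consumer keeps its real mass, so
    IS reduces to ``alpha(mC) / mC``; ``unit_consumer_mass=True``
    additionally sets mC = 1 (an alternative reading under which IS
    equals the search rate at unit mass).

    Returns :data:`PASS` for ordinary links (use the real traits).
    """
    resource = web.species(link.resource_id)
    if not resource.is_mass_independent:
        return PASS
    consumer = web.species(link.consumer_id)
    if unit_consumer_mass:
        return (1.0, 1.0, 1.0)
    if consumer.body_mass is UNSET:
        raise EstimationError(
            f"consumer {consumer.id!r} of mass-independent resource "
            f"{resource.id!r} has no body mass"
        )
    return (1.0, consumer.body_mass, 1.0)


@dataclass(frozen=True)
class InteractionEstimate:
    """Monte-Carlo interaction-strength samples for a single link."""

    link: TrophicLink
    dimensionality: str
    samples: np.ndarray        # shape (n_samples,), all > 0
    median_is: float
    alpha_point: float         # search rate at point-estimate exponents
    xR_point: float            # resource density actually used

    @property
    def q25(self) -> float:
        return float(np.percentile(self.samples, 25))

    @property
    def q75(self) -> float:
        return float(np.percentile(self.samples, 75))


def _link_inputs(web: FoodWeb, link: TrophicLink, *, unit_consumer_mass: bool = False):
    """Resolve (dim, mR, mC, xR_empirical, density_needed) for one link."""
    resource = web.species(link.resource_id)
    consumer = web.species(link.consumer_id)
    dim = classify_dimensionality(consumer.movement, resource.movement)
    policy = mass_independent_policy(link, web, unit_consumer_mass=unit_consumer_mass)
    if policy is not PASS:
        mR, mC, xR = policy
        return dim, mR, mC, xR, False
    if consumer.body_mass is UNSET:
        raise EstimationError(f"consumer {consumer.id!r} has no body mass")
    mC = consumer.body_mass
    if resource.empirical_density is not UNSET:
        if resource.body_mass is UNSET:
            # Density known but mass unknown: treat resource mass as unit.
            return dim, 1.0, mC, resource.empirical_density, False
        return dim, resource.body_mass, mC, resource.empirical_density, False
    if resource.body_mass is UNSET:
        raise EstimationError(
            f"resource {resource.id!r} has neither body mass nor empirical density"
        )
    return dim, resource.body_mass, mC, None, True


def point_interaction_strength(
    web: FoodWeb,
    coeffs: ScalingCoefficients,
    *,
    unit_consumer_mass: bool = False,
) -> dict[TrophicLink, float]:
    """Closed-form IS at the point-estimate exponents, per link."""
    out: dict[TrophicLink, float] = {}
    for link in web.links:
        dim, mR, mC, xR_emp, needs_density = _link_inputs(
            web, link, unit_consumer_mass=unit_consumer_mass
        )
        alpha = search_rate(mC, dim, coeffs)
        xR = resource_density(mR, dim, coeffs) if needs_density else xR_emp
        out[link] = interaction_strength_value(alpha, xR, mR, mC)
    return out


def monte_carlo_interaction_strengths(
    web: FoodWeb,
    coeffs: ScalingCoefficients,
    n_samples: int = 1000,
    seed: int = 0,
    *,
    unit_consumer_mass: bool = False,
) -> dict[TrophicLink, InteractionEstimate]:
    """Propagate scaling-exponent uncertainty into per-link IS samples.

    Each of the ``n_samples`` replicates draws one exponent per scaling
    law per dimensionality (four draws: search-rate 2D/3D, density
    2D/3D) from Normal(point, se) and recomputes every link's IS with
    those shared exponents.  Intercepts stay at their point estimates.
    Deterministic under ``seed``.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    rng = np.random.default_rng(seed)
    # Exponent draws: columns (search_2D, search_3D, dens_2D, dens_3D).
    points = np.array(
        [
            coeffs.search_rate_exponent_2D,
            coeffs.search_rate_exponent_3D,
            coeffs.density_exponent_2D,
            coeffs.density_exponent_3D,
        ]
    )
    ses = np.array(
        [
            coeffs.search_rate_exponent_se_2D,
            coeffs.search_rate_exponent_se_3D,
            coeffs.density_exponent_se_2D,
            coeffs.density_exponent_se_3D,
        ]
    )
    draws = rng.normal(points, ses, size=(n_samples, 4))

    out: dict[TrophicLink, InteractionEstimate] = {}
    for link in web.links:
        dim, mR, mC, xR_emp, needs_density = _link_inputs(
            web, link, unit_consumer_mass=unit_consumer_mass
        )
        a_int, _, _ = coeffs.search_rate_params(dim)
        search_col = 0 if dim == MOVEMENT_2D else 1
        alpha_samples = a_int * mC ** draws[:, search_col]
        alpha_point = search_rate(mC, dim, coeffs)
        if needs_density:
            d_int, _, _ = coeffs.density_params(dim)
            dens_col = 2 if dim == MOVEMENT_2D else 3
            xR_samples = d_int * mR ** draws[:, dens_col]
            xR_point = resource_density(mR, dim, coeffs)
        else:
            xR_samples = np.full(n_samples, xR_emp)
            xR_point = xR_emp
        samples = alpha_samples * xR_samples * mR / mC
        out[link] = InteractionEstimate(
            link=link,
            dimensionality=dim,
            samples=samples,
            median_is=float(np.median(samples)),
            alpha_point=alpha_point,
            xR_point=float(xR_point),
        )
    return out


def median_interaction_strengths(
    estimates: dict[TrophicLink, InteractionEstimate],
) -> dict[TrophicLink, float]:
    """Per-link median IS — the weights used by stability analyses."""
    return {link: est.median_is for link, est in estimates.items()}


def total_interaction_strength(
    species_id: str,
    estimates: dict[TrophicLink, InteractionEstimate],
    web: FoodWeb,
) -> float:
    """Sum of median IS over every link touching ``species_id``.

    Both incoming (as resource) and outgoing (as consumer) links count;
    a self-link counts once.
    """
    web.species(species_id)
    return float(
        sum(
            est.median_is
            for link, est in estimates.items()
            if species_id in (link.resource_id, link.consumer_id)
        )
    )


def estimates_table(estimates: dict[TrophicLink, InteractionEstimate]):
    """Per-link output table (one row per link, sorted)."""
    import pandas as pd

    rows = []
    for link in sorted(estimates):
        est = estimates[link]
        rows.append(
            {
                "resource": link.resource_id,
                "consumer": link.consumer_id,
                "dimensionality": est.dimensionality,
                "alpha": est.alpha_point,
                "xR": est.xR_point,
                "median_is": est.median_is,
                "q25_is": est.q25,
                "q75_is": est.q75,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "resource", "consumer", "dimensionality", "alpha", "xR",
            "median_is", "q25_is", "q75_is",
        ],
    )
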