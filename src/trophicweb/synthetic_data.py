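"""Synthetic food webs with trait annotations.

The generator emulates the statistical shape of a well-resolved coastal
Antarctic web — on the order of a hundred species, directed connectance
near 0.05, log-normal body masses that increase with trophic height, a
benthic-dominated (mostly 2D) movement split, and a basal layer of
mass-independent resources (the macroalgae/detritus analogue) — so that
every pipeline stage can be exercised without external data.  Topology
comes from the classic niche model; it makes no attempt to reproduce
any particular empirical degree sequence or module structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .foodweb_core import (
    UNSET,
    FoodWeb,
    FoodWebError,
    MOVEMENT_2D,
    MOVEMENT_3D,
    Species,
    TrophicLink,
)
from .topology_metrics import trophic_levels


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic-web generator.

    Defaults mirror the target study system's shape: 110 species at
    directed connectance 0.054, about half of the basal layer flagged
    as mass-independent resources, body masses log-normal in grams
    (log-mean −2 at the base, rising 2.5 natural-log units per trophic
    level, log-sd 1), and a quarter of species pelagic (3D).
    """

    S: int = 110
    C: float = 0.054
    basal_fraction: float = 0.5
    mass_log_mean: float = -2.0
    mass_log_sd: float = 1.0
    mass_tl_slope: float = 2.5
    p_pelagic: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 5:
            raise ValueError(f"S must be >= 5, got {self.S}")
        if not 0 < self.C < 0.5:
            raise ValueError(f"C must be in (0, 0.5), got {self.C}")
        if not 0 < self.basal_fraction < 1:
            raise ValueError("basal_fraction must be in (0, 1)")
        if not 0 <= self.p_pelagic <= 1:
            raise ValueError("p_pelagic must be in [0, 1]")


def _species_ids(S: int) -> list[str]:
    width = len(str(S - 1))
    return [f"sp{str(i).zfill(width)}" for i in range(S)]


def niche_model_web(cfg: SynthConfig, max_attempts: int = 100) -> FoodWeb:
    """Niche-model topology at the target connectance.

    Each species receives a niche value n_i ~ U(0,1); its feeding range
    is r_i = n_i · Beta(1, 1/(2C) − 1) with centre c_i ~ U(r_i/2, n_i),
    and it consumes every species whose niche value falls inside
    [c_i − r_i/2, c_i + r_i/2].  The species with the smallest niche
    value is forced basal.  Webs are regenerated (fresh draws from the
    same seeded stream) until the undirected projection is connected
    and every consumer has a feeding path to a basal species.
    """
    rng = np.random.default_rng(cfg.seed)
    beta_b = 1.0 / (2.0 * cfg.C) - 1.0
    ids = _species_ids(cfg.S)
    for _ in range(max_attempts):
        n = rng.uniform(size=cfg.S)
        r = n * rng.beta(1.0, beta_b, size=cfg.S)
        r[np.argmin(n)] = 0.0  # the lowest-niche species is basal
        c = rng.uniform(r / 2.0, np.maximum(n, r / 2.0 + 1e-12))
        lo, hi = c - r / 2.0, c + r / 2.0
        links = [
            TrophicLink(ids[j], ids[i])
            for i in range(cfg.S)
            for j in range(cfg.S)
            if lo[i] <= n[j] <= hi[i] and r[i] > 0
        ]
        web = FoodWeb((Species(id=s) for s in ids), links)
        if not _connected(web):
            continue
        try:
            trophic_levels(web)  # raises if any consumer is ungrounded
        except FoodWebError:
            continue
        return web
    raise FoodWebError(
        f"could not generate a connected, grounded niche web in "
        f"{max_attempts} attempts (S={cfg.S}, C={cfg.C})"
    )


def _connected(web: FoodWeb) -> bool:
    import networkx as nx

    g = web.to_undirected()
    return g.number_of_nodes() > 0 and nx.is_connected(g)


def assign_traits(web: FoodWeb, cfg: SynthConfig) -> FoodWeb:
    """Annotate a bare topology with masses, movement and resource flags.

    Body masses are log-normal with log-mean rising by ``mass_tl_slope``
    per trophic level above the base, so consumers sit above their prey
    on average.  Basal species are flagged mass-independent with
    probability ``basal_fraction``; flagged species get no body mass
    (like detritus, their mass is meaningless to consumers).  Movement
    is 3D with probability ``p_pelagic``, else 2D.  Empirical densities
    are left unset so estimation exercises the allometric density path.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    tls = trophic_levels(web)
    new_species = []
    for sp in web:  # lexicographic order: draws are reproducible
        tl = tls[sp.id]
        log_mass = rng.normal(
            cfg.mass_log_mean + cfg.mass_tl_slope * (tl - 1.0), cfg.mass_log_sd
        )
        movement = MOVEMENT_3D if rng.random() < cfg.p_pelagic else MOVEMENT_2D
        is_basal = not web.prey_of(sp.id)
        mass_independent = bool(is_basal and rng.random() < cfg.basal_fraction)
        new_species.append(
            replace(
                sp,
                body_mass=UNSET if mass_independent else float(math.exp(log_mass)),
                movement=movement,
                is_mass_independent=mass_independent,
            )
        )
    return FoodWeb(new_species, web.links)


def synthetic_web(cfg: SynthConfig) -> FoodWeb:
    """Niche topology plus traits in one call."""
    return assign_traits(niche_model_web(cfg), cfg)


def fixture_web() -> FoodWeb:
    """A 6-species web whose every metric is hand-computable.

    Two basal resources (B1 detritus-like and mass-independent, B2 a
    producer with known density), two herbivores (H1, H2), one
    intermediate consumer (I1, the only pelagic hunter besides T1) and
    a top predator (T1).  Links (resource → consumer)::

        B1→H1  B1→H2  B2→H2  B2→I1  H1→I1  H2→I1  I1→T1

    Hand-derived values (prey-averaged TL; omnivory = population SD of
    prey TLs; similarity = mean pairwise Jaccard of prey∪predator sets):

    ======= ===== ====== ========== ============ =================
    species  TL   degree  omnivory  similarity    component count
                                                  after removing it
    ======= ===== ====== ========== ============ =================
    B1      1     2      0          1/6           1
    B2      1     2      0          97/300        1
    H1      2     2      0          3/10          1
    H2      2     3      0          17/60         1
    I1      8/3   4      sqrt(2)/3  13/75         2
    T1      11/3  1      0          4/15          1
    ======= ===== ====== ========== ============ =================

    With the round-number coefficients of :func:`fixture_coefficients`
    (all exponent SEs zero) the point-estimate interaction strengths
    are::

        B1→H1: 0.1*10^0.75/10            = 0.0562341...
        B1→H2: same                      = 0.0562341...
        B2→H2: 0.1*10^0.75 * 2 / 10      = 0.1124682...
        B2→I1: 0.1*100^0.75 * 2 / 100    = 0.0632456...
        H1→I1: 0.1*100^0.75 * 10^-0.75 * 10/100 = 0.0562341...
        H2→I1: same                      = 0.0562341...
        I1→T1: 0.01*1000 * 100^-1 * 100/1000    = 0.01
    """
    species = [
        Species("B1", name="aged detritus", body_mass=UNSET,
                movement=MOVEMENT_2D, is_mass_independent=True),
        Species("B2", name="macroalga", body_mass=1.0,
                movement=MOVEMENT_2D, empirical_density=2.0),
        Species("H1", name="grazer 1", body_mass=10.0, movement=MOVEMENT_2D),
        Species("H2", name="grazer 2", body_mass=10.0, movement=MOVEMENT_2D),
        Species("I1", name="demersal fish", body_mass=100.0, movement=MOVEMENT_3D),
        Species("T1", name="top predator", body_mass=1000.0, movement=MOVEMENT_3D),
    ]
    links = [
        TrophicLink("B1", "H1"),
        TrophicLink("B1", "H2"),
        TrophicLink("B2", "H2"),
        TrophicLink("B2", "I1"),
        TrophicLink("H1", "I1"),
        TrophicLink("H2", "I1"),
        TrophicLink("I1", "T1"),
    ]
    return FoodWeb(species, links)


def fixture_coefficients():
    """Round-number scaling coefficients for hand calculation (SEs 0)."""
    from .interaction_strength import ScalingCoefficients

    return ScalingCoefficients(
        search_rate_intercept_2D=0.1,
        search_rate_exponent_2D=0.75,
        search_rate_exponent_se_2D=0.0,
        search_rate_intercept_3D=0.01,
        search_rate_exponent_3D=1.0,
        search_rate_exponent_se_3D=0.0,
        density_intercept_2D=1.0,
        density_exponent_2D=-0.75,
        density_exponent_se_2D=0.0,
        density_intercept_3D=1.0,
        density_exponent_3D=-1.0,
        density_exponent_se_3D=0.0,
    )
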