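"""Unweighted species-level food-web properties.

Covers the classical topological descriptors used to characterize a
species' role: prey-averaged trophic level, degree (prey + predators),
omnivory (spread of prey trophic levels), trophic similarity (overlap
of combined prey/predator neighborhoods) and the among-module
participation coefficient on a modularity partition.  Cannibalistic
self-links are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .foodweb_core import FoodWeb, ValidationError


@dataclass(frozen=True)
class SpeciesMetrics:
    """Per-species bundle of topological metrics (plus total IS)."""

    species_id: str
    trophic_level: float
    degree: int
    omnivory: float
    trophic_similarity: float
    intermodule_connectivity: float
    total_is: float
    module: int


def trophic_levels(web: FoodWeb) -> dict[str, float]:
    """Prey-averaged trophic levels.

    TL_i = 1 for basal species, else 1 + mean TL of i's prey; the
    mutual recursion is solved exactly as the linear system
    (I − D)·TL = 1 with D the row-normalized diet matrix.  Every
    consumer must reach a basal species through its diet, otherwise the
    system has no grounded solution and the offending set is reported.
    """
    ids = web.species_ids
    if not ids:
        return {}
    index = {s: i for i, s in enumerate(ids)}
    basal = set(web.basal_species())

    # Grounding check: walk down diet links from each consumer.
    reach_basal = set(basal)
    # Fixed-point over the "some prey chain hits basal" relation.
    changed = True
    while changed:
        changed = False
        for s in ids:
            if s in reach_basal:
                continue
            if any(p in reach_basal for p in web.prey_of(s)):
                reach_basal.add(s)
                changed = True
    ungrounded = sorted(set(ids) - reach_basal)
    if ungrounded:
        raise ValidationError(
            "consumers with no feeding path to a basal species: "
            + ", ".join(ungrounded)
        )

    n = len(ids)
    d = np.zeros((n, n))
    for s in ids:
        prey = web.prey_of(s)
        if prey:
            w = 1.0 / len(prey)
            for p in prey:
                d[index[s], index[p]] = w
    tl = np.linalg.solve(np.eye(n) - d, np.ones(n))
    return {s: float(tl[index[s]]) for s in ids}


def degree(web: FoodWeb, species_id: str) -> int:
    """Prey count plus predator count (self-links excluded)."""
    return len(web.prey_of(species_id)) + len(web.predators_of(species_id))


def omnivory(web: FoodWeb, species_id: str, tls: dict[str, float]) -> float:
    """Population standard deviation of the prey's trophic levels.

    Zero for basal and single-prey species: feeding at one level only
    is no omnivory at all.
    """
    prey = web.prey_of(species_id)
    if len(prey) < 2:
        return 0.0
    return float(np.std([tls[p] for p in prey]))


def _neighborhood(web: FoodWeb, species_id: str) -> frozenset[str]:
    return frozenset(web.prey_of(species_id)) | frozenset(web.predators_of(species_id))


def pairwise_trophic_similarity(web: FoodWeb, i: str, j: str) -> float:
    """Jaccard overlap of two species' combined prey∪predator sets."""
    ni, nj = _neighborhood(web, i), _neighborhood(web, j)
    union = ni | nj
    if not union:
        return 0.0
    return len(ni & nj) / len(union)


def trophic_similarity(web: FoodWeb, species_id: str) -> float:
    """Mean pairwise similarity of ``species_id`` to every other species."""
    if web.n_species < 2:
        raise ValidationError("trophic similarity needs at least two species")
    others = [s for s in web.species_ids if s != species_id]
    return float(
        np.mean([pairwise_trophic_similarity(web, species_id, j) for j in others])
    )


def detect_modules(web: FoodWeb, seed: int = 0, n_restarts: int = 20) -> dict[str, int]:
    """Modularity partition of the undirected projection.

    Runs the Louvain heuristic ``n_restarts`` times with derived seeds
    and keeps the highest-modularity partition (first winner on ties),
    so the result is deterministic under ``seed``.  Module ids are
    renumbered by the lexicographically smallest member.
    """
    if web.n_species == 0:
        raise ValidationError("cannot detect modules in an empty web")
    g = web.to_undirected()
    best: list[set[str]] | None = None
    best_q = -np.inf
    for r in range(n_restarts):
        partition = nx.community.louvain_communities(g, seed=seed * n_restarts + r)
        q = nx.community.modularity(g, partition) if g.number_of_edges() else 0.0
        if q > best_q + 1e-12:
            best_q = q
            best = [set(c) for c in partition]
    assert best is not None
    ordered = sorted(best, key=lambda c: min(c))
    return {s: m for m, comm in enumerate(ordered) for s in comm}


def intermodule_connectivity(
    web: FoodWeb, modules: dict[str, int], species_id: str
) -> float:
    """Among-module participation coefficient.

    c_i = 1 − Σ_m (k_im / k_i)² with k_im the number of i's undirected
    links into module m.  Zero when all links stay within one module
    (or the species has no links); approaches 1 − 1/M as links spread
    evenly over M modules.
    """
    g = web.to_undirected()
    neighbors = list(g.neighbors(species_id))
    k = len(neighbors)
    if k == 0:
        return 0.0
    counts: dict[int, int] = {}
    for nb in neighbors:
        counts[modules[nb]] = counts.get(modules[nb], 0) + 1
    return 1.0 - sum((c / k) ** 2 for c in counts.values())


def compute_species_metrics(
    web: FoodWeb,
    total_is: dict[str, float] | None = None,
    seed: int = 0,
) -> dict[str, SpeciesMetrics]:
    """All per-species metrics in one pass.

    ``total_is`` (per-species summed median interaction strength from
    the estimation stage) is copied through; omitted entries are 0.
    """
    tls = trophic_levels(web)
    modules = detect_modules(web, seed=seed)
    total_is = total_is or {}
    out: dict[str, SpeciesMetrics] = {}
    for s in web.species_ids:
        out[s] = SpeciesMetrics(
            species_id=s,
            trophic_level=tls[s],
            degree=degree(web, s),
            omnivory=omnivory(web, s, tls),
            trophic_similarity=(
                trophic_similarity(web, s) if web.n_species >= 2 else 0.0
            ),
            intermodule_connectivity=intermodule_connectivity(web, modules, s),
            total_is=float(total_is.get(s, 0.0)),
            module=modules[s],
        )
    return out


def metrics_table(metrics: dict[str, SpeciesMetrics]) -> pd.DataFrame:
    """One row per species, sorted by id."""
    rows = [
        {
            "species": m.species_id,
            "trophic_level": m.trophic_level,
            "degree": m.degree,
            "omnivory": m.omnivory,
            "trophic_similarity": m.trophic_similarity,
            "intermodule_connectivity": m.intermodule_connectivity,
            "total_is": m.total_is,
            "module": m.module,
        }
        for _, m in sorted(metrics.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "species", "trophic_level", "degree", "omnivory",
            "trophic_similarity", "intermodule_connectivity", "total_is", "module",
        ],
    )
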