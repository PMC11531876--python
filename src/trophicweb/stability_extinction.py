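"""Quasi-sign-stability (QSS) and sequential extinction simulations.

Local stability of a community is read off the Jacobian at equilibrium.
With per-species self-regulation unknown, the diagonal is set to zero
and stability is assessed quasi-sign-stably: the sign pattern of the
community matrix is kept fixed — for every feeding link the consumer's
column entry on the resource row is negative, the transpose entry
positive — while the magnitudes are randomized below the estimated
interaction strength of the link.  Each replicate records the maximum
real part of the eigenvalues; the median (and IQR) over replicates
summarizes how much self-regulation the web would need to be stable —
more negative meaning more stable.

Sequential extinctions remove the top-k species of a ranking criterion
one at a time from a static order computed on the intact web, re-running
QSS and counting connected components after every removal.  Secondary
extinctions are not modelled: species left without prey stay in the web
as isolated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .foodweb_core import FoodWeb, ValidationError, TrophicLink
from .topology_metrics import SpeciesMetrics

import pandas as pd

CRITERIA = (
    "total_is",
    "trophic_level",
    "degree",
    "omnivory",
    "trophic_similarity",
    "intermodule_connectivity",
)


@dataclass(frozen=True)
class QSSResult:
    """Distribution of the maximum real eigenvalue part over replicates."""

    eigen_samples: np.ndarray
    median_eigen: float
    mean_eigen: float
    iqr: tuple[float, float]


@dataclass(frozen=True)
class ExtinctionStep:
    removed_species_id: str
    rank_metric_value: float
    qss: QSSResult
    n_components: int
    n_species_remaining: int


@dataclass(frozen=True)
class ExtinctionTrajectory:
    criterion: str
    steps: tuple[ExtinctionStep, ...]

    @property
    def fragmentation_points(self) -> tuple[str, ...]:
        return tuple(detect_fragmentation(self))


def build_sign_jacobian(
    web: FoodWeb,
    is_medians: dict[TrophicLink, float],
    rng: np.random.Generator,
    *,
    magnitude: str = "uniform",
) -> np.ndarray:
    """One randomized community matrix honoring the web's sign pattern.

    For a link with resource i and consumer j the consumer's effect on
    the resource is ``A[i, j] = -u1 * IS_ij`` and the resource's effect
    on the consumer ``A[j, i] = +u2 * IS_ij``, with u1, u2 independent
    Uniform(0, 1] draws (``magnitude="fixed"`` pins both at 1, giving
    the deterministic maximum-magnitude matrix).  Self-links and the
    diagonal are zero: self-regulation is deliberately absent.
    """
    ids = web.species_ids
    index = {s: i for i, s in enumerate(ids)}
    a = np.zeros((len(ids), len(ids)))
    for link in web.links:
        if link.is_self_link:
            continue
        try:
            is_val = is_medians[link]
        except KeyError:
            raise ValidationError(
                f"no interaction strength for link "
                f"{link.resource_id}->{link.consumer_id}"
            ) from None
        i, j = index[link.resource_id], index[link.consumer_id]
        if magnitude == "fixed":
            u1 = u2 = 1.0
        else:
            # 1 - U[0,1) lies in (0, 1].
            u1, u2 = 1.0 - rng.random(2)
        a[i, j] = -u1 * is_val
        a[j, i] = +u2 * is_val
    return a


def max_real_eigenvalue(a: np.ndarray) -> float:
    """Maximum real part over the eigenvalues of a dense matrix."""
    if a.size == 0:
        return 0.0
    return float(np.max(np.linalg.eigvals(a).real))


def qss(
    web: FoodWeb,
    is_medians: dict[TrophicLink, float],
    n_reps: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    *,
    magnitude: str = "uniform",
) -> QSSResult:
    """Quasi-sign-stability of a web under randomized magnitudes.

    Builds ``n_reps`` randomized Jacobians and records each one's
    maximum real eigenvalue part.  Deterministic under ``seed``.
    """
    if web.n_species == 0:
        raise ValidationError("cannot compute QSS of an empty web")
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    rng = np.random.default_rng(seed)
    samples = np.empty(n_reps)
    for r in range(n_reps):
        samples[r] = max_real_eigenvalue(
            build_sign_jacobian(web, is_medians, rng, magnitude=magnitude)
        )
    return QSSResult(
        eigen_samples=samples,
        median_eigen=float(np.median(samples)),
        mean_eigen=float(np.mean(samples)),
        iqr=(float(np.percentile(samples, 25)), float(np.percentile(samples, 75))),
    )


def rank_species(
    metrics: dict[str, SpeciesMetrics], criterion: str
) -> list[str]:
    """Species in decreasing order of one metric, computed once.

    Ties break lexicographically by species id.  The order is static:
    it reflects the intact web, not the remnant after removals.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    for s, m in metrics.items():
        if getattr(m, criterion) is None:
            raise ValueError(f"species {s!r} lacks metric {criterion!r}")
    return sorted(metrics, key=lambda s: (-getattr(metrics[s], criterion), s))


def count_components(web: FoodWeb) -> int:
    """Connected components of the undirected projection.

    Species with no links count as singleton components; the empty web
    has zero components.
    """
    if web.n_species == 0:
        return 0
    return nx.number_connected_components(web.to_undirected())


def _child_seed(
    master_seed: int, criterion: str, step: int
) -> np.random.SeedSequence:
    """Deterministic per-(criterion, step) seed for extinction QSS."""
    return np.random.SeedSequence(
        master_seed, spawn_key=(CRITERIA.index(criterion), step)
    )


def sequential_extinction(
    web: FoodWeb,
    order: list[str],
    metrics: dict[str, SpeciesMetrics],
    is_medians: dict[TrophicLink, float],
    criterion: str,
    k: int = 50,
    n_reps: int = 1000,
    seed: int = 0,
) -> ExtinctionTrajectory:
    """Remove the first ``k`` species of ``order``, tracking QSS and cohesion.

    After each removal the remnant web's QSS (with ``n_reps``
    randomized Jacobians, seeded per step from the master seed) and the
    number of connected components are recorded.  Links of removed
    species disappear; orphaned species remain as isolated nodes — no
    secondary extinctions are simulated.
    """
    if k > web.n_species:
        raise ValueError(f"k={k} exceeds species count {web.n_species}")
    current = web
    steps: list[ExtinctionStep] = []
    for t, sid in enumerate(order[:k], start=1):
        if sid not in current:
            raise KeyError(f"species {sid!r} already absent at step {t}")
        current = current.remove_species(sid)
        if current.n_species == 0:
            break
        medians = {
            l: is_medians[l]
            for l in current.links
            if l in is_medians
        }
        step_qss = qss(
            current,
            medians,
            n_reps=n_reps,
            seed=_child_seed(seed, criterion, t),
        )
        steps.append(
            ExtinctionStep(
                removed_species_id=sid,
                rank_metric_value=float(getattr(metrics[sid], criterion)),
                qss=step_qss,
                n_components=count_components(current),
                n_species_remaining=current.n_species,
            )
        )
    return ExtinctionTrajectory(criterion=criterion, steps=tuple(steps))


def detect_fragmentation(traj: ExtinctionTrajectory) -> list[str]:
    """Removed species whose step raised the component count.

    The first step is compared against 1 (an intact, connected web);
    each later step against its predecessor.
    """
    out: list[str] = []
    previous = 1
    for step in traj.steps:
        if step.n_components > previous:
            out.append(step.removed_species_id)
        previous = step.n_components
    return out


def run_all_extinctions(
    web: FoodWeb,
    metrics: dict[str, SpeciesMetrics],
    is_medians: dict[TrophicLink, float],
    k: int = 50,
    n_reps: int = 1000,
    seed: int = 0,
    criteria: tuple[str, ...] = CRITERIA,
) -> dict[str, ExtinctionTrajectory]:
    """One extinction trajectory per ranking criterion."""
    k = min(k, web.n_species)
    return {
        c: sequential_extinction(
            web, rank_species(metrics, c), metrics, is_medians, c,
            k=k, n_reps=n_reps, seed=seed,
        )
        for c in criteria
    }


def trajectory_table(traj: ExtinctionTrajectory) -> pd.DataFrame:
    """Per-step output table for one criterion."""
    rows = [
        {
            "step": t,
            "removed_species": s.removed_species_id,
            "metric_value": s.rank_metric_value,
            "median_eigen": s.qss.median_eigen,
            "q25": s.qss.iqr[0],
            "q75": s.qss.iqr[1],
            "n_components": s.n_components,
        }
        for t, s in enumerate(traj.steps, start=1)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "step", "removed_species", "metric_value",
            "median_eigen", "q25", "q75", "n_components",
        ],
    )
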