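"""Data model and I/O for directed food webs with species traits.

A food web is a directed graph whose edges point from resource to
consumer (the direction of energy flow).  Each species carries the
traits the allometric interaction-strength machinery needs: body mass
in grams, a movement-space classification (2D for benthic-style,
3D for pelagic-style movement), a flag marking mass-independent
resources (macroalgae, sponges, necromass, detritus — nodes whose
mass and density do not constrain their consumers), and an optional
empirical population density.

Species iteration order is lexicographic by id everywhere, so every
downstream matrix and table is reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger("trophicweb")

#: Sentinel for traits that are not set (body mass of detritus, etc.).
UNSET = None

MOVEMENT_2D = "2D"
MOVEMENT_3D = "3D"
_VALID_MOVEMENTS = frozenset({MOVEMENT_2D, MOVEMENT_3D})


class FoodWebError(Exception):
    """Base class for food-web construction and parsing errors."""


class ParseError(FoodWebError):
    """A delimited input file could not be parsed."""


class ValidationError(FoodWebError):
    """The constructed web violates a structural invariant."""


@dataclass(frozen=True)
class Species:
    """A node of the food web with its trait annotations.

    Parameters
    ----------
    id
        Stable, case-sensitive identifier (whitespace-trimmed).
    name
        Free-text label; defaults to the id.
    body_mass
        Body mass in grams (> 0), or ``None`` when unknown.  Every
        species that appears as a consumer must have a body mass.
    movement
        ``"2D"`` (benthic-style) or ``"3D"`` (pelagic-style).
    is_mass_independent
        True for resources whose mass/density are independent from the
        consumer (macroalgae, sponges, necromass, detritus); these may
        have unset body mass.
    empirical_density
        Observed density (individuals per unit area or volume, > 0), or
        ``None`` to fall back to the allometric density scaling.
    """

    id: str
    name: str = ""
    body_mass: float | None = UNSET
    movement: str = MOVEMENT_2D
    is_mass_independent: bool = False
    empirical_density: float | None = UNSET

    def __post_init__(self) -> None:
        object.__setattr__(self, "id", self.id.strip())
        if not self.id:
            raise ValidationError("species id must be non-empty")
        if not self.name:
            object.__setattr__(self, "name", self.id)
        if self.movement not in _VALID_MOVEMENTS:
            raise ValidationError(
                f"species {self.id!r}: movement must be one of "
                f"{sorted(_VALID_MOVEMENTS)}, got {self.movement!r}"
            )
        if self.body_mass is not None and not self.body_mass > 0:
            raise ValidationError(
                f"species {self.id!r}: body_mass must be > 0, got {self.body_mass}"
            )
        if self.empirical_density is not None and not self.empirical_density > 0:
            raise ValidationError(
                f"species {self.id!r}: empirical_density must be > 0, "
                f"got {self.empirical_density}"
            )


@dataclass(frozen=True, order=True)
class TrophicLink:
    """A directed feeding link from resource to consumer."""

    resource_id: str
    consumer_id: str

    @property
    def is_self_link(self) -> bool:
        return self.resource_id == self.consumer_id


class FoodWeb:
    """A directed food web: species plus resource→consumer links.

    Construction validates referential integrity (every link endpoint
    must name a known species) and link uniqueness.  Self-links
    (cannibalism) are accepted on input; stability analyses zero the
    Jacobian diagonal so they never act as self-regulation.
    """

    def __init__(self, species: Iterable[Species], links: Iterable[TrophicLink]):
        self._species: dict[str, Species] = {}
        for sp in species:
            if sp.id in self._species:
                raise ValidationError(f"duplicate species id {sp.id!r}")
            self._species[sp.id] = sp
        seen: set[TrophicLink] = set()
        dups: list[TrophicLink] = []
        for link in links:
            if link in seen:
                dups.append(link)
            seen.add(link)
        if dups:
            raise ValidationError(
                "duplicate links: "
                + ", ".join(f"{l.resource_id}->{l.consumer_id}" for l in sorted(dups))
            )
        for link in seen:
            for endpoint in (link.resource_id, link.consumer_id):
                if endpoint not in self._species:
                    raise ValidationError(
                        f"link {link.resource_id}->{link.consumer_id} references "
                        f"unknown species {endpoint!r}"
                    )
        self._links: tuple[TrophicLink, ...] = tuple(sorted(seen))

    # -- basic accessors -------------------------------------------------

    @property
    def species_ids(self) -> tuple[str, ...]:
        """Species ids in lexicographic order."""
        return tuple(sorted(self._species))

    @property
    def links(self) -> tuple[TrophicLink, ...]:
        """Links in lexicographic (resource, consumer) order."""
        return self._links

    @property
    def n_species(self) -> int:
        return len(self._species)

    @property
    def n_links(self) -> int:
        return len(self._links)

    @property
    def connectance(self) -> float:
        """Directed connectance L / S^2."""
        if self.n_species == 0:
            return 0.0
        return self.n_links / self.n_species**2

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._species

    def __iter__(self) -> Iterator[Species]:
        for sid in self.species_ids:
            yield self._species[sid]

    def species(self, species_id: str) -> Species:
        try:
            return self._species[species_id]
        except KeyError:
            raise KeyError(f"unknown species {species_id!r}") from None

    def prey_of(self, species_id: str) -> tuple[str, ...]:
        """Resources consumed by ``species_id`` (self-links excluded)."""
        self.species(species_id)
        return tuple(
            sorted(
                l.resource_id
                for l in self._links
                if l.consumer_id == species_id and not l.is_self_link
            )
        )

    def predators_of(self, species_id: str) -> tuple[str, ...]:
        """Consumers feeding on ``species_id`` (self-links excluded)."""
        self.species(species_id)
        return tuple(
            sorted(
                l.consumer_id
                for l in self._links
                if l.resource_id == species_id and not l.is_self_link
            )
        )

    def basal_species(self) -> tuple[str, ...]:
        """Species with no prey (primary producers / dead resources)."""
        return tuple(s for s in self.species_ids if not self.prey_of(s))

    def remove_species(self, species_id: str) -> "FoodWeb":
        """Return a new web without ``species_id`` and its links."""
        if species_id not in self._species:
            raise KeyError(f"species {species_id!r} already absent")
        return FoodWeb(
            (sp for sp in self._species.values() if sp.id != species_id),
            (
                l
                for l in self._links
                if species_id not in (l.resource_id, l.consumer_id)
            ),
        )

    def to_digraph(self) -> nx.DiGraph:
        """Directed networkx view (resource → consumer), nodes sorted."""
        g = nx.DiGraph()
        g.add_nodes_from(self.species_ids)
        g.add_edges_from((l.resource_id, l.consumer_id) for l in self._links)
        return g

    def to_undirected(self) -> nx.Graph:
        """Undirected projection with self-loops dropped."""
        g = nx.Graph()
        g.add_nodes_from(self.species_ids)
        g.add_edges_from(
            (l.resource_id, l.consumer_id)
            for l in self._links
            if not l.is_self_link
        )
        return g

    def with_species(self, species: Species) -> "FoodWeb":
        """Return a new web with one species' traits replaced."""
        self.species(species.id)
        return FoodWeb(
            (species if sp.id == species.id else sp for sp in self._species.values()),
            self._links,
        )


@dataclass
class ValidationReport:
    """Report-only summary of structural issues in a web."""

    n_species: int
    n_links: int
    connectance: float
    consumers_without_mass: list[str] = field(default_factory=list)
    isolated_species: list[str] = field(default_factory=list)
    self_links: list[str] = field(default_factory=list)

    @property
    def issues(self) -> list[str]:
        out = []
        out += [f"consumer without body mass: {s}" for s in self.consumers_without_mass]
        out += [f"isolated species: {s}" for s in self.isolated_species]
        out += [f"self-link: {s}" for s in self.self_links]
        return out

    @property
    def ok(self) -> bool:
        return not self.consumers_without_mass


def validate_foodweb(web: FoodWeb) -> ValidationReport:
    """Check trait completeness and structural oddities.

    Reports consumers lacking a body mass (fatal for interaction-strength
    estimation), isolated species, and self-links, together with the
    summary counts S, L and connectance L/S².
    """
    consumers_without_mass = [
        s
        for s in web.species_ids
        if web.prey_of(s) and web.species(s).body_mass is UNSET
    ]
    isolated = [
        s for s in web.species_ids if not web.prey_of(s) and not web.predators_of(s)
    ]
    self_links = sorted(l.resource_id for l in web.links if l.is_self_link)
    return ValidationReport(
        n_species=web.n_species,
        n_links=web.n_links,
        connectance=web.connectance,
        consumers_without_mass=consumers_without_mass,
        isolated_species=isolated,
        self_links=self_links,
    )


# -- file I/O ------------------------------------------------------------

#: Default column names; override via the ``columns`` mapping of
#: :func:`read_foodweb` when the deposited files use different headers.
DEFAULT_COLUMNS: dict[str, str] = {
    "resource": "resource",
    "consumer": "consumer",
    "species": "species",
    "body_mass": "body_mass_g",
    "movement": "movement",
    "is_mass_independent": "is_mass_independent",
    "empirical_density": "empirical_density",
}

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}


def _parse_bool(value: object, path: Path, line: int) -> bool:
    text = str(value).strip().lower()
    if text in ("nan", "none"):
        return False
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ParseError(f"{path}:{line}: cannot interpret {value!r} as boolean")


def _parse_optional_float(value: object, path: Path, line: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return UNSET
    text = str(value).strip()
    if text == "" or text.lower() in ("nan", "na", "none"):
        return UNSET
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"{path}:{line}: column {column!r}: cannot parse {value!r} as number"
        ) from None


def read_foodweb(
    edge_list_path: str | Path,
    trait_table_path: str | Path | None = None,
    *,
    delimiter: str = ",",
    columns: Mapping[str, str] | None = None,
) -> FoodWeb:
    """Read a food web from an edge-list CSV and an optional trait table.

    The edge list needs ``resource`` and ``consumer`` columns; the trait
    table is keyed by ``species`` with optional ``body_mass_g``,
    ``movement``, ``is_mass_independent`` and ``empirical_density``
    columns (names remappable through ``columns``).  Species that appear
    in the edge list but not in the trait table are created with unset
    traits and reported via a warning.  Unknown trait columns are ignored.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    edge_list_path = Path(edge_list_path)

    try:
        edges = pd.read_csv(edge_list_path, sep=delimiter, dtype=str, comment="#")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{edge_list_path}: {exc}") from exc
    for required in (cols["resource"], cols["consumer"]):
        if required not in edges.columns:
            raise ParseError(
                f"{edge_list_path}: missing required column {required!r} "
                f"(found {list(edges.columns)})"
            )

    links: list[TrophicLink] = []
    for row_idx in edges.index:
        line = row_idx + 2  # header is line 1
        resource = edges.at[row_idx, cols["resource"]]
        consumer = edges.at[row_idx, cols["consumer"]]
        if pd.isna(resource) or pd.isna(consumer):
            raise ParseError(f"{edge_list_path}:{line}: empty resource or consumer")
        links.append(TrophicLink(str(resource).strip(), str(consumer).strip()))

    traits: dict[str, Species] = {}
    if trait_table_path is not None:
        trait_table_path = Path(trait_table_path)
        try:
            tt = pd.read_csv(trait_table_path, sep=delimiter, dtype=str, comment="#")
        except pd.errors.ParserError as exc:
            raise ParseError(f"{trait_table_path}: {exc}") from exc
        if cols["species"] not in tt.columns:
            raise ParseError(
                f"{trait_table_path}: missing key column {cols['species']!r}"
            )
        for row_idx in tt.index:
            line = row_idx + 2
            sid = str(tt.at[row_idx, cols["species"]]).strip()
            kwargs: dict[str, object] = {}
            if cols["body_mass"] in tt.columns:
                kwargs["body_mass"] = _parse_optional_float(
                    tt.at[row_idx, cols["body_mass"]], trait_table_path, line,
                    cols["body_mass"],
                )
            if cols["movement"] in tt.columns:
                movement = tt.at[row_idx, cols["movement"]]
                if not pd.isna(movement) and str(movement).strip():
                    kwargs["movement"] = str(movement).strip().upper()
            if cols["is_mass_independent"] in tt.columns:
                kwargs["is_mass_independent"] = _parse_bool(
                    tt.at[row_idx, cols["is_mass_independent"]], trait_table_path, line
                )
            if cols["empirical_density"] in tt.columns:
                kwargs["empirical_density"] = _parse_optional_float(
                    tt.at[row_idx, cols["empirical_density"]], trait_table_path, line,
                    cols["empirical_density"],
                )
            if sid in traits:
                raise ParseError(
                    f"{trait_table_path}:{line}: duplicate trait row for {sid!r}"
                )
            traits[sid] = Species(id=sid, **kwargs)  # type: ignore[arg-type]

    edge_species = {l.resource_id for l in links} | {l.consumer_id for l in links}
    missing = sorted(edge_species - set(traits))
    if missing and trait_table_path is not None:
        warnings.warn(
            f"{len(missing)} species present in edges but missing from traits "
            f"(created with unset traits): {', '.join(missing[:10])}"
            + ("..." if len(missing) > 10 else ""),
            stacklevel=2,
        )
    for sid in missing:
        traits[sid] = Species(id=sid)

    if not links:
        warnings.warn(f"{edge_list_path}: empty edge list", stacklevel=2)

    return FoodWeb(traits.values(), links)


def write_foodweb(web: FoodWeb, edge_list_path: str | Path,
                  trait_table_path: str | Path, *, delimiter: str = ",") -> None:
    """Write a web back to the edge-list / trait-table CSV dialect."""
    pd.DataFrame(
        [(l.resource_id, l.consumer_id) for l in web.links],
        columns=["resource", "consumer"],
    ).to_csv(edge_list_path, sep=delimiter, index=False)
    rows = []
    for sp in web:
        rows.append(
            {
                "species": sp.id,
                "body_mass_g": "" if sp.body_mass is UNSET else repr(sp.body_mass),
                "movement": sp.movement,
                "is_mass_independent": str(sp.is_mass_independent).lower(),
                "empirical_density": (
                    "" if sp.empirical_density is UNSET else repr(sp.empirical_density)
                ),
            }
        )
    pd.DataFrame(rows).to_csv(trait_table_path, sep=delimiter, index=False)


def write_results(
    tables: Mapping[str, pd.DataFrame], out_dir: str | Path, *, delimiter: str = ","
) -> list[Path]:
    """Write named result tables as delimited text files with headers.

    Floats are rendered with ``repr`` so that a read-back round-trips to
    the identical values.  Returns the paths written, sorted by name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(tables):
        path = out_dir / f"{name}.csv"
        try:
            tables[name].to_csv(
                path, sep=delimiter, index=False, float_format=None
            )
        except OSError as exc:
            raise FoodWebError(f"failed to write {path}: {exc}") from exc
        written.append(path)
    return written


def read_results(out_dir: str | Path, *, delimiter: str = ",") -> dict[str, pd.DataFrame]:
    """Read back every table written by :func:`write_results`."""
    out_dir = Path(out_dir)
    return {
        p.stem: pd.read_csv(p, sep=delimiter) for p in sorted(out_dir.glob("*.csv"))
    }


def to_graphml(web: FoodWeb, path: str | Path,
               link_weights: Mapping[TrophicLink, float] | None = None) -> None:
    """Export the (optionally weighted) web as GraphML."""
    g = web.to_digraph()
    for sp in web:
        node = g.nodes[sp.id]
        node["name"] = sp.name
        node["movement"] = sp.movement
        node["is_mass_independent"] = sp.is_mass_independent
        if sp.body_mass is not UNSET:
            node["body_mass_g"] = float(sp.body_mass)
    if link_weights is not None:
        for link, w in link_weights.items():
            g.edges[link.resource_id, link.consumer_id]["weight"] = float(w)
    nx.write_graphml(g, path)
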