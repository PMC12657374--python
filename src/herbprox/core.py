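"""Core data model: interactome graph, entity catalog, target sets.

The interactome is an undirected, unweighted protein-protein interaction
network; every proximity metric in this package is a function of shortest
path lengths (hop counts) on this graph.  Entities live in a four-layer
catalog (formula -> herb -> ingredient -> target, plus disease -> target);
an entity's *target set* is its annotated proteins restricted to the
interactome's nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractomeGraph",
    "EntityCatalog",
    "TargetSet",
    "load_interactome",
    "load_catalog",
    "target_set",
    "herb_target_union",
]


class CatalogError(ValueError):
    """Raised for malformed or empty catalog/interactome inputs."""


@dataclass
class InteractomeGraph:
    """Undirected deduplicated protein network.

    Parameters
    ----------
    graph
        The underlying :class:`networkx.Graph`; no self-loops, edges stored
        once regardless of input orientation.
    lcc_flag
        True when the graph was restricted to its largest connected
        component, in which case all pairwise distances are finite.
    n_dropped_nodes
        Nodes discarded by the LCC restriction.
    """

    graph: nx.Graph
    lcc_flag: bool = False
    n_dropped_nodes: int = 0

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> list[tuple[str, str]]:
        """Canonical sorted edge list (each edge once, endpoints sorted)."""
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


@dataclass
class EntityCatalog:
    """Identifier sets plus the four deduplicated association tables."""

    formula_ids: set[str] = field(default_factory=set)
    herb_ids: set[str] = field(default_factory=set)
    ingredient_ids: set[str] = field(default_factory=set)
    disease_ids: set[str] = field(default_factory=set)
    formula_herb: list[tuple[str, str]] = field(default_factory=list)
    herb_ingredient: list[tuple[str, str]] = field(default_factory=list)
    ingredient_target: list[tuple[str, str]] = field(default_factory=list)
    disease_target: list[tuple[str, str]] = field(default_factory=list)

    def herbs_of_formula(self, formula_id: str) -> list[str]:
        return sorted({h for f, h in self.formula_herb if f == formula_id})

    def ingredients_of_herb(self, herb_id: str) -> list[str]:
        return sorted({i for h, i in self.herb_ingredient if h == herb_id})

    def ingredients_of_formula(self, formula_id: str) -> list[str]:
        out: set[str] = set()
        for herb in self.herbs_of_formula(formula_id):
            out.update(self.ingredients_of_herb(herb))
        return sorted(out)

    def targets_of_ingredient(self, ingredient_id: str) -> set[str]:
        return {t for i, t in self.ingredient_target if i == ingredient_id}

    def targets_of_disease(self, disease_id: str) -> set[str]:
        return {t for d, t in self.disease_target if d == disease_id}

    def formulas_of_herb(self, herb_id: str) -> list[str]:
        return sorted({f for f, h in self.formula_herb if h == herb_id})


@dataclass(frozen=True)
class TargetSet:
    """An entity's annotated proteins mapped onto the interactome.

    ``proteins`` is always a nonempty subset of the graph's nodes;
    ``n_dropped`` counts annotated targets absent from the interactome.
    """

    entity_id: str
    entity_level: str  # ingredient | herb | disease
    proteins: frozenset[str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not self.proteins:
            raise CatalogError(
                f"no mappable targets for {self.entity_level} {self.entity_id!r}"
            )
        if self.entity_level not in {"ingredient", "herb", "disease"}:
            raise CatalogError(f"unknown entity level {self.entity_level!r}")

    def __len__(self) -> int:
        return len(self.proteins)


def load_interactome(
    edge_table: Iterable[Sequence[str]], restrict_lcc: bool = True
) -> InteractomeGraph:
    """Build an :class:`InteractomeGraph` from a two-column record stream.

    Self-loops in the input are tolerated and dropped; reversed duplicates
    collapse to one undirected edge.  With ``restrict_lcc`` (the default)
    only the largest connected component is kept, so that every shortest
    path is finite; ties between equally large components go to the one
    containing the lexicographically smallest node.
    """
    g = nx.Graph()
    n_self_loops = 0
    n_rows = 0
    for lineno, row in enumerate(edge_table, start=1):
        if len(row) != 2:
            raise CatalogError(f"interactome row {lineno}: expected 2 columns, got {len(row)}")
        a, b = str(row[0]).strip(), str(row[1]).strip()
        if not a or not b:
            raise CatalogError(f"interactome row {lineno}: empty protein ID")
        n_rows += 1
        if a == b:
            n_self_loops += 1
            continue
        g.add_edge(a, b)
    if n_rows == 0:
        raise CatalogError("empty interactome edge table")
    if n_self_loops:
        logger.info("dropped %d self-loop rows", n_self_loops)

    n_dropped = 0
    lcc = False
    if restrict_lcc and g.number_of_nodes() > 0:
        components = list(nx.connected_components(g))
        largest = max(len(c) for c in components)
        # ties go to the component holding the lexicographically smallest node
        best = min((c for c in components if len(c) == largest), key=min)
        n_dropped = g.number_of_nodes() - len(best)
        if n_dropped:
            logger.info("LCC restriction dropped %d nodes", n_dropped)
        g = g.subgraph(best).copy()
        lcc = True
    return InteractomeGraph(graph=g, lcc_flag=lcc, n_dropped_nodes=n_dropped)


def _dedup_pairs(rows: Iterable[Sequence[str]], table: str) -> list[tuple[str, str]]:
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    for lineno, row in enumerate(rows, start=1):
        if len(row) != 2:
            raise CatalogError(f"{table} row {lineno}: expected 2 columns, got {len(row)}")
        a, b = str(row[0]).strip(), str(row[1]).strip()
        if not a or not b:
            raise CatalogError(f"{table} row {lineno}: empty ID")
        if (a, b) not in seen:
            seen.add((a, b))
            out.append((a, b))
    return out


def load_catalog(
    formula_herb: Iterable[Sequence[str]] = (),
    herb_ingredient: Iterable[Sequence[str]] = (),
    ingredient_target: Iterable[Sequence[str]] = (),
    disease_target: Iterable[Sequence[str]] = (),
) -> EntityCatalog:
    """Assemble a deduplicated :class:`EntityCatalog` from four pair streams.

    ID sets are the unions of identifiers observed in each column.  An empty
    ingredient-target table is an error: no proximity is computable without
    at least one annotated ingredient.
    """
    fh = _dedup_pairs(formula_herb, "formula_herb")
    hi = _dedup_pairs(herb_ingredient, "herb_ingredient")
    it = _dedup_pairs(ingredient_target, "ingredient_target")
    dt = _dedup_pairs(disease_target, "disease_target")
    if not it:
        raise CatalogError("empty ingredient_target table: no proximity computable")
    return EntityCatalog(
        formula_ids={f for f, _ in fh},
        herb_ids={h for _, h in fh} | {h for h, _ in hi},
        ingredient_ids={i for _, i in hi} | {i for i, _ in it},
        disease_ids={d for d, _ in dt},
        formula_herb=fh,
        herb_ingredient=hi,
        ingredient_target=it,
        disease_target=dt,
    )


def target_set(
    entity_id: str,
    level: str,
    catalog: EntityCatalog,
    graph: InteractomeGraph,
) -> TargetSet:
    """Map an entity's annotated targets onto the interactome.

    Off-graph targets are dropped (counted in ``n_dropped``); an entity
    whose every target is off-graph raises, since its distances are
    undefined.  ``level='herb'`` delegates to :func:`herb_target_union`.
    """
    if level == "herb":
        return herb_target_union(entity_id, catalog, graph)
    if level == "ingredient":
        if entity_id not in catalog.ingredient_ids:
            raise CatalogError(f"unknown ingredient {entity_id!r}")
        annotated = catalog.targets_of_ingredient(entity_id)
    elif level == "disease":
        if entity_id not in catalog.disease_ids:
            raise CatalogError(f"unknown disease {entity_id!r}")
        annotated = catalog.targets_of_disease(entity_id)
    else:
        raise CatalogError(f"unknown entity level {level!r}")
    mapped = annotated & graph.nodes
    n_dropped = len(annotated) - len(mapped)
    if n_dropped:
        logger.debug("%s %s: %d targets off-graph", level, entity_id, n_dropped)
    if not mapped:
        raise CatalogError(f"no mappable targets for {level} {entity_id!r}")
    return TargetSet(entity_id, level, frozenset(mapped), n_dropped)


def herb_target_union(
    herb_id: str, catalog: EntityCatalog, graph: InteractomeGraph
) -> TargetSet:
    """Union of the herb's ingredients' mapped target sets (T_H)."""
    if herb_id not in catalog.herb_ids:
        raise CatalogError(f"unknown herb {herb_id!r}")
    proteins: set[str] = set()
    n_dropped = 0
    any_ok = False
    for ing in catalog.ingredients_of_herb(herb_id):
        try:
            ts = target_set(ing, "ingredient", catalog, graph)
        except CatalogError:
            continue
        any_ok = True
        proteins.update(ts.proteins)
        n_dropped += ts.n_dropped
    if not any_ok or not proteins:
        raise CatalogError(f"herb {herb_id!r} has no ingredient with mappable targets")
    return TargetSet(herb_id, "herb", frozenset(proteins), n_dropped)
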