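"""Combination analysis: in-formula synergy scans, the five combination
recommendation patterns, landscape graphs, community detection, and ADMET
filtering.

A *combination landscape* is the typed, scored network a recommendation
query returns: herb/ingredient/disease nodes joined by proximity edges
(distance, Z, p, significance flag).  Turning the landscape into a weighted
graph (edge weight exp(-distance)) and running Louvain community detection
yields candidate synergy modules; the module containing the disease node
collects the ingredients most likely to act together on it.  An ADMET
property table can then filter the surviving candidates on
absorption/bioavailability/toxicity criteria.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .core import CatalogError, EntityCatalog, InteractomeGraph, target_set
from .proximity import DistanceEngine, _engine, center_distance
from .significance import NullModel, z_test

logger = logging.getLogger(__name__)

__all__ = [
    "LandscapeEdge",
    "CombinationLandscape",
    "AdmetTable",
    "FilterSpec",
    "PATTERNS",
    "formula_synergy_scan",
    "recommend",
    "build_combination_graph",
    "detect_modules",
    "disease_module_members",
    "admet_filter",
    "build_disease_landscape",
]

PATTERNS = (
    "herb+herb",
    "ingredient+ingredient",
    "herb+herb+disease",
    "ingredient+ingredient+disease",
    "prescription+prescription+disease",
)


@dataclass(frozen=True)
class LandscapeEdge:
    source: str
    target: str
    relation: str  # ing-ing | herb-herb | ing-disease | herb-disease
    distance: float
    z: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class CombinationLandscape:
    """Scored multi-entity network returned by a recommendation query."""

    nodes: dict[str, str]  # node id -> level (ingredient | herb | disease)
    edges: list[LandscapeEdge] = field(default_factory=list)
    query: dict = field(default_factory=dict)

    def add_edge(self, edge: LandscapeEdge) -> None:
        for endpoint in (edge.source, edge.target):
            if endpoint not in self.nodes:
                raise ValueError(f"edge endpoint {endpoint!r} not a landscape node")
        if not math.isfinite(edge.distance):
            raise ValueError("landscape edges must carry finite distances")
        self.edges.append(edge)

    def to_node_link(self) -> dict:
        return {
            "query": self.query,
            "nodes": [{"id": n, "level": lv} for n, lv in sorted(self.nodes.items())],
            "links": [
                {
                    "source": e.source,
                    "target": e.target,
                    "relation": e.relation,
                    "distance": round(e.distance, 6),
                    "z": round(e.z, 6),
                    "p": float(f"{e.p:.4g}"),
                    "significant": e.significant,
                }
                for e in self.edges
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_node_link(), sort_keys=True)

    @classmethod
    def from_node_link(cls, d: dict) -> "CombinationLandscape":
        ls = cls(nodes={n["id"]: n["level"] for n in d["nodes"]}, query=d.get("query", {}))
        for link in d["links"]:
            ls.add_edge(LandscapeEdge(link["source"], link["target"], link["relation"],
                                      link["distance"], link["z"], link["p"]))
        return ls

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"source": e.source, "target": e.target, "relation": e.relation,
                 "distance": e.distance, "z": e.z, "p": e.p, "significant": e.significant}
                for e in self.edges
            ],
            columns=["source", "target", "relation", "distance", "z", "p", "significant"],
        )


def _usable_ingredients(
    ingredient_ids: Iterable[str], catalog: EntityCatalog, eng: DistanceEngine
) -> dict[str, frozenset[str]]:
    out = {}
    for ing in sorted(set(ingredient_ids)):
        try:
            out[ing] = target_set(ing, "ingredient", catalog, eng.interactome).proteins
        except CatalogError:
            logger.info("ingredient %s skipped: no mappable targets", ing)
    return out


def formula_synergy_scan(
    formula_id: str,
    catalog: EntityCatalog,
    graph: InteractomeGraph | DistanceEngine,
    null: NullModel,
    alpha: float = 0.05,
) -> list[LandscapeEdge]:
    """Scan every unordered in-formula ingredient pair with the closest
    distance and flag the significant ones.

    Each of the formula's C(k,2) usable ingredient pairs is scored with the
    closest distance and Z-tested against the supplied null (random-pair by
    default upstream); pairs with p < alpha are returned sorted ascending by
    distance.
    """
    eng = _engine(graph)
    if formula_id not in catalog.formula_ids:
        raise CatalogError(f"unknown formula {formula_id!r}")
    sets = _usable_ingredients(catalog.ingredients_of_formula(formula_id), catalog, eng)
    if len(sets) < 2:
        raise CatalogError(f"formula {formula_id!r} has <2 ingredients with mappable targets")
    hits = []
    for a, b in combinations(sorted(sets), 2):
        d = eng.closest(sets[a], sets[b])
        res = z_test(d, null)
        if res.p < alpha:
            hits.append(LandscapeEdge(a, b, "ing-ing", d, res.z, res.p))
    hits.sort(key=lambda e: (e.distance, e.source, e.target))
    return hits


def _score_edge(
    eng: DistanceEngine,
    catalog: EntityCatalog,
    a: str,
    b: str,
    relation: str,
    null: NullModel,
) -> LandscapeEdge:
    if relation == "ing-ing":
        ta = target_set(a, "ingredient", catalog, eng.interactome).proteins
        tb = target_set(b, "ingredient", catalog, eng.interactome).proteins
        d = eng.closest(ta, tb)
    elif relation == "herb-herb":
        d = center_distance(a, b, catalog, eng).value
    elif relation in {"ing-disease", "herb-disease"}:
        level = "ingredient" if relation == "ing-disease" else "herb"
        tx = target_set(a, level, catalog, eng.interactome).proteins
        ty = target_set(b, "disease", catalog, eng.interactome).proteins
        d = eng.directed(tx, ty)
    else:
        raise ValueError(f"unknown relation {relation!r}")
    res = z_test(d, null)
    return LandscapeEdge(a, b, relation, d, res.z, res.p)


def recommend(
    pattern: str,
    inputs: Sequence[str],
    catalog: EntityCatalog,
    graph: InteractomeGraph | DistanceEngine,
    nulls: Mapping[str, NullModel],
    include_within: bool = False,
) -> CombinationLandscape:
    """Run one of the five combination-recommendation patterns.

    ``inputs`` matches the pattern's arity, e.g. ``("I1","I2","D1")`` for
    ``ingredient+ingredient+disease``.  ``nulls`` maps relation names
    (``ing-ing``, ``herb-herb``, ``ing-disease``, ``herb-disease``) to the
    null models used for their Z-tests; only the relations the pattern
    produces are required.  Prescription patterns expand each prescription
    (formula) to its herbs and ingredients and score all cross-prescription
    herb-herb and ingredient-ingredient pairs (within-prescription pairs
    too when ``include_within``), plus every entity-disease edge.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; expected one of {PATTERNS}")
    eng = _engine(graph)
    parts = pattern.split("+")
    if len(inputs) != len(parts):
        raise ValueError(f"pattern {pattern} expects {len(parts)} inputs, got {len(inputs)}")

    ls = CombinationLandscape(nodes={}, query={"pattern": pattern, "inputs": list(inputs)})

    def need_null(rel: str) -> NullModel:
        if rel not in nulls:
            raise ValueError(f"pattern {pattern} needs a null model for relation {rel!r}")
        return nulls[rel]

    if parts[:2] in (["herb", "herb"], ["ingredient", "ingredient"]):
        level = parts[0]
        a, b = inputs[0], inputs[1]
        rel = "ing-ing" if level == "ingredient" else "herb-herb"
        ls.nodes[a] = level
        ls.nodes[b] = level
        ls.add_edge(_score_edge(eng, catalog, a, b, rel, need_null(rel)))
        if len(parts) == 3:  # +disease
            disease = inputs[2]
            ls.nodes[disease] = "disease"
            drel = "ing-disease" if level == "ingredient" else "herb-disease"
            for ent in (a, b):
                ls.add_edge(_score_edge(eng, catalog, ent, disease, drel, need_null(drel)))
            if level == "herb":
                # constituent ingredients also scored against the disease
                for herb in (a, b):
                    for ing in _usable_ingredients(
                        catalog.ingredients_of_herb(herb), catalog, eng
                    ):
                        if ing not in ls.nodes:
                            ls.nodes[ing] = "ingredient"
                            ls.add_edge(_score_edge(eng, catalog, ing, disease,
                                                    "ing-disease", need_null("ing-disease")))
        return ls

    # prescription+prescription+disease
    pa, pb, disease = inputs
    for f in (pa, pb):
        if f not in catalog.formula_ids:
            raise CatalogError(f"unknown prescription/formula {f!r}")
    ls.nodes[disease] = "disease"
    herbs = {f: catalog.herbs_of_formula(f) for f in (pa, pb)}
    ings = {f: sorted(_usable_ingredients(catalog.ingredients_of_formula(f), catalog, eng))
            for f in (pa, pb)}
    for f in (pa, pb):
        for h in herbs[f]:
            ls.nodes.setdefault(h, "herb")
        for i in ings[f]:
            ls.nodes.setdefault(i, "ingredient")

    hh_null, ii_null = need_null("herb-herb"), need_null("ing-ing")
    hd_null, id_null = need_null("herb-disease"), need_null("ing-disease")

    def herb_pairs():
        yield from product(herbs[pa], herbs[pb])
        if include_within:
            for f in (pa, pb):
                yield from combinations(herbs[f], 2)

    def ing_pairs():
        yield from product(ings[pa], ings[pb])
        if include_within:
            for f in (pa, pb):
                yield from combinations(ings[f], 2)

    seen: set[tuple[str, str, str]] = set()
    for a, b in herb_pairs():
        if a == b:
            continue
        key = ("herb-herb", *sorted((a, b)))
        if key in seen:
            continue
        seen.add(key)
        try:
            ls.add_edge(_score_edge(eng, catalog, a, b, "herb-herb", hh_null))
        except CatalogError as err:
            logger.info("herb pair (%s,%s) skipped: %s", a, b, err)
    for a, b in ing_pairs():
        if a == b:
            continue
        key = ("ing-ing", *sorted((a, b)))
        if key in seen:
            continue
        seen.add(key)
        ta = target_set(a, "ingredient", catalog, eng.interactome).proteins
        tb = target_set(b, "ingredient", catalog, eng.interactome).proteins
        d = eng.closest(ta, tb)
        res = z_test(d, ii_null)
        ls.add_edge(LandscapeEdge(a, b, "ing-ing", d, res.z, res.p))
    for f in (pa, pb):
        for h in herbs[f]:
            try:
                ls.add_edge(_score_edge(eng, catalog, h, disease, "herb-disease", hd_null))
            except CatalogError:
                pass
        for i in ings[f]:
            ls.add_edge(_score_edge(eng, catalog, i, disease, "ing-disease", id_null))
    return ls


def build_combination_graph(
    landscape: CombinationLandscape,
    significant_only: bool = True,
    weight_transform=None,
) -> nx.Graph:
    """Weighted undirected graph over the landscape.

    Edge weight defaults to exp(-distance) — monotone decreasing and finite
    at distance 0, where shared-target pairs sit.  With ``significant_only``
    (default) only p < 0.05 edges survive.
    """
    if not landscape.edges:
        raise ValueError("empty landscape")
    wt = weight_transform or (lambda d: math.exp(-d))
    g = nx.Graph()
    for node in sorted(landscape.nodes):
        g.add_node(node, level=landscape.nodes[node])
    kept = 0
    for e in landscape.edges:
        if significant_only and not e.significant:
            continue
        g.add_edge(e.source, e.target, weight=wt(e.distance),
                   distance=e.distance, relation=e.relation)
        kept += 1
    if kept == 0:
        raise ValueError("no surviving edges after significance filter")
    return g


def detect_modules(
    graph: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> dict[str, int]:
    """Louvain modularity-maximizing partition of a weighted graph.

    Deterministic given the seed; community labels are renumbered so that
    communities appear in order of their lexicographically smallest member.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comms = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    return {node: label for label, members in enumerate(comms) for node in members}


def disease_module_members(labels: Mapping[str, int], disease_node: str) -> list[str]:
    """All non-disease nodes sharing the disease node's community, sorted."""
    if disease_node not in labels:
        raise ValueError(f"disease node {disease_node!r} not in labelling")
    target_label = labels[disease_node]
    return sorted(n for n, lab in labels.items()
                  if lab == target_label and n != disease_node)


@dataclass
class AdmetTable:
    """Per-ingredient ADMET properties: categorical '+'/'-' or numeric."""

    rows: pd.DataFrame  # index: ingredient_id; columns: property names

    def __post_init__(self) -> None:
        if self.rows.index.has_duplicates:
            raise ValueError("duplicate ingredient rows in ADMET table")

    @property
    def registry(self) -> list[str]:
        return list(self.rows.columns)

    def value(self, ingredient_id: str, prop: str):
        if ingredient_id not in self.rows.index:
            return None
        v = self.rows.at[ingredient_id, prop]
        return None if pd.isna(v) else v


@dataclass(frozen=True)
class FilterSpec:
    """Conjunctive ADMET filter: a list of (property, comparator, value)
    with comparator in {eq, ge, le}.  Parsed from one-conjunct-per-line
    text such as ``HIA eq +`` / ``OB ge 30``."""

    conjuncts: tuple[tuple[str, str, str], ...]

    @classmethod
    def parse(cls, text: str) -> "FilterSpec":
        conj = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3 or parts[1] not in {"eq", "ge", "le"}:
                raise ValueError(f"filter line {lineno}: expected 'PROP eq|ge|le VALUE'")
            conj.append((parts[0], parts[1], parts[2]))
        return cls(conjuncts=tuple(conj))

    def validate(self, table: AdmetTable) -> None:
        for prop, _, _ in self.conjuncts:
            if prop not in table.registry:
                raise ValueError(f"unknown ADMET property {prop!r}")


def _satisfies(value, comparator: str, ref: str) -> bool:
    if comparator == "eq":
        return str(value) == ref
    x, r = float(value), float(ref)
    return x >= r if comparator == "ge" else x <= r


def admet_filter(
    table: AdmetTable, spec: FilterSpec, candidate_ids: Iterable[str]
) -> list[str]:
    """IDs satisfying every conjunct; candidates missing any referenced
    property are excluded (and logged), never silently passed."""
    spec.validate(table)
    survivors = []
    for cid in sorted(set(candidate_ids)):
        ok = True
        for prop, comp, ref in spec.conjuncts:
            v = table.value(cid, prop)
            if v is None:
                logger.info("ADMET filter: %s missing property %s, excluded", cid, prop)
                ok = False
                break
            if not _satisfies(v, comp, ref):
                ok = False
                break
        if ok:
            survivors.append(cid)
    return survivors


def build_disease_landscape(
    disease_id: str,
    ingredient_ids: Sequence[str],
    catalog: EntityCatalog,
    graph: InteractomeGraph | DistanceEngine,
    ii_null: NullModel,
    id_null: NullModel,
) -> CombinationLandscape:
    """Batch ingredient-ingredient + ingredient-disease landscape.

    Convenience composition used for module analysis of a candidate set:
    scores all C(k,2) ingredient pairs (closest distance) and every
    ingredient-disease edge (directed proximity) against the supplied
    nulls, returning one landscape centred on the disease node.
    """
    eng = _engine(graph)
    sets = _usable_ingredients(ingredient_ids, catalog, eng)
    if not sets:
        raise CatalogError("no usable ingredients")
    ls = CombinationLandscape(
        nodes={disease_id: "disease", **{i: "ingredient" for i in sets}},
        query={"pattern": "disease_landscape", "inputs": [disease_id, *sorted(sets)]},
    )
    ty = target_set(disease_id, "disease", catalog, eng.interactome).proteins
    for a, b in combinations(sorted(sets), 2):
        d = eng.closest(sets[a], sets[b])
        res = z_test(d, ii_null)
        ls.add_edge(LandscapeEdge(a, b, "ing-ing", d, res.z, res.p))
    for i in sorted(sets):
        d = eng.directed(sets[i], ty)
        res = z_test(d, id_null)
        ls.add_edge(LandscapeEdge(i, disease_id, "ing-disease", d, res.z, res.p))
    return ls
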