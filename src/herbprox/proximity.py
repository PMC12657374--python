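"""Network-proximity metrics between target sets on the interactome.

Four metrics are provided, all in unweighted hop counts:

* **closest** (d^C) — symmetric average, over every target in either set, of
  its minimum distance to the other set.  The ingredient-ingredient synergy
  score.
* **shortest** (d^S) — average shortest-path length over all cross-set
  target pairs.  The ingredient-level edge weight used for herb comparisons.
* **center** (d^CC) — d^S between the two herbs' *center* ingredients, a
  center being the ingredient minimizing its summed distance to the herb's
  other ingredients.  The herb-herb score.
* **disease-directed** — average, over the disease's genes, of the minimum
  distance to the drug's targets.  Directed from disease to drug; the
  repositioning score.

Smaller values mean closer target neighbourhoods and hence stronger
putative interaction.  All metrics assume finite shortest paths, which the
default largest-connected-component restriction guarantees.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np

from .core import CatalogError, EntityCatalog, InteractomeGraph, TargetSet, target_set

__all__ = [
    "DistanceValue",
    "DistanceEngine",
    "closest_distance",
    "shortest_distance",
    "center_ingredient",
    "center_distance",
    "disease_proximity",
    "all_pairs_distances",
]


class UnreachableError(ValueError):
    """A required shortest path does not exist (disconnected interactome)."""


@dataclass(frozen=True)
class DistanceValue:
    """A computed proximity value between two entities' target sets."""

    metric: str  # closest | shortest | center | disease_directed
    value: float
    pair: tuple[str, str]

    def __float__(self) -> float:
        return self.value


class DistanceEngine:
    """Shortest-path machinery with per-set multi-source BFS caching.

    Each target set's distance field (distance from every graph node to the
    nearest member of the set) is computed once per set and reused across
    every metric evaluation, so a screen over k entities costs k BFS runs,
    not k^2.
    """

    def __init__(self, interactome: InteractomeGraph):
        self.interactome = interactome
        self._adj = interactome.graph.adj
        self._multi_cache: dict[frozenset[str], dict[str, int]] = {}

    def _bfs(self, sources: frozenset[str]) -> dict[str, int]:
        dist = {s: 0 for s in sorted(sources)}
        q = deque(sorted(sources))
        while q:
            u = q.popleft()
            du = dist[u]
            for v in self._adj[u]:
                if v not in dist:
                    dist[v] = du + 1
                    q.append(v)
        return dist

    def set_field(self, targets: frozenset[str]) -> dict[str, int]:
        """Distance from every reachable node to the nearest set member."""
        field = self._multi_cache.get(targets)
        if field is None:
            field = self._bfs(targets)
            self._multi_cache[targets] = field
        return field

    @lru_cache(maxsize=100_000)
    def node_field(self, node: str) -> dict[str, int]:
        return self._bfs(frozenset({node}))

    def _min_dist(self, node: str, other: frozenset[str]) -> int:
        d = self.set_field(other).get(node)
        if d is None:
            raise UnreachableError(
                f"node {node!r} unreachable from target set; "
                "load the interactome with restrict_lcc=True"
            )
        return d

    def closest(self, a: frozenset[str], b: frozenset[str]) -> float:
        total = sum(self._min_dist(x, b) for x in a)
        total += sum(self._min_dist(y, a) for y in b)
        return total / (len(a) + len(b))

    def shortest(self, a: frozenset[str], b: frozenset[str], norm: str = "product") -> float:
        if norm not in {"product", "sum"}:
            raise ValueError(f"shortest_norm must be 'product' or 'sum', got {norm!r}")
        total = 0
        for x in sorted(a):
            field = self.node_field(x)
            for y in b:
                d = field.get(y)
                if d is None:
                    raise UnreachableError(f"no path between {x!r} and {y!r}")
                total += d
        denom = len(a) * len(b) if norm == "product" else len(a) + len(b)
        return total / denom

    def directed(self, x: frozenset[str], y: frozenset[str]) -> float:
        """Mean over y-members of the distance to the nearest x-member."""
        field = self.set_field(x)
        total = 0
        for g in y:
            d = field.get(g)
            if d is None:
                raise UnreachableError(f"disease gene {g!r} unreachable from drug targets")
            total += d
        return total / len(y)


def _engine(graph: InteractomeGraph | DistanceEngine) -> DistanceEngine:
    return graph if isinstance(graph, DistanceEngine) else DistanceEngine(graph)


def closest_distance(
    a: TargetSet, b: TargetSet, graph: InteractomeGraph | DistanceEngine
) -> DistanceValue:
    """Closest distance d^C: each target's minimum cross-set distance,
    summed over both sets and divided by |A|+|B|.  Symmetric; zero when the
    sets coincide."""
    eng = _engine(graph)
    return DistanceValue("closest", eng.closest(a.proteins, b.proteins), (a.entity_id, b.entity_id))


def shortest_distance(
    a: TargetSet,
    b: TargetSet,
    graph: InteractomeGraph | DistanceEngine,
    norm: str = "product",
) -> DistanceValue:
    """Shortest distance d^S: mean shortest-path length over all |a|x|b|
    cross-set target pairs (``norm='product'``); ``norm='sum'`` divides the
    same sum by |a|+|b| instead."""
    eng = _engine(graph)
    return DistanceValue(
        "shortest", eng.shortest(a.proteins, b.proteins, norm), (a.entity_id, b.entity_id)
    )


def center_ingredient(
    herb_id: str,
    catalog: EntityCatalog,
    graph: InteractomeGraph | DistanceEngine,
    pairwise_distance: Callable[[str, str], float] | None = None,
) -> str:
    """The herb's center ingredient: argmin over its ingredients u of the
    summed distance to the herb's other ingredients.

    The default pairwise distance is d^S between ingredient target sets;
    ties break to the lexicographically smallest ingredient ID.  Ingredients
    without mappable targets are excluded.
    """
    eng = _engine(graph)
    candidates = []
    sets: dict[str, TargetSet] = {}
    for ing in catalog.ingredients_of_herb(herb_id):
        try:
            sets[ing] = target_set(ing, "ingredient", catalog, eng.interactome)
        except CatalogError:
            continue
        candidates.append(ing)
    if not candidates:
        raise CatalogError(f"herb {herb_id!r} has no ingredient with mappable targets")

    if pairwise_distance is None:
        def pairwise_distance(u: str, v: str) -> float:
            return eng.shortest(sets[u].proteins, sets[v].proteins)

    best_id, best_sum = None, None
    for u in sorted(candidates):
        s = sum(pairwise_distance(u, v) for v in candidates if v != u)
        if best_sum is None or s < best_sum:
            best_id, best_sum = u, s
    return best_id


def center_distance(
    herb_a: str,
    herb_b: str,
    catalog: EntityCatalog,
    graph: InteractomeGraph | DistanceEngine,
    norm: str = "product",
) -> DistanceValue:
    """Center distance d^CC: d^S between the two herbs' center ingredients —
    the herb-herb interaction score on the ingredient-ingredient network."""
    eng = _engine(graph)
    ca = center_ingredient(herb_a, catalog, eng)
    cb = center_ingredient(herb_b, catalog, eng)
    ta = target_set(ca, "ingredient", catalog, eng.interactome)
    tb = target_set(cb, "ingredient", catalog, eng.interactome)
    value = eng.shortest(ta.proteins, tb.proteins, norm)
    return DistanceValue("center", value, (herb_a, herb_b))


def disease_proximity(
    x: TargetSet, y: TargetSet, graph: InteractomeGraph | DistanceEngine
) -> DistanceValue:
    """Disease-directed proximity: (1/|Y|) sum over disease genes y of the
    minimum distance to any drug target.  Not symmetric; zero iff the
    disease genes are a subset of the drug targets."""
    eng = _engine(graph)
    return DistanceValue(
        "disease_directed", eng.directed(x.proteins, y.proteins), (x.entity_id, y.entity_id)
    )


def all_pairs_distances(
    sets: Sequence[TargetSet],
    graph: InteractomeGraph | DistanceEngine,
    metric: str = "closest",
) -> np.ndarray:
    """Symmetric matrix of pairwise closest/shortest distances between the
    given target sets, reusing each set's BFS field across rows."""
    if metric not in {"closest", "shortest"}:
        raise ValueError(f"metric must be 'closest' or 'shortest', got {metric!r}")
    if not sets:
        raise ValueError("sets must be nonempty")
    eng = _engine(graph)
    n = len(sets)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        if metric == "shortest" and len(sets[i].proteins) > 1:
            mat[i, i] = eng.shortest(sets[i].proteins, sets[i].proteins)
        for j in range(i + 1, n):
            if metric == "closest":
                v = eng.closest(sets[i].proteins, sets[j].proteins)
            else:
                v = eng.shortest(sets[i].proteins, sets[j].proteins)
            mat[i, j] = mat[j, i] = v
    return mat
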