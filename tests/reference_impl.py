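"""Naive reference implementations of the proximity metrics.

These enumerate full all-pairs shortest-path tables with networkx and apply
the metric definitions literally, with no caching or batching — the
independent oracle the fast implementations are checked against.
"""

from __future__ import annotations

import networkx as nx


def apsp(graph: nx.Graph) -> dict:
    return dict(nx.all_pairs_shortest_path_length(graph))


def naive_closest(graph: nx.Graph, a: set, b: set) -> float:
    d = apsp(graph)
    total = sum(min(d[x][y] for y in b) for x in a)
    total += sum(min(d[x][y] for x in a) for y in b)
    return total / (len(a) + len(b))


def naive_shortest(graph: nx.Graph, a: set, b: set, norm: str = "product") -> float:
    d = apsp(graph)
    total = sum(d[x][y] for x in a for y in b)
    denom = len(a) * len(b) if norm == "product" else len(a) + len(b)
    return total / denom


def naive_disease_proximity(graph: nx.Graph, x: set, y: set) -> float:
    d = apsp(graph)
    return sum(min(d[g][t] for t in x) for g in y) / len(y)


def naive_center(ingredients: list[str], pairwise) -> str:
    """Argmin of summed pairwise distance, ties to smallest ID."""
    best, best_sum = None, None
    for u in sorted(ingredients):
        s = sum(pairwise(u, v) for v in ingredients if v != u)
        if best_sum is None or s < best_sum:
            best, best_sum = u, s
    return best


def modularity(graph: nx.Graph, partition: list[set]) -> float:
    return nx.community.modularity(graph, partition, weight="weight")


def best_partition_bruteforce(graph: nx.Graph) -> list[set]:
    """Exhaustive modularity maximization over all set partitions.

    Only feasible for very small graphs (Bell(8) = 4140 partitions)."""
    nodes = sorted(graph.nodes)

    def partitions(items):
        if not items:
            yield []
            return
        head, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] | {head}] + part[i + 1:]
            yield part + [{head}]

    best, best_q = None, None
    for part in partitions(nodes):
        q = modularity(graph, part)
        if best_q is None or q > best_q:
            best, best_q = part, q
    return best
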