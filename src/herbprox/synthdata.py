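"""Synthetic scenarios: interactomes with a planted disease module and
planted proximal ("synergistic") ingredients.

The generator emulates the shape of a curated herb-ingredient-target-disease
catalog at desk scale so every stage of the pipeline is testable without
external data.  A scenario consists of

* a connected random interactome (Barabasi-Albert by default, capturing the
  heavy-tailed degree distribution of real protein networks);
* a *disease module*: a breadth-first ball of ``disease_module_size`` nodes
  around a seeded centre, used as the disease's gene set — connected by
  construction, so proximity to it is well defined;
* *planted* ingredients, which draw ``round(proximity_bias * targets_per_entity)``
  of their targets from inside the module and the rest uniformly from the
  whole graph, and *background* ingredients drawing all targets uniformly.
  ``proximity_bias`` is the effect size: at 0 planted and background are
  exchangeable, at 1 a planted ingredient's targets sit entirely in the
  module;
* a catalog wrapping the ingredients into herbs and the herbs into
  formulas, with consecutive planted ingredients co-assigned to a shared
  formula so in-formula synergy scans can find the planted pairs;
* ground truth: planted/background ID lists and the planted pair list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .core import EntityCatalog, InteractomeGraph, load_catalog
from .combination import AdmetTable

__all__ = [
    "SyntheticScenario",
    "ScenarioTruth",
    "generate_interactome",
    "generate_scenario",
    "generate_admet_table",
]


@dataclass
class SyntheticScenario:
    """Configuration of one synthetic study scenario.

    Defaults give a 1000-node Barabasi-Albert interactome (m=3), a 30-gene
    disease module, 20 planted vs 80 background ingredients with 8 targets
    each and proximity bias 0.8 — small enough that a full screen runs in
    seconds, large enough that planted signal is unambiguous.
    """

    graph_model: str = "barabasi_albert"
    graph_params: dict = field(default_factory=lambda: {"n": 1000, "m": 3})
    disease_module_size: int = 30
    n_planted_entities: int = 20
    n_background_entities: int = 80
    targets_per_entity: int = 8
    proximity_bias: float = 0.8
    ingredients_per_herb: int = 4
    herbs_per_formula: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.proximity_bias <= 1.0:
            raise ValueError("proximity_bias must be in [0, 1]")


@dataclass
class ScenarioTruth:
    """Planted/background labels and the planted pair list."""

    disease_id: str
    module_genes: list[str]
    planted: list[str]
    background: list[str]
    planted_pairs: list[tuple[str, str]]

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioTruth":
        d = json.loads(text)
        d["planted_pairs"] = [tuple(p) for p in d["planted_pairs"]]
        return cls(**d)


def generate_interactome(
    model: str = "barabasi_albert",
    params: dict | None = None,
    seed: int = 0,
    max_tries: int = 50,
) -> InteractomeGraph:
    """Generate a connected random interactome with node IDs P0001...

    Models: ``barabasi_albert`` (params n, m), ``watts_strogatz``
    (n, k, p), ``erdos_renyi`` (n, p).  Regenerates (advancing the seed)
    until the realization is connected, then relabels nodes.
    """
    params = dict(params or {})
    builders = {
        "barabasi_albert": lambda s: nx.barabasi_albert_graph(seed=s, **params),
        "watts_strogatz": lambda s: nx.watts_strogatz_graph(seed=s, **params),
        "erdos_renyi": lambda s: nx.gnp_random_graph(seed=s, **params),
    }
    if model not in builders:
        raise ValueError(f"unknown graph model {model!r}")
    for attempt in range(max_tries):
        g = builders[model](int(seed) + attempt)
        if g.number_of_edges() == 0:
            raise ValueError(f"model {model} with params {params} yields no edges")
        if nx.is_connected(g):
            break
    else:
        raise ValueError(f"could not generate a connected {model} graph in {max_tries} tries")
    width = max(4, len(str(g.number_of_nodes())))
    mapping = {old: f"P{idx + 1:0{width}d}" for idx, old in enumerate(sorted(g.nodes))}
    g = nx.relabel_nodes(g, mapping)
    out = nx.Graph()
    out.add_nodes_from(sorted(g.nodes))
    out.add_edges_from(sorted(tuple(sorted(e)) for e in g.edges))
    return InteractomeGraph(graph=out, lcc_flag=True, n_dropped_nodes=0)


def _bfs_ball(graph: nx.Graph, center: str, size: int) -> list[str]:
    """First ``size`` nodes in breadth-first order from the centre, with
    deterministic (sorted) neighbour expansion."""
    seen = [center]
    seen_set = {center}
    frontier = [center]
    while len(seen) < size and frontier:
        nxt = []
        for u in frontier:
            for v in sorted(graph.adj[u]):
                if v not in seen_set:
                    seen_set.add(v)
                    seen.append(v)
                    nxt.append(v)
                    if len(seen) == size:
                        return seen
        frontier = nxt
    return seen


def generate_scenario(
    config: SyntheticScenario | None = None,
) -> tuple[EntityCatalog, InteractomeGraph, ScenarioTruth]:
    """Generate a full synthetic scenario (catalog, interactome, truth).

    Every generated target is a graph node, so the catalog maps with zero
    dropped targets.  Planted ingredients are paired consecutively
    (ING_P001-ING_P002, ...) and each pair shares at least one formula.
    """
    cfg = config or SyntheticScenario()
    rng = np.random.default_rng(cfg.seed)
    interactome = generate_interactome(cfg.graph_model, cfg.graph_params, seed=cfg.seed)
    nodes = sorted(interactome.graph.nodes)
    if cfg.disease_module_size > len(nodes):
        raise ValueError("disease module size exceeds number of proteins")

    center = nodes[int(rng.integers(len(nodes)))]
    module = sorted(_bfs_ball(interactome.graph, center, cfg.disease_module_size))
    disease_id = "DIS_0001"

    n_in_module = round(cfg.proximity_bias * cfg.targets_per_entity)
    planted = [f"ING_P{i + 1:03d}" for i in range(cfg.n_planted_entities)]
    background = [f"ING_B{i + 1:03d}" for i in range(cfg.n_background_entities)]

    ingredient_target: list[tuple[str, str]] = []
    for ing in planted:
        in_mod = rng.choice(module, size=min(n_in_module, len(module)), replace=False)
        n_rest = cfg.targets_per_entity - len(in_mod)
        rest = rng.choice(nodes, size=n_rest, replace=False) if n_rest else []
        targets = sorted(set(map(str, in_mod)) | set(map(str, rest)))
        ingredient_target += [(ing, t) for t in targets]
    for ing in background:
        targets = sorted(set(map(str, rng.choice(nodes, size=cfg.targets_per_entity,
                                                 replace=False))))
        ingredient_target += [(ing, t) for t in targets]

    # herbs: planted pairs kept adjacent so each pair lands in one herb's
    # formula; herb/formula grouping is round-robin-free and deterministic
    all_ings = planted + background
    herbs = []
    herb_ingredient: list[tuple[str, str]] = []
    for i in range(0, len(all_ings), cfg.ingredients_per_herb):
        herb = f"HRB_{i // cfg.ingredients_per_herb + 1:03d}"
        herbs.append(herb)
        herb_ingredient += [(herb, ing) for ing in all_ings[i:i + cfg.ingredients_per_herb]]

    formula_herb: list[tuple[str, str]] = []
    for i in range(0, len(herbs), cfg.herbs_per_formula):
        formula = f"FOR_{i // cfg.herbs_per_formula + 1:03d}"
        formula_herb += [(formula, h) for h in herbs[i:i + cfg.herbs_per_formula]]

    disease_target = [(disease_id, g) for g in module]
    catalog = load_catalog(
        formula_herb=formula_herb,
        herb_ingredient=herb_ingredient,
        ingredient_target=ingredient_target,
        disease_target=disease_target,
    )

    planted_pairs = [(planted[i], planted[i + 1]) for i in range(0, len(planted) - 1, 2)]
    truth = ScenarioTruth(
        disease_id=disease_id,
        module_genes=module,
        planted=planted,
        background=background,
        planted_pairs=planted_pairs,
    )
    return catalog, interactome, truth


def generate_admet_table(ingredient_ids, seed: int = 0) -> AdmetTable:
    """Toy ADMET table: HIA (+/-), OB (0-100), BBB (+/-), hepatotoxicity
    (+/-) per ingredient, seeded.  Marginal rates loosely follow typical
    natural-product profiles (most absorb well, a minority is orally
    bioavailable or hepatotoxic)."""
    ids = sorted(set(ingredient_ids))
    if not ids:
        raise ValueError("no ingredient IDs")
    rng = np.random.default_rng(seed)
    rows = pd.DataFrame(
        {
            "HIA": rng.choice(["+", "-"], size=len(ids), p=[0.85, 0.15]),
            "OB": np.round(rng.uniform(0.0, 100.0, size=len(ids)), 2),
            "BBB": rng.choice(["+", "-"], size=len(ids), p=[0.65, 0.35]),
            "hepatotoxicity": rng.choice(["+", "-"], size=len(ids), p=[0.35, 0.65]),
        },
        index=pd.Index(ids, name="ingredient_id"),
    )
    return AdmetTable(rows=rows)
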