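"""Significance testing for proximity scores.

Three regimes back the scoring:

1. **Random-pair null + one-tailed Fisher Z.**  A null distribution of
   distances is sampled from a universe of random entity pairs (default
   n=1000); the observed distance is converted to Z = (x - mu_null) /
   sigma_null and to a one-tailed p.  Because *small* distances indicate
   strong interaction, p is the standard-normal LEFT tail: the probability
   that a null distance falls at or below the observed one.
2. **Per-test disease nulls.**  Disease screens draw a fresh 1000-pair null
   per test (see :mod:`herbprox.screening`), using the same machinery.
3. **Empirical 5%-tail threshold.**  For browse-scale screening the null is
   the exhaustive pool of pairs co-occurring in formulas; a pair is flagged
   when its distance falls in the pool's lowest-q tail (nearest-rank
   quantile, default q=0.05).

Significance everywhere means p < 0.05 (no multiple-testing correction by
default; a Benjamini-Hochberg helper is provided).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .core import EntityCatalog, InteractomeGraph, target_set
from .proximity import DistanceEngine, _engine

__all__ = [
    "NullModel",
    "SignificanceResult",
    "sample_null",
    "cooccurrence_pool",
    "z_test",
    "empirical_threshold",
    "benjamini_hochberg",
]

ALPHA = 0.05


@dataclass
class NullModel:
    """A sampled or exhaustive distance distribution backing Z-tests.

    ``strategy`` is ``random_pairs`` (n pairs drawn uniformly with
    replacement, seeded) or ``cooccurrence_pool`` (every pair co-occurring
    in at least one formula, exhaustive, no seed).
    """

    values: list[float]
    strategy: str
    level: str  # herb_herb | ingredient_ingredient | herb_disease | ingredient_disease
    seed: int | None = None
    mu_null: float = field(init=False)
    sigma_null: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("null model needs at least 2 values")
        self.mu_null = float(np.mean(self.values))
        self.sigma_null = float(np.std(self.values, ddof=1))
        if self.sigma_null == 0.0:
            raise ValueError("degenerate null: sigma_null is zero")

    @property
    def n(self) -> int:
        return len(self.values)

    def to_json(self) -> str:
        return json.dumps(
            {
                "values": self.values,
                "strategy": self.strategy,
                "level": self.level,
                "seed": self.seed,
                "mu_null": self.mu_null,
                "sigma_null": self.sigma_null,
                "n": self.n,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NullModel":
        d = json.loads(text)
        return cls(values=d["values"], strategy=d["strategy"], level=d["level"], seed=d["seed"])


@dataclass(frozen=True)
class SignificanceResult:
    observed: float
    z: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def _pair_distance_fn(
    level: str, catalog: EntityCatalog, eng: DistanceEngine
) -> Callable[[str, str], float]:
    """Distance function matching the null's level: closest for
    ingredient pairs, center for herb pairs, directed for disease pairs."""
    from .proximity import center_distance  # local import avoids cycle at module load

    if level == "ingredient_ingredient":
        def fn(a: str, b: str) -> float:
            ta = target_set(a, "ingredient", catalog, eng.interactome)
            tb = target_set(b, "ingredient", catalog, eng.interactome)
            return eng.closest(ta.proteins, tb.proteins)
    elif level == "herb_herb":
        def fn(a: str, b: str) -> float:
            return center_distance(a, b, catalog, eng).value
    elif level in {"ingredient_disease", "herb_disease"}:
        ent_level = level.split("_")[0]
        def fn(a: str, b: str) -> float:
            tx = target_set(a, ent_level, catalog, eng.interactome)
            ty = target_set(b, "disease", catalog, eng.interactome)
            return eng.directed(tx.proteins, ty.proteins)
    else:
        raise ValueError(f"unknown null level {level!r}")
    return fn


def sample_null(
    pair_universe: Sequence[tuple[str, str]],
    level: str,
    catalog: EntityCatalog,
    graph: InteractomeGraph | DistanceEngine,
    n: int = 1000,
    seed: int = 0,
    distance_fn: Callable[[str, str], float] | None = None,
) -> NullModel:
    """Sample a null distance distribution from a pair universe.

    Draws ``n`` pairs uniformly *with replacement* (seeded NumPy generator)
    and computes the level-appropriate distance for each; repeated pairs
    reuse the engine's BFS cache, so large n stays cheap.
    """
    if not pair_universe:
        raise ValueError("empty pair universe")
    if n < 2:
        raise ValueError("null sample size must be >= 2")
    eng = _engine(graph)
    fn = distance_fn or _pair_distance_fn(level, catalog, eng)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pair_universe), size=n)
    cache: dict[tuple[str, str], float] = {}
    values = []
    for i in idx:
        pair = tuple(pair_universe[int(i)])
        if pair not in cache:
            cache[pair] = fn(*pair)
        values.append(cache[pair])
    return NullModel(values=values, strategy="random_pairs", level=level, seed=seed)


def cooccurrence_universe(
    catalog: EntityCatalog, level: str
) -> list[tuple[str, str]]:
    """All unordered pairs co-occurring in at least one formula, sorted."""
    pairs: set[tuple[str, str]] = set()
    for formula in sorted(catalog.formula_ids):
        if level == "herb_herb":
            members = catalog.herbs_of_formula(formula)
        elif level == "ingredient_ingredient":
            members = catalog.ingredients_of_formula(formula)
        else:
            raise ValueError(f"co-occurrence level must be herb_herb or "
                             f"ingredient_ingredient, got {level!r}")
        pairs.update(tuple(sorted(p)) for p in combinations(members, 2))
    return sorted(pairs)


def cooccurrence_pool(
    catalog: EntityCatalog,
    level: str,
    graph: InteractomeGraph | DistanceEngine,
    distance_fn: Callable[[str, str], float] | None = None,
) -> NullModel:
    """Exhaustive null over every pair co-occurring in a formula.

    No sampling and no seed: the pool is the deduplicated union of
    within-formula pairs at the requested level, each scored once.  Pairs
    whose endpoints have no mappable targets are skipped.
    """
    from .core import CatalogError

    eng = _engine(graph)
    universe = cooccurrence_universe(catalog, level)
    if not universe:
        raise ValueError(f"no co-occurring {level} pair in any formula")
    fn = distance_fn or _pair_distance_fn(level, catalog, eng)
    values = []
    for a, b in universe:
        try:
            values.append(fn(a, b))
        except CatalogError:
            continue
    if not values:
        raise ValueError("no scorable co-occurring pair")
    return NullModel(values=values, strategy="cooccurrence_pool", level=level, seed=None)


def z_test(observed: float, null: NullModel) -> SignificanceResult:
    """One-tailed Fisher Z-test of an observed distance against a null.

    Z = (observed - mu_null) / sigma_null; p is the standard-normal lower
    tail Phi(Z), so distances far *below* the null mean are significant.
    """
    z = (observed - null.mu_null) / null.sigma_null
    p = float(stats.norm.cdf(z))
    return SignificanceResult(observed=float(observed), z=float(z), p=p)


def empirical_threshold(null: NullModel, q: float = 0.05) -> float:
    """Nearest-rank q-quantile of the null values.

    Rank = ceil(q*n) on the ascending sort (1-based); a pair is flagged in
    the browse regime when its distance is <= this threshold.
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0,1), got {q}")
    ordered = sorted(null.values)
    rank = math.ceil(q * len(ordered))
    return float(ordered[rank - 1])


def benjamini_hochberg(pvalues: Sequence[float], alpha: float = ALPHA) -> list[bool]:
    """Optional FDR control over a family of raw p-values (off by default
    throughout the package: the scoring regimes use raw p < 0.05)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    max_k = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= alpha * rank / m:
            max_k = rank
    for rank, i in enumerate(order, start=1):
        flags[i] = rank <= max_k
    return flags.tolist()
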