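"""Repositioning screens and stratified distance reports.

A repositioning screen ranks every herb or ingredient by its directed
proximity to a disease's gene set (or every disease against a fixed
entity), attaching a per-test sampled null and Fisher-Z significance to
each row.  Stratified reports compare distance distributions between herb
strata (formula-frequency median split, or simple vs complex prescriptions
at N_herbs < 6 vs >= 6) with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CatalogError, EntityCatalog, InteractomeGraph, target_set
from .proximity import DistanceEngine, _engine
from .significance import NullModel, sample_null, z_test

logger = logging.getLogger(__name__)

__all__ = ["ScreenResult", "StrataReport", "reposition_for_disease",
           "reposition_for_entity", "stratified_distance_report"]

RESULT_COLUMNS = ["entity_id", "disease_id", "metric", "distance", "z", "p",
                  "significant", "rank"]


@dataclass
class ScreenResult:
    """Ranked, significance-flagged screen rows plus null provenance.

    ``rows`` is a DataFrame with columns entity_id, disease_id, metric,
    distance, z, p, significant, rank; ranks are 1-based ascending by
    distance with ties broken by entity then disease ID.  ``skipped`` lists
    (entity_id, reason) for entities with no mappable targets.
    """

    rows: pd.DataFrame
    null: NullModel
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def provenance(self) -> dict:
        return {"strategy": self.null.strategy, "n": self.null.n,
                "seed": self.null.seed, "level": self.null.level}


def _rank_rows(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=RESULT_COLUMNS[:-1])
    df = df.sort_values(["distance", "entity_id", "disease_id"],
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def reposition_for_disease(
    disease_id: str,
    level: str,
    catalog: EntityCatalog,
    graph: InteractomeGraph | DistanceEngine,
    n_null: int = 1000,
    seed: int = 0,
) -> ScreenResult:
    """Rank every entity at ``level`` by directed proximity to one disease.

    The null is sampled once per screen from the (entity, disease) pair
    universe at this level — the per-test regime — and shared across the
    screen's rows.
    """
    if level not in {"herb", "ingredient"}:
        raise ValueError(f"level must be 'herb' or 'ingredient', got {level!r}")
    eng = _engine(graph)
    ty = target_set(disease_id, "disease", catalog, eng.interactome)

    entity_ids = sorted(catalog.herb_ids if level == "herb" else catalog.ingredient_ids)
    if not entity_ids:
        raise CatalogError(f"catalog has no {level} entities")
    universe = [(e, d) for e in entity_ids for d in sorted(catalog.disease_ids)]
    null = sample_null(universe, f"{level}_disease", catalog, eng, n=n_null, seed=seed)

    records, skipped = [], []
    for e in entity_ids:
        try:
            tx = target_set(e, level, catalog, eng.interactome)
        except CatalogError as err:
            skipped.append((e, str(err)))
            logger.info("skipped %s %s: %s", level, e, err)
            continue
        d = eng.directed(tx.proteins, ty.proteins)
        res = z_test(d, null)
        records.append({"entity_id": e, "disease_id": disease_id,
                        "metric": "disease_directed", "distance": d,
                        "z": res.z, "p": res.p, "significant": res.significant})
    if not records:
        raise CatalogError(f"no {level} with mappable targets")
    return ScreenResult(rows=_rank_rows(records), null=null, skipped=skipped)


def reposition_for_entity(
    entity_id: str,
    level: str,
    catalog: EntityCatalog,
    graph: InteractomeGraph | DistanceEngine,
    n_null: int = 1000,
    seed: int = 0,
) -> ScreenResult:
    """Rank every disease by directed proximity to one herb/ingredient —
    the top-ranked diseases are candidate novel indications."""
    if level not in {"herb", "ingredient"}:
        raise ValueError(f"level must be 'herb' or 'ingredient', got {level!r}")
    eng = _engine(graph)
    tx = target_set(entity_id, level, catalog, eng.interactome)
    disease_ids = sorted(catalog.disease_ids)
    if not disease_ids:
        raise CatalogError("catalog has no diseases")

    entity_ids = sorted(catalog.herb_ids if level == "herb" else catalog.ingredient_ids)
    universe = [(e, d) for e in entity_ids for d in disease_ids]
    null = sample_null(universe, f"{level}_disease", catalog, eng, n=n_null, seed=seed)

    records, skipped = [], []
    for d_id in disease_ids:
        try:
            ty = target_set(d_id, "disease", catalog, eng.interactome)
        except CatalogError as err:
            skipped.append((d_id, str(err)))
            continue
        d = eng.directed(tx.proteins, ty.proteins)
        res = z_test(d, null)
        records.append({"entity_id": entity_id, "disease_id": d_id,
                        "metric": "disease_directed", "distance": d,
                        "z": res.z, "p": res.p, "significant": res.significant})
    if not records:
        raise CatalogError("no disease with mappable genes")
    df = pd.DataFrame(records, columns=RESULT_COLUMNS[:-1])
    df = df.sort_values(["distance", "disease_id"], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return ScreenResult(rows=df, null=null, skipped=skipped)


@dataclass
class StrataReport:
    """Per-stratum distance summaries plus a rank-sum comparison."""

    strata: pd.DataFrame          # columns: stratum, n, median, iqr
    p_value: float | None         # Wilcoxon rank-sum p between the two strata
    spec: str

    def summary(self) -> str:
        lines = [f"strata_spec: {self.spec}"]
        for _, r in self.strata.iterrows():
            lines.append(f"  {r.stratum}: n={int(r.n)} median={r['median']:.4f} iqr={r.iqr:.4f}")
        lines.append(f"  rank-sum p: {'n/a' if self.p_value is None else format(self.p_value, '.4g')}")
        return "\n".join(lines)


def _herb_frequency_strata(catalog: EntityCatalog) -> dict[str, str]:
    """high/low split of herbs at the median of their formula-occurrence
    counts; herbs exactly at the median go to the HIGH stratum."""
    counts = {h: len(catalog.formulas_of_herb(h)) for h in sorted(catalog.herb_ids)}
    med = float(np.median(list(counts.values())))
    return {h: ("high_frequency" if c >= med else "low_frequency")
            for h, c in counts.items()}


def _formula_complexity_strata(catalog: EntityCatalog, cutoff: int = 6) -> dict[str, str]:
    """Herbs labelled by the complexity of the formulas they appear in:
    simple prescriptions have N_herbs < cutoff, complex >= cutoff.  A herb
    in both kinds contributes to the stratum of each formula row it appears
    in; here we assign by the herb's maximum formula size."""
    out = {}
    for h in sorted(catalog.herb_ids):
        sizes = [len(catalog.herbs_of_formula(f)) for f in catalog.formulas_of_herb(h)]
        if not sizes:
            continue
        out[h] = "complex" if max(sizes) >= cutoff else "simple"
    return out


def stratified_distance_report(
    results: pd.DataFrame | ScreenResult,
    catalog: EntityCatalog,
    strata_spec: str,
) -> StrataReport:
    """Compare screen distances between herb strata.

    ``strata_spec='herb_frequency_median_split'`` splits herbs at the median
    of their formula-occurrence counts (ties to high); ``'formula_complexity'``
    splits at N_herbs < 6 vs >= 6.  Emits per-stratum n/median/IQR and a
    two-sided Wilcoxon rank-sum p (None when a stratum is empty).
    """
    rows = results.rows if isinstance(results, ScreenResult) else results
    if rows.empty:
        raise ValueError("empty results")
    if strata_spec == "herb_frequency_median_split":
        labels = _herb_frequency_strata(catalog)
        order = ["high_frequency", "low_frequency"]
    elif strata_spec == "formula_complexity":
        labels = _formula_complexity_strata(catalog)
        order = ["complex", "simple"]
    else:
        raise ValueError(f"unsupported strata_spec {strata_spec!r}")

    groups: dict[str, np.ndarray] = {}
    for name in order:
        members = {e for e, s in labels.items() if s == name}
        vals = rows.loc[rows.entity_id.isin(members), "distance"].to_numpy()
        groups[name] = vals

    recs = []
    for name in order:
        v = groups[name]
        if len(v):
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            recs.append({"stratum": name, "n": len(v), "median": med, "iqr": q3 - q1})
        else:
            recs.append({"stratum": name, "n": 0, "median": np.nan, "iqr": np.nan})
    strata = pd.DataFrame(recs)

    a, b = groups[order[0]], groups[order[1]]
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue) \
        if len(a) and len(b) else None
    return StrataReport(strata=strata, p_value=p, spec=strata_spec)
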