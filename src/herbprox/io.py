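"""Readers and writers: bit-stable CSV/JSON serialization for every
artefact the pipeline produces.

Conventions: comma-separated UTF-8 with a mandatory header row; IDs
restricted to ``[A-Za-z0-9_:-]`` and never quoted; distances with 6 decimal
places; p-values in scientific notation with 4 significant digits.  Every
writer's output round-trips through its paired reader.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path

import pandas as pd
import yaml

from .combination import AdmetTable, CombinationLandscape
from .core import (
    CatalogError,
    EntityCatalog,
    InteractomeGraph,
    load_catalog,
    load_interactome,
)
from .screening import ScreenResult
from .significance import NullModel
from .synthdata import ScenarioTruth

__all__ = [
    "read_interactome",
    "write_interactome",
    "read_catalog",
    "write_catalog",
    "read_admet_table",
    "write_admet_table",
    "write_screen_result",
    "read_screen_result",
    "write_landscape",
    "read_landscape",
    "write_null_model",
    "read_null_model",
    "RunConfig",
]

_ID_RE = re.compile(r"^[A-Za-z0-9_:\-]+$")

CATALOG_TABLES = {
    "formula_herb": ("formula_id", "herb_id"),
    "herb_ingredient": ("herb_id", "ingredient_id"),
    "ingredient_target": ("ingredient_id", "protein_id"),
    "disease_target": ("disease_id", "protein_id"),
}


def _read_pairs(path: Path, expected_cols: tuple[str, str]) -> list[tuple[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise CatalogError(f"{path}: empty file")
        header = [h.strip() for h in header]
        if tuple(header[:2]) != expected_cols:
            raise CatalogError(
                f"{path}: expected columns {expected_cols}, found {tuple(header[:2])}"
            )
        return [(row[0].strip(), row[1].strip()) for row in reader if row]


def read_interactome(path: str | Path, restrict_lcc: bool = True) -> InteractomeGraph:
    """Read a protein_a,protein_b edge table (CSV or TSV, header required)."""
    rows = _read_pairs(Path(path), ("protein_a", "protein_b"))
    return load_interactome(rows, restrict_lcc=restrict_lcc)


def write_interactome(graph: InteractomeGraph, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["protein_a", "protein_b"])
        w.writerows(graph.edge_table())


def read_catalog(directory: str | Path) -> EntityCatalog:
    """Read the four catalog CSVs (formula_herb.csv etc.) from a directory,
    or a single JSON mirror ``catalog.json`` if present."""
    directory = Path(directory)
    json_path = directory / "catalog.json"
    if json_path.exists():
        with open(json_path, encoding="utf-8") as fh:
            d = json.load(fh)
        return load_catalog(**{k: [tuple(r) for r in d.get(k, [])] for k in CATALOG_TABLES})
    tables = {}
    for name, cols in CATALOG_TABLES.items():
        p = directory / f"{name}.csv"
        tables[name] = _read_pairs(p, cols) if p.exists() else []
    return load_catalog(**tables)


def write_catalog(catalog: EntityCatalog, directory: str | Path, as_json: bool = False) -> None:
    """Write the four association tables as CSVs (default) or one JSON
    mirror; rows are emitted sorted for byte-stable output."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = {name: sorted(getattr(catalog, name)) for name in CATALOG_TABLES}
    if as_json:
        with open(directory / "catalog.json", "w", encoding="utf-8") as fh:
            json.dump({k: [list(r) for r in v] for k, v in data.items()},
                      fh, sort_keys=True, indent=1)
            fh.write("\n")
        return
    for name, cols in CATALOG_TABLES.items():
        with open(directory / f"{name}.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            w.writerows(data[name])


def read_admet_table(path: str | Path) -> AdmetTable:
    df = pd.read_csv(path, dtype=str).set_index("ingredient_id")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    for col in df.columns:
        if numeric[col].notna().all():
            df[col] = numeric[col]
    return AdmetTable(rows=df)


def write_admet_table(table: AdmetTable, path: str | Path) -> None:
    table.rows.sort_index().to_csv(path)


def write_screen_result(result: ScreenResult, path: str | Path) -> None:
    """ScreenResult CSV plus a .provenance.json sidecar (null strategy,
    n, seed, skipped entities)."""
    path = Path(path)
    df = result.rows.copy()
    df["distance"] = df["distance"].map(lambda v: f"{v:.6f}")
    df["z"] = df["z"].map(lambda v: f"{v:.6f}")
    df["p"] = df["p"].map(lambda v: f"{v:.4g}")
    df.to_csv(path, index=False)
    sidecar = {"null": result.provenance, "skipped": result.skipped}
    with open(path.with_suffix(".provenance.json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_screen_result(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("distance", "z", "p"):
        df[col] = df[col].astype(float)
    df["significant"] = df["significant"].astype(bool)
    return df


def write_landscape(landscape: CombinationLandscape, path: str | Path,
                    labels: dict[str, int] | None = None) -> None:
    """Node-link JSON; community labels, when given, are appended as a node
    attribute.  A flat edge CSV is written alongside (.edges.csv)."""
    path = Path(path)
    doc = landscape.to_node_link()
    if labels is not None:
        for node in doc["nodes"]:
            node["community"] = labels.get(node["id"])
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)
        fh.write("\n")
    with open(path.with_suffix(".edges.csv"), "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target", "relation", "distance", "z", "p", "significant"])
        for e in landscape.edges:
            w.writerow([e.source, e.target, e.relation, f"{e.distance:.6f}",
                        f"{e.z:.6f}", f"{e.p:.4g}", e.significant])


def read_landscape(path: str | Path) -> CombinationLandscape:
    with open(path, encoding="utf-8") as fh:
        return CombinationLandscape.from_node_link(json.load(fh))


def write_null_model(null: NullModel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(null.to_json())
        fh.write("\n")


def read_null_model(path: str | Path) -> NullModel:
    with open(path, encoding="utf-8") as fh:
        return NullModel.from_json(fh.read())


def write_truth(truth: ScenarioTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(truth.to_json())
        fh.write("\n")


def read_truth(path: str | Path) -> ScenarioTruth:
    with open(path, encoding="utf-8") as fh:
        return ScenarioTruth.from_json(fh.read())


class RunConfig(dict):
    """Resolved run configuration: YAML file values overridden by CLI
    flags; all seeds explicit; echoed to the output directory."""

    DEFAULTS = {
        "shortest_norm": "product",
        "weight_transform": "exp_neg",
        "null_strategy": "random_pairs",
        "null_n": 1000,
        "seed": 0,
        "alpha": 0.05,
        "louvain_resolution": 1.0,
    }

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        cfg = cls(cls.DEFAULTS)
        if path:
            with open(path, encoding="utf-8") as fh:
                cfg.update(yaml.safe_load(fh) or {})
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        return cfg

    def echo(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "run_config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(dict(self), fh, sort_keys=True)
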