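"""Readers and writers for the tabular, config and graph formats.

All tables are UTF-8 TSV with one header row and the id in the first
column; rule sets and pipeline settings are YAML (JSON is valid YAML);
networks are GraphML or a TSV edge list.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any

import networkx as nx
import pandas as pd
import yaml

from .datamodel import (
    EliminationRuleSet,
    MetadataTable,
    OtuCountTable,
    PageRankScores,
    SampleMetadata,
    Taxonomy,
    TaxonomyAssignment,
    TrophicNetwork,
    ValidationError,
)

SAMPLES_AS_ROWS = "samples_as_rows"
OTUS_AS_ROWS = "otus_as_rows"

_METADATA_COLUMNS = [
    "sample_id",
    "sample_kind",
    "predator_group",
    "predator_species",
    "feeding_habit",
    "station",
]


def read_count_table(path: str | Path, orientation: str = SAMPLES_AS_ROWS) -> OtuCountTable:
    """Read a delimited count table and validate it as an OtuCountTable."""
    if orientation not in (SAMPLES_AS_ROWS, OTUS_AS_ROWS):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric count {bad.iloc[0]!r} at row "
                f"{bad.index[0]!r}, column {col!r}"
            )
    if orientation == OTUS_AS_ROWS:
        df = df.T
    try:
        return OtuCountTable(df)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from None


def write_count_table(table: OtuCountTable, path: str | Path) -> None:
    table.counts.rename_axis("sample_id").to_csv(path, sep="\t")


def read_taxonomy(path: str | Path, vocabulary=None) -> Taxonomy:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"otu_id", "lineage", "category"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: taxonomy needs columns {sorted(required)}")
    assignments = [
        TaxonomyAssignment(
            otu_id=row.otu_id,
            lineage=tuple(p for p in row.lineage.split(";") if p),
            category=row.category,
        )
        for row in df.itertuples()
    ]
    return Taxonomy(assignments, vocabulary=vocabulary)


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    rows = [
        {"otu_id": a.otu_id, "lineage": ";".join(a.lineage), "category": a.category}
        for a in taxonomy.assignments.values()
    ]
    pd.DataFrame(rows, columns=["otu_id", "lineage", "category"]).to_csv(
        path, sep="\t", index=False
    )


def read_metadata(path: str | Path) -> MetadataTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: metadata is missing columns {sorted(missing)}")
    return MetadataTable(
        SampleMetadata(**{c: getattr(row, c) for c in _METADATA_COLUMNS})
        for row in df.itertuples()
    )


def write_metadata(metadata: MetadataTable, path: str | Path) -> None:
    rows = [{c: getattr(r, c) for c in _METADATA_COLUMNS} for r in metadata]
    pd.DataFrame(rows, columns=_METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def _load_config_mapping(path: str | Path) -> dict[str, Any]:
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping at top level")
    return data


def default_rules_path() -> Path:
    """Path of the packaged default elimination-rule config."""
    return Path(str(resources.files("trophonet").joinpath("data/default_rules.yaml")))


def read_rules(path: str | Path) -> EliminationRuleSet:
    """Read an elimination-rule config (YAML or JSON).

    Schema: ``vocabulary`` (list), ``phytoplankton_categories`` (list),
    ``global`` (list), ``groups`` (mapping group -> list, or group ->
    {eliminate: list, feeding_habit: str}).
    """
    data = _load_config_mapping(path)
    groups_raw = data.get("groups", {})
    per_group: dict[str, list[str]] = {}
    for g, spec in groups_raw.items():
        per_group[g] = list(spec["eliminate"] if isinstance(spec, dict) else spec)
    try:
        return EliminationRuleSet(
            per_group=per_group,
            global_eliminations=data.get("global", []),
            phytoplankton_categories=data.get("phytoplankton_categories", []),
            vocabulary=data.get("vocabulary"),
        )
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from None


def default_rules() -> EliminationRuleSet:
    return read_rules(default_rules_path())


def read_feeding_habits(path: str | Path | None = None) -> dict[str, str]:
    """Predator group -> feeding habit, from a rules config (default bundled)."""
    data = _load_config_mapping(path or default_rules_path())
    habits = {}
    for g, spec in data.get("groups", {}).items():
        if isinstance(spec, dict) and "feeding_habit" in spec:
            habits[g] = spec["feeding_habit"]
    return habits


def read_node_classes(path: str | Path | None = None) -> dict[str, str]:
    """Node label -> ecological class, from a rules config (default bundled)."""
    data = _load_config_mapping(path or default_rules_path())
    return dict(data.get("node_classes", {}))


def write_network(
    network: TrophicNetwork,
    scores: PageRankScores | None,
    path: str | Path,
    fmt: str = "graphml",
) -> None:
    """Serialize a trophic network; GraphML keeps all attributes, the TSV
    edge list keeps predator, prey, weight."""
    g = network.graph.copy()
    if scores is not None:
        missing = [n for n in g.nodes if n not in scores.scores]
        if missing:
            raise ValidationError(f"nodes missing from PageRank scores: {missing}")
        nx.set_node_attributes(
            g, {n: float(scores.scores[n]) for n in g.nodes}, "pagerank"
        )
    if fmt == "graphml":
        g.graph["mode"] = network.mode
        nx.write_graphml(g, path)
    elif fmt == "edgelist":
        rows = [
            {"predator": u, "prey": v, "weight": d["weight"]}
            for u, v, d in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["predator", "prey", "weight"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str | Path) -> TrophicNetwork:
    g = nx.read_graphml(path)
    mode = g.graph.pop("mode", "reads")
    return TrophicNetwork(graph=nx.DiGraph(g), mode=mode)


def write_json(data: Any, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(data, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
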