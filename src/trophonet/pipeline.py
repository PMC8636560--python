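"""End-to-end orchestration: ingest or simulate, filter, summarize,
ordinate, cluster, and build scored trophic networks, with a manifest
recording configuration, seed, and per-stage record counts.

All randomness flows from the single configured seed (the simulator derives
one substream per sample; NMDS restarts use the seed directly), so a given
config + seed pair always reproduces the same output directory byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as tio
from . import network as tnet
from . import ordination as tord
from . import preprocess as tpre
from . import simulate as tsim
from .datamodel import GroupDietSummary, PreyProfile, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "trophonet_out",
    "rules": None,  # bundled 22-group default
    "k_dominant": 10,
    "grouping_level": "group",
    "cluster_thresholds": [30.0, 40.0, 50.0],
    "ordination_level": "groups",  # or "individuals"
    "nmds": {"k": 2, "n_restarts": 20, "max_iter": 500, "tol": 1e-6},
    "network": {
        "modes": ["reads", "frequency"],
        "edge_thresholds": {"reads": 0.01, "frequency": 0.0},
    },
    "damping": 0.85,
    "water_key": "water",
}


def load_pipeline_config(path: str | Path) -> dict[str, Any]:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return merge_config(data)


def merge_config(overrides: dict[str, Any]) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _config_hash(config: dict[str, Any]) -> str:
    # the output location is not part of the run's identity
    canon = json.dumps(
        {k: v for k, v in config.items() if k not in ("outdir", "inputs")},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


def _simulation_config(block: dict[str, Any], seed: int) -> tsim.SimulationConfig:
    block = dict(block)
    preset = block.pop("preset", None)
    if preset == "five_guild_demo":
        allowed = {
            "n_individuals_per_group",
            "reads_per_individual",
            "concentration",
            "copy_number_bias",
        }
        bad = set(block) - allowed
        if bad:
            raise ValidationError(f"unknown five_guild_demo overrides: {sorted(bad)}")
        return tsim.five_guild_demo_config(seed=seed, **block)
    if preset is not None:
        raise ValidationError(f"unknown simulation preset {preset!r}")
    specs = [
        tsim.DietSpec(
            predator_group=s["predator_group"],
            mean_diet=s["mean_diet"],
            concentration=float(s.get("concentration", 20.0)),
            feeding_habit=s.get("feeding_habit", "omnivore"),
            species=s.get("species", ""),
            guild=s.get("guild", ""),
        )
        for s in block.pop("diet_specs")
    ]
    return tsim.SimulationConfig(diet_specs=specs, seed=seed, **block)


# -- stage I/O helpers -------------------------------------------------------


def write_profiles(profiles: list[PreyProfile], path: str | Path) -> None:
    matrix = tord.profiles_to_matrix(profiles)
    matrix.insert(0, "n_prey_reads", [p.n_prey_reads for p in profiles])
    matrix.rename_axis("sample_id").to_csv(path, sep="\t")


def read_profiles(path: str | Path) -> list[PreyProfile]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    profiles = []
    for sample_id, row in df.iterrows():
        n = int(row["n_prey_reads"])
        props = {
            c: float(v) for c, v in row.drop("n_prey_reads").items() if v > 0
        }
        profiles.append(
            PreyProfile(sample_id=str(sample_id), proportions=props, n_prey_reads=n)
        )
    return profiles


def write_summaries(summaries: list[GroupDietSummary], path: str | Path) -> None:
    rows = []
    for s in summaries:
        cats = sorted(set(s.mean_proportions) | set(s.appearance_frequency))
        for stat, mapping in (
            ("mean_proportion", s.mean_proportions),
            ("appearance_frequency", s.appearance_frequency),
        ):
            for c in cats:
                rows.append(
                    {
                        "group": s.group_key,
                        "n_replicates": s.n_replicates,
                        "n_nonempty": s.n_nonempty,
                        "statistic": stat,
                        "category": c,
                        "value": mapping.get(c, 0.0),
                    }
                )
        if not cats:  # flagged empty group
            rows.append(
                {
                    "group": s.group_key,
                    "n_replicates": s.n_replicates,
                    "n_nonempty": 0,
                    "statistic": "empty_group",
                    "category": "",
                    "value": float("nan"),
                }
            )
    pd.DataFrame(
        rows,
        columns=["group", "n_replicates", "n_nonempty", "statistic", "category", "value"],
    ).to_csv(path, sep="\t", index=False)


def read_summaries(path: str | Path) -> list[GroupDietSummary]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for group, block in df.groupby("group", sort=True):
        mean = {
            r.category: r.value
            for r in block.itertuples()
            if r.statistic == "mean_proportion"
        }
        freq = {
            r.category: r.value
            for r in block.itertuples()
            if r.statistic == "appearance_frequency"
        }
        flagged = (block["statistic"] == "empty_group").any()
        out.append(
            GroupDietSummary(
                group_key=str(group),
                n_replicates=int(block["n_replicates"].iloc[0]),
                mean_proportions=mean,
                appearance_frequency=freq,
                n_nonempty=int(block["n_nonempty"].iloc[0]),
                flagged_empty=bool(flagged),
            )
        )
    return out


# -- stages ------------------------------------------------------------------


def _ingest(config, outdir, stages):
    if "simulate" in config and config["simulate"]:
        sim_cfg = _simulation_config(config["simulate"], seed=int(config["seed"]))
        table, taxonomy, metadata, truth = tsim.simulate_dataset(sim_cfg)
        tio.write_count_table(table, outdir / "counts.tsv")
        tio.write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
        tio.write_metadata(metadata, outdir / "metadata.tsv")
        truth_rows = [
            {"sample_id": s, "category": c, "planted_proportion": v}
            for s in sorted(truth.diets)
            for c, v in sorted(truth.diets[s].items())
        ]
        pd.DataFrame(
            truth_rows, columns=["sample_id", "category", "planted_proportion"]
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    elif "inputs" in config and config["inputs"]:
        paths = config["inputs"]
        table = tio.read_count_table(paths["counts"])
        taxonomy = tio.read_taxonomy(paths["taxonomy"])
        metadata = tio.read_metadata(paths["metadata"])
    else:
        raise ValidationError("config needs either a 'simulate' or an 'inputs' block")
    stages.append({"name": "ingest", "n_records": len(table.sample_ids)})
    return table, taxonomy, metadata


def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Execute every stage and return (and write) the run manifest."""
    config = merge_config(config)
    if not config.get("simulate") and not config.get("inputs"):
        raise ValidationError("config needs either a 'simulate' or an 'inputs' block")
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict[str, Any]] = []

    table, taxonomy, metadata = _ingest(config, outdir, stages)
    rules = tio.read_rules(config["rules"]) if config["rules"] else tio.default_rules()

    filtered = tpre.eliminate_taxa(table, taxonomy, metadata, rules)
    stages.append({"name": "eliminate", "n_records": len(filtered.otu_ids)})

    profiles = []
    for sample_id in filtered.sample_ids:
        counts = filtered.sample_counts(sample_id)
        selected = tpre.select_dominant_otus(counts, k=int(config["k_dominant"]))
        profiles.append(tpre.standardize_reads(counts, selected))
    stages.append(
        {"name": "standardize", "n_records": sum(not p.is_empty for p in profiles)}
    )

    profiles = [tpre.aggregate_by_category(p, taxonomy) for p in profiles]
    stages.append({"name": "aggregate", "n_records": len(profiles)})
    write_profiles(profiles, outdir / "profiles.tsv")
    empty_ids = [p.sample_id for p in profiles if p.is_empty]
    pd.DataFrame({"sample_id": empty_ids, "flag": ["no_prey_reads"] * len(empty_ids)}).to_csv(
        outdir / "qc_flagged_samples.tsv", sep="\t", index=False
    )

    grouping = tpre.grouping_by_metadata(
        metadata, level=config["grouping_level"], water_key=config["water_key"]
    )
    summaries = tpre.summarize_group(profiles, grouping)
    stages.append({"name": "summarize", "n_records": len(summaries)})
    write_summaries(summaries, outdir / "group_summary.tsv")

    # ordination on gut samples only (individuals or group means)
    gut_ids = {m.sample_id for m in metadata.gut_samples()}
    gut_summaries = [s for s in summaries if s.group_key != config["water_key"]]
    if config["ordination_level"] == "individuals":
        items = [p for p in profiles if p.sample_id in gut_ids and not p.is_empty]
    else:
        items = [
            PreyProfile(s.group_key, dict(s.mean_proportions), 1)
            for s in gut_summaries
            if not s.flagged_empty
        ]
    transformed = tord.transform_profiles(items, transform="sqrt")
    sim = tord.bray_curtis_similarity(transformed)
    stages.append({"name": "similarity", "n_records": len(sim.item_ids)})
    sim.to_frame().rename_axis("item").to_csv(outdir / "similarity.tsv", sep="\t")

    cluster_df = pd.DataFrame(index=pd.Index(sim.item_ids, name="item"))
    for t in config["cluster_thresholds"]:
        assignment = tord.average_linkage_clusters(sim, float(t))
        cluster_df[f"cluster_at_{t:g}"] = [
            assignment.labels[i] for i in sim.item_ids
        ]
    stages.append({"name": "cluster", "n_records": len(cluster_df)})
    cluster_df.to_csv(outdir / "clusters.tsv", sep="\t")

    nmds_cfg = config["nmds"]
    result = tord.nmds(
        sim,
        k=int(nmds_cfg["k"]),
        n_restarts=int(nmds_cfg["n_restarts"]),
        seed=int(config["seed"]),
        max_iter=int(nmds_cfg["max_iter"]),
        tol=float(nmds_cfg["tol"]),
    )
    stages.append({"name": "nmds", "n_records": len(result.item_ids)})
    nmds_df = result.to_frame().rename_axis("item")
    nmds_df["stress"] = result.stress
    nmds_df.to_csv(outdir / "nmds.tsv", sep="\t")

    node_classes = tio.read_node_classes(config["rules"])
    n_edges = 0
    pagerank_by_mode: dict[str, dict[str, float]] = {}
    for mode in config["network"]["modes"]:
        net = tnet.build_network(
            gut_summaries,
            mode=mode,
            edge_threshold=float(config["network"]["edge_thresholds"][mode]),
            node_classes=node_classes,
        )
        scores = tnet.pagerank(net, damping=float(config["damping"]))
        tio.write_network(net, scores, outdir / f"network_{mode}.graphml", "graphml")
        tio.write_network(net, scores, outdir / f"network_{mode}_edges.tsv", "edgelist")
        pd.DataFrame(
            sorted(scores.scores.items()), columns=["node", "pagerank"]
        ).to_csv(outdir / f"pagerank_{mode}.tsv", sep="\t", index=False)
        n_edges += net.graph.number_of_edges()
        pagerank_by_mode[mode] = scores.scores
    stages.append({"name": "network_pagerank", "n_records": n_edges})

    manifest = {
        "config_hash": _config_hash(config),
        "seed": int(config["seed"]),
        "package_version": _pkg_version("trophonet"),
        "stages": stages,
        "nmds_stress": result.stress,
        "n_empty_gut_samples": len(empty_ids),
        "top_hubs": {
            mode: tnet.rank_hubs(
                tnet.PageRankScores(scores, float(config["damping"]), 0, True), 3
            )
            for mode, scores in pagerank_by_mode.items()
        },
    }
    tio.write_json(manifest, outdir / "manifest.json")
    return manifest
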