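"""Table readers/writers, run configuration and the end-to-end pipeline.

All tables are UTF-8 TSV with a header row (tab-separated so Chinese
prescription/herb labels containing commas need no quoting).  Every run
emits a JSON manifest (config, seed, input hashes, package version)
sufficient to reproduce it exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import kg
from .dgi import EmbeddingSet, TrainConfig, train
from .similarity import (
    DEFAULT_THRESHOLDS, METRICS, apply_exclusions, pairwise_similarity,
    screen, summarize,
)

logger = logging.getLogger("presim")

NODE_COLUMNS = ["id", "node_type", "label", "role"]
EDGE_COLUMNS = ["source", "target", "relation"]
ANNOTATION_COLUMNS = ["prescription_id", "pediatric", "respiratory_only"]
SIMILARITY_COLUMNS = ["target_id", "candidate_id", "metric", "value"]


class TableValidationError(ValueError):
    """Input table failed validation; message lists offending rows."""


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableValidationError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def read_nodes(path) -> pd.DataFrame:
    df = _read_tsv(path, ["id", "node_type"])
    if "label" not in df.columns:
        df["label"] = df["id"]
    if "role" not in df.columns:
        df["role"] = "none"
    df.loc[df["role"] == "", "role"] = "none"
    problems = []
    dup = df[df["id"].duplicated(keep=False)]
    for i in dup.index:
        problems.append(f"row {i + 2}: duplicate id {df.at[i, 'id']!r}")
    bad_type = df[~df["node_type"].isin(kg.NODE_TYPES)]
    for i in bad_type.index:
        problems.append(f"row {i + 2}: unknown node_type {df.at[i, 'node_type']!r}")
    if problems:
        raise TableValidationError(f"{path}: " + "; ".join(problems[:20]))
    return df[NODE_COLUMNS]


def read_edges(path, node_ids=None) -> pd.DataFrame:
    df = _read_tsv(path, EDGE_COLUMNS)
    problems = []
    bad_rel = df[~df["relation"].isin(kg.RELATIONS)]
    for i in bad_rel.index:
        problems.append(f"row {i + 2}: unknown relation {df.at[i, 'relation']!r}")
    if node_ids is not None:
        known = set(node_ids)
        for col in ("source", "target"):
            for i in df.index[~df[col].isin(known)]:
                problems.append(f"row {i + 2}: {col} {df.at[i, col]!r} not in node table")
    if problems:
        raise TableValidationError(f"{path}: " + "; ".join(problems[:20]))
    return df[EDGE_COLUMNS]


def read_annotations(path) -> pd.DataFrame:
    df = _read_tsv(path, ANNOTATION_COLUMNS)
    truthy = {"1", "true", "True", "yes"}
    for col in ("pediatric", "respiratory_only"):
        df[col] = df[col].isin(truthy)
    return df[ANNOTATION_COLUMNS]


def read_similarity_values(path) -> pd.DataFrame:
    """Read a raw similarity table (e.g. the reference study's released
    supplementary values): target_id, candidate_id, metric, value."""
    df = _read_tsv(path, SIMILARITY_COLUMNS)
    df["value"] = df["value"].astype(float)
    return df


def load_graph(nodes_path, edges_path) -> kg.KnowledgeGraph:
    nodes_df = read_nodes(nodes_path)
    edges_df = read_edges(edges_path, node_ids=nodes_df["id"])
    nodes = [kg.NodeRecord(**row) for row in nodes_df.to_dict("records")]
    edges = [kg.EdgeRecord(**row) for row in edges_df.to_dict("records")]
    return kg.build_graph(nodes, edges)


def write_similarities(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = table.copy()
    out["value"] = out["value"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def write_embeddings(embeddings: EmbeddingSet, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(embeddings.H, columns=[f"e{j}" for j in range(embeddings.H.shape[1])])
    df.insert(0, "node_id", embeddings.node_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g", encoding="utf-8")
    return path


def graph_summary(graph: kg.KnowledgeGraph) -> dict:
    return {
        "n_nodes": graph.n_nodes,
        "n_edges": len(graph.edges),
        "node_counts": graph.type_counts(),
        "relation_counts": graph.relation_counts(),
    }


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def stage_seed(base_seed: int, stage: str) -> int:
    """Independent per-stage stream: stable hash of (seed, stage), < 2^31."""
    digest = hashlib.blake2b(f"{base_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Full-pipeline configuration (mirrors the CLI flags / TOML file)."""

    nodes: str = "nodes.tsv"
    edges: str = "edges.tsv"
    annotations: str | None = None
    out_dir: str = "presim_out"
    train: TrainConfig = field(default_factory=TrainConfig)
    metrics: tuple[str, ...] = METRICS
    cosine_threshold: float = DEFAULT_THRESHOLDS["cosine"]
    jaccard_threshold: float = DEFAULT_THRESHOLDS["jaccard"]
    feature_scheme: str = "identity"
    log_level: str = "INFO"

    def __post_init__(self):
        if not -1.0 <= self.cosine_threshold <= 1.0:
            raise ValueError("cosine threshold must be in [-1, 1]")
        if not 0.0 <= self.jaccard_threshold <= 1.0:
            raise ValueError("jaccard threshold must be in [0, 1]")
        for m in self.metrics:
            if m not in METRICS:
                raise ValueError(f"unknown metric {m!r}")

    def threshold(self, metric: str) -> float:
        return self.cosine_threshold if metric == "cosine" else self.jaccard_threshold

    @classmethod
    def from_toml(cls, path, **overrides) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        train_cfg = TrainConfig(**data.pop("train", {}))
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "metrics" in data:
            data["metrics"] = tuple(data["metrics"])
        return cls(train=train_cfg, **data)


def run_pipeline(config: RunConfig) -> dict:
    """build -> train -> similarity (both metrics) -> summarize -> screen ->
    apply_exclusions; writes all artifacts plus a reproducibility manifest.

    Returns a dict of artifact paths and in-memory results.  Idempotent for
    a fixed seed.  Training is skipped when cosine is not requested."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    logger.info("stage=build nodes=%s edges=%s", config.nodes, config.edges)
    graph = load_graph(config.nodes, config.edges)
    (out / "graph_summary.json").write_text(
        json.dumps(graph_summary(graph), indent=2) + "\n", encoding="utf-8"
    )

    embeddings = None
    final_objective = None
    if "cosine" in config.metrics:
        logger.info("stage=train hidden_units=%d epochs=%d",
                    config.train.hidden_units, config.train.epochs)
        features = kg.init_features(graph, config.feature_scheme)
        embeddings, history = train(
            graph, config.train, features=features, return_history=True
        )
        final_objective = history[-1] if history else None
        write_embeddings(embeddings, out / "embeddings.tsv")

    annotations = (
        read_annotations(config.annotations) if config.annotations else None
    )

    results: dict = {"graph": graph, "embeddings": embeddings, "paths": {}}
    stats_obj: dict = {}
    tables = []
    for metric in config.metrics:
        logger.info("stage=similarity metric=%s", metric)
        table = pairwise_similarity(graph, embeddings=embeddings, metric=metric)
        tables.append(table)
        stats_obj[metric] = summarize(table["value"].to_numpy()).as_dict()
        screened = screen(table, config.threshold(metric))
        if annotations is not None:
            screened = apply_exclusions(screened, annotations)
        parts = [screened.pairs.assign(status="retained", reason="")]
        if len(screened.excluded):
            parts.append(screened.excluded.assign(status="excluded"))
        report = pd.concat(parts, ignore_index=True)
        path = out / f"screen_{metric}.tsv"
        report.to_csv(path, sep="\t", index=False, encoding="utf-8")
        results[metric] = {"table": table, "screen": screened}
        results["paths"][f"screen_{metric}"] = path

    sim_path = write_similarities(pd.concat(tables, ignore_index=True),
                                  out / "similarities.tsv")
    stats_path = out / "stats.json"
    stats_path.write_text(json.dumps(stats_obj, indent=2) + "\n", encoding="utf-8")

    manifest = {
        "package_version": _pkg_version("presim"),
        "seed": config.train.seed,
        "final_objective": final_objective,
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "train"},
            "train": asdict(config.train),
        },
        "input_sha256": {
            "nodes": _sha256(config.nodes),
            "edges": _sha256(config.edges),
            **({"annotations": _sha256(config.annotations)}
               if config.annotations else {}),
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                             encoding="utf-8")
    results["paths"].update(
        {"similarities": sim_path, "stats": stats_path, "manifest": manifest_path,
         "out_dir": out}
    )
    return results
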