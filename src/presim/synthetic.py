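"""Synthetic knowledge-graph generator with planted prescription clusters.

Emulates the shape of the reference dataset — 87 prescriptions (20 target,
67 candidate) linked to diseases, symptoms, herbs, herb attributes,
ingredients and molecular targets in the proportions of its node-count
table — while planting ground-truth structure: prescriptions are grouped
into clusters, and members of a cluster draw their herbs, diseases and
symptoms from a shared per-cluster pool with probability
``within_cluster_overlap`` (otherwise uniformly from the whole universe).
Same-cluster target/candidate pairs are thereby designated similar, making
similarity recovery testable end to end without any external data.

Node ids are opaque; no attempt is made at pharmacological realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd


class ParameterError(ValueError):
    """Infeasible generator parameters (e.g. cluster pool too small)."""


@dataclass
class SyntheticParams:
    """Generator knobs.  Defaults are ~1/10 of the reference dataset's node
    counts, except prescriptions (kept at the full 20 + 67, since they are
    the objects under study) and the small closed attribute vocabularies
    (property/flavor/meridian/category, kept at full size)."""

    n_target: int = 20
    n_candidate: int = 67
    n_disease: int = 9
    n_symptom: int = 12
    n_disease_target: int = 1086
    n_herb: int = 19
    n_property: int = 5
    n_flavor: int = 12
    n_meridian: int = 12
    n_category: int = 35
    n_ingredient: int = 130
    n_ingredient_target: int = 253

    n_clusters: int = 3
    within_cluster_overlap: float = 0.8

    herbs_per_prescription: int = 6
    diseases_per_prescription: int = 3
    symptoms_per_prescription: int = 4
    targets_per_disease: int = 30
    ingredients_per_herb: int = 7
    max_targets_per_ingredient: int = 4
    max_flavors_per_herb: int = 3
    max_meridians_per_herb: int = 3

    seed: int = 0

    @property
    def background_degree(self) -> int:
        """Mean direct attribute links per prescription."""
        return (
            self.herbs_per_prescription
            + self.diseases_per_prescription
            + self.symptoms_per_prescription
        )

    @classmethod
    def paper_scale(cls, **overrides) -> "SyntheticParams":
        """Full reference-dataset node counts (15,210 nodes in total)."""
        full = dict(
            n_disease=84, n_symptom=113, n_disease_target=10856, n_herb=183,
            n_ingredient=1294, n_ingredient_target=2529,
        )
        full.update(overrides)
        return cls(**full)

    def validate(self) -> None:
        counts = {k: v for k, v in asdict(self).items() if k.startswith("n_")}
        if any(v < 1 for v in counts.values()):
            raise ParameterError("all counts must be positive")
        if not 0.0 <= self.within_cluster_overlap <= 1.0:
            raise ParameterError("within_cluster_overlap must be in [0, 1]")
        for name, universe, per in (
            ("herb", self.n_herb, self.herbs_per_prescription),
            ("disease", self.n_disease, self.diseases_per_prescription),
            ("symptom", self.n_symptom, self.symptoms_per_prescription),
        ):
            pool = universe // self.n_clusters
            if pool < per:
                raise ParameterError(
                    f"{name} cluster pool ({pool}) smaller than draws per "
                    f"prescription ({per}); enlarge n_{name} or reduce n_clusters"
                )


@dataclass
class GroundTruth:
    """Cluster assignment per prescription plus the designated-similar
    (target, candidate) pairs (same-cluster pairs)."""

    clusters: dict[str, int]
    similar_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"clusters": self.clusters,
             "similar_pairs": [list(p) for p in self.similar_pairs]},
            indent=2, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            clusters=obj["clusters"],
            similar_pairs=[tuple(p) for p in obj["similar_pairs"]],
        )


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _cluster_draw(rng, k, pool, universe, overlap):
    """k draws without replacement: ~Binomial(k, overlap) from the cluster
    pool, the rest from the remaining universe."""
    n_shared = min(int(rng.binomial(k, overlap)), len(pool), k)
    shared = list(rng.choice(pool, size=n_shared, replace=False))
    rest_universe = [u for u in universe if u not in set(shared)]
    rest = list(rng.choice(rest_universe, size=k - n_shared, replace=False))
    return shared + rest


def generate_kg(params: SyntheticParams | None = None):
    """Generate (node table, edge table, ground truth); fully seeded.

    Returns two DataFrames in the nodes.tsv / edges.tsv dialect plus a
    :class:`GroundTruth`.
    """
    p = params or SyntheticParams()
    p.validate()
    rng = np.random.default_rng(p.seed)

    pres = _ids("presc_t", p.n_target) + _ids("presc_c", p.n_candidate)
    roles = ["target"] * p.n_target + ["candidate"] * p.n_candidate
    dis = _ids("dis", p.n_disease)
    sym = _ids("sym", p.n_symptom)
    dtg = _ids("dtg", p.n_disease_target)
    herb = _ids("herb", p.n_herb)
    prop = _ids("prop", p.n_property)
    flav = _ids("flav", p.n_flavor)
    meri = _ids("meri", p.n_meridian)
    cat = _ids("cat", p.n_category)
    ing = _ids("ing", p.n_ingredient)
    itg = _ids("itg", p.n_ingredient_target)

    nodes = []
    for ids, ntype, rs in (
        (pres, "prescription", roles), (dis, "disease", None),
        (sym, "symptom", None), (dtg, "disease_target", None),
        (herb, "herb", None), (prop, "property", None), (flav, "flavor", None),
        (meri, "meridian", None), (cat, "category", None),
        (ing, "ingredient", None), (itg, "ingredient_target", None),
    ):
        for i, nid in enumerate(ids):
            nodes.append(
                {"id": nid, "node_type": ntype, "label": nid,
                 "role": rs[i] if rs else "none"}
            )

    # disjoint per-cluster pools of herbs/diseases/symptoms
    pools = {}
    for name, universe in (("herb", herb), ("disease", dis), ("symptom", sym)):
        size = len(universe) // p.n_clusters
        order = list(rng.permutation(universe))
        pools[name] = [order[c * size:(c + 1) * size] for c in range(p.n_clusters)]

    clusters = {pid: i % p.n_clusters for i, pid in enumerate(pres)}

    edges = []
    for pid in pres:
        c = clusters[pid]
        for name, universe, k, rel in (
            ("herb", herb, p.herbs_per_prescription, "prescription-herb"),
            ("disease", dis, p.diseases_per_prescription, "prescription-disease"),
            ("symptom", sym, p.symptoms_per_prescription, "prescription-symptom"),
        ):
            for other in _cluster_draw(
                rng, k, pools[name][c], universe, p.within_cluster_overlap
            ):
                edges.append({"source": pid, "target": other, "relation": rel})

    for d in dis:
        for t in rng.choice(dtg, size=min(p.targets_per_disease, len(dtg)), replace=False):
            edges.append({"source": d, "target": t, "relation": "disease-disease_target"})

    for h in herb:
        edges.append({"source": h, "target": rng.choice(prop),
                      "relation": "herb-property"})
        edges.append({"source": h, "target": rng.choice(cat),
                      "relation": "herb-category"})
        for f in rng.choice(flav, size=rng.integers(1, p.max_flavors_per_herb + 1),
                            replace=False):
            edges.append({"source": h, "target": f, "relation": "herb-flavor"})
        for m in rng.choice(meri, size=rng.integers(1, p.max_meridians_per_herb + 1),
                            replace=False):
            edges.append({"source": h, "target": m, "relation": "herb-meridian"})
        for i in rng.choice(ing, size=min(p.ingredients_per_herb, len(ing)),
                            replace=False):
            edges.append({"source": h, "target": i, "relation": "herb-ingredient"})

    for i in ing:
        for t in rng.choice(itg, size=rng.integers(1, p.max_targets_per_ingredient + 1),
                            replace=False):
            edges.append({"source": i, "target": t,
                          "relation": "ingredient-ingredient_target"})

    targets = pres[: p.n_target]
    candidates = pres[p.n_target:]
    similar = [
        (t, c) for t in targets for c in candidates if clusters[t] == clusters[c]
    ]
    truth = GroundTruth(clusters=clusters, similar_pairs=similar)
    nodes_df = pd.DataFrame(nodes, columns=["id", "node_type", "label", "role"])
    edges_df = pd.DataFrame(edges, columns=["source", "target", "relation"])
    return nodes_df, edges_df, truth


def write_synthetic(params: SyntheticParams, out_dir) -> dict[str, Path]:
    """Generate and write nodes.tsv, edges.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes_df, edges_df, truth = generate_kg(params)
    paths = {
        "nodes": out / "nodes.tsv",
        "edges": out / "edges.tsv",
        "truth": out / "truth.json",
    }
    nodes_df.to_csv(paths["nodes"], sep="\t", index=False)
    edges_df.to_csv(paths["edges"], sep="\t", index=False)
    paths["truth"].write_text(truth.to_json() + "\n", encoding="utf-8")
    return paths


def recovery_metric(similarity_table: pd.DataFrame, truth: GroundTruth) -> float:
    """Separation score: mean similarity over designated-similar pairs minus
    mean over all other target x candidate pairs."""
    similar = set(truth.similar_pairs)
    if not similar:
        raise ValueError("ground truth designates no similar pairs")
    mask = [
        (t, c) in similar
        for t, c in zip(similarity_table["target_id"], similarity_table["candidate_id"])
    ]
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("no designated-similar pairs present in the table")
    if mask.all():
        raise ValueError("every pair is designated similar; no background to compare")
    values = similarity_table["value"].to_numpy(dtype=np.float64)
    return float(values[mask].mean() - values[~mask].mean())
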