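"""Pairwise prescription similarity: cosine on embeddings, Jaccard on sets.

Every target prescription is compared against every candidate, giving
``n_targets * n_candidates`` values per metric (20 x 67 = 1340 at the
reference dataset's scale).  The value distribution is summarized with the
same nine statistics used to characterize the reference results (mean, max,
min, SD, excess kurtosis, skewness, P25/P75/P95), then screened against a
threshold and post-filtered with indication-based exclusion rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dgi import EmbeddingSet
from .kg import DEFAULT_ATTRIBUTE_TYPES, KnowledgeGraph, attribute_set

METRICS = ("cosine", "jaccard")

#: Screening thresholds: cosine at the P95 of the reference distribution,
#: Jaccard at 0.50 because its P95 (0.32) does not indicate high similarity.
DEFAULT_THRESHOLDS = {"cosine": 0.77, "jaccard": 0.50}


def cosine(u, v) -> float:
    """Cosine of the angle between two vectors, in [-1, 1].

    A zero vector has no direction; its similarity is defined as 0 (with a
    warning) so degenerate inputs do not crash the pipeline.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        warnings.warn("cosine of a zero vector is undefined; returning 0.0")
        return 0.0
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def jaccard(a, b) -> float:
    """|a ∩ b| / |a ∪ b|, in [0, 1]; two empty sets give 0."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def pairwise_similarity(
    graph: KnowledgeGraph,
    embeddings: EmbeddingSet | None = None,
    metric: str = "cosine",
    included_types=DEFAULT_ATTRIBUTE_TYPES,
) -> pd.DataFrame:
    """All target x candidate similarity records for one metric.

    Cosine compares learned embedding vectors (all node information flows
    into them); Jaccard compares macro-level attribute sets.  Returns a
    DataFrame with columns target_id, candidate_id, metric, value.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    targets = graph.prescriptions(role="target")
    candidates = graph.prescriptions(role="candidate")
    if not targets or not candidates:
        raise ValueError(
            f"need at least one target and one candidate prescription "
            f"(got {len(targets)} targets, {len(candidates)} candidates)"
        )

    if metric == "cosine":
        if embeddings is None:
            raise ValueError("cosine similarity requires trained embeddings")
        T = embeddings.subset(targets)
        C = embeddings.subset(candidates)
        tn = np.linalg.norm(T, axis=1)
        cn = np.linalg.norm(C, axis=1)
        if np.any(tn == 0) or np.any(cn == 0):
            warnings.warn("zero-norm embedding encountered; its cosines set to 0.0")
        tn[tn == 0] = np.inf
        cn[cn == 0] = np.inf
        values = np.clip((T / tn[:, None]) @ (C / cn[:, None]).T, -1.0, 1.0)
    else:
        t_sets = [attribute_set(graph, t, included_types) for t in targets]
        c_sets = [attribute_set(graph, c, included_types) for c in candidates]
        values = np.array([[jaccard(a, b) for b in c_sets] for a in t_sets])

    rows = [
        (t, c, metric, values[i, j])
        for i, t in enumerate(targets)
        for j, c in enumerate(candidates)
    ]
    return pd.DataFrame(rows, columns=["target_id", "candidate_id", "metric", "value"])


@dataclass
class SummaryStats:
    """Nine-statistic distribution summary of a similarity vector."""

    mean: float
    max: float
    min: float
    sd: float
    kurtosis: float
    skewness: float
    p25: float
    p75: float
    p95: float
    n: int

    def as_dict(self) -> dict:
        return {
            "mean": self.mean, "max": self.max, "min": self.min, "sd": self.sd,
            "kurtosis": self.kurtosis, "skewness": self.skewness,
            "p25": self.p25, "p75": self.p75, "p95": self.p95, "n": self.n,
        }


def summarize(values) -> SummaryStats:
    """Distribution summary: sample SD (n-1), Fisher excess kurtosis,
    bias-corrected skewness, linear-interpolation percentiles.

    With n < 2 the moment statistics are undefined and reported as NaN.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot summarize an empty value list")
    small = x.size < 2
    if small:
        warnings.warn("n < 2: sd/kurtosis/skewness undefined, reported as NaN")
    constant = np.all(x == x[0])
    p25, p75, p95 = np.percentile(x, [25, 75, 95])
    return SummaryStats(
        mean=float(x.mean()),
        max=float(x.max()),
        min=float(x.min()),
        sd=float("nan") if small else float(x.std(ddof=1)),
        kurtosis=float("nan") if small or constant else float(sps.kurtosis(x, fisher=True, bias=False)),
        skewness=float("nan") if small or constant else float(sps.skew(x, bias=False)),
        p25=float(p25),
        p75=float(p75),
        p95=float(p95),
        n=int(x.size),
    )


@dataclass
class ScreenResult:
    metric: str
    threshold: float
    pairs: pd.DataFrame
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["target_id", "candidate_id", "metric", "value", "reason"]
        )
    )

    @property
    def n_retained(self) -> int:
        return len(self.pairs)


def screen(table: pd.DataFrame, threshold: float) -> ScreenResult:
    """Retain pairs with value >= threshold (inclusive: pairs sitting
    exactly at the cutoff are high-similarity findings)."""
    metrics = table["metric"].unique()
    if len(metrics) != 1:
        raise ValueError(f"screen expects a single-metric table, got {list(metrics)}")
    retained = table[table["value"] >= threshold].reset_index(drop=True)
    return ScreenResult(metric=str(metrics[0]), threshold=threshold, pairs=retained)


#: rule name -> annotation column it keys on.  Pairs touching a prescription
#: flagged pediatric, or one that only treats respiratory disease (cough and
#: asthma), are false positives for repositioning and are removed.
EXCLUSION_RULES = ("pediatric", "respiratory_only")


def apply_exclusions(
    result: ScreenResult,
    annotations: pd.DataFrame,
    rules=EXCLUSION_RULES,
) -> ScreenResult:
    """Move screened pairs whose target or candidate carries an excluded
    tag into ``excluded`` with the rule name; unannotated prescriptions are
    kept with a warning."""
    ann = annotations.set_index("prescription_id")
    keep_rows, drop_rows = [], []
    for row in result.pairs.itertuples(index=False):
        reason = None
        for rule in rules:
            for pid in (row.target_id, row.candidate_id):
                if pid not in ann.index:
                    warnings.warn(f"no annotation for {pid!r}; pair retained")
                    continue
                if bool(ann.loc[pid, rule]):
                    reason = rule
                    break
            if reason:
                break
        (drop_rows if reason else keep_rows).append(
            row._asdict() | ({"reason": reason} if reason else {})
        )
    pairs = pd.DataFrame(keep_rows, columns=result.pairs.columns)
    excluded = pd.DataFrame(
        drop_rows, columns=list(result.pairs.columns) + ["reason"]
    )
    if len(result.excluded):
        excluded = pd.concat([result.excluded, excluded], ignore_index=True)
    return ScreenResult(
        metric=result.metric, threshold=result.threshold, pairs=pairs, excluded=excluded
    )
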