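import itertools

import numpy as np
import pandas as pd
import pytest

from presim import (
    EmbeddingSet, TrainConfig, apply_exclusions, cosine, jaccard,
    pairwise_similarity, screen, summarize, train,
)
from presim.dgi import readout
from presim.synthetic import recovery_metric

from conftest import make_graph


class TestCosine:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ((3, 4), (3, 4), 1.0),
            ((1, 0), (0, 1), 0.0),
            ((1, 0), (-1, 0), -1.0),
            ((1, 1), (2, 2), 1.0),
        ],
    )
    def test_known_angles(self, u, v, expected):
        assert cosine(u, v) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="zero vector"):
            assert cosine((0, 0), (1, 2)) == 0.0

    def test_symmetry_and_range_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            u, v = rng.normal(size=5), rng.normal(size=5)
            assert cosine(u, v) == pytest.approx(cosine(v, u), abs=1e-12)
            assert -1.0 <= cosine(u, v) <= 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cosine((1, 2), (1, 2, 3))


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"x", "y"}, {"x", "y"}, 1.0),
            ({"x"}, {"y"}, 0.0),
            ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
            (set(), set(), 0.0),
            (set(), {"x"}, 0.0),
        ],
    )
    def test_known_sets(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)

    def test_exhaustive_on_six_element_universe(self):
        """Matches element-by-element enumeration for every subset pair."""
        universe = list(range(6))
        subsets = [
            frozenset(c)
            for r in range(7)
            for c in itertools.combinations(universe, r)
        ]
        for a in subsets:
            for b in subsets:
                inter = sum(1 for x in universe if x in a and x in b)
                union = sum(1 for x in universe if x in a or x in b)
                expected = inter / union if union else 0.0
                assert jaccard(a, b) == pytest.approx(expected, abs=1e-12)
                assert jaccard(a, b) == jaccard(b, a)


def _role_graph(n_targets, n_candidates):
    nodes = [(f"T{i}", "prescription", "target") for i in range(n_targets)]
    nodes += [(f"C{i}", "prescription", "candidate") for i in range(n_candidates)]
    nodes += [("H1", "herb")]
    edges = [(n[0], "H1", "prescription-herb") for n in nodes[: n_targets + n_candidates]]
    return make_graph(nodes, edges)


def _fake_embeddings(graph, d=4, seed=0):
    H = np.random.default_rng(seed).normal(size=(graph.n_nodes, d))
    return EmbeddingSet(H=H, summary=readout(H), node_ids=graph.node_ids)


class TestPairwiseSimilarity:
    @pytest.mark.parametrize("nt, nc", [(20, 67), (1, 1), (2, 3)])
    def test_pair_count_is_targets_times_candidates(self, nt, nc):
        graph = _role_graph(nt, nc)
        table = pairwise_similarity(graph, _fake_embeddings(graph), "cosine")
        assert len(table) == nt * nc
        assert table[["target_id", "candidate_id"]].drop_duplicates().shape[0] == nt * nc

    def test_missing_roles_rejected(self):
        graph = make_graph(
            [("T1", "prescription", "target"), ("H1", "herb")],
            [("T1", "H1", "prescription-herb")],
        )
        with pytest.raises(ValueError, match="candidate"):
            pairwise_similarity(graph, _fake_embeddings(graph), "cosine")

    def test_cosine_requires_embeddings(self, tiny_graph):
        with pytest.raises(ValueError, match="embeddings"):
            pairwise_similarity(tiny_graph, None, "cosine")

    def test_jaccard_route_uses_attribute_sets(self, tiny_graph):
        table = pairwise_similarity(tiny_graph, metric="jaccard")
        # P1: {H1,H2,D1,F1}; P2: {H1,S1,F1}; intersection {H1,F1}, union 5
        assert len(table) == 1
        assert table["value"].iloc[0] == pytest.approx(2 / 5)

    def test_cosine_self_similarity_is_one(self, mini_synthetic):
        graph, _ = mini_synthetic
        emb = train(graph, TrainConfig(hidden_units=8, epochs=3, seed=0))
        for pid in graph.prescriptions()[:10]:
            v = emb.vector(pid)
            assert cosine(v, v) == pytest.approx(1.0, abs=1e-9)

    def test_within_cluster_cosine_exceeds_background(self, default_synthetic):
        graph, truth = default_synthetic
        emb = train(graph, TrainConfig(hidden_units=32, epochs=26, seed=1))
        table = pairwise_similarity(graph, emb, "cosine")
        assert recovery_metric(table, truth) > 0.05


class TestSummarize:
    def test_symmetric_sample(self):
        stats = summarize([1, 2, 3, 4, 5])
        assert stats.mean == 3
        assert stats.skewness == pytest.approx(0.0, abs=1e-12)
        assert stats.sd == pytest.approx(np.sqrt(2.5), abs=1e-9)

    def test_constant_sample(self):
        stats = summarize([0.4] * 10)
        assert stats.sd == 0.0
        assert stats.p25 == stats.p95 == 0.4

    def test_single_value_flags_undefined_moments(self):
        with pytest.warns(UserWarning, match="n < 2"):
            stats = summarize([0.3])
        assert stats.mean == 0.3
        assert np.isnan(stats.sd) and np.isnan(stats.kurtosis)

    def test_matches_textbook_oracle_on_random_samples(self):
        """Sample SD, bias-corrected skewness G1 and excess kurtosis G2
        recomputed from raw central moments."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.gamma(2.0, size=rng.integers(10, 1000))
            n = x.size
            m = x.mean()
            m2 = ((x - m) ** 2).mean()
            m3 = ((x - m) ** 3).mean()
            m4 = ((x - m) ** 4).mean()
            sd = np.sqrt(n * m2 / (n - 1))
            g1 = m3 / m2 ** 1.5
            G1 = g1 * np.sqrt(n * (n - 1)) / (n - 2)
            g2 = m4 / m2 ** 2 - 3
            G2 = ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))
            stats = summarize(x)
            assert stats.sd == pytest.approx(sd, rel=1e-9)
            assert stats.skewness == pytest.approx(G1, rel=1e-9)
            assert stats.kurtosis == pytest.approx(G2, rel=1e-9)
            assert stats.min <= stats.p25 <= stats.p75 <= stats.p95 <= stats.max


def _table(values, metric="cosine"):
    return pd.DataFrame(
        {
            "target_id": [f"T{i}" for i in range(len(values))],
            "candidate_id": [f"C{i}" for i in range(len(values))],
            "metric": metric,
            "value": values,
        }
    )


class TestScreen:
    def test_threshold_is_inclusive(self):
        result = screen(_table([0.50, 0.77, 0.80]), 0.77)
        assert result.n_retained == 2
        assert (result.pairs["value"] >= 0.77).all()

    def test_threshold_above_max_retains_nothing(self):
        assert screen(_table([0.1, 0.2]), 0.95).n_retained == 0

    def test_raising_threshold_never_increases_retention(self):
        rng = np.random.default_rng(8)
        values = rng.random(200)
        counts = [screen(_table(values), t).n_retained
                  for t in np.linspace(0, 1, 21)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_mixed_metric_table_rejected(self):
        table = pd.concat([_table([0.5]), _table([0.5], metric="jaccard")])
        with pytest.raises(ValueError, match="single-metric"):
            screen(table, 0.5)


class TestApplyExclusions:
    def _annotations(self, ids, pediatric=(), respiratory=()):
        return pd.DataFrame(
            {
                "prescription_id": ids,
                "pediatric": [i in pediatric for i in ids],
                "respiratory_only": [i in respiratory for i in ids],
            }
        )

    def test_sixty_eight_to_twelve_bookkeeping(self):
        """Given annotations tagging 56 of 68 screened pairs as false
        positives, exactly 12 survive with rule-name audit trail."""
        rng = np.random.default_rng(1)
        targets = [f"T{i}" for i in range(5)]
        candidates = [f"C{i}" for i in range(68)]
        table = pd.DataFrame(
            {
                "target_id": rng.choice(targets, size=68),
                "candidate_id": candidates,
                "metric": "cosine",
                "value": rng.uniform(0.77, 0.88, size=68),
            }
        )
        result = screen(table, 0.77)
        assert result.n_retained == 68
        ann = self._annotations(
            targets + candidates,
            pediatric=set(candidates[:30]),
            respiratory=set(candidates[30:56]),
        )
        curated = apply_exclusions(result, ann)
        assert curated.n_retained == 12
        assert len(curated.excluded) == 56
        assert set(curated.excluded["reason"]) == {"pediatric", "respiratory_only"}

    def test_empty_rule_list_is_identity(self):
        result = screen(_table([0.8, 0.9]), 0.77)
        ann = self._annotations(["T0", "T1", "C0", "C1"], pediatric={"C0"})
        out = apply_exclusions(result, ann, rules=())
        pd.testing.assert_frame_equal(out.pairs, result.pairs)

    def test_all_candidates_tagged_retains_nothing(self):
        result = screen(_table([0.8, 0.9]), 0.77)
        ann = self._annotations(["T0", "T1", "C0", "C1"], pediatric={"C0", "C1"})
        assert apply_exclusions(result, ann).n_retained == 0

    def test_missing_annotation_warns_and_retains(self):
        result = screen(_table([0.8]), 0.77)
        ann = self._annotations(["T0"])
        with pytest.warns(UserWarning, match="no annotation"):
            out = apply_exclusions(result, ann)
        assert out.n_retained == 1
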