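"""Correlation gates, the hypergeometric sponge test (with enumeration
oracle), network assembly and summaries."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from spongenet import network


def enumeration_sponge_p(N: int, K: int, n: int, k: int) -> float:
    """P(|A ∩ B| >= k) by exhaustive enumeration of all n-subsets."""
    universe = range(N)
    a = set(range(K))
    total = hits = 0
    for b in itertools.combinations(universe, n):
        total += 1
        hits += len(a & set(b)) >= k
    return hits / total


class TestSpearman:
    def test_antimonotone_is_minus_one(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        assert network.spearman(x, -(x**3)) == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        assert network.spearman([1, 2, 3], [2, 1, 3]) == pytest.approx(0.5)

    def test_constant_flagged_undefined(self):
        assert math.isnan(network.spearman([1, 2, 3], [5, 5, 5]))

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x, y = rng.normal(size=(2, 8))
            assert network.spearman(x, y) == pytest.approx(
                stats.spearmanr(x, y).statistic
            )

    @given(
        st.lists(st.integers(min_value=-100, max_value=100), min_size=4, max_size=12, unique=True),
        st.sampled_from(["exp", "cube", "affine"]),
    )
    def test_invariant_under_monotone_transform(self, xs, transform):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        y = rng.permutation(len(xs)).astype(float)
        x = np.array(xs, dtype=float)
        fx = {"exp": np.exp(x / 50), "cube": x**3, "affine": 3 * x + 7}[transform]
        assert network.spearman(fx, y) == pytest.approx(network.spearman(x, y))


class TestSpongeTest:
    def test_derived_instance(self):
        # N=10, K=4, n=3, k=2 -> 40/120
        res = network.sponge_test(
            set("abcd"), {"a", "b", "j"}, set("abcdefghij")
        )
        assert res.k == 2
        assert res.pvalue == pytest.approx(40 / 120)
        assert res.pvalue == pytest.approx(enumeration_sponge_p(10, 4, 3, 2))

    def test_zero_overlap_is_one(self):
        res = network.sponge_test({"a"}, {"b"}, set("abcdef"))
        assert res.pvalue == 1.0

    def test_identical_sets_match_enumeration(self):
        for N, n in [(6, 2), (8, 3), (10, 4)]:
            universe = {f"m{i}" for i in range(N)}
            s = set(sorted(universe)[:n])
            res = network.sponge_test(s, s, universe)
            assert res.pvalue == pytest.approx(1 / math.comb(N, n))
            assert res.pvalue == pytest.approx(enumeration_sponge_p(N, n, n, n))

    def test_enumeration_oracle_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(60):
            N = int(rng.integers(2, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = {f"m{i}" for i in range(N)}
            a = set(rng.choice(sorted(universe), size=K, replace=False))
            b = set(rng.choice(sorted(universe), size=n, replace=False))
            res = network.sponge_test(a, b, universe)
            assert res.pvalue == pytest.approx(
                enumeration_sponge_p(N, K, n, res.k), abs=1e-12
            )

    def test_pmf_sums_to_one(self):
        for N, K, n in [(10, 4, 3), (12, 6, 5), (7, 7, 3)]:
            support = np.arange(max(0, n + K - N), min(K, n) + 1)
            total = stats.hypergeom.pmf(support, N, K, n).sum()
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            network.sponge_test(set(), set(), set())


def _expr(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"s{i}" for i in range(6)])


class TestCorrelationGates:
    def test_negative_pair_retained_and_boundary(self):
        expr = _expr({
            "miRNA_1": [1, 2, 3, 4, 5, 6],
            "t_anti": [6, 5, 4, 3, 2, 1],        # rho = -1
            "t_weak": [2, 1, 4, 3, 6, 5],        # rho with x = +0.77 -> excluded
        })
        rel = {("miRNA_1", "t_anti"), ("miRNA_1", "t_weak")}
        out = network.negative_pairs(expr, rel)
        assert set(out["target_id"]) == {"t_anti"}

    def test_scc_minus_069_excluded(self):
        # engineered rank correlation strictly between -0.7 and 0
        expr = _expr({"m": [1, 2, 3, 4, 5, 6], "t": [4, 5, 6, 1, 2, 3]})
        rho = network.spearman(expr.loc["m"], expr.loc["t"])
        assert rho > -0.7
        out = network.negative_pairs(expr, {("m", "t")})
        assert out.empty

    def test_non_target_excluded_despite_correlation(self):
        expr = _expr({"m": [1, 2, 3, 4, 5, 6], "t": [6, 5, 4, 3, 2, 1]})
        out = network.negative_pairs(expr, set())
        assert out.empty

    def test_positive_pairs_identical_vectors(self):
        expr = _expr({
            "m": [6, 5, 4, 3, 2, 1],
            "a": [1, 2, 3, 4, 5, 6],
            "b": [1, 2, 3, 4, 5, 6],
        })
        negative = network.negative_pairs(expr, {("m", "a"), ("m", "b")})
        pos = network.positive_pairs(expr, negative)
        assert len(pos) == 1 and pos["pcc"].iloc[0] == pytest.approx(1.0)

    def test_positive_pair_without_shared_mirna_excluded(self):
        expr = _expr({
            "m1": [6, 5, 4, 3, 2, 1],
            "m2": [5, 6, 4, 3, 2, 1],
            "a": [1, 2, 3, 4, 5, 6],
            "b": [1, 2, 3, 4, 5, 6],
        })
        negative = network.negative_pairs(expr, {("m1", "a"), ("m2", "b")})
        assert len(negative) == 2
        pos = network.positive_pairs(expr, negative)
        assert pos.empty


class TestBuildAndSummarize:
    def _toy_inputs(self, sponge_p=0.01):
        negative = pd.DataFrame(
            {"mirna_id": ["m1", "m1"], "target_id": ["a", "b"], "scc": [-0.9, -0.8]}
        )
        positive = pd.DataFrame(
            {"gene_a": ["a"], "gene_b": ["b"], "pcc": [0.95],
             "shared_mirnas": [frozenset({"m1"})]}
        )
        sponge = pd.DataFrame(
            {"gene_a": ["a"], "gene_b": ["b"], "k": [1], "K": [1], "n": [1],
             "N": [10], "pvalue": [sponge_p]}
        )
        classes = {"m1": "miRNA", "a": "mRNA", "b": "lncRNA"}
        return negative, positive, sponge, classes

    def test_empty_inputs_empty_network(self):
        g = network.build_network(
            pd.DataFrame(columns=["mirna_id", "target_id", "scc"]),
            pd.DataFrame(columns=["gene_a", "gene_b", "pcc", "shared_mirnas"]),
            pd.DataFrame(columns=["gene_a", "gene_b", "k", "K", "n", "N", "pvalue"]),
            classes={},
        )
        assert g.number_of_nodes() == 0

    def test_significant_pair_edge_present(self):
        g = network.build_network(*self._toy_inputs(sponge_p=0.01))
        assert g.has_edge("a", "b")
        assert g.edges["a", "b"]["edge_type"] == "cerna_pair"

    def test_pair_at_p_006_absent(self):
        g = network.build_network(*self._toy_inputs(sponge_p=0.06))
        assert not g.has_edge("a", "b")
        assert g.has_edge("m1", "a")  # targeting edges are kept

    def test_dangling_id_rejected(self):
        negative, positive, sponge, classes = self._toy_inputs()
        del classes["b"]
        with pytest.raises(ValueError, match="dangling"):
            network.build_network(negative, positive, sponge, classes)

    def test_cerna_endpoints_share_mirna_neighbor(self):
        g = network.build_network(*self._toy_inputs())
        for u, v, d in g.edges(data=True):
            if d["edge_type"] == "cerna_pair":
                shared = set(g.neighbors(u)) & set(g.neighbors(v))
                assert any(g.nodes[x]["node_type"] == "miRNA" for x in shared)

    def test_summary_counts(self):
        g = nx.Graph()
        for m in ("m1", "m2"):
            g.add_node(m, node_type="miRNA")
        for t in ("t1", "t2", "t3"):
            g.add_node(t, node_type="mRNA")
        for m, t in [("m1", "t1"), ("m1", "t2"), ("m2", "t2"), ("m2", "t3")]:
            g.add_edge(m, t, edge_type="mirna_target", scc=-0.8)
        table = network.summarize_network(g)
        row = table.set_index("Target_Type").loc["mRNA"]
        assert (row["Target_Num"], row["miRNA_Num"], row["Pairs_Num"]) == (3, 2, 4)
        # empty classes report zeros and the schema matches the standard layout
        assert list(table.columns) == ["Target_Type", "Target_Num", "miRNA_Num", "Pairs_Num"]
        assert (table.set_index("Target_Type").loc["circRNA"] == 0).all()


def test_threshold_relaxation_never_shrinks_edges(default_dataset):
    from spongenet import pipeline

    cfg, m, truth, mirnas, transcripts = default_dataset
    strict = pipeline.run_pipeline(m, mirnas, transcripts, truth=truth)
    relaxed = pipeline.run_pipeline(
        m, mirnas, transcripts, truth=truth, scc=-0.5, pcc=0.8, alpha=0.2
    )
    strict_edges = set(map(frozenset, strict.net.edges()))
    relaxed_edges = set(map(frozenset, relaxed.net.edges()))
    assert strict_edges <= relaxed_edges
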