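"""ceRNA network construction.

The selection chain follows the sponge-network recipe: (1) miRNA-transcript
pairs that are predicted targets AND strongly negatively rank-correlated
(Spearman <= -0.7 by default, comparator configurable); (2) transcript pairs
that share at least one such miRNA and are strongly positively correlated
(Pearson > 0.9); (3) a hypergeometric upper-tail test on the number of shared
miRNAs between the two transcripts' targeting sets against the miRNA
universe, keeping pairs with p < 0.05 (no multiplicity correction by default,
a BH option exists).

Correlations are computed on log2(normalized count + 1); Spearman is
rank-based and therefore unaffected by the transform. Ties get average ranks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

DEFAULT_SCC = -0.7
DEFAULT_PCC = 0.9
DEFAULT_ALPHA = 0.05


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (average ranks); NaN when undefined.

    A zero-variance vector has no rank ordering, so the coefficient is
    flagged undefined (NaN) rather than guessed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class SpongeTestResult:
    """Shared-miRNA sponge test for one candidate ceRNA pair."""

    gene_a: str
    gene_b: str
    k: int  # shared miRNAs
    K: int  # miRNAs targeting gene_a
    n: int  # miRNAs targeting gene_b
    N: int  # universe size
    pvalue: float

    def __post_init__(self):
        if not (self.k <= min(self.K, self.n) and max(self.K, self.n) <= self.N):
            raise ValueError("inconsistent hypergeometric counts")


def sponge_test(
    set_a: set[str],
    set_b: set[str],
    universe: set[str],
    gene_a: str = "a",
    gene_b: str = "b",
) -> SpongeTestResult:
    """Upper-tail hypergeometric P(X >= k) on the shared-miRNA count.

    ``set_a``/``set_b`` are the miRNA sets targeting each transcript; the
    universe is the miRNA pool both sets are drawn from.
    """
    if not universe:
        raise ValueError("empty miRNA universe")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("target sets must be subsets of the universe")
    N, K, n = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return SpongeTestResult(gene_a, gene_b, k, K, n, N, pvalue=min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Correlation gates
# ---------------------------------------------------------------------------


def negative_pairs(
    expr: pd.DataFrame,
    relation: set[tuple[str, str]],
    threshold: float = DEFAULT_SCC,
    inclusive: bool = True,
) -> pd.DataFrame:
    """miRNA-target pairs that are predicted targets and anti-correlated.

    ``expr`` is a features x samples matrix of (log) normalized expression
    restricted to differentially expressed features; pairs whose members are
    absent from it are dropped (they failed the DE gate). Returns columns
    mirna_id, target_id, scc.
    """
    rows = []
    for mirna_id, target_id in sorted(relation):
        if mirna_id not in expr.index or target_id not in expr.index:
            continue
        rho = spearman(expr.loc[mirna_id].to_numpy(), expr.loc[target_id].to_numpy())
        if math.isnan(rho):
            continue
        ok = rho <= threshold if inclusive else rho < threshold
        if ok:
            rows.append((mirna_id, target_id, rho))
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "scc"])


def positive_pairs(
    expr: pd.DataFrame,
    negative: pd.DataFrame,
    threshold: float = DEFAULT_PCC,
) -> pd.DataFrame:
    """Candidate ceRNA pairs: share >= 1 retained miRNA, Pearson > threshold.

    Candidates are the targets appearing in >= 1 negative pair. Returns
    columns gene_a, gene_b, pcc, shared_mirnas (frozenset), with gene_a <
    gene_b.
    """
    target_mirnas: dict[str, set[str]] = {}
    for _, row in negative.iterrows():
        target_mirnas.setdefault(row["target_id"], set()).add(row["mirna_id"])
    rows = []
    for a, b in itertools.combinations(sorted(target_mirnas), 2):
        shared = target_mirnas[a] & target_mirnas[b]
        if not shared:
            continue
        r = pearson(expr.loc[a].to_numpy(), expr.loc[b].to_numpy())
        if not math.isnan(r) and r > threshold:
            rows.append((a, b, r, frozenset(shared)))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc", "shared_mirnas"])


def sponge_tests_for_pairs(
    positive: pd.DataFrame,
    negative: pd.DataFrame,
    universe: set[str],
    adjust: bool = False,
) -> pd.DataFrame:
    """Sponge test per candidate pair; optional BH column across pairs."""
    target_mirnas: dict[str, set[str]] = {}
    for _, row in negative.iterrows():
        target_mirnas.setdefault(row["target_id"], set()).add(row["mirna_id"])
    results = []
    for _, row in positive.iterrows():
        res = sponge_test(
            target_mirnas[row["gene_a"]],
            target_mirnas[row["gene_b"]],
            universe,
            gene_a=row["gene_a"],
            gene_b=row["gene_b"],
        )
        results.append(res)
    df = pd.DataFrame(
        [(r.gene_a, r.gene_b, r.k, r.K, r.n, r.N, r.pvalue) for r in results],
        columns=["gene_a", "gene_b", "k", "K", "n", "N", "pvalue"],
    )
    if adjust and len(df):
        df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Assembly and summary
# ---------------------------------------------------------------------------


def build_network(
    negative: pd.DataFrame,
    positive: pd.DataFrame,
    sponge_results: pd.DataFrame,
    classes: dict[str, str],
    alpha: float = DEFAULT_ALPHA,
    use_fdr: bool = False,
) -> nx.Graph:
    """Assemble the typed ceRNA network.

    Nodes carry ``node_type`` (miRNA/mRNA/lncRNA/circRNA); miRNA-target edges
    carry the SCC, ceRNA-pair edges (kept only when sponge p < alpha) carry
    the PCC and sponge p-value.
    """
    missing = (
        (set(negative["mirna_id"]) | set(negative["target_id"])) - set(classes)
        if len(negative)
        else set()
    )
    if missing:
        raise ValueError(f"dangling ids without class labels: {sorted(missing)}")
    g = nx.Graph()
    for _, row in negative.iterrows():
        g.add_node(row["mirna_id"], node_type="miRNA")
        g.add_node(row["target_id"], node_type=classes[row["target_id"]])
        g.add_edge(
            row["mirna_id"], row["target_id"], edge_type="mirna_target", scc=row["scc"]
        )
    col = "fdr" if use_fdr else "pvalue"
    pmap = {
        frozenset((r["gene_a"], r["gene_b"])): r[col]
        for _, r in sponge_results.iterrows()
    }
    for _, row in positive.iterrows():
        key = frozenset((row["gene_a"], row["gene_b"]))
        p = pmap.get(key)
        if p is None or not p < alpha:
            continue
        g.add_edge(
            row["gene_a"],
            row["gene_b"],
            edge_type="cerna_pair",
            pcc=row["pcc"],
            sponge_p=float(p),
        )
    return g


def summarize_network(net: nx.Graph) -> pd.DataFrame:
    """Per-class tally of the retained miRNA-target relation.

    Columns follow the conventional layout Target_Type, Target_Num,
    miRNA_Num, Pairs_Num: distinct targets, distinct miRNAs and pair count
    per target RNA class.
    """
    per_class: dict[str, dict[str, set | int]] = {
        cls: {"targets": set(), "mirnas": set(), "pairs": 0}
        for cls in ("mRNA", "lncRNA", "circRNA")
    }
    for u, v, data in net.edges(data=True):
        if data.get("edge_type") != "mirna_target":
            continue
        if net.nodes[u].get("node_type") == "miRNA":
            mirna, target = u, v
        else:
            mirna, target = v, u
        cls = net.nodes[target].get("node_type")
        if cls not in per_class:
            continue
        per_class[cls]["targets"].add(target)
        per_class[cls]["mirnas"].add(mirna)
        per_class[cls]["pairs"] += 1
    rows = [
        (cls, len(d["targets"]), len(d["mirnas"]), d["pairs"])
        for cls, d in per_class.items()
    ]
    return pd.DataFrame(
        rows, columns=["Target_Type", "Target_Num", "miRNA_Num", "Pairs_Num"]
    )


def network_edges_frame(net: nx.Graph) -> pd.DataFrame:
    """Flatten a network into the edges.tsv layout."""
    rows = []
    for u, v, data in net.edges(data=True):
        if data["edge_type"] == "mirna_target":
            rows.append((u, v, "mirna_target", data["scc"], np.nan, np.nan))
        else:
            rows.append((u, v, "cerna_pair", data["pcc"], data["sponge_p"], np.nan))
    return pd.DataFrame(
        rows, columns=["source", "target", "edge_type", "statistic", "p", "fdr"]
    )
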