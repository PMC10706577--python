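"""Hypergeometric over-representation of annotation terms.

For each term with K annotated genes in a universe of N, and a study set of n
genes hitting k of them, the p-value is the upper tail P(X >= k) — the same
kernel as the shared-miRNA sponge test. P-values are BH-adjusted across terms
by default. Annotations are flat term -> gene sets (no ontology propagation).
The universe defaults to all annotated genes in the supplied map and is
explicitly configurable.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


def enrich(
    study: set[str],
    annotation: dict[str, set[str]],
    universe: set[str] | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-term enrichment table sorted by p-value then term id."""
    if not study:
        raise ValueError("empty study set")
    if universe is None:
        universe = set().union(*annotation.values()) if annotation else set()
    if not universe:
        raise ValueError("empty universe")
    if not study <= universe:
        raise ValueError("study set must be a subset of the universe")
    N, n = len(universe), len(study)
    rows = []
    for term_id in sorted(annotation):
        genes = annotation[term_id] & universe
        K = len(genes)
        k = len(genes & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, k, K, n, N, min(max(p, 0.0), 1.0)))
    table = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "pvalue"])
    table["fdr"] = bh_adjust(table["pvalue"].to_numpy()) if adjust and len(table) else pd.NA
    return table.sort_values(["pvalue", "term_id"], kind="stable").reset_index(drop=True)


def top_k(table: pd.DataFrame, k: int = 20, order: str = "pvalue") -> pd.DataFrame:
    """The k most-enriched terms; ties broken by term_id, then stably."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return (
        table.sort_values([order, "term_id"], kind="stable")
        .head(k)
        .reset_index(drop=True)
    )
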