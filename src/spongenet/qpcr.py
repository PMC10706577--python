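"""Relative quantification of qRT-PCR data by the Livak 2^-ddCt method.

dCt = Ct(target) - Ct(reference) per sample; ddCt = dCt - mean dCt of the
control group; fold change = 2^-ddCt and log2 fold = -ddCt exactly. No
amplification-efficiency correction is applied (pure Livak). Technical
replicates, when present, are averaged on the Ct scale before dCt;
biological replicates propagate to a mean +/- s.d. on the fold scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["sample_id", "group", "gene_id", "role", "ct"]


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    bad = set(table["role"]) - {"target", "reference"}
    if bad:
        raise ValueError(f"unknown role {sorted(bad)}")
    return table


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    control_group: str,
) -> pd.DataFrame:
    """Per-sample fold change of ``target`` normalized to ``reference``.

    Returns one row per sample: sample_id, group, delta_ct, ddct, fold,
    log2fold.
    """
    validate_ct_table(table)
    # technical replicates average on the Ct scale
    ct = (
        table.groupby(["sample_id", "group", "gene_id", "role"], as_index=False)["ct"]
        .mean()
    )
    tgt = ct[(ct["gene_id"] == target) & (ct["role"] == "target")]
    ref = ct[(ct["gene_id"] == reference) & (ct["role"] == "reference")]
    merged = tgt.merge(
        ref[["sample_id", "group", "ct"]],
        on=["sample_id", "group"],
        suffixes=("_target", "_ref"),
        how="left",
    )
    if merged["ct_ref"].isna().any():
        bad = merged.loc[merged["ct_ref"].isna(), "sample_id"].tolist()
        raise ValueError(f"samples without reference measurement: {bad}")
    if control_group not in set(merged["group"]):
        raise ValueError(f"control group {control_group!r} absent")
    merged["delta_ct"] = merged["ct_target"] - merged["ct_ref"]
    control_mean = merged.loc[merged["group"] == control_group, "delta_ct"].mean()
    merged["ddct"] = merged["delta_ct"] - control_mean
    merged["fold"] = 2.0 ** -merged["ddct"]
    merged["log2fold"] = -merged["ddct"]
    return merged[["sample_id", "group", "delta_ct", "ddct", "fold", "log2fold"]]


def group_fold_summary(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- s.d. of the fold change per group (biological replicates)."""
    return (
        per_sample.groupby("group")["fold"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "fold_mean", "std": "fold_sd", "count": "n"})
    )


def concordance(qpcr_log2fc: pd.Series, seq_log2fc: pd.Series) -> float:
    """Fraction of shared genes whose log2 fold changes agree in sign.

    Zero agrees only with zero.
    """
    shared = qpcr_log2fc.index.intersection(seq_log2fc.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between qPCR and sequencing tables")
    a = np.sign(qpcr_log2fc.loc[shared].to_numpy(dtype=float))
    b = np.sign(seq_log2fc.loc[shared].to_numpy(dtype=float))
    return float(np.mean(a == b))
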