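#!/usr/bin/env python
"""Validate sequencing calls with simulated qRT-PCR and 2^-ddCt.

Emulates the bench step: for a panel of DE features (and a couple of null
features), Ct values are generated so that the target's cycle shift matches
its planted expression change (one PCR cycle = one log2 unit), with a stable
reference gene and small measurement noise. The Livak 2^-ddCt fold changes
are then compared with the sequencing log2FC by sign concordance. Writes
results/qpcr_ct.csv and results/qpcr_folds.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from spongenet.qpcr import concordance, delta_delta_ct, group_fold_summary

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"
CT_NOISE_SD = 0.15  # cycles


def main() -> None:
    rng = np.random.default_rng(SEED)
    de = pd.read_csv(ROOT / "de.tsv", sep="\t").set_index("feature_id")
    panel = (
        list(de[(de["class"] == "miRNA") & (de["call"] == "up")].index[:3])
        + list(de[(de["class"] == "mRNA") & (de["call"] == "down")].index[:3])
        + list(de[(de["class"] == "lncRNA") & (de["call"] != "ns")].index[:2])
        + list(de[(de["class"] == "circRNA") & (de["call"] != "ns")].index[:2])
    )
    rows = []
    for gene in panel:
        log2fc = de.loc[gene, "log2fc"]
        ref_gene = "U6" if de.loc[gene, "class"] == "miRNA" else "18S"
        for g, shift in (("whole", 0.0), ("lobed", -log2fc)):
            for rep in range(1, 4):
                sid = f"{g}_{rep}"
                rows.append((sid, g, gene, "target",
                             22.0 + shift + rng.normal(0, CT_NOISE_SD), rep))
                rows.append((sid, g, ref_gene, "reference",
                             15.0 + rng.normal(0, CT_NOISE_SD), rep))
    ct = pd.DataFrame(rows, columns=["sample_id", "group", "gene_id", "role", "ct", "replicate"])
    ct.to_csv(ROOT / "qpcr_ct.csv", index=False)

    qpcr_fc = {}
    summaries = []
    for gene in panel:
        ref_gene = "U6" if de.loc[gene, "class"] == "miRNA" else "18S"
        sub = ct[ct["gene_id"].isin([gene, ref_gene])]
        per_sample = delta_delta_ct(sub, gene, ref_gene, control_group="whole")
        qpcr_fc[gene] = per_sample.loc[per_sample["group"] == "lobed", "log2fold"].mean()
        s = group_fold_summary(per_sample)
        s.insert(0, "gene", gene)
        summaries.append(s)
    folds = pd.concat(summaries, ignore_index=True)
    folds.to_csv(ROOT / "qpcr_folds.tsv", sep="\t", index=False)

    qpcr_series = pd.Series(qpcr_fc)
    seq_series = de.loc[panel, "log2fc"]
    agree = concordance(qpcr_series, seq_series)
    print(f"panel of {len(panel)} genes; sign concordance qPCR vs sequencing: {agree:.2f}")
    print(folds.to_string(index=False))
    print(f"-> {ROOT/'qpcr_folds.tsv'}")


if __name__ == "__main__":
    main()
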