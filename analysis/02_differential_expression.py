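#!/usr/bin/env python
"""Differential expression across the four RNA classes.

TMM normalization, the conditional NB exact test, BH adjustment within each
class, and the class-specific calls (mRNA/lncRNA on FDR < 0.05, miRNA/circRNA
on raw p < 0.05, all with |log2FC| > 1). Writes results/de.tsv and prints the
per-class up/down tally.
"""

from pathlib import Path

from spongenet.diffexpr import run_de
from spongenet.io import read_counts

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    m = read_counts(ROOT / "dataset" / "counts.tsv")
    table = run_de(m)
    table.to_csv(ROOT / "de.tsv", sep="\t", index=False)
    print(f"{(table['call'] != 'ns').sum()} of {len(table)} features called DE -> {ROOT/'de.tsv'}")
    for cls, sub in table.groupby("class"):
        up, down = (sub["call"] == "up").sum(), (sub["call"] == "down").sum()
        print(f"  {cls:8s} {up:4d} up {down:4d} down")


if __name__ == "__main__":
    main()
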