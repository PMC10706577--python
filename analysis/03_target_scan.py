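#!/usr/bin/env python
"""Scan differentially expressed transcripts for miRNA response elements.

Uses the plant-style complementarity penalty (mismatch 1, G:U 0.5, indel 2,
doubled at miRNA positions 2-13; cutoff 3.0) restricted to DE miRNAs vs DE
transcripts, since only those can enter the network. Writes results/hits.tsv
with 1-based inclusive coordinates.
"""

from pathlib import Path

import pandas as pd

from spongenet.io import read_fasta
from spongenet.targets import scan_targets

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    de = pd.read_csv(ROOT / "de.tsv", sep="\t")
    de_ids = set(de.loc[de["call"] != "ns", "feature_id"])
    mirnas = [r for r in read_fasta(ROOT / "dataset" / "mirnas.fa") if r.id in de_ids]
    transcripts = [
        r for r in read_fasta(ROOT / "dataset" / "transcripts.fa") if r.id in de_ids
    ]
    rows = []
    for mi in mirnas:
        for tr in transcripts:
            for h in scan_targets(mi, tr):
                rows.append((h.mirna_id, h.transcript_id, h.start + 1, h.end, h.score))
    hits = pd.DataFrame(
        rows, columns=["mirna_id", "transcript_id", "start", "end", "score"]
    )
    hits.to_csv(ROOT / "hits.tsv", sep="\t", index=False)
    n_pairs = hits[["mirna_id", "transcript_id"]].drop_duplicates().shape[0]
    print(f"{len(hits)} sites over {n_pairs} (miRNA, transcript) pairs "
          f"from {len(mirnas)} DE miRNAs x {len(transcripts)} DE transcripts -> {ROOT/'hits.tsv'}")


if __name__ == "__main__":
    main()
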