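#!/usr/bin/env python
"""Generate the synthetic two-condition whole-transcriptome dataset.

Emulates the study design: whole-leaf vs lobed-leaf, three replicates each,
four RNA classes, with 10 planted sponge modules (pairs of transcripts
sharing two suppressing miRNAs) plus background differential features.
Writes counts.tsv, mirnas.fa, transcripts.fa and truth.json under
results/dataset/.
"""

from pathlib import Path

from spongenet.synthetic import SimConfig, simulate_counts, simulate_sequences, write_dataset

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "dataset"


def main() -> None:
    cfg = SimConfig(n_sponge_modules=10, seed=SEED)
    m, truth = simulate_counts(cfg)
    mirnas, transcripts = simulate_sequences(cfg, truth)
    write_dataset(cfg, OUT, m, truth, mirnas, transcripts)
    n_de = len(truth.de_features)
    print(f"dataset: {m.counts.shape[0]} features x {m.counts.shape[1]} samples -> {OUT}")
    print(f"planted: {len(truth.sponge_pairs)} sponge pairs, "
          f"{len(truth.mirna_target_edges)} miRNA-target edges, {n_de} DE features")


if __name__ == "__main__":
    main()
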