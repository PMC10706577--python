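# spongenet

Inference of competing-endogenous-RNA (ceRNA) networks from two-condition
whole-transcriptome count data, built around the question of which
miRNA-mediated modules separate two plant phenotypes (the motivating case:
whole vs lobed mulberry leaves, three replicates per group, with mRNA,
lncRNA, circRNA and miRNA libraries). Because such studies rarely deposit
reusable raw data, the package pairs the analysis with a synthetic-data
generator that plants known sponge modules, so every stage can be validated
by recovery of ground truth.

## What it computes

Given a count matrix with per-feature RNA classes and per-sample groups, plus
FASTA sequences for miRNAs and transcripts:

1. **Differential expression** — TMM normalization, a conditional
   negative-binomial exact test on group sums (φ = 0 reduces to the exact
   binomial test), BH adjustment within each class, and class-specific calls:
   mRNA/lncRNA at FDR < 0.05, miRNA/circRNA at raw p < 0.05, both with
   |log2FC| > 1.
2. **MRE scanning** — plant-style complementarity penalties (mismatch 1,
   G:U wobble 0.5, indel 2, doubled at miRNA positions 2–13; cutoff 3.0).
3. **Network gates** — miRNA–target pairs with Spearman ρ ≤ −0.7; candidate
   ceRNA pairs sharing a miRNA with Pearson r > 0.9; and for each pair the
   shared-sponge test
   P(X ≥ k), X ~ Hypergeom(N, K, n), with K and n the two transcripts'
   miRNA-set sizes, k the overlap and N the miRNA universe; pairs kept at
   p < 0.05.
4. **Hairpin screening** — precursor candidates pass iff MFE < −18 kcal/mol,
   MFEI = (|MFE|/len×100)/GC% ≥ 0.85, ≤ 3 asymmetric bulges and ≤ 4
   mismatches in the mature:star duplex, mature within one arm.
5. **qRT-PCR quantification** — Livak 2^−ΔΔCt fold changes and sign
   concordance with sequencing log2FC.
6. **Enrichment & reporting** — hypergeometric term over-representation with
   top-20 reporting, spectral interpretation rates, Venn partitions, and a
   machine-readable run report.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic data
and write their tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_differential_expression.py
python analysis/03_target_scan.py
python analysis/04_cerna_network.py
```

Output of `04_cerna_network.py`:

```
Target_Type  Target_Num  miRNA_Num  Pairs_Num
       mRNA          14         20         28
     lncRNA           3          6          6
    circRNA           3          6          6

planted sponge pairs recovered: 10/10; false pairs: 0/10
```

The table counts, per target RNA class, the distinct targets, distinct
miRNAs and retained negatively-correlated pairs in the network; the last line
scores the network's ceRNA edges against the ten planted sponge modules —
here all ten are recovered with no false pair. The remaining drivers
(`05`–`08`) screen constructed hairpins, validate calls with simulated qPCR
(sign concordance 1.00 on a 10-gene panel), run enrichment (the two planted
signal terms rank first among 82), and aggregate everything into
`results/report.json`.

The same machinery is scriptable, e.g.:

```python
from spongenet.synthetic import SimConfig
from spongenet.pipeline import run_synthetic_pipeline

res = run_synthetic_pipeline(SimConfig(n_sponge_modules=10, seed=1))
print(res.summary)          # per-class network tally
print(res.recovery)         # {'recall': 1.0, 'false_pair_rate': 0.0, ...}
```

A thin CLI mirrors the stages (`spongenet simulate|de|targets|network|
hairpin|qpcr|enrich|report`); run `spongenet --help`.

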