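# Methods

`spongenet` implements a competing-endogenous-RNA (ceRNA) network inference
pipeline of the kind used to explain phenotypic contrasts (here: whole vs
lobed leaves) from whole-transcriptome count data, together with a synthetic
data generator that plants the structure the pipeline is supposed to detect.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic experiments do and do not demonstrate.

## The ceRNA model and selection chain

Transcripts (mRNA, lncRNA, circRNA) that carry response elements (MREs) for
the same miRNA compete for it; two transcripts sharing many targeting miRNAs
and co-varying positively are candidate sponge partners. The pipeline encodes
this as a chain of gates:

1. **Differential expression per class.** mRNA and lncRNA are gated on
   BH-adjusted FDR < 0.05, miRNA and circRNA on raw p < 0.05, all with
   |log2FC| > 1 (strict inequality). BH is applied within each RNA class,
   since the classes come from separate libraries with very different
   feature counts.
2. **Targeting + negative correlation.** A (miRNA, transcript) pair enters
   only if the transcript carries a predicted MRE and the pair's Spearman
   rank correlation over all samples is ≤ −0.7. The comparator is inclusive
   (≤); it is exposed as a parameter because usage in the field varies
   between "< −0.7" and "≤ −0.7" and the difference has measure zero on
   continuous data.
3. **Positive co-expression.** Unordered pairs of retained targets that share
   at least one retained miRNA and have Pearson correlation > 0.9.
4. **Shared-sponge test.** For target miRNA-sets A and B inside a universe of
   N miRNAs, the upper-tail hypergeometric probability
   P(X ≥ |A∩B|) with X ~ Hypergeom(N, |A|, |B|). Pairs with p < 0.05 are
   kept. P-values are used raw by default (a BH option exists but is off):
   the selection chain this mirrors applies no correction at this stage.
   The universe defaults to the differentially expressed miRNAs entering the
   stage; it is configurable to all detected miRNAs.

Correlations are computed on log2(normalized count + 1). Spearman is
rank-based, so the transform is irrelevant there; Pearson on the log scale is
the variant that tolerates the 4-fold planted shifts without being dominated
by them. With n = 6 samples the Spearman lattice is coarse; ties take average
ranks and no continuity correction is applied. Zero-variance vectors have no
rank ordering and are flagged undefined and excluded rather than imputed.

## Count model and the exact test

Counts are modelled NB(μ, φ) with variance μ + φμ²; φ = 0 degrades to
Poisson. Library sizes are normalized by trimmed-mean-of-M-values (TMM)
factors (30% trim on log-ratios, 5% on abundance, precision-weighted,
geometric mean 1). For testing, counts are rescaled to the geometric-mean
effective library size and rounded; then, writing n_g for the replicates in
group g, the group sum is NB(n_g μ, φ/n_g) and the conditional law of one
group's sum given the total is free of μ. The two-sided p-value sums the
conditional probabilities of all outcomes no more likely than the observed
one (ties included with a 1e-10 relative tolerance). At φ = 0 the conditional
law is Binomial(s, n_a/(n_a+n_b)) and the test is the exact binomial test.

This is an in-house conditional exact test in the spirit of the classical
count-based DE tools, not a re-implementation of any of them; equality with
edgeR output is neither claimed nor expected. Its calibration is checked
empirically: on 1000 simulated null features the rejection rate at nominal
0.05 stays within ±0.02 for φ ∈ {0, 0.2} (being a discrete exact test it
sits slightly below nominal, ~0.045–0.048 on average).

The common dispersion, when not supplied, is estimated by a robust
method-of-moments: per feature and group, (s² − μ̂)/μ̂² pooled across groups,
then the median over informative features, floored at 1e-4. The median (not
the mean) keeps a minority of genuinely differential or latently structured
features from inflating the estimate. The fold-change pseudo-count (prior)
defaults to 0.5.

## Target-site scoring

No specific predictor is prescribed for plant MRE scanning here, so the de
facto plant small-RNA penalty convention is used: antiparallel alignment of
the miRNA against each transcript window, penalties mismatch 1.0, G:U wobble
0.5, indel 2.0, all doubled at miRNA positions 2–13 (1-based, 5′ end), hit
cutoff 3.0. All parameters are configurable. Alignment is gap-limited: at
most one unopposed base on either strand, enumerated over window lengths
L−1, L, L+1 with prefix/suffix sums rather than full dynamic programming —
O(L·k) per miRNA/transcript pair, vectorized. An indel's doubling position is
taken from the adjacent miRNA position (capped at the 3′ end for a terminal
gap). Overlapping hits are all reported; the downstream relation is a set of
(miRNA, transcript) pairs, so duplicates collapse. Scores are invariant to
T/U spelling and case. "Family" grouping is reduced to a seed-identity
utility (identical positions 2–8 ⇒ same family); no remote queries.

## Hairpin screening

Precursor candidates arrive as sequence + dot-bracket + MFE (Vienna format);
folding itself is out of scope. A candidate passes when all of:
MFE < −18 kcal/mol (strict); MFEI ≥ 0.85 where AMFE = |MFE|/length×100 and
MFEI = AMFE/GC%; ≤ 3 asymmetric bulge events; ≤ 4 mismatches; and the mature
sequence lies within one arm. The "≥ 0.85" energy criterion is implemented as
the MFEI — the standard plant-precursor index with exactly that magnitude —
because a literal folding free energy of +0.85 kcal/mol is physically
meaningless for a gate used together with "below −18 kcal/mol".

Duplex metrics walk the mature arm between consecutive paired positions:
g_m unpaired mature bases opposite g_s unpaired star bases contribute
min(g_m, g_s) mismatches and, when g_m ≠ g_s, one asymmetric bulge event of
|g_m − g_s| bases. Bulge counting is event-based because "asymmetrically
bulging base pairs" is ambiguous between events and bases; both counts are
reported and the event count gates. Unpaired mature bases at the span
boundary have no defined opposing run and are counted as mismatches
(conservative). The terminal loop is the unpaired stretch between the
innermost base pair; a mature span overlapping it is rejected for duplex
metrics and fails the screen.

## qRT-PCR quantification

Pure Livak: ΔCt = Ct(target) − Ct(reference) per sample, ΔΔCt = ΔCt − mean
ΔCt of the control group, fold = 2^−ΔΔCt, log2 fold = −ΔΔCt exactly. No
amplification-efficiency correction. Technical replicates are averaged on the
Ct scale before ΔCt; biological replicates propagate to mean ± s.d. on the
fold scale. The reference gene is per-assay configurable (the convention
followed by the analysis driver: U6 for miRNA assays, 18S rRNA otherwise;
β-actin appears in some validation designs, which is why this is a parameter
and not a constant). Concordance between qPCR and sequencing is the fraction
of shared genes with matching log2FC sign, zero agreeing only with zero.

## Enrichment

Term over-representation uses the same hypergeometric upper-tail kernel as
the sponge test, against a universe defaulting to all annotated genes in the
supplied term→gene map (a "genomic background" is version-bound and must be
supplied explicitly when available). Annotations are flat sets — no GO DAG
propagation. BH across terms is on by default here (unlike the sponge stage)
since term lists are long and reported as tables; top-k reporting (default
20) breaks p-value ties by term id for determinism.

## The synthetic generator

`SimConfig` defaults define the emulated study: 200 mRNA / 40 lncRNA /
10 circRNA / 20 miRNA, two groups × 3 replicates, NB counts with baseline
mean 300 (per-feature lognormal spread, σ = 0.5), dispersion φ = 0.03,
library-size factors U(0.8, 1.25). Planted structure: sponge modules (default
5; the recovery study uses 10), each with 2 member transcripts (always ≥ 1
mRNA, partner class cycling through mRNA/lncRNA/circRNA) and
`mre_per_module` = 2 miRNAs drawn disjointly across modules while the miRNA
class allows. Module miRNAs are up-regulated in group 2 by 2^de_log2fc
(default 4×); members are multiplied by `suppression` (default 0.25). Two
shared miRNAs per module is the minimum that makes a planted pair detectable
by the sponge test at p < 0.05 for universes up to ~45 miRNAs (k = K = n = 1
gives p = n·K/N ≥ 0.05 there), so it is the defensible default for a
generator whose planted pairs are meant to be recoverable. Another 5% of each
class is background-differential with no network role.

Mean shifts alone do not guarantee rank correlation at n = 6, so each module
also carries a latent expression pattern: a centered within-group contrast
(linspace(−1, 1) over replicates, permuted independently per group and
module) loading +latent_log2 on the module miRNAs and −latent_log2 on the
members (default 1.0 on the log2 scale). Because the contrast is centered and
identical in magnitude for both loadings, group sums — the statistic the
exact test conditions on — are scaled by the same constant in both groups,
so the latent adds within-group correlation without corrupting DE testing.
Dispersion and library-size figures have no observed counterpart to copy;
they are frank choices exposed in the config.

Sequences: 21-nt mature miRNAs, uniform-random transcripts (default 400 nt)
with one embedded reverse-complement MRE per planted edge, carrying 0 or
`max_defects` (default ≤ 1) substitutions placed uniformly. Hairpins are
constructed, not folded: flank + mature arm + loop + modified reverse
complement + flank, with the dot-bracket derived from the construction and
the MFE an assigned annotation. Construction guarantees `duplex_metrics`
returns exactly the planted (mismatch, bulge) counts; defects are kept off
the mature ends, and bulge gaps avoid mismatch-adjacent positions so events
never merge.

Determinism: one seed drives everything; equal seeds give byte-identical
files. The sequence stream is spawned from (seed, 1) so counts and sequences
are independent draws but jointly reproducible. The CLI requires no seed but
draws and logs one when omitted.

### What the synthetic experiments show — and what they don't

Passing the recovery study (≥ 80% of planted pairs recovered, ≤ 10% false
pairs over 25 seeds at the strong configuration) shows the selection chain is
internally consistent and well-calibrated against data satisfying its own
assumptions: NB margins, monotone miRNA→target suppression, genuinely shared
MREs, uncorrelated background. Real tissue data violate all of these to some
degree — correlated co-expression programs unrelated to miRNA sharing,
isoform ambiguity, expression-dependent dispersion, predictor error on real
sites. Recovery rates here are therefore upper bounds of an idealized regime,
not estimates of sensitivity on real libraries. Likewise, the generator's
hairpins certify the metric walk, not thermodynamic plausibility.

## Problem sizes and defaults used in checks

The shipped checks use: 25 seeds × (270 features × 6 samples) for recovery;
1000 null features per dispersion setting for calibration; 500 random
instances with universe ≤ 12 for the enumeration oracle (exhaustive subsets);
the 7 × 5 (mismatch × bulge) hairpin grid. These sizes give Monte-Carlo
standard errors comfortably below the margins being asserted while keeping a
full run in the low minutes on one core.

## Known limitations

* The exact test assumes a common dispersion and equalized libraries; no
  GLM designs, batch covariates, or per-feature dispersion shrinkage.
* Gap-limited alignment misses multi-indel sites (rare in plant MREs but not
  impossible); no thermodynamic duplex energies.
* The hairpin walk assumes a clean two-arm stem-loop; multiloop-containing
  structures are outside its contract.
* The GenBank fetch helper requires network access; nothing else does.
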