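"""Synthetic data with planted ground truth for the ceRNA pipeline.

The generator emulates a two-condition (whole-leaf vs lobed-leaf) design with
three replicates per group across four RNA classes. Counts are negative
binomial with variance mu + phi * mu^2 (phi = 0 degrades to Poisson). The
planted structure mirrors what the analysis is supposed to detect:

* sponge modules: each module picks ``mre_per_module`` miRNAs (up-regulated
  in group 2 by 2^de_log2fc) and two member transcripts whose group-2 means
  are multiplied by ``suppression`` — the targets of an up-regulated miRNA
  are knocked down;
* a per-module latent expression pattern (a centered within-group contrast,
  permuted per module) loads positively on the module's miRNAs and
  negatively on its members. Mean shifts alone do not guarantee rank
  correlation at n = 6, and because the contrast is centered the group sums
  (what the exact test conditions on) are unaffected;
* background differential features in every class with no network role.

Sequences: 21-nt mature miRNAs; transcripts carry an embedded
reverse-complement MRE for every planted (miRNA, transcript) edge, with at
most ``max_defects`` substitutions. Hairpins are constructed (not folded):
the MFE is an assigned annotation, and the dot-bracket encodes exactly the
planted mismatches and asymmetric bulges.

Determinism: the same seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    CountMatrix,
    FastaRecord,
    StructureRecord,
    write_counts,
    write_fasta,
    write_structure,
)

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_BASES = "ACGU"


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic experiment."""

    n_mrna: int = 200
    n_lncrna: int = 40
    n_circrna: int = 10
    n_mirna: int = 20
    n_reps: int = 3
    baseline_mean: float = 300.0
    dispersion: float = 0.03
    lib_size_range: tuple[float, float] = (0.8, 1.25)
    de_log2fc: float = 2.0
    suppression: float = 0.25
    n_sponge_modules: int = 5
    mre_per_module: int = 2
    background_de_frac: float = 0.05
    latent_log2: float = 1.0
    transcript_length: int = 400
    max_defects: int = 1
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_circrna", "n_mirna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2 (correlation undefined below)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 < self.suppression <= 1:
            raise ValueError("suppression must lie in (0, 1]")
        if self.n_sponge_modules < 0 or self.mre_per_module < 1:
            raise ValueError("invalid sponge module settings")
        lo, hi = self.lib_size_range
        if not 0 < lo <= hi:
            raise ValueError("invalid lib_size_range")


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    de_features: set[str] = field(default_factory=set)
    mirna_target_edges: set[tuple[str, str]] = field(default_factory=set)
    sponge_pairs: set[frozenset[str]] = field(default_factory=set)
    hairpin_specs: list[tuple[str, int, int]] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "de_features": sorted(self.de_features),
            "mirna_target_edges": sorted(map(list, self.mirna_target_edges)),
            "sponge_pairs": sorted(sorted(p) for p in self.sponge_pairs),
            "hairpin_specs": self.hairpin_specs,
        }


def _feature_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    ids, classes = [], []
    for cls, n in (
        ("mRNA", config.n_mrna),
        ("lncRNA", config.n_lncrna),
        ("circRNA", config.n_circrna),
        ("miRNA", config.n_mirna),
    ):
        ids.extend(f"{cls}_{i:04d}" for i in range(1, n + 1))
        classes.extend([cls] * n)
    return ids, classes


def planted_means(config: SimConfig) -> tuple[list[str], list[str], np.ndarray, GroundTruth]:
    """Expected count means (before library scaling) and the planted truth.

    Exposed so the mean structure can be inspected without sampling; uses
    the same RNG stream prefix as :func:`simulate_counts`.
    """
    rng = np.random.default_rng(config.seed)
    return _plan(config, rng)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw the count matrix and record the planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids, classes, mu, truth = _plan(config, rng)
    ns = mu.shape[1]

    lib = rng.uniform(*config.lib_size_range, size=ns)
    mu = mu * lib[None, :]
    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    samples = [f"WL_{i+1}" for i in range(config.n_reps)] + [
        f"LL_{i+1}" for i in range(config.n_reps)
    ]
    groups = ["whole"] * config.n_reps + ["lobed"] * config.n_reps
    m = CountMatrix(
        feature_ids=ids,
        classes=classes,
        sample_ids=samples,
        groups=groups,
        counts=counts.astype(np.int64),
    )
    return m, truth


def _plan(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[str], list[str], np.ndarray, GroundTruth]:
    config.validate()
    ids, classes = _feature_ids(config)
    nf = len(ids)
    ns = 2 * config.n_reps
    idx = {f: i for i, f in enumerate(ids)}
    by_class = {
        cls: [f for f, c in zip(ids, classes) if c == cls]
        for cls in ("mRNA", "lncRNA", "circRNA", "miRNA")
    }

    truth = GroundTruth()

    # --- sponge modules ----------------------------------------------------
    # one disjoint miRNA set per module when the class allows; reuse only
    # when it does not (overlap dilutes the per-module latent signal)
    needed = config.n_sponge_modules * config.mre_per_module
    pool_size = min(config.n_mirna, max(config.mre_per_module, needed))
    de_mirna_pool = list(rng.choice(by_class["miRNA"], size=pool_size, replace=False))
    member_classes_cycle = ["mRNA", "lncRNA", "circRNA"]
    free = {cls: list(feats) for cls, feats in by_class.items()}
    modules = []
    unused_pool = list(de_mirna_pool)
    for mod in range(config.n_sponge_modules):
        if len(unused_pool) >= config.mre_per_module:
            mirnas = [unused_pool.pop(0) for _ in range(config.mre_per_module)]
        else:
            mirnas = list(
                rng.choice(de_mirna_pool, size=config.mre_per_module, replace=False)
            )
        partner_cls = member_classes_cycle[mod % len(member_classes_cycle)]
        m1 = free["mRNA"].pop(int(rng.integers(len(free["mRNA"]))))
        m2 = free[partner_cls].pop(int(rng.integers(len(free[partner_cls]))))
        modules.append({"mirnas": mirnas, "members": [m1, m2]})
        truth.sponge_pairs.add(frozenset((m1, m2)))
        for mi in mirnas:
            for mem in (m1, m2):
                truth.mirna_target_edges.add((mi, mem))
        truth.de_features.update(mirnas)
        truth.de_features.update((m1, m2))
    for mi in {m for mod in modules for m in mod["mirnas"]}:
        if mi in free["miRNA"]:
            free["miRNA"].remove(mi)

    # --- background DE features (no network role) --------------------------
    bg_up, bg_down = set(), set()
    for cls in ("mRNA", "lncRNA", "circRNA", "miRNA"):
        n_bg = int(round(config.background_de_frac * len(by_class[cls])))
        if n_bg == 0 or len(free[cls]) == 0:
            continue
        chosen = rng.choice(free[cls], size=min(n_bg, len(free[cls])), replace=False)
        half = len(chosen) // 2
        bg_up.update(chosen[:half])
        bg_down.update(chosen[half:])
    truth.de_features.update(bg_up | bg_down)

    # --- per-feature means --------------------------------------------------
    base = config.baseline_mean * rng.lognormal(mean=0.0, sigma=0.5, size=nf)
    mult2 = np.ones(nf)  # group-2 multiplier
    for mod in modules:
        for mi in mod["mirnas"]:
            mult2[idx[mi]] = 2.0**config.de_log2fc
        for mem in mod["members"]:
            mult2[idx[mem]] = config.suppression
    for f in bg_up:
        mult2[idx[f]] = 2.0**config.de_log2fc
    for f in bg_down:
        mult2[idx[f]] = 2.0**-config.de_log2fc

    mu = np.tile(base[:, None], (1, ns))
    g2 = np.arange(ns) >= config.n_reps
    mu[:, g2] *= mult2[:, None]

    # --- module latent pattern (centered within each group) ----------------
    contrast = np.linspace(-1.0, 1.0, config.n_reps)
    for mod in modules:
        z = np.concatenate([rng.permutation(contrast), rng.permutation(contrast)])
        up = 2.0 ** (config.latent_log2 * z)
        for mi in mod["mirnas"]:
            mu[idx[mi]] *= up
        for mem in mod["members"]:
            mu[idx[mem]] /= up

    return ids, classes, mu, truth


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def simulate_sequences(
    config: SimConfig, truth: GroundTruth
) -> tuple[list[FastaRecord], list[FastaRecord]]:
    """Mature miRNAs (21 nt) and transcripts with embedded MREs.

    Every planted (miRNA, transcript) edge gets one reverse-complement
    binding site with at most ``config.max_defects`` substitutions placed in
    the transcript; sponge-pair members therefore carry MREs for the same
    miRNAs. A seed distinct from the count stream keeps the two draws
    independent but jointly reproducible.
    """
    config.validate()
    rng = np.random.default_rng((config.seed, 1))
    ids, classes = _feature_ids(config)
    mirna_ids = [f for f, c in zip(ids, classes) if c == "miRNA"]
    transcript_ids = [f for f, c in zip(ids, classes) if c != "miRNA"]

    mirnas = {mid: _random_rna(rng, 21) for mid in mirna_ids}

    sites: dict[str, list[str]] = {t: [] for t in transcript_ids}
    for mid, tid in sorted(truth.mirna_target_edges):
        if len(mirnas[mid]) > config.transcript_length:
            raise ValueError("transcript shorter than MRE")
        site = list(revcomp(mirnas[mid]))
        n_def = int(rng.integers(0, config.max_defects + 1))
        for pos in rng.choice(len(site), size=n_def, replace=False):
            alternatives = [b for b in _BASES if b != site[pos]]
            site[pos] = alternatives[int(rng.integers(3))]
        sites[tid].append("".join(site))

    transcripts = []
    for tid in transcript_ids:
        seq = list(_random_rna(rng, config.transcript_length))
        if sites[tid]:
            # non-overlapping slots for the planted sites
            slot = config.transcript_length // len(sites[tid])
            for j, site in enumerate(sites[tid]):
                lo = j * slot
                hi = min((j + 1) * slot, config.transcript_length) - len(site)
                if hi < lo:
                    raise ValueError("transcript too short for planted sites")
                start = int(rng.integers(lo, hi + 1))
                seq[start : start + len(site)] = list(site)
        transcripts.append(FastaRecord(id=tid, seq="".join(seq)))
    mirna_records = [FastaRecord(id=mid, seq=seq) for mid, seq in mirnas.items()]
    return mirna_records, transcripts


@dataclass(frozen=True)
class SyntheticHairpin:
    """A constructed precursor with its planted duplex defects."""

    structure: StructureRecord
    mature: FastaRecord
    mature_span: tuple[int, int]
    planted_mismatches: int
    planted_bulges: int


def simulate_hairpin(
    mature: str,
    n_mismatch: int,
    n_bulge: int,
    loop_len: int = 8,
    mfe: float = -40.0,
    flank: int = 8,
    seed: int = 0,
    hairpin_id: str = "hairpin",
) -> SyntheticHairpin:
    """Construct a stem-loop with exactly the requested duplex defects.

    Layout: 5' flank (unpaired) + mature arm + terminal loop + star arm
    (modified reverse complement) + 3' flank. Mismatches replace the star
    base opposite an interior mature position with a non-pairing base (both
    positions unpaired); each asymmetric bulge inserts one extra unpaired
    base into the star strand between two mature positions. The MFE is an
    assigned annotation, not computed thermodynamics.
    """
    mature = mature.upper().replace("T", "U")
    L = len(mature)
    if not 18 <= L <= 24:
        raise ValueError("mature length must be 18-24 nt")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 (sterically impossible below)")
    if n_mismatch < 0 or n_bulge < 0:
        raise ValueError("defect counts must be >= 0")
    if mfe > 0:
        raise ValueError("assigned MFE must be <= 0")
    rng = np.random.default_rng(seed)

    interior = list(range(1, L - 1))
    if n_mismatch > len(interior):
        raise ValueError("too many mismatches for this mature length")
    mismatch_pos = set(
        rng.choice(interior, size=n_mismatch, replace=False).tolist()
    )
    # bulge gaps (between mature i and i+1) must be distinct and not sit
    # inside a mismatch run in a way that cancels the asymmetry
    gap_candidates = [
        g
        for g in range(1, L - 2)
        if g not in mismatch_pos and (g + 1) not in mismatch_pos
    ]
    if n_bulge > len(gap_candidates):
        raise ValueError("too many bulges for this mature length")
    bulge_gaps = set(rng.choice(gap_candidates, size=n_bulge, replace=False).tolist())

    def nonpairing(base: str) -> str:
        partner = _COMPLEMENT[base]
        wobble = {"G": "U", "U": "G"}.get(base)
        choices = [b for b in _BASES if b not in {partner, wobble}]
        return choices[int(rng.integers(len(choices)))]

    # star strand runs antiparallel: built from mature 3' -> 5'
    star_seq: list[str] = []
    star_db: list[str] = []
    for i in range(L - 1, -1, -1):
        if i in mismatch_pos:
            star_seq.append(nonpairing(mature[i]))
            star_db.append(".")
        else:
            star_seq.append(_COMPLEMENT[mature[i]])
            star_db.append(")")
        if i >= 1 and (i - 1) in bulge_gaps:
            star_seq.append(_BASES[int(rng.integers(4))])
            star_db.append(".")

    mature_db = "".join("." if i in mismatch_pos else "(" for i in range(L))
    flank5 = _random_rna(rng, flank)
    flank3 = _random_rna(rng, flank)
    loop = _random_rna(rng, loop_len)
    seq = flank5 + mature + loop + "".join(star_seq) + flank3
    db = (
        "." * flank
        + mature_db
        + "." * loop_len
        + "".join(star_db)
        + "." * flank
    )
    structure = StructureRecord(id=hairpin_id, seq=seq, dotbracket=db, mfe=float(mfe))
    return SyntheticHairpin(
        structure=structure,
        mature=FastaRecord(id=f"{hairpin_id}_mature", seq=mature),
        mature_span=(flank, flank + L),
        planted_mismatches=n_mismatch,
        planted_bulges=n_bulge,
    )


def write_dataset(
    config: SimConfig,
    outdir: str | Path,
    m: CountMatrix,
    truth: GroundTruth,
    mirnas: list[FastaRecord],
    transcripts: list[FastaRecord],
    hairpins: list[StructureRecord] | None = None,
) -> None:
    """Emit counts.tsv, FASTA files, truth.json (and hairpins.dbn)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(m, outdir / "counts.tsv")
    write_fasta(mirnas, outdir / "mirnas.fa")
    write_fasta(transcripts, outdir / "transcripts.fa")
    payload = truth.to_json()
    payload["config"] = dataclasses.asdict(config)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    if hairpins:
        write_structure(hairpins, outdir / "hairpins.dbn")
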