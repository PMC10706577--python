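"""Pre-miRNA hairpin screening from sequence + dot-bracket structure.

A candidate precursor passes when, jointly:

* folding free energy (MFE) below -18 kcal/mol (strict),
* MFEI (minimal folding free energy index, AMFE / GC%) >= 0.85, where
  AMFE = |MFE| / length * 100,
* at most 3 asymmetric bulge events in the mature:star duplex,
* at most 4 mismatched base pairs in the duplex,
* the mature sequence does not span the terminal loop.

Bulge counting is event-based: a maximal run of unpaired bases on only one
strand of the duplex is one event (the per-base total is reported alongside).
Mismatches are unpaired mature bases opposed by unpaired star bases.

Folding itself is out of scope here; structures arrive from Vienna-format
input or from the synthetic constructor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import FastaRecord, StructureRecord, as_rna, pair_table

logger = logging.getLogger(__name__)

MFE_GATE = -18.0  # kcal/mol, strict <
MFEI_GATE = 0.85
MAX_ASYM_BULGES = 3
MAX_MISMATCHES = 4


@dataclass(frozen=True)
class HairpinMetrics:
    mfe: float
    length: int
    gc_percent: float
    amfe: float
    mfei: float
    mismatches: int
    asym_bulges: int
    bulged_bases: int
    mature_arm: str  # "5p" | "3p"
    spans_loop: bool


@dataclass(frozen=True)
class Verdict:
    passed: bool
    flags: dict


def gc_percent(seq: str) -> float:
    s = as_rna(seq)
    return 100.0 * sum(c in "GC" for c in s) / len(s)


def locate_mature(
    hairpin: StructureRecord, mature: FastaRecord
) -> tuple[int, int, str, bool]:
    """Locate the mature miRNA in the precursor.

    Returns (start, end) 0-based half-open, the arm (5p/3p) relative to the
    terminal loop, and whether the mature span overlaps the loop. The
    leftmost occurrence is used (with a warning if several exist).
    """
    hseq = as_rna(hairpin.seq)
    mseq = as_rna(mature.seq)
    start = hseq.find(mseq)
    if start < 0:
        raise ValueError(f"mature {mature.id} not found in hairpin {hairpin.id}")
    if hseq.find(mseq, start + 1) >= 0:
        logger.warning(
            "mature %s occurs more than once in %s; using leftmost",
            mature.id,
            hairpin.id,
        )
    end = start + len(mseq)
    db = hairpin.dotbracket
    if "(" not in db or ")" not in db:
        raise ValueError(f"hairpin {hairpin.id} has no stem")
    # terminal loop: the unpaired stretch between the innermost base pair
    last_open = max(i for i, c in enumerate(db) if c == "(")
    first_close = min(i for i, c in enumerate(db) if c == ")" and i > last_open)
    loop_start, loop_end = last_open + 1, first_close  # half-open
    spans_loop = start < loop_end and end > loop_start
    arm = "5p" if start < loop_start else "3p"
    return start, end, arm, spans_loop


def duplex_metrics(
    hairpin: StructureRecord, mature_span: tuple[int, int]
) -> tuple[int, int, int]:
    """(mismatches, asymmetric bulge events, bulged bases) in the duplex.

    Walks the mature arm between consecutive paired positions i1 < i2 with
    star partners j1 > j2: with g_m unpaired mature bases and g_s unpaired
    star bases in between, min(g_m, g_s) are mismatches (unpaired bases
    opposed on both strands) and any excess on one strand is a single
    asymmetric bulge event of |g_m - g_s| bases. Unpaired bases at the
    mature boundary have no opposed star run defined; they count as
    mismatches (conservative).
    """
    start, end = mature_span
    db = hairpin.dotbracket
    if "(" in db and ")" in db:
        last_open = max(i for i, c in enumerate(db) if c == "(")
        first_close = min(i for i, c in enumerate(db) if c == ")" and i > last_open)
        if start < first_close and end > last_open + 1:
            raise ValueError("mature spans the loop; duplex metrics undefined")
    table = pair_table(db)
    paired = [i for i in range(start, end) if table[i] >= 0]
    if not paired:
        raise ValueError("mature arm entirely unpaired")
    partners = [table[i] for i in paired]
    if not (
        all(p >= end for p in partners) or all(p < start for p in partners)
    ):
        raise ValueError("mature spans the loop; duplex metrics undefined")

    mismatches = 0
    bulge_events = 0
    bulged_bases = 0
    # boundary unpaired mature bases
    mismatches += (paired[0] - start) + (end - 1 - paired[-1])
    for i1, i2, j1, j2 in zip(paired, paired[1:], partners, partners[1:]):
        g_m = i2 - i1 - 1
        g_s = abs(j1 - j2) - 1
        mismatches += min(g_m, g_s)
        if g_m != g_s:
            bulge_events += 1
            bulged_bases += abs(g_m - g_s)
    return mismatches, bulge_events, bulged_bases


def mfei(mfe: float, length: int, gc: float) -> tuple[float, float]:
    """(AMFE, MFEI) from the energy, length and GC percentage."""
    if gc <= 0:
        raise ValueError("GC percentage must be positive")
    if mfe > 0:
        raise ValueError("MFE must be <= 0 kcal/mol")
    amfe = abs(mfe) / length * 100.0
    return amfe, amfe / gc


def hairpin_metrics(
    hairpin: StructureRecord, mature: FastaRecord
) -> HairpinMetrics:
    start, end, arm, spans_loop = locate_mature(hairpin, mature)
    gc = gc_percent(hairpin.seq)
    amfe, index = mfei(hairpin.mfe, len(hairpin.seq), gc)
    if spans_loop:
        mismatches, bulges, bulged = -1, -1, -1
    else:
        mismatches, bulges, bulged = duplex_metrics(hairpin, (start, end))
    return HairpinMetrics(
        mfe=hairpin.mfe,
        length=len(hairpin.seq),
        gc_percent=gc,
        amfe=amfe,
        mfei=index,
        mismatches=mismatches,
        asym_bulges=bulges,
        bulged_bases=bulged,
        mature_arm=arm,
        spans_loop=spans_loop,
    )


def apply_criteria(metrics: HairpinMetrics) -> Verdict:
    """Conjunction of the four screening criteria plus the loop constraint."""
    flags = {
        "mfe_below_-18": metrics.mfe < MFE_GATE,
        "mfei_ge_0.85": metrics.mfei >= MFEI_GATE,
        "asym_bulges_le_3": not metrics.spans_loop
        and 0 <= metrics.asym_bulges <= MAX_ASYM_BULGES,
        "mismatches_le_4": not metrics.spans_loop
        and 0 <= metrics.mismatches <= MAX_MISMATCHES,
        "mature_within_arm": not metrics.spans_loop,
    }
    return Verdict(passed=all(flags.values()), flags=flags)
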