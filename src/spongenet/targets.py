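"""Plant-style miRNA target-site (MRE) scanning.

Each transcript window is aligned antiparallel to the miRNA and scored with
the penalty convention widely used for plant small-RNA targets: mismatch 1.0,
G:U wobble 0.5, indel 2.0, with every penalty doubled at miRNA positions 2-13
(1-based from the 5' end). Windows whose total penalty is at or below the
cutoff (default 3.0) are reported as hits. Alignment is gap-limited (at most
``max_indel`` = 1 unpaired position on either strand), enumerated by bounded
window lengths rather than full dynamic programming, so scanning one miRNA
against a transcript of length L is O(L * k).

Coordinates in :class:`TargetHit` are 0-based half-open on the transcript;
rendered reports are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import FastaRecord, as_rna

MISMATCH = 1.0
WOBBLE = 0.5
INDEL = 2.0
CORE = (2, 13)  # 1-based inclusive miRNA positions with doubled penalties
DEFAULT_CUTOFF = 3.0

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

# penalty[miRNA base, target base] for an antiparallel pairing
_PENALTY = np.full((5, 5), MISMATCH)
for _m, _t in ((0, 3), (3, 0), (1, 2), (2, 1)):  # A:U, U:A, C:G, G:C
    _PENALTY[_m, _t] = 0.0
for _m, _t in ((2, 3), (3, 2)):  # G:U wobble
    _PENALTY[_m, _t] = WOBBLE
_SYMBOL = {0.0: "|", WOBBLE: "o"}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in as_rna(seq)], dtype=np.int8)


def _weights(length: int) -> np.ndarray:
    w = np.ones(length)
    w[CORE[0] - 1 : CORE[1]] = 2.0
    return w


@dataclass(frozen=True)
class TargetHit:
    """One scored miRNA binding site on a transcript."""

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    score: float
    alignment: str

    def render_coords(self) -> str:
        """1-based inclusive span for reports."""
        return f"{self.start + 1}-{self.end}"


def _site_scores_ungapped(mi: np.ndarray, tr: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Penalty of every window of len(mi); entry a scores tr[a : a+len(mi)]."""
    L = mi.size
    if tr.size < L:
        return np.empty(0)
    # reversed windows: row j of the view equals tr[::-1][j : j+L]
    view = np.lib.stride_tricks.sliding_window_view(tr[::-1], L)
    pen = _PENALTY[mi[None, :], view[::-1]]  # row a: mi[i] vs tr[a+L-1-i]
    return pen @ w


def _site_scores_gap(
    mi: np.ndarray, tr: np.ndarray, w: np.ndarray, site_len: int
) -> np.ndarray:
    """Best single-gap penalty for every window of ``site_len``.

    site_len = len(mi) + 1: one unopposed transcript base (gap in miRNA);
    site_len = len(mi) - 1: one unopposed miRNA base (gap in transcript).
    """
    L = mi.size
    if tr.size < site_len:
        return np.empty(0)
    view = np.lib.stride_tricks.sliding_window_view(tr[::-1], site_len)[::-1]
    nwin = view.shape[0]
    if site_len == L + 1:
        # skip reversed-site index k in 0..L; before the gap mi[i] vs rs[i],
        # after it mi[i] vs rs[i+1]
        A = _PENALTY[mi[None, :], view[:, :L]] * w
        B = _PENALTY[mi[None, :], view[:, 1:]] * w
        gap_pos = np.minimum(np.arange(L + 1), L - 1)
    elif site_len == L - 1:
        # miRNA position k unopposed; before it mi[i] vs rs[i], after it
        # mi[i] vs rs[i-1]
        A = _PENALTY[mi[None, :L - 1], view] * w[: L - 1]
        B = _PENALTY[mi[None, 1:], view] * w[1:]
        gap_pos = np.arange(L)
    else:
        raise ValueError("site_len must be len(mi) +/- 1")
    gap_pen = INDEL * w[gap_pos]
    prefA = np.concatenate([np.zeros((nwin, 1)), np.cumsum(A, axis=1)], axis=1)
    sufB = np.concatenate(
        [np.cumsum(B[:, ::-1], axis=1)[:, ::-1], np.zeros((nwin, 1))], axis=1
    )
    totals = prefA + sufB + gap_pen[None, :]
    return totals.min(axis=1)


def _render_alignment(mi_seq: str, site_seq: str) -> str:
    """Pairing string for the best gapless or single-gap alignment of a site."""
    mi = _encode(mi_seq)
    rs = _encode(site_seq)[::-1]
    L, S = mi.size, rs.size
    w = _weights(L)

    def glyphs(mvec, tvec, wvec):
        return [
            _SYMBOL.get(_PENALTY[a, b], " ") for a, b in zip(mvec, tvec)
        ], float(np.sum(_PENALTY[mvec, tvec] * wvec))

    if S == L:
        g, _ = glyphs(mi, rs, w)
        return f"miRNA 5'-{mi_seq}-3'\n         {''.join(g)}\nsite  3'-{site_seq[::-1]}-5'"
    # single gap: pick the split minimizing penalty
    best = None
    if S == L + 1:
        for k in range(L + 1):
            pen = (
                float(np.sum(_PENALTY[mi[:k], rs[:k]] * w[:k]))
                + INDEL * w[min(k, L - 1)]
                + float(np.sum(_PENALTY[mi[k:], rs[k + 1 :]] * w[k:]))
            )
            if best is None or pen < best[0]:
                best = (pen, k)
        k = best[1]
        mline = mi_seq[:k] + "-" + mi_seq[k:]
        tline = (site_seq[::-1])
        g1, _ = glyphs(mi[:k], rs[:k], w[:k])
        g2, _ = glyphs(mi[k:], rs[k + 1 :], w[k:])
        marks = "".join(g1) + " " + "".join(g2)
    else:
        for k in range(L):
            pen = (
                float(np.sum(_PENALTY[mi[:k], rs[:k]] * w[:k]))
                + INDEL * w[k]
                + float(np.sum(_PENALTY[mi[k + 1 :], rs[k:]] * w[k + 1 :]))
            )
            if best is None or pen < best[0]:
                best = (pen, k)
        k = best[1]
        mline = mi_seq
        tline = site_seq[::-1][:k] + "-" + site_seq[::-1][k:]
        g1, _ = glyphs(mi[:k], rs[:k], w[:k])
        g2, _ = glyphs(mi[k + 1 :], rs[k:], w[k + 1 :])
        marks = "".join(g1) + " " + "".join(g2)
    return f"miRNA 5'-{mline}-3'\n         {marks}\nsite  3'-{tline}-5'"


def scan_targets(
    mirna: FastaRecord,
    transcript: FastaRecord,
    cutoff: float = DEFAULT_CUTOFF,
    max_indel: int = 1,
) -> list[TargetHit]:
    """All binding sites of ``mirna`` on ``transcript`` with penalty <= cutoff.

    Overlapping hits are allowed; each reported span carries its best
    alignment score. Raises if the transcript is shorter than the miRNA minus
    ``max_indel``.
    """
    L = len(mirna.seq)
    if not 18 <= L <= 26:
        raise ValueError(f"miRNA length {L} outside 18-26 nt")
    if len(transcript.seq) < L - max_indel:
        raise ValueError("transcript shorter than miRNA minus max_indel")
    mi = _encode(mirna.seq)
    tr = _encode(transcript.seq)
    w = _weights(L)
    t_rna = as_rna(transcript.seq)

    hits: list[TargetHit] = []
    lengths = [L] + ([L + 1, L - 1] if max_indel >= 1 else [])
    for site_len in lengths:
        if site_len == L:
            scores = _site_scores_ungapped(mi, tr, w)
        else:
            scores = _site_scores_gap(mi, tr, w, site_len)
        for a in np.nonzero(scores <= cutoff)[0]:
            site = t_rna[a : a + site_len]
            hits.append(
                TargetHit(
                    mirna_id=mirna.id,
                    transcript_id=transcript.id,
                    start=int(a),
                    end=int(a + site_len),
                    score=float(scores[a]),
                    alignment=_render_alignment(as_rna(mirna.seq), site),
                )
            )
    hits.sort(key=lambda h: (h.start, h.end, h.score))
    return hits


def target_relation(
    mirnas: Iterable[FastaRecord],
    transcripts: Iterable[FastaRecord],
    cutoff: float = DEFAULT_CUTOFF,
    max_indel: int = 1,
) -> set[tuple[str, str]]:
    """Deduplicated (miRNA id, transcript id) pairs with >= 1 sub-cutoff hit."""
    mirnas = list(mirnas)
    transcripts = list(transcripts)
    relation: set[tuple[str, str]] = set()
    for mi in mirnas:
        for tr in transcripts:
            if len(tr.seq) < len(mi.seq) - max_indel:
                continue
            if scan_targets(mi, tr, cutoff=cutoff, max_indel=max_indel):
                relation.add((mi.id, tr.id))
    return relation


def seed_families(mirnas: Sequence[FastaRecord]) -> dict[str, list[str]]:
    """Group miRNAs sharing identical seed (positions 2-8, 1-based)."""
    fams: dict[str, list[str]] = {}
    for rec in mirnas:
        fams.setdefault(as_rna(rec.seq)[1:8], []).append(rec.id)
    return fams
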