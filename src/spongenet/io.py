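"""Readers, writers and small sequence utilities.

Formats handled:

* FASTA (60-column wrapped on output; T and U both accepted on input).
* Vienna ``.dbn`` structure records: ``>id`` / sequence / dot-bracket ending
  in ``(MFE)``.
* ``counts.tsv`` — feature_id, class, one column per sample, with a second
  header row carrying the per-sample group labels.
* ``edges.tsv`` — source, target, edge_type, statistic, p, fdr.

Coordinates are 0-based half-open internally and 1-based inclusive in any
rendered report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight

logger = logging.getLogger(__name__)

RNA_CLASSES = ("mRNA", "lncRNA", "circRNA", "miRNA")
_ALPHABET = set("ACGUTN")

#: mass of one water molecule (Da); one per peptide chain.
WATER_MASS = 18.0153


def as_rna(seq: str) -> str:
    """Normalize a nucleotide string to upper-case RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def as_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class FastaRecord:
    """A single FASTA entry; ``seq`` is validated against the IUPAC subset."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid FASTA id: {self.id!r}")
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq.upper()) - _ALPHABET
        if bad:
            raise ValueError(
                f"illegal characters {sorted(bad)} in record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def seq_length(record: FastaRecord) -> int:
    """Length of the record's sequence in nucleotides."""
    return len(record.seq)


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Parse a FASTA file.

    A hand parser is used (rather than delegating) so malformed input can be
    rejected with the offending line number; round-trip equivalence with
    Biopython is covered by the test suite.
    """
    records: list[FastaRecord] = []
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush():
        if header is None:
            return
        hid, _, desc = header.partition(" ")
        try:
            records.append(FastaRecord(id=hid, seq="".join(chunks), description=desc))
        except ValueError as exc:
            raise ValueError(f"{path}: line {header_line}: {exc}") from exc

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise ValueError(f"{path}: line {lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ValueError(
                        f"{path}: line {lineno}: sequence before any '>' header"
                    )
                bad = set(line.upper()) - _ALPHABET
                if bad:
                    raise ValueError(
                        f"{path}: line {lineno}: illegal characters {sorted(bad)}"
                    )
                chunks.append(line.upper())
    flush()
    if not records:
        logger.warning("no records found in %s", path)
    return records


def write_fasta(records: Iterable[FastaRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Vienna dot-bracket structures
# ---------------------------------------------------------------------------

_BRACKETS = set("().")


@dataclass(frozen=True)
class StructureRecord:
    """An RNA sequence with its secondary structure and folding energy."""

    id: str
    seq: str
    dotbracket: str
    mfe: float

    def __post_init__(self):
        if len(self.dotbracket) != len(self.seq):
            raise ValueError(
                f"{self.id}: length mismatch (seq {len(self.seq)} nt, "
                f"structure {len(self.dotbracket)})"
            )
        bad = set(self.dotbracket) - _BRACKETS
        if bad:
            raise ValueError(
                f"{self.id}: unsupported structure characters {sorted(bad)} "
                "(pseudoknots are rejected, not ignored)"
            )
        depth = 0
        for c in self.dotbracket:
            if c == "(":
                depth += 1
            elif c == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError(f"{self.id}: unbalanced brackets")
        if depth != 0:
            raise ValueError(f"{self.id}: unbalanced brackets")


def pair_table(dotbracket: str) -> np.ndarray:
    """Partner index per position (-1 where unpaired)."""
    table = np.full(len(dotbracket), -1, dtype=int)
    stack: list[int] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            table[i], table[j] = j, i
    return table


def read_structure(path: str | Path) -> list[StructureRecord]:
    """Parse three-line Vienna records: ``>id`` / sequence / structure (MFE)."""
    records = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) % 3:
        raise ValueError(f"{path}: truncated record (lines not a multiple of 3)")
    for i in range(0, len(lines), 3):
        head, seq, struct = lines[i : i + 3]
        if not head.startswith(">"):
            raise ValueError(f"{path}: expected '>' header, got {head!r}")
        struct = struct.strip()
        if "(" in struct and struct.endswith(")") and " " in struct:
            db, _, tail = struct.rpartition(" ")
            mfe = float(tail.strip("()"))
        else:
            raise ValueError(f"{path}: {head[1:]}: missing trailing (MFE)")
        records.append(
            StructureRecord(id=head[1:].split()[0], seq=as_rna(seq), dotbracket=db.strip(), mfe=mfe)
        )
    return records


def write_structure(records: Iterable[StructureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n{rec.dotbracket} ({rec.mfe:g})\n")


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Non-negative integer counts with feature classes and sample groups."""

    feature_ids: list[str]
    classes: list[str]
    sample_ids: list[str]
    groups: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        nf, ns = self.counts.shape
        if len(self.feature_ids) != nf or len(self.classes) != nf:
            raise ValueError("feature annotation length mismatch")
        if len(self.sample_ids) != ns or len(self.groups) != ns:
            raise ValueError("sample annotation length mismatch")
        if len(set(self.feature_ids)) != nf:
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != ns:
            raise ValueError("duplicate sample ids")
        unknown = set(self.classes) - set(RNA_CLASSES)
        if unknown:
            raise ValueError(
                f"unknown RNA class {sorted(unknown)}; allowed: {RNA_CLASSES}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        levels = sorted(set(self.groups))
        if len(levels) != 2:
            raise ValueError(f"exactly two groups required, got {levels}")
        for g in levels:
            if self.groups.count(g) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")

    @property
    def group_levels(self) -> tuple[str, str]:
        # first-appearance order: level 0 is the reference (group 1)
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return tuple(seen)  # type: ignore[return-value]

    def group_mask(self, level: str) -> np.ndarray:
        return np.array([g == level for g in self.groups])

    def subset(self, feature_ids: Sequence[str]) -> "CountMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in feature_ids]
        return CountMatrix(
            feature_ids=list(feature_ids),
            classes=[self.classes[i] for i in rows],
            sample_ids=list(self.sample_ids),
            groups=list(self.groups),
            counts=self.counts[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)
        df.insert(0, "class", self.classes)
        return df


def write_counts(m: CountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tclass\t" + "\t".join(m.sample_ids) + "\n")
        fh.write("group\t-\t" + "\t".join(m.groups) + "\n")
        for fid, cls, row in zip(m.feature_ids, m.classes, m.counts):
            fh.write(fid + "\t" + cls + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_counts(path: str | Path) -> CountMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        group_row = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["feature_id", "class"] or group_row[0] != "group":
            raise ValueError(f"{path}: not a counts.tsv (bad header rows)")
        sample_ids = header[2:]
        groups = group_row[2:]
        body = pd.read_csv(fh, sep="\t", header=None, names=header)
    counts = body[sample_ids].to_numpy()
    if not np.all(np.equal(np.mod(counts, 1), 0)) or (counts < 0).any():
        raise ValueError(f"{path}: counts must be non-negative integers")
    return CountMatrix(
        feature_ids=body["feature_id"].tolist(),
        classes=body["class"].tolist(),
        sample_ids=sample_ids,
        groups=groups,
        counts=counts.astype(np.int64),
    )


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    cols = ["source", "target", "edge_type", "statistic", "p", "fdr"]
    out = edges.copy()
    for c in cols:
        if c not in out.columns:
            out[c] = np.nan
    out[cols].to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sequence descriptors
# ---------------------------------------------------------------------------


def orf_descriptors(n_residues: int) -> int:
    """CDS length in bp for an ORF of ``n_residues`` amino acids plus stop."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return 3 * (n_residues + 1)


def protein_mass(aa_seq: str) -> float:
    """Average molecular mass of a peptide in Da (residue masses + one water)."""
    seq = aa_seq.upper()
    if not seq:
        raise ValueError("empty peptide")
    try:
        return float(molecular_weight(seq, seq_type="protein", monoisotopic=False))
    except ValueError as exc:
        raise ValueError(f"unknown residue in peptide: {exc}") from exc


def fetch_cds_translation(accession: str, email: str = "spongenet@example.org") -> str:
    """Fetch a GenBank record and return its first CDS translation.

    Requires network access to NCBI; raises ``IOError`` when offline.
    """
    from Bio import Entrez, SeqIO

    Entrez.email = email
    with Entrez.efetch(db="nuccore", id=accession, rettype="gb", retmode="text") as handle:
        record = SeqIO.read(handle, "genbank")
    for feat in record.features:
        if feat.type == "CDS" and "translation" in feat.qualifiers:
            return feat.qualifiers["translation"][0]
    raise ValueError(f"no CDS translation in {accession}")
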