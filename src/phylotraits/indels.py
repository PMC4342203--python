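"""Simple indel coding and multi-locus concatenation.

Gap runs in an alignment carry phylogenetic information that nucleotide
columns miss. Simple indel coding turns every distinct internal maximal gap
run — identified by its exact (start, end) column span, 1-based inclusive —
into one binary character: a taxon scores 1 when it has precisely that gap
run, ``?`` when a longer gap run of its own strictly subsumes the span
(the taxon is uninformative about that particular indel), and 0 otherwise.
Terminal gap runs are treated as missing data, not coded.

Concatenation unions the taxon sets of per-locus partitions, fills absent
taxa with ``?``, and records per-partition (and per-indel-block) character
set boundaries, NEXUS-style.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from Bio import SeqIO

from .errors import ValidationError
from .util import normalize_label

__all__ = [
    "AlignmentPartition",
    "IndelCharacter",
    "IndelCharacterMatrix",
    "Supermatrix",
    "find_indels",
    "simple_indel_coding",
    "concatenate_partitions",
    "read_fasta_alignment",
    "write_fasta_alignment",
]

_GAP = "-"
_ALPHABET = set("ACGTN-?acgtn01")  # 0/1 admit appended standard characters


@dataclass
class AlignmentPartition:
    """One aligned locus: name plus per-taxon sequences of equal length."""

    name: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValidationError(f"partition {self.name!r} is empty")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValidationError(f"unequal sequence lengths in {self.name!r}: {sorted(lengths)}")
        bad = {c for s in self.sequences.values() for c in s} - _ALPHABET
        if bad:
            raise ValidationError(f"unexpected characters in {self.name!r}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    def drop_all_gap_columns(self) -> "AlignmentPartition":
        """Remove columns that are gaps in every taxon (warns when any)."""
        L = self.length
        keep = [
            j for j in range(L)
            if any(s[j] != _GAP for s in self.sequences.values())
        ]
        if len(keep) == L:
            return self
        warnings.warn(
            f"{self.name}: deleted {L - len(keep)} all-gap column(s) before coding",
            stacklevel=2,
        )
        return AlignmentPartition(
            self.name, {t: "".join(s[j] for j in keep) for t, s in self.sequences.items()}
        )


@dataclass(frozen=True)
class IndelCharacter:
    start: int  # 1-based inclusive
    end: int
    codes: tuple[tuple[str, str], ...]  # (taxon, '0'|'1'|'?')

    def code_of(self, taxon: str) -> str:
        return dict(self.codes)[taxon]


@dataclass
class IndelCharacterMatrix:
    partition: str
    characters: list[IndelCharacter]

    def __len__(self) -> int:
        return len(self.characters)

    def spans(self) -> list[tuple[int, int]]:
        return [(c.start, c.end) for c in self.characters]


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal '-' runs as 1-based inclusive (start, end)."""
    runs = []
    j = 0
    L = len(seq)
    while j < L:
        if seq[j] == _GAP:
            s = j
            while j < L and seq[j] == _GAP:
                j += 1
            runs.append((s + 1, j))
        else:
            j += 1
    return runs


def find_indels(aln: AlignmentPartition) -> list[tuple[int, int]]:
    """Distinct internal maximal gap-run spans across all taxa.

    Runs touching the first or last alignment column are terminal gaps —
    missing data, not indel events — and are excluded. Spans are returned
    sorted by (start, end); runs with identical endpoints in different taxa
    are one span.
    """
    L = aln.length
    spans = {
        run
        for seq in aln.sequences.values()
        for run in _gap_runs(seq)
        if run[0] > 1 and run[1] < L
    }
    return sorted(spans)


def simple_indel_coding(
    aln: AlignmentPartition, drop_all_gap_columns: bool = False
) -> IndelCharacterMatrix:
    """Code every internal gap span as one binary character per taxon.

    1: the taxon's own gap run is exactly the span; ?: a gap run of the
    taxon strictly contains the span (or missing data covers it); 0:
    anything else, including partial overlap with residues inside the span.

    Columns gapped in every taxon are kept by default, so span coordinates
    always refer to the input alignment; pass ``drop_all_gap_columns=True``
    to delete them first (coordinates then refer to the cleaned matrix).
    """
    if drop_all_gap_columns:
        aln = aln.drop_all_gap_columns()
    spans = find_indels(aln)
    runs_by_taxon = {t: set(_gap_runs(s)) for t, s in aln.sequences.items()}
    chars: list[IndelCharacter] = []
    for s, e in spans:
        codes = []
        for taxon, seq in aln.sequences.items():
            runs = runs_by_taxon[taxon]
            if (s, e) in runs:
                code = "1"
            elif any(rs <= s and e <= re and (rs, re) != (s, e) for rs, re in runs):
                code = "?"
            elif any(c == "?" for c in seq[s - 1 : e]):
                code = "?"
            else:
                code = "0"
            codes.append((taxon, code))
        chars.append(IndelCharacter(s, e, tuple(codes)))
    return IndelCharacterMatrix(aln.name, chars)


# ----------------------------------------------------------------------
# Concatenation


@dataclass
class Supermatrix:
    """Concatenated partitions (+ appended indel blocks) with charsets."""

    sequences: dict[str, str]
    charsets: list[tuple[str, int, int]]  # (name, start, end) 1-based inclusive

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def to_nexus(self, path: str) -> None:
        taxa = list(self.sequences)
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(taxa)} NCHAR={self.length};\n")
            fh.write('  FORMAT DATATYPE=STANDARD SYMBOLS="ACGTN01" MISSING=? GAP=-;\n')
            fh.write("  MATRIX\n")
            width = max(len(t) for t in taxa) + 2
            for t in taxa:
                fh.write(f"    {t:<{width}}{self.sequences[t]}\n")
            fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
            for name, s, e in self.charsets:
                fh.write(f"  CHARSET {name} = {s}-{e};\n")
            fh.write("END;\n")


def concatenate_partitions(
    parts: Sequence[AlignmentPartition],
    indels: Sequence[IndelCharacterMatrix] | None = None,
) -> Supermatrix:
    """Concatenate loci into one matrix; optionally append indel characters.

    The taxon set is the sorted union; a taxon absent from a partition is
    filled with '?' over that block. Character-set boundaries are recorded
    per partition and per indel block, so total width = sum of partition
    lengths + indel columns.
    """
    if not parts:
        raise ValidationError("need at least one partition")
    names = [p.name for p in parts]
    if len(names) != len(set(names)):
        raise ValidationError("duplicate partition names")
    taxa = sorted({t for p in parts for t in p.taxa})
    rows = {t: [] for t in taxa}
    charsets: list[tuple[str, int, int]] = []
    col = 0
    for p in parts:
        charsets.append((p.name, col + 1, col + p.length))
        for t in taxa:
            rows[t].append(p.sequences.get(t, "?" * p.length))
        col += p.length
    for m in indels or []:
        if len(m) == 0:
            continue
        charsets.append((f"{m.partition}_indels", col + 1, col + len(m)))
        for t in taxa:
            rows[t].append(
                "".join(dict(c.codes).get(t, "?") for c in m.characters)
            )
        col += len(m)
    return Supermatrix({t: "".join(r) for t, r in rows.items()}, charsets)


# ----------------------------------------------------------------------
# I/O


def read_fasta_alignment(path: str, name: str | None = None) -> AlignmentPartition:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        label = normalize_label(rec.id)
        if label in seqs:
            raise ValidationError(f"duplicate taxon {label!r} in {path}")
        seqs[label] = str(rec.seq).upper()
    if not seqs:
        raise ValidationError(f"no sequences found in {path}")
    return AlignmentPartition(name or path, seqs)


def write_fasta_alignment(aln: AlignmentPartition, path: str) -> None:
    with open(path, "w") as fh:
        for t, s in aln.sequences.items():
            fh.write(f">{t}\n{s}\n")
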