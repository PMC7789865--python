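"""Reading, QC filtering and codon-level representation of CDS FASTA files.

A coding sequence passes quality control iff its length is a multiple of 3,
it starts with ATG, ends with TAA/TAG/TGA, contains no internal stop codon,
no ambiguous base, and codes for at least ``min_aa`` non-stop codons.
Rejections are reported, never raised; a :class:`QcReport` accounts for every
input record.
"""

from __future__ import annotations

import collections
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .genetic_code import CODON_TO_AA, START_CODON, STOP_CODONS

_VALID_BASES = frozenset("ACGT")
_WS = re.compile(r"\s+")

#: rejection reasons, in the order they are checked
QC_REASONS = (
    "not_multiple_of_3",
    "ambiguous_base",
    "no_start",
    "no_stop",
    "internal_stop",
    "too_short",
)


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One raw FASTA record after normalization (uppercase, U->T)."""

    id: str
    sequence: str


@dataclass(frozen=True)
class CodingSequence:
    """A QC'd CDS as an ordered codon list (initiation codon first, stop last)."""

    id: str
    codons: tuple[str, ...]
    length_aa: int

    @property
    def sequence(self) -> str:
        return "".join(self.codons)

    @property
    def body(self) -> tuple[str, ...]:
        """Codons excluding the terminal stop."""
        return self.codons[:-1] if self.codons and CODON_TO_AA.get(self.codons[-1]) == "*" else self.codons


@dataclass
class QcReport:
    n_input: int = 0
    n_passed: int = 0
    rejections: list[tuple[str, str]] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\treason\n")
            for gid, reason in self.rejections:
                fh.write(f"{gid}\t{reason}\n")

    def reason_counts(self) -> dict[str, int]:
        out = collections.Counter(reason for _, reason in self.rejections)
        return {r: out.get(r, 0) for r in QC_REASONS if out.get(r, 0)}


def _normalize(seq: str) -> str:
    return _WS.sub("", seq).upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a (possibly line-wrapped) nucleotide FASTA file.

    Lowercase letters are uppercased and RNA ``U`` is mapped to ``T``; all
    whitespace inside sequence lines is removed.

    Raises
    ------
    FastaParseError
        If sequence data precedes the first header (the error names the
        offending line number) or if two records share an identifier.
    """
    path = Path(path)
    # Pre-validate structure: Biopython tolerates text before the first
    # header, but this artifact's contract requires a located parse error.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: sequence data before first FASTA header at line {lineno}"
                )
            break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, sequence=_normalize(str(rec.seq))))
    return records


def write_fasta(
    records: Iterable[SequenceRecord | CodingSequence], path: str | Path, width: int = 60
) -> None:
    """Write records (raw or QC'd) as wrapped FASTA; deterministic output."""
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.sequence
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _qc_reason(seq: str, min_aa: int) -> str | None:
    if len(seq) % 3 != 0:
        return "not_multiple_of_3"
    if set(seq) - _VALID_BASES:
        return "ambiguous_base"
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons[0] != START_CODON:
        return "no_start"
    if codons[-1] not in STOP_CODONS:
        return "no_stop"
    if any(c in STOP_CODONS for c in codons[:-1]):
        return "internal_stop"
    if len(codons) - 1 < min_aa:
        return "too_short"
    return None


def qc_filter_cds(
    records: Iterable[SequenceRecord], min_aa: int = 100
) -> tuple[list[CodingSequence], QcReport]:
    """Apply the CDS quality filter; returns passing sequences and a report.

    ``min_aa`` is the minimum number of non-stop codons (the "longer than 100
    amino acids" criterion, read inclusively as >= 100).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    passed: list[CodingSequence] = []
    report = QcReport()
    for rec in records:
        report.n_input += 1
        reason = _qc_reason(rec.sequence, min_aa)
        if reason is not None:
            report.rejections.append((rec.id, reason))
            continue
        codons = tuple(rec.sequence[i : i + 3] for i in range(0, len(rec.sequence), 3))
        passed.append(CodingSequence(id=rec.id, codons=codons, length_aa=len(codons) - 1))
        report.n_passed += 1
    return passed, report


class CodonCountTable:
    """Counts over the 64 codons for one gene or a pooled gene set."""

    __slots__ = ("counts",)

    def __init__(self, counts: dict[str, int] | None = None):
        self.counts: dict[str, int] = dict(counts or {})

    @classmethod
    def from_codons(cls, codons: Iterable[str]) -> "CodonCountTable":
        return cls(collections.Counter(codons))

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = collections.Counter(self.counts)
        merged.update(other.counts)
        return CodonCountTable(dict(merged))

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CodonCountTable) and self.counts == other.counts

    def total(self, include_stop: bool = True) -> int:
        if include_stop:
            return sum(self.counts.values())
        return sum(n for c, n in self.counts.items() if CODON_TO_AA.get(c) != "*")

    def family_counts(self, aa: str) -> dict[str, int]:
        from .genetic_code import FAMILIES

        return {c: self.counts.get(c, 0) for c in FAMILIES[aa]}

    def __repr__(self) -> str:  # pragma: no cover
        return f"CodonCountTable(n={self.total()})"


def count_codons(cds: CodingSequence, include_stop: bool = False) -> CodonCountTable:
    """Tally codon usage of one CDS; the terminal stop is counted iff requested."""
    codons = cds.codons if include_stop else cds.body
    return CodonCountTable.from_codons(codons)


def pool_counts(tables: Iterable[CodonCountTable]) -> CodonCountTable:
    """Sum codon counts across genes (Table-3-style pooling)."""
    merged: collections.Counter = collections.Counter()
    for t in tables:
        merged.update(t.counts)
    return CodonCountTable(dict(merged))
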