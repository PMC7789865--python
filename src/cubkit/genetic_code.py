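"""Standard genetic code tables and synonymous-family structure.

The analysis treats each amino acid as a single synonymous family, so Leu,
Ser and Arg are six-fold families (their two codon blocks are merged), Ile is
the only three-fold family, and Met/Trp are uninformative singletons.  The
three termination codons form an optional family of their own: they are
excluded from the 59 "informative" sense codons used by RSCU/ENc/CAI/COA but
can still be tabulated in report layouts.

Tables are derived from Biopython's standard (NCBI table 1) codon table at
import time rather than hand-typed.
"""

from __future__ import annotations

from Bio.Data import CodonTable as _CodonTable
from Bio.SeqUtils import seq3 as _seq3

_standard = _CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with "*" for the three stop codons
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
STOP_CODONS: tuple[str, ...] = tuple(sorted(_standard.stop_codons))
for _c in STOP_CODONS:
    CODON_TO_AA[_c] = "*"

ALL_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if CODON_TO_AA[c] != "*")

START_CODON = "ATG"

#: amino acid (one-letter, "*" for stop) -> sorted tuple of its codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in ALL_CODONS:
    _aa = CODON_TO_AA[_codon]
    FAMILIES[_aa] = FAMILIES.get(_aa, ()) + (_codon,)

#: amino acid -> degeneracy k (number of synonymous codons)
DEGENERACY: dict[str, int] = {aa: len(cods) for aa, cods in FAMILIES.items()}

#: amino acids with >= 2 synonymous codons (excludes Met, Trp and stop)
SYNONYMOUS_AA: tuple[str, ...] = tuple(
    sorted(aa for aa, k in DEGENERACY.items() if k >= 2 and aa != "*")
)

#: the 59 sense codons informative for bias (ATG and TGG removed)
INFORMATIVE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if DEGENERACY[CODON_TO_AA[c]] >= 2
)

#: amino acids whose family is exactly four-fold degenerate (Sueoka's
#: convention for PR2 third-position counts): Ala, Gly, Pro, Thr, Val
FOURFOLD_AA: tuple[str, ...] = tuple(
    sorted(aa for aa in SYNONYMOUS_AA if DEGENERACY[aa] == 4)
)

#: degeneracy class -> number of amino acids in the class (9, 1, 5, 3)
ENC_CLASS_SIZES: dict[int, int] = {}
for _aa in SYNONYMOUS_AA:
    _k = DEGENERACY[_aa]
    ENC_CLASS_SIZES[_k] = ENC_CLASS_SIZES.get(_k, 0) + 1


def aa_name(aa: str) -> str:
    """Three-letter name for a one-letter amino acid code ('TER' for stop)."""
    return "TER" if aa == "*" else _seq3(aa)


def is_gc(base: str) -> bool:
    return base in ("G", "C")


def third_base(codon: str) -> str:
    return codon[2]
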