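"""Per-gene nucleotide composition and positional GC metrics.

All metrics are computed on the CDS body, i.e. with the terminal stop codon
excluded; fractions are kept in [0, 1] internally and only scaled to
percentages at the reporting layer.  GC3s restricts the third-position GC
fraction to codons of amino acids with at least two synonymous codons
(Met, Trp and stops contribute nothing), whereas GC3 runs over every body
codon.  Third-position base counts (A3/U3/G3/C3) are tallied both over the
synonymous-codon scope and over the strictly four-fold degenerate families
(the default scope of the PR2 analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple

from .cds_io import CodingSequence
from .genetic_code import (
    CODON_TO_AA,
    DEGENERACY,
    FOURFOLD_AA,
    SYNONYMOUS_AA,
    is_gc,
)

Scope = Literal["all_synonymous", "fourfold_only"]


class ThirdPositionCounts(NamedTuple):
    a3: int
    u3: int
    g3: int
    c3: int
    scope: str

    @property
    def total(self) -> int:
        return self.a3 + self.u3 + self.g3 + self.c3


@dataclass(frozen=True)
class CompositionRecord:
    id: str
    frac_a: float
    frac_t: float
    frac_g: float
    frac_c: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc_all: float
    gc3s: float  # NaN when the gene has no synonymous codon
    third_fourfold: ThirdPositionCounts | None
    third_synonymous: ThirdPositionCounts | None


def gc3s_of(cds: CodingSequence) -> float:
    """GC fraction at third positions of synonymous codons (NaN if none)."""
    n = gc = 0
    for codon in cds.body:
        aa = CODON_TO_AA[codon]
        if aa == "*" or DEGENERACY[aa] < 2:
            continue
        n += 1
        gc += is_gc(codon[2])
    return gc / n if n else math.nan


def third_position_counts(
    cds: CodingSequence, scope: Scope = "fourfold_only"
) -> ThirdPositionCounts | None:
    """Third-position base counts over the selected codon scope.

    ``fourfold_only`` restricts to the five strictly four-fold degenerate
    families (Ala, Gly, Pro, Thr, Val); ``all_synonymous`` uses every codon
    of a multi-codon family.  Returns None when no codon is in scope.
    """
    if scope == "fourfold_only":
        aa_in_scope = set(FOURFOLD_AA)
    elif scope == "all_synonymous":
        aa_in_scope = set(SYNONYMOUS_AA)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    tally = {"A": 0, "T": 0, "G": 0, "C": 0}
    for codon in cds.body:
        if CODON_TO_AA[codon] in aa_in_scope:
            tally[codon[2]] += 1
    if sum(tally.values()) == 0:
        return None
    return ThirdPositionCounts(tally["A"], tally["T"], tally["G"], tally["C"], scope)


def composition_of(cds: CodingSequence) -> CompositionRecord:
    """All composition metrics of one QC'd CDS (stop codon excluded)."""
    body = cds.body
    if not body:
        raise ValueError(f"{cds.id}: empty CDS body")
    seq = "".join(body)
    n = len(seq)
    base = {b: seq.count(b) for b in "ATGC"}
    pos_gc = [0, 0, 0]
    for codon in body:
        for j in range(3):
            pos_gc[j] += is_gc(codon[j])
    ncod = len(body)
    gc1, gc2, gc3 = (pos_gc[j] / ncod for j in range(3))
    return CompositionRecord(
        id=cds.id,
        frac_a=base["A"] / n,
        frac_t=base["T"] / n,
        frac_g=base["G"] / n,
        frac_c=base["C"] / n,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc12=(gc1 + gc2) / 2,
        gc_all=(gc1 + gc2 + gc3) / 3,
        gc3s=gc3s_of(cds),
        third_fourfold=third_position_counts(cds, "fourfold_only"),
        third_synonymous=third_position_counts(cds, "all_synonymous"),
    )
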