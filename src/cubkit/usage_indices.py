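"""Codon-usage indices: RSCU, ENc (Wright's estimator), expected ENc, CAI.

RSCU
    RSCU(c) = k * n_c / sum_family(n), the observed count relative to the
    uniform-usage expectation within the amino acid's synonymous family.
    Family sums therefore equal the degeneracy k; single-codon amino acids
    (Met, Trp) have RSCU 1 whenever present.

ENc
    The effective number of codons estimated from per-family codon
    homozygosity F = (n * sum(p_hat^2) - 1) / (n - 1), averaged within each
    degeneracy class k, and combined as

        ENc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

    (2 single-codon amino acids, 9 two-fold, 1 three-fold, 5 four-fold and 3
    six-fold families, counting Leu/Ser/Arg as six-fold).  A gene using one
    codon per amino acid approaches 20; uniform usage gives 61.  Families
    with n <= 1 carry no information and are skipped; a missing three-fold
    class is imputed with (F2 + F4)/2, any other missing class is omitted
    from the sum.  The estimate is capped into [20, 61].

Expected ENc
    The null curve under pure third-position compositional pressure,
    ENc_exp(s) = 2 + s + 29 / (s^2 + (1 - s)^2) with s = GC3s.

CAI
    Relative adaptiveness w(c) = n_c / max_family(n) from a pooled reference
    of (proxy) highly expressed genes; a gene's CAI is the geometric mean of
    w over its codons, with Met, Trp and stops excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .cds_io import CodonCountTable
from .genetic_code import (
    CODON_TO_AA,
    DEGENERACY,
    ENC_CLASS_SIZES,
    FAMILIES,
    SYNONYMOUS_AA,
)

logger = logging.getLogger(__name__)

ENC_MIN, ENC_MAX = 20.0, 61.0


@dataclass
class RscuVector:
    """RSCU values per codon; families absent from the data map to NaN."""

    values: dict[str, float]

    def __getitem__(self, codon: str) -> float:
        return self.values[codon]


@dataclass
class EncValue:
    enc: float
    f_bar: dict[int, float] = field(default_factory=dict)
    n_classes_missing: int = 0


@dataclass
class CaiValue:
    cai: float
    weights: dict[str, float] = field(default_factory=dict)


def rscu(counts: CodonCountTable, include_stops: bool = False) -> RscuVector:
    """Relative synonymous codon usage of one gene or a pooled count table.

    Families with zero total are reported as NaN (missing), not zero.  With
    ``include_stops`` the three termination codons are treated as a k=3
    family of their own (the report-table convention).
    """
    aa_set = list(SYNONYMOUS_AA) + ["M", "W"]
    if include_stops:
        aa_set.append("*")
    values: dict[str, float] = {}
    for aa in aa_set:
        family = FAMILIES[aa]
        k = len(family)
        total = sum(counts[c] for c in family)
        for c in family:
            values[c] = k * counts[c] / total if total else math.nan
    return RscuVector(values=values)


def _family_homozygosity(counts: CodonCountTable, aa: str) -> tuple[int, float]:
    family = FAMILIES[aa]
    ns = [counts[c] for c in family]
    n = sum(ns)
    if n < 2:
        return n, math.nan
    f = (n * sum((ni / n) ** 2 for ni in ns) - 1) / (n - 1)
    return n, f


def enc(counts: CodonCountTable) -> EncValue:
    """Wright's effective number of codons for a single gene.

    The input must exclude stop codons (``count_codons`` default).  Returns
    NaN when no synonymous family has at least two counted codons.
    """
    class_fs: dict[int, list[float]] = {k: [] for k in ENC_CLASS_SIZES}
    for aa in SYNONYMOUS_AA:
        n, f = _family_homozygosity(counts, aa)
        if not math.isnan(f):
            class_fs[DEGENERACY[aa]].append(f)
    f_bar = {k: sum(fs) / len(fs) for k, fs in class_fs.items() if fs}
    if 3 not in f_bar and 2 in f_bar and 4 in f_bar:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2
    usable = {k: f for k, f in f_bar.items() if f > 0}
    n_missing = len(ENC_CLASS_SIZES) - len(usable)
    if not usable:
        return EncValue(enc=math.nan, f_bar=f_bar, n_classes_missing=n_missing)
    total = 2.0 + sum(ENC_CLASS_SIZES[k] / f for k, f in usable.items())
    return EncValue(
        enc=min(ENC_MAX, max(ENC_MIN, total)), f_bar=f_bar, n_classes_missing=n_missing
    )


def expected_enc(gc3s: float) -> float:
    """Null-model ENc at synonymous third-position GC content ``gc3s``."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError("gc3s must lie in [0, 1]")
    s = gc3s
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def enc_deviation(enc_obs: float, enc_exp: float) -> float:
    """Relative ENc deficit (ENc_exp - ENc_obs) / ENc_exp."""
    if enc_exp <= 0:
        raise ValueError("enc_exp must be positive")
    return (enc_exp - enc_obs) / enc_exp


def cai_weights(
    reference: CodonCountTable | list[CodonCountTable], zero_floor: float = 0.5
) -> dict[str, float]:
    """Relative adaptiveness weights from a reference gene set.

    Reference tables are pooled before weighting.  Zero-count codons within
    an observed family are floored at ``zero_floor`` occurrences so that the
    geometric mean of a gene using them is penalised, not annihilated.
    Families entirely absent from the reference are uninformative and get
    weight 1 (with a logged warning).
    """
    if isinstance(reference, list):
        from .cds_io import pool_counts

        if not reference:
            raise ValueError("reference gene set is empty")
        pooled = pool_counts(reference)
    else:
        pooled = reference
    weights: dict[str, float] = {}
    for aa in SYNONYMOUS_AA:
        family = FAMILIES[aa]
        ns = {c: float(pooled[c]) for c in family}
        if sum(ns.values()) == 0:
            logger.warning("CAI reference has no %s codons; weights set to 1", aa)
            weights.update({c: 1.0 for c in family})
            continue
        floored = {c: max(n, zero_floor) for c, n in ns.items()}
        top = max(floored.values())
        weights.update({c: n / top for c, n in floored.items()})
    weights["ATG"] = 1.0
    weights["TGG"] = 1.0
    return weights


def cai(counts: CodonCountTable, weights: dict[str, float]) -> CaiValue:
    """Codon adaptation index: geometric mean of weights over counted codons.

    ATG, TGG and stop codons are excluded.  Computed as a mean of logs for
    numerical stability; the contract is the plain geometric mean.
    """
    log_sum = 0.0
    n = 0
    for codon, count in counts.counts.items():
        aa = CODON_TO_AA.get(codon)
        if aa is None or aa == "*" or DEGENERACY[aa] < 2 or count == 0:
            continue
        w = weights[codon]
        if w <= 0:
            raise ValueError(f"non-positive CAI weight for {codon}")
        log_sum += count * math.log(w)
        n += count
    if n == 0:
        return CaiValue(cai=math.nan, weights=weights)
    return CaiValue(cai=math.exp(log_sum / n), weights=weights)
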