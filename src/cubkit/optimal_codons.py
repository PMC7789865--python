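"""Optimal-codon determination from high- vs low-expression gene pools.

Genes are ranked by CAI; the top and bottom fractions (default 5% each) form
the high- and low-expression pools.  Codon counts are summed within each
pool before RSCU is computed, and every codon of a multi-codon sense family
is tested with a 2x2 Pearson chi-square (this codon vs rest of family,
high vs low pool; no continuity correction).  A codon is optimal when
p < 0.01 and its RSCU is higher in the high pool.  ATG and TGG are excluded
from testing; termination codons appear in the table and are tested but are
never flagged optimal.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from dataclasses import dataclass
from scipy import stats

from .cds_io import CodonCountTable, pool_counts
from .genetic_code import DEGENERACY, FAMILIES, SYNONYMOUS_AA, aa_name
from .usage_indices import rscu

logger = logging.getLogger(__name__)

P_OPTIMAL = 0.01


@dataclass(frozen=True)
class ExpressionPartition:
    high_ids: tuple[str, ...]
    low_ids: tuple[str, ...]
    fraction: float
    ranking_index: str = "CAI"


def partition_by_cai(
    genes: pd.DataFrame, fraction: float = 0.05
) -> ExpressionPartition:
    """Top/bottom CAI gene sets of equal size max(1, round(fraction * n)).

    ``genes`` needs columns ``id`` and ``CAI``.  Ties are broken by gene id
    (lexicographic) for determinism; the two sets are guaranteed disjoint.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    df = genes[["id", "CAI"]].dropna()
    n = len(df)
    size = max(1, math.floor(fraction * n + 0.5))
    if 2 * size > n:
        raise ValueError(f"too few genes ({n}) for fraction {fraction}")
    ordered = df.sort_values(["CAI", "id"], ascending=[False, True])["id"].tolist()
    return ExpressionPartition(
        high_ids=tuple(ordered[:size]),
        low_ids=tuple(ordered[-size:]),
        fraction=fraction,
    )


def pooled_rscu_table(
    high: list[CodonCountTable] | CodonCountTable,
    low: list[CodonCountTable] | CodonCountTable,
) -> pd.DataFrame:
    """Per-codon pooled counts and RSCU for the two expression pools.

    Counts are summed across genes within each pool before RSCU is computed.
    The layout covers all sense codons plus the stop-codon family, sorted by
    (amino acid name, codon); test columns are left to
    :func:`optimal_codon_test`.
    """
    high_pool = pool_counts(high) if isinstance(high, list) else high
    low_pool = pool_counts(low) if isinstance(low, list) else low
    if high_pool.total() == 0 or low_pool.total() == 0:
        raise ValueError("both pools must contain codons")
    rscu_high = rscu(high_pool, include_stops=True)
    rscu_low = rscu(low_pool, include_stops=True)
    rows = []
    for aa in sorted(FAMILIES, key=aa_name):
        for codon in FAMILIES[aa]:
            rows.append(
                {
                    "amino_acid": aa_name(aa),
                    "codon": codon,
                    "rscu_high": rscu_high.values.get(codon, math.nan),
                    "n_high": high_pool[codon],
                    "rscu_low": rscu_low.values.get(codon, math.nan),
                    "n_low": low_pool[codon],
                }
            )
    return pd.DataFrame(rows)


def optimal_codon_test(records: pd.DataFrame) -> pd.DataFrame:
    """Fill chi2/p/optimal columns of a pooled-RSCU table.

    Each codon of a multi-codon family is tested against the rest of its
    family across pools.  Families with zero total in either pool are
    skipped (flagged not-optimal, logged).
    """
    df = records.copy()
    df["chi2"] = math.nan
    df["p"] = math.nan
    df["optimal"] = False
    fam_totals = df.groupby("amino_acid")[["n_high", "n_low"]].sum()
    for idx, row in df.iterrows():
        aa3 = row["amino_acid"]
        codon = row["codon"]
        family_size = DEGENERACY["*" if aa3 == "TER" else _one_letter(aa3)]
        if family_size < 2 or aa3 in ("Met", "Trp"):
            continue
        fam_high = int(fam_totals.loc[aa3, "n_high"])
        fam_low = int(fam_totals.loc[aa3, "n_low"])
        if fam_high == 0 or fam_low == 0:
            logger.warning("family %s empty in one pool; %s skipped", aa3, codon)
            continue
        a, c = int(row["n_high"]), int(row["n_low"])
        table = np.array([[a, fam_high - a], [c, fam_low - c]])
        if table.sum(axis=0).min() == 0:
            # codon (or its complement) absent from both pools: no test
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        df.loc[idx, "chi2"] = float(chi2)
        df.loc[idx, "p"] = float(p)
        df.loc[idx, "optimal"] = bool(
            aa3 != "TER" and p < P_OPTIMAL and row["rscu_high"] > row["rscu_low"]
        )
    return df


def _one_letter(aa3: str) -> str:
    for aa in FAMILIES:
        if aa_name(aa) == aa3:
            return aa
    raise KeyError(aa3)


def optimal_codons_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Run the full optimal-codon procedure from a pre-pooled counts table.

    ``counts`` needs columns ``codon`` (DNA alphabet), ``n_high`` and
    ``n_low``; codons absent from the table count as zero.  This is the
    entry point for tabulated high/low pool counts when the underlying
    sequences are not available.
    """
    high = CodonCountTable(dict(zip(counts["codon"], counts["n_high"].astype(int))))
    low = CodonCountTable(dict(zip(counts["codon"], counts["n_low"].astype(int))))
    table = pooled_rscu_table(high, low)
    return optimal_codon_test(table)
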