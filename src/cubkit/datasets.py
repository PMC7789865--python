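"""Bundled worked-example data."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_rpalmatum_highlow() -> pd.DataFrame:
    """Pooled codon counts of the high/low-expression gene pools of a
    *Rheum palmatum* transcriptome CDS set.

    The high and low pools are the top and bottom 5% of 2,626 QC'd CDSs
    ranked by CAI; counts are codon totals summed over each pool.  Columns:
    ``amino_acid`` (three-letter, ``TER`` for stop), ``codon`` (DNA
    alphabet), ``n_high``, ``n_low``, and ``reconstructed`` (1 for the few
    codons whose counts were not tabulated at source and were back-calculated
    from the family RSCU value and the printed count of a sibling codon;
    their per-codon values are placeholders that preserve the family totals,
    and the Glu family is absent because no member was tabulated).

    This table lets the pooled-RSCU and optimal-codon stages run without any
    sequence data.
    """
    with resources.files("cubkit").joinpath("data/rpalmatum_highlow_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
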