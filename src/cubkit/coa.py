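"""Correspondence analysis of the gene x codon RSCU matrix.

The gene x 59-codon RSCU matrix is decomposed with the chi-square metric:
divide by the grand total, form standardized residuals
(O - E) / sqrt(E) under row-by-column independence, take the SVD, and report
principal coordinates.  Axis k explains sigma_k^2 / sum(sigma^2) of the total
inertia, and the total inertia equals the table's chi-square statistic
divided by its grand total.

Because every complete RSCU row sums to the same constant (the family sums
equal the degeneracies), decomposing the raw RSCU matrix is identical to
decomposing row profiles; missing families in a gene are imputed with the
family-uniform value 1.0 per codon so that this property is preserved and no
bias direction is induced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import INFORMATIVE_CODONS
from .usage_indices import RscuVector


@dataclass
class CoaResult:
    gene_ids: list[str]
    codons: list[str]
    gene_coords: np.ndarray  # genes x axes, principal coordinates
    codon_coords: np.ndarray  # codons x axes, principal coordinates
    singular_values: np.ndarray  # all non-trivial axes, descending
    inertia_fraction: np.ndarray  # per retained axis
    total_inertia: float

    @property
    def n_axes(self) -> int:
        return self.gene_coords.shape[1]


def rscu_matrix(
    vectors: dict[str, RscuVector], impute: float = 1.0
) -> pd.DataFrame:
    """Stack per-gene RSCU vectors into a genes x 59 matrix.

    NaN entries (families absent from a gene) are imputed with the neutral
    family-uniform value so row profiles stay well defined.
    """
    df = pd.DataFrame(
        {gid: [vec.values.get(c, math.nan) for c in INFORMATIVE_CODONS] for gid, vec in vectors.items()},
        index=list(INFORMATIVE_CODONS),
    ).T
    return df.fillna(impute)


def correspondence_analysis(table: np.ndarray, n_axes: int = 4) -> tuple[
    np.ndarray, np.ndarray, np.ndarray, float
]:
    """Plain correspondence analysis of a non-negative matrix.

    Returns (row principal coords, column principal coords, singular values,
    total inertia), with coordinates truncated to ``n_axes`` axes.  Rows and
    columns must have positive sums.
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 2 or np.any(X < 0):
        raise ValueError("input must be a non-negative 2-D matrix")
    grand = X.sum()
    if grand <= 0:
        raise ValueError("matrix has zero grand total")
    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(r == 0) or np.any(c == 0):
        raise ValueError("matrix has an all-zero row or column")
    E = np.outer(r, c)
    S = (P - E) / np.sqrt(E)
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    rank = min(X.shape[0] - 1, X.shape[1] - 1)
    sv = sv[:rank]
    U = U[:, :rank]
    Vt = Vt[:rank]
    total_inertia = float(np.sum(sv**2))
    k = min(n_axes, rank)
    row_coords = (U[:, :k] * sv[:k]) / np.sqrt(r)[:, None]
    col_coords = (Vt[:k].T * sv[:k]) / np.sqrt(c)[:, None]
    return row_coords, col_coords, sv, total_inertia


def coa_on_rscu(
    rscu_df: pd.DataFrame,
    n_axes: int = 4,
    orient_by: np.ndarray | pd.Series | None = None,
) -> CoaResult:
    """Correspondence analysis of a genes x codons RSCU matrix.

    ``orient_by`` (typically per-gene GC3) fixes the sign of Axis 1 so that
    its Pearson correlation with the supplied vector is non-negative; the
    remaining axes are oriented so their largest-magnitude gene coordinate
    is positive.  Requires at least 3 genes.
    """
    if rscu_df.shape[0] < 3:
        raise ValueError("correspondence analysis needs at least 3 genes")
    # decompose row profiles: a no-op for complete RSCU rows (constant row
    # sum 59) but it makes gene coordinates exactly invariant to scaling a
    # single gene's RSCU row by a positive constant
    mat = rscu_df.to_numpy(dtype=float)
    row_sums = mat.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise ValueError("every gene needs a positive RSCU row sum")
    gene_coords, codon_coords, sv, total = correspondence_analysis(
        mat / row_sums, n_axes=n_axes
    )
    k = gene_coords.shape[1]
    for axis in range(k):
        flip = False
        if axis == 0 and orient_by is not None and total > 0:
            v = np.asarray(orient_by, dtype=float)
            x = gene_coords[:, 0]
            if np.std(v) > 0 and np.std(x) > 0:
                flip = np.corrcoef(x, v)[0, 1] < 0
        else:
            col = gene_coords[:, axis]
            if col.size and np.max(np.abs(col)) > 0:
                flip = col[np.argmax(np.abs(col))] < 0
        if flip:
            gene_coords[:, axis] *= -1
            codon_coords[:, axis] *= -1
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = (sv[:k] ** 2 / total) if total > 0 else np.zeros(k)
    return CoaResult(
        gene_ids=list(rscu_df.index),
        codons=list(rscu_df.columns),
        gene_coords=gene_coords,
        codon_coords=codon_coords,
        singular_values=sv,
        inertia_fraction=np.asarray(fractions),
        total_inertia=total,
    )


def axis1_scores(result: CoaResult) -> pd.Series:
    """First-axis gene coordinates (sign-stabilized), indexed by gene id."""
    if result.n_axes < 1:
        raise ValueError("result has no axes")
    return pd.Series(result.gene_coords[:, 0], index=result.gene_ids, name="Axis1")
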