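"""Gene-set-level codon bias diagnostics.

* Neutrality regression: ordinary least squares of GC12 on GC3 across genes,
  with the Pearson correlation of the pair.  A slope near 1 is read as
  third-position composition dragging the first two positions along
  (mutational pressure); a slope near 0 as selective constraint on the
  protein-coding positions.
* ENc-GC3s table: observed ENc against the expected null curve, with the
  relative deviation (ENc_exp - ENc_obs)/ENc_exp and its 0.05-width
  frequency histogram.
* PR2 bias: per-gene point [G3/(G3+C3), A3/(A3+U3)] with quadrant counts
  about the (0.5, 0.5) no-strand-bias centre.
* Parameter correlation matrix over GC12, GC3, GCall, ENc, CAI and the
  first correspondence-analysis axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .composition import CompositionRecord, Scope
from .usage_indices import enc_deviation, expected_enc

CORRELATION_PARAMS = ("GC12", "GC3", "GCall", "ENc", "CAI", "Axis1")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int
    stderr: float  # standard error of the slope


@dataclass(frozen=True)
class Pr2Point:
    id: str
    x: float  # G3 / (G3 + C3)
    y: float  # A3 / (A3 + U3)
    quadrant: int  # 1: x>.5,y>.5; 2: x<.5,y>.5; 3: x<.5,y<.5; 4: x>.5,y<.5
    on_boundary: bool


@dataclass
class CorrelationMatrix:
    parameters: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    method: str
    n: int


def neutrality_regression(points: list[tuple[float, float]]) -> RegressionResult:
    """OLS of GC12 on GC3 over (GC3, GC12) pairs; NaN pairs are dropped."""
    arr = np.asarray(points, dtype=float)
    arr = arr[~np.isnan(arr).any(axis=1)]
    if arr.shape[0] < 3:
        raise ValueError("neutrality regression needs at least 3 complete points")
    gc3, gc12 = arr[:, 0], arr[:, 1]
    if np.ptp(gc3) == 0:
        raise ValueError("GC3 has zero variance; regression undefined")
    fit = stats.linregress(gc3, gc12)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        n=int(arr.shape[0]),
        stderr=float(fit.stderr),
    )


def enc_gc3s_table(
    genes: pd.DataFrame, bin_width: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed-vs-expected ENc table plus binned deviation frequencies.

    ``genes`` must carry columns ``id``, ``GC3s`` and ``ENc``.  Genes with a
    missing value in either are excluded from the table.
    """
    df = genes[["id", "GC3s", "ENc"]].dropna().copy()
    df["ENc_exp"] = df["GC3s"].map(expected_enc)
    df["deviation"] = [
        enc_deviation(o, e) for o, e in zip(df["ENc"], df["ENc_exp"])
    ]
    df["below_curve"] = df["ENc"] < df["ENc_exp"]
    dev = df["deviation"]
    lo = math.floor(dev.min() / bin_width) * bin_width
    hi = math.ceil(dev.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    counts, edges = np.histogram(dev, bins=edges)
    hist = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "n_genes": counts}
    )
    return df.reset_index(drop=True), hist


def _quadrant(x: float, y: float) -> tuple[int, bool]:
    on_boundary = x == 0.5 or y == 0.5
    # candidates consistent with >=/<= at the boundary; ties go to the
    # lowest quadrant index for reproducible totals
    candidates = []
    for q, (xs, ys) in {1: (1, 1), 2: (-1, 1), 3: (-1, -1), 4: (1, -1)}.items():
        if (x - 0.5) * xs >= 0 and (y - 0.5) * ys >= 0:
            candidates.append(q)
    return min(candidates), on_boundary


def pr2_analysis(
    genes: list[CompositionRecord], scope: Scope = "fourfold_only"
) -> tuple[list[Pr2Point], dict]:
    """PR2-bias points and quadrant statistics for a gene set.

    Genes with an empty scope or with A3+U3 = 0 or G3+C3 = 0 are excluded
    (listed under ``excluded`` in the summary).  The summary also counts the
    points falling inside the central [0.2, 0.8] x [0.2, 0.8] box.
    """
    points: list[Pr2Point] = []
    excluded: list[str] = []
    for rec in genes:
        counts = (
            rec.third_fourfold if scope == "fourfold_only" else rec.third_synonymous
        )
        if counts is None or counts.a3 + counts.u3 == 0 or counts.g3 + counts.c3 == 0:
            excluded.append(rec.id)
            continue
        x = counts.g3 / (counts.g3 + counts.c3)
        y = counts.a3 / (counts.a3 + counts.u3)
        q, boundary = _quadrant(x, y)
        points.append(Pr2Point(id=rec.id, x=x, y=y, quadrant=q, on_boundary=boundary))
    quadrants = {q: sum(p.quadrant == q for p in points) for q in (1, 2, 3, 4)}
    summary = {
        "scope": scope,
        "n": len(points),
        "quadrants": quadrants,
        "n_on_boundary": sum(p.on_boundary for p in points),
        "n_in_central_box": sum(
            0.2 <= p.x <= 0.8 and 0.2 <= p.y <= 0.8 for p in points
        ),
        "excluded": excluded,
    }
    return points, summary


def correlation_matrix(
    genes: pd.DataFrame, method: str = "pearson"
) -> CorrelationMatrix:
    """Pairwise correlations (and p-values) of the six bias parameters.

    ``genes`` must carry the columns in :data:`CORRELATION_PARAMS`.  Rows
    with any missing value are dropped so every pair uses the same genes.
    Constant parameters yield NaN correlations with a warning.  P-values are
    two-sided and unadjusted.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    df = genes[list(CORRELATION_PARAMS)].dropna()
    n = len(df)
    if n < 3:
        raise ValueError("correlation matrix needs at least 3 complete genes")
    params = CORRELATION_PARAMS
    r = pd.DataFrame(np.eye(len(params)), index=params, columns=params)
    p = pd.DataFrame(np.zeros((len(params), len(params))), index=params, columns=params)
    test = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i, a in enumerate(params):
        for j, b in enumerate(params):
            if j <= i:
                continue
            xa, xb = df[a].to_numpy(), df[b].to_numpy()
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                warnings.warn(f"parameter {a if np.ptp(xa) == 0 else b} is constant")
                rij = pij = math.nan
            else:
                res = test(xa, xb)
                rij, pij = float(res.statistic), float(res.pvalue)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return CorrelationMatrix(parameters=params, r=r, p=p, method=method, n=n)
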