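"""The end-to-end codon-usage-bias model and its results object.

:class:`CodonUsageAnalysis` is built from CDS sequences (raw FASTA records
or already-QC'd coding sequences); :meth:`~CodonUsageAnalysis.fit` runs the
whole analysis -- QC, per-gene composition and indices (RSCU, ENc, CAI),
neutrality regression, ENc-GC3s and PR2 diagnostics, correspondence
analysis of the RSCU matrix, the parameter correlation matrix, and
optimal-codon determination from the CAI-extreme gene pools -- and returns a
:class:`CodonUsageResults` carrying every table, with ``summary()`` and
``save()`` for reporting.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from ._report import round_half_up
from .bias_diagnostics import (
    CorrelationMatrix,
    Pr2Point,
    RegressionResult,
    correlation_matrix,
    enc_gc3s_table,
    neutrality_regression,
    pr2_analysis,
)
from .cds_io import (
    CodingSequence,
    CodonCountTable,
    QcReport,
    SequenceRecord,
    count_codons,
    pool_counts,
    read_fasta,
    qc_filter_cds,
)
from .coa import CoaResult, axis1_scores, coa_on_rscu, rscu_matrix
from .composition import composition_of
from .genetic_code import FAMILIES, aa_name
from .optimal_codons import (
    ExpressionPartition,
    optimal_codon_test,
    partition_by_cai,
    pooled_rscu_table,
)
from .usage_indices import cai, cai_weights, enc, enc_deviation, expected_enc, rscu


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _gc_class(gc_all: float) -> str:
    if gc_all > 0.60:
        return ">60%"
    if gc_all >= 0.45:
        return "45-60%"
    return "<45%"


@dataclass
class CodonUsageResults:
    """Fitted results; all tables use fractions in [0, 1] except where noted."""

    qc_report: QcReport
    gene_metrics: pd.DataFrame
    rscu_pooled: pd.DataFrame
    cai_weights: dict[str, float]
    neutrality: RegressionResult
    enc_gc3s: pd.DataFrame
    enc_deviation_hist: pd.DataFrame
    pr2_points: list[Pr2Point]
    pr2_summary: dict
    coa: CoaResult
    correlations: CorrelationMatrix
    partition: ExpressionPartition
    optimal_codons: pd.DataFrame
    config: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.gene_metrics)

    @property
    def n_optimal(self) -> int:
        return int(self.optimal_codons["optimal"].sum())

    def gc_histogram(self, bin_width: float = 0.025) -> pd.DataFrame:
        """Frequency table of overall GC content, binned at 2.5%."""
        gc = self.gene_metrics["GCall"]
        lo = math.floor(gc.min() / bin_width) * bin_width
        hi = math.ceil(gc.max() / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, edges = np.histogram(gc, bins=edges)
        return pd.DataFrame(
            {"bin_low": edges[:-1], "bin_high": edges[1:], "n_genes": counts}
        )

    def summary(self) -> str:
        gm = self.gene_metrics
        frac = self.coa.inertia_fraction
        lines = [
            "Codon usage bias analysis",
            "=" * 58,
            f"Genes analysed:        {self.n_genes} "
            f"(of {self.qc_report.n_input} input; {len(self.qc_report.rejections)} rejected by QC)",
            f"Mean GC / GC1 / GC2 / GC3 (%): "
            f"{100 * gm['GCall'].mean():.2f} / {100 * gm['GC1'].mean():.2f} / "
            f"{100 * gm['GC2'].mean():.2f} / {100 * gm['GC3'].mean():.2f}",
            f"ENc: mean {gm['ENc'].mean():.2f}, range "
            f"{gm['ENc'].min():.2f}-{gm['ENc'].max():.2f}; "
            f"{int((gm['ENc'] < 35).sum())} genes < 35",
            f"CAI: mean {gm['CAI'].mean():.3f} "
            f"(reference: {self.config.get('cai_reference', 'lowest-ENc pool')})",
            f"Neutrality plot: GC12 = {self.neutrality.slope:.3f} * GC3 + "
            f"{self.neutrality.intercept:.3f}  (r = {self.neutrality.r:.3f}, "
            f"p = {self.neutrality.p:.3g}, n = {self.neutrality.n})",
            f"ENc-GC3s: {int(self.enc_gc3s['below_curve'].sum())}/{len(self.enc_gc3s)} "
            f"genes below the expected curve",
            f"PR2 ({self.pr2_summary['scope']}): quadrants "
            + ", ".join(f"Q{q}={n}" for q, n in self.pr2_summary["quadrants"].items())
            + f"; {self.pr2_summary['n_in_central_box']} in [0.2,0.8]^2",
            f"COA: Axis1 {100 * frac[0]:.2f}% and Axis2 "
            + (f"{100 * frac[1]:.2f}%" if len(frac) > 1 else "n/a")
            + " of total inertia",
            f"Axis1-GC3 correlation: r = "
            f"{self.correlations.r.loc['Axis1', 'GC3']:.3f}",
            f"Optimal codons (p < 0.01, high-pool biased): {self.n_optimal} "
            f"of {int(self.optimal_codons['chi2'].notna().sum())} tested "
            f"({len(self.partition.high_ids)} genes per pool)",
        ]
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, str]:
        """Write the report bundle as TSV/JSON; returns file -> sha256."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        def _write(df: pd.DataFrame, name: str) -> None:
            df.to_csv(outdir / name, sep="\t", index=False, float_format="%.6f")

        self.qc_report.to_tsv(outdir / "qc_report.tsv")
        _write(self.gene_metrics, "gene_metrics.tsv")
        pooled = self.rscu_pooled.copy()
        pooled["RSCU"] = pooled["RSCU"].map(lambda v: round_half_up(v, 2))
        _write(pooled, "rscu_pooled.tsv")
        _write(
            pd.DataFrame(
                [
                    {
                        "slope": self.neutrality.slope,
                        "intercept": self.neutrality.intercept,
                        "r": self.neutrality.r,
                        "p": self.neutrality.p,
                        "n": self.neutrality.n,
                    }
                ]
            ),
            "neutrality.tsv",
        )
        _write(self.enc_gc3s, "enc_gc3s.tsv")
        _write(self.enc_deviation_hist, "enc_deviation_hist.tsv")
        _write(
            pd.DataFrame(
                [
                    {"id": p.id, "x_g3": p.x, "y_a3": p.y, "quadrant": p.quadrant,
                     "on_boundary": p.on_boundary}
                    for p in self.pr2_points
                ]
            ),
            "pr2.tsv",
        )
        _write(self.gc_histogram(), "gc_histogram.tsv")
        coa_df = pd.DataFrame(
            self.coa.gene_coords,
            columns=[f"Axis{k + 1}" for k in range(self.coa.n_axes)],
        )
        coa_df.insert(0, "id", self.coa.gene_ids)
        coa_df["gc_class"] = self.gene_metrics.set_index("id").loc[
            self.coa.gene_ids, "GC_class"
        ].to_numpy()
        _write(coa_df, "coa_genes.tsv")
        ax = pd.DataFrame(
            {
                "axis": np.arange(1, self.coa.n_axes + 1),
                "inertia_fraction": self.coa.inertia_fraction,
                "cumulative": np.cumsum(self.coa.inertia_fraction),
            }
        )
        _write(ax, "coa_axes.tsv")
        self.correlations.r.to_csv(outdir / "correlations_r.tsv", sep="\t", float_format="%.6f")
        self.correlations.p.to_csv(outdir / "correlations_p.tsv", sep="\t", float_format="%.6g")
        opt = self.optimal_codons.copy()
        for col in ("rscu_high", "rscu_low"):
            opt[col] = opt[col].map(lambda v: round_half_up(v, 2))
        _write(opt, "optimal_codons.tsv")

        checksums = {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest()
            for f in sorted(outdir.iterdir())
            if f.suffix == ".tsv"
        }
        manifest = {
            "cubkit_version": __version__,
            "config": self.config,
            "n_genes": self.n_genes,
            "checksums": checksums,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return checksums


class CodonUsageAnalysis:
    """Codon-usage-bias model over a CDS collection.

    Parameters
    ----------
    sequences
        Raw :class:`SequenceRecord` objects (QC is applied during fit) or
        already-validated :class:`CodingSequence` objects.
    min_aa
        Minimum CDS length in non-stop codons for QC.
    cai_reference
        ``None`` to derive CAI weights internally from the pooled counts of
        the most codon-biased ``reference_fraction`` of genes (a proxy for
        highly expressed genes), or an explicit codon->weight map.
    reference_method
        How the internal reference is ranked: ``"enc_residual"`` (default;
        lowest ENc relative to the GC3s-expected curve) or ``"enc"`` (lowest
        raw ENc).
    partition_fraction
        Fraction of genes in each of the high/low CAI pools for
        optimal-codon determination.
    pr2_scope
        ``"fourfold_only"`` (default) or ``"all_synonymous"``.
    correlation_method
        ``"pearson"`` (default) or ``"spearman"``.
    n_axes
        Correspondence-analysis axes to retain.
    """

    def __init__(
        self,
        sequences: Sequence[SequenceRecord | CodingSequence],
        *,
        min_aa: int = 100,
        cai_reference: dict[str, float] | None = None,
        reference_fraction: float = 0.05,
        reference_method: str = "enc_residual",
        partition_fraction: float = 0.05,
        pr2_scope: str = "fourfold_only",
        correlation_method: str = "pearson",
        n_axes: int = 4,
    ):
        self.sequences = list(sequences)
        self.min_aa = min_aa
        self.cai_reference = cai_reference
        self.reference_fraction = reference_fraction
        if reference_method not in ("enc_residual", "enc"):
            raise ValueError("reference_method must be 'enc_residual' or 'enc'")
        self.reference_method = reference_method
        self.partition_fraction = partition_fraction
        self.pr2_scope = pr2_scope
        self.correlation_method = correlation_method
        self.n_axes = n_axes

    @classmethod
    def from_fasta(cls, path: str | Path, **kwargs) -> "CodonUsageAnalysis":
        return cls(read_fasta(path), **kwargs)

    def fit(self) -> CodonUsageResults:
        # --- QC ---------------------------------------------------------
        if self.sequences and isinstance(self.sequences[0], CodingSequence):
            genes: list[CodingSequence] = list(self.sequences)  # type: ignore[arg-type]
            report = QcReport(n_input=len(genes), n_passed=len(genes))
        else:
            genes, report = qc_filter_cds(self.sequences, min_aa=self.min_aa)  # type: ignore[arg-type]
        if not genes:
            raise PipelineError("qc", "no sequences passed the CDS quality filter")

        # --- per-gene composition and indices ---------------------------
        counts = {g.id: count_codons(g) for g in genes}
        comps = {g.id: composition_of(g) for g in genes}
        rscus = {g.id: rscu(counts[g.id]) for g in genes}
        encs = {g.id: enc(counts[g.id]).enc for g in genes}

        if self.cai_reference is not None:
            weights = dict(self.cai_reference)
            ref_label = "user-supplied"
        else:
            # Rank candidate reference genes by their ENc deficit below the
            # GC3s-expected curve (default): raw ENc conflates selective bias
            # with compositional extremity, whereas the residual isolates the
            # selection signal a highly-expressed reference should carry.
            def _rank_key(g: CodingSequence) -> tuple[float, str]:
                e = encs[g.id]
                s = comps[g.id].gc3s
                if math.isnan(e):
                    return (math.inf, g.id)
                if self.reference_method == "enc_residual" and not math.isnan(s):
                    return (e - expected_enc(s), g.id)
                return (e, g.id)

            ranked = sorted(genes, key=_rank_key)
            n_ref = max(1, math.floor(self.reference_fraction * len(genes) + 0.5))
            weights = cai_weights([counts[g.id] for g in ranked[:n_ref]])
            ref_label = (
                f"most ENc-deficient {self.reference_fraction:.0%} pool (n={n_ref})"
                if self.reference_method == "enc_residual"
                else f"lowest-ENc {self.reference_fraction:.0%} pool (n={n_ref})"
            )
        cais = {g.id: cai(counts[g.id], weights).cai for g in genes}

        rows = []
        for g in genes:
            c = comps[g.id]
            e_obs = encs[g.id]
            e_exp = expected_enc(c.gc3s) if not math.isnan(c.gc3s) else math.nan
            rows.append(
                {
                    "id": g.id,
                    "length_aa": g.length_aa,
                    "frac_A": c.frac_a,
                    "frac_T": c.frac_t,
                    "frac_G": c.frac_g,
                    "frac_C": c.frac_c,
                    "GC1": c.gc1,
                    "GC2": c.gc2,
                    "GC3": c.gc3,
                    "GC12": c.gc12,
                    "GCall": c.gc_all,
                    "GC3s": c.gc3s,
                    "ENc": e_obs,
                    "ENc_exp": e_exp,
                    "ENc_dev": enc_deviation(e_obs, e_exp)
                    if not (math.isnan(e_obs) or math.isnan(e_exp))
                    else math.nan,
                    "CAI": cais[g.id],
                    "GC_class": _gc_class(c.gc_all),
                }
            )
        gm = pd.DataFrame(rows).sort_values("id").reset_index(drop=True)

        # --- pooled RSCU (whole-set usage table) ------------------------
        pooled = pool_counts(list(counts.values()))
        pooled_rscu = rscu(pooled, include_stops=True)
        pooled_rows = [
            {
                "amino_acid": aa_name(aa),
                "codon": codon,
                "n": pooled[codon],
                "RSCU": pooled_rscu.values.get(codon, math.nan),
            }
            for aa in sorted(FAMILIES, key=aa_name)
            for codon in FAMILIES[aa]
        ]
        pooled_df = pd.DataFrame(pooled_rows)
        pooled_df["preferred"] = pooled_df["RSCU"] > 1

        # --- correspondence analysis ------------------------------------
        try:
            mat = rscu_matrix(rscus)
            mat = mat.loc[gm["id"]]
            coa_res = coa_on_rscu(
                mat, n_axes=self.n_axes, orient_by=gm.set_index("id").loc[mat.index, "GC3"]
            )
        except ValueError as err:
            raise PipelineError("coa", str(err)) from err
        gm = gm.merge(axis1_scores(coa_res).rename("Axis1"), left_on="id", right_index=True)

        # --- diagnostics -------------------------------------------------
        try:
            neut = neutrality_regression(list(zip(gm["GC3"], gm["GC12"])))
        except ValueError as err:
            raise PipelineError("neutrality", str(err)) from err
        enc_table, enc_hist = enc_gc3s_table(gm)
        pr2_points, pr2_summary = pr2_analysis(
            [comps[i] for i in gm["id"]], scope=self.pr2_scope
        )
        corr = correlation_matrix(gm, method=self.correlation_method)

        # --- optimal codons ----------------------------------------------
        try:
            part = partition_by_cai(gm, fraction=self.partition_fraction)
        except ValueError as err:
            raise PipelineError("optimal", str(err)) from err
        high = [count_codons(g, include_stop=True) for g in genes if g.id in set(part.high_ids)]
        low = [count_codons(g, include_stop=True) for g in genes if g.id in set(part.low_ids)]
        optimal = optimal_codon_test(pooled_rscu_table(high, low))

        return CodonUsageResults(
            qc_report=report,
            gene_metrics=gm,
            rscu_pooled=pooled_df,
            cai_weights=weights,
            neutrality=neut,
            enc_gc3s=enc_table,
            enc_deviation_hist=enc_hist,
            pr2_points=pr2_points,
            pr2_summary=pr2_summary,
            coa=coa_res,
            correlations=corr,
            partition=part,
            optimal_codons=optimal,
            config={
                "min_aa": self.min_aa,
                "cai_reference": ref_label,
                "reference_method": self.reference_method,
                "partition_fraction": self.partition_fraction,
                "pr2_scope": self.pr2_scope,
                "correlation_method": self.correlation_method,
                "n_axes": self.n_axes,
            },
        )
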