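"""Optional diagnostic plots for fitted results (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model import CodonUsageResults
from .usage_indices import expected_enc


def plot_neutrality(results: CodonUsageResults, ax=None):
    """GC12 vs GC3 scatter with the fitted regression line."""
    ax = ax or plt.subplots()[1]
    gm = results.gene_metrics
    ax.scatter(gm["GC3"], gm["GC12"], s=8, alpha=0.5)
    xs = np.linspace(gm["GC3"].min(), gm["GC3"].max(), 50)
    fit = results.neutrality
    ax.plot(xs, fit.intercept + fit.slope * xs, "r-",
            label=f"slope={fit.slope:.3f}, r={fit.r:.3f}")
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    ax.legend()
    return ax


def plot_enc_gc3s(results: CodonUsageResults, ax=None):
    """Observed ENc against GC3s with the null expectation curve."""
    ax = ax or plt.subplots()[1]
    df = results.enc_gc3s
    ax.scatter(df["GC3s"], df["ENc"], s=8, alpha=0.5)
    xs = np.linspace(0.0, 1.0, 200)
    ax.plot(xs, [expected_enc(s) for s in xs], "k-", label="expected")
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENc")
    ax.set_ylim(15, 65)
    ax.legend()
    return ax


def plot_pr2(results: CodonUsageResults, ax=None):
    """PR2-bias square with the (0.5, 0.5) centre lines."""
    ax = ax or plt.subplots()[1]
    ax.scatter([p.x for p in results.pr2_points], [p.y for p in results.pr2_points],
               s=8, alpha=0.5)
    ax.axhline(0.5, color="k", lw=0.8)
    ax.axvline(0.5, color="k", lw=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("G3 / (G3 + C3)")
    ax.set_ylabel("A3 / (A3 + U3)")
    return ax


def plot_coa(results: CodonUsageResults, ax=None):
    """Gene cloud on the first two correspondence-analysis axes, by GC class."""
    ax = ax or plt.subplots()[1]
    coords = results.coa.gene_coords
    classes = results.gene_metrics.set_index("id").loc[
        results.coa.gene_ids, "GC_class"
    ]
    for cls in ("<45%", "45-60%", ">60%"):
        mask = (classes == cls).to_numpy()
        if mask.any() and coords.shape[1] >= 2:
            ax.scatter(coords[mask, 0], coords[mask, 1], s=8, alpha=0.6, label=cls)
    frac = results.coa.inertia_fraction
    ax.set_xlabel(f"Axis 1 ({100 * frac[0]:.1f}%)")
    if len(frac) > 1:
        ax.set_ylabel(f"Axis 2 ({100 * frac[1]:.1f}%)")
    ax.legend(title="GC content")
    return ax


def plot_cai_enc(results: CodonUsageResults, ax=None):
    """ENc against CAI (expression-level diagnostic)."""
    ax = ax or plt.subplots()[1]
    gm = results.gene_metrics
    ax.scatter(gm["CAI"], gm["ENc"], s=8, alpha=0.5)
    ax.set_xlabel("CAI")
    ax.set_ylabel("ENc")
    return ax


def save_all(results: CodonUsageResults, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, fn in [
        ("neutrality.png", plot_neutrality),
        ("enc_gc3s.png", plot_enc_gc3s),
        ("pr2.png", plot_pr2),
        ("coa.png", plot_coa),
        ("cai_enc.png", plot_cai_enc),
    ]:
        fig, ax = plt.subplots(figsize=(5, 4))
        fn(results, ax=ax)
        fig.tight_layout()
        path = outdir / name
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
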