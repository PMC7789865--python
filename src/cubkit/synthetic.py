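"""Synthetic CDS generator with known codon-bias ground truth.

The generator emulates a QC'd plant transcriptome CDS set: a few hundred
genes of >= 100 codons, AT-rich overall (GC around 46-47%), a broad
third-position GC spread (roughly 21-89% with mean 46.6%), a weak positive
coupling between GC12 and GC3 (neutrality slope ~0.17), and an expression
gradient correlated with synonymous codon bias so that the most biased genes
reach an effective codon number near 31 while unbiased genes sit near 61.

Per gene i the generator draws a latent expression rank e_i ~ U(0,1), a
bias level b_i = bias_strength * (coupling * e_i + (1-coupling) * u_i), a
synonymous third-position GC target theta_i (a stratified Beta quantile over
``gc3_range``), and a codon count from a clipped lognormal.  Amino acids are
sampled from a gently tilted distribution whose GC content at codon
positions 1-2 tracks the gene's GC3 linearly with the configured neutrality
slope.  Within each synonymous family the codon distribution is a tilted
multinomial:

    weight(c)  proportional to  exp(b_i * [c == preferred]) * t3(c)

with t3(c) = tau_i for codons ending G/C and (1 - tau_i) otherwise, so that
bias_strength 0 with a mid-range GC3 target gives (near-)uniform family
usage and large bias_strength collapses each family onto its planted
preferred codon.  The gene-level tilt tau_i is solved numerically so that
the expected synonymous third-position GC content equals theta_i exactly,
whatever the gene's bias level and the planted codon identities; the
realized per-gene GC3s therefore scatters around the target by multinomial
noise only.  The terminal stop codon is drawn uniformly from TAA/TAG/TGA
and takes no part in the bias machinery.

All randomness flows from a single seed; each gene uses a substream derived
from (seed, gene_index), so datasets are reproducible under partial
regeneration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

from .cds_io import CodingSequence, write_fasta
from .composition import gc3s_of
from .genetic_code import FAMILIES, STOP_CODONS, SYNONYMOUS_AA, is_gc

_AA20 = tuple(sorted(set(SYNONYMOUS_AA) | {"M", "W"}))
_SYN_IDX = tuple(i for i, aa in enumerate(_AA20) if aa not in ("M", "W"))
_BETA_A = 1.1  # shape of the GC3-target distribution (long right tail)


def _gc12_score(aa: str) -> float:
    fam = FAMILIES[aa]
    return float(np.mean([(is_gc(c[0]) + is_gc(c[1])) / 2 for c in fam]))


_S = np.array([_gc12_score(aa) for aa in _AA20])
_S_MEAN = float(_S.mean())
_S_SCALE = float(np.max(np.abs(_S - _S_MEAN)))
_S_VAR = float(np.mean((_S - _S_MEAN) ** 2))
# d(GC3)/d(theta) is damped by the invariant Met/Trp third positions, so the
# GC12 tilt is scaled up to keep the nominal GC12-on-GC3 slope
_MW_FRACTION = 2 / len(_AA20)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic CDS set."""

    n_genes: int = 500
    length_distribution: tuple[int, int, float] = (100, 800, 0.45)  # min/max aa, lognormal sigma
    gc3_range: tuple[float, float] = (0.21, 0.89)
    gc3_mean: float = 0.466
    gc12_slope: float = 0.171
    bias_strength: float = 2.0
    expression_coupling: float = 0.8
    preferred_codons: dict[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.gc3_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("gc3_range must be within [0, 1]")
        if self.length_distribution[0] < 100:
            raise ValueError("minimum length must be >= 100 aa (post-QC survivability)")
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")
        if not 0 <= self.expression_coupling <= 1:
            raise ValueError("expression_coupling must lie in [0, 1]")
        if lo < hi and not (lo < self.gc3_mean < hi):
            raise ValueError("gc3_mean must lie inside gc3_range")

    def resolved_preferred(self) -> dict[str, str]:
        """Planted preferred codon per family (drawn from the seed if unset)."""
        if self.preferred_codons is not None:
            return dict(self.preferred_codons)
        rng = np.random.default_rng([self.seed, 104729])
        return {aa: str(rng.choice(FAMILIES[aa])) for aa in SYNONYMOUS_AA}


def _gc3_target(config: GeneratorConfig, gene_index: int) -> float:
    lo, hi = config.gc3_range
    if hi == lo:
        return lo
    m = (config.gc3_mean - lo) / (hi - lo)
    b = _BETA_A * (1 - m) / m
    q = (gene_index + 0.5) / config.n_genes
    return lo + (hi - lo) * float(beta_dist.ppf(q, _BETA_A, b))


def _aa_probs(config: GeneratorConfig, theta: float) -> np.ndarray:
    # linear tilt of the amino-acid distribution so that the expected GC12
    # tracks the gene's (whole-body) GC3 with slope gc12_slope
    g = config.gc12_slope * (1 - _MW_FRACTION) * _S_SCALE / _S_VAR
    delta = float(np.clip(g * (theta - config.gc3_mean), -1.0, 1.0))
    p = (1.0 + delta * (_S - _S_MEAN) / _S_SCALE) / len(_AA20)
    return p / p.sum()


def _family_weights(
    family: tuple[str, ...], preferred: str | None, bias: float, tau: float
) -> np.ndarray:
    w = np.array(
        [
            math.exp(bias if c == preferred else 0.0)
            * (tau if is_gc(c[2]) else 1.0 - tau)
            for c in family
        ]
    )
    if w.sum() == 0:  # tau exactly 0 or 1 with a one-sided family
        w = np.ones(len(family))
    return w


def _expected_gc3s(
    aa_probs: np.ndarray, preferred: dict[str, str], bias: float, tau: float
) -> float:
    """Expected synonymous third-position GC fraction at tilt ``tau``."""
    num = den = 0.0
    for ai in _SYN_IDX:
        aa = _AA20[ai]
        fam = FAMILIES[aa]
        w = _family_weights(fam, preferred.get(aa), bias, tau)
        gc = sum(wi for wi, c in zip(w, fam) if is_gc(c[2]))
        num += aa_probs[ai] * gc / w.sum()
        den += aa_probs[ai]
    return num / den


def _solve_tau(
    aa_probs: np.ndarray, preferred: dict[str, str], bias: float, theta: float
) -> float:
    """Tilt tau whose expected GC3s equals the target (monotone 1-D root)."""
    eps = 1e-9
    f = lambda t: _expected_gc3s(aa_probs, preferred, bias, t) - theta
    if f(eps) >= 0:
        return eps
    if f(1 - eps) <= 0:
        return 1 - eps
    return float(brentq(f, eps, 1 - eps, xtol=1e-10))


def generate_gene(
    config: GeneratorConfig, gene_index: int
) -> tuple[CodingSequence, dict]:
    """One synthetic CDS plus its ground-truth record."""
    rng = np.random.default_rng([config.seed, 15485863, gene_index])
    expression = float(rng.uniform())
    mix = config.expression_coupling * expression + (
        1 - config.expression_coupling
    ) * float(rng.uniform())
    bias = config.bias_strength * mix
    theta = _gc3_target(config, gene_index)

    min_aa, max_aa, sigma = config.length_distribution
    median = float(np.sqrt(min_aa * max_aa))
    length_aa = int(np.clip(round(np.exp(rng.normal(np.log(median), sigma))), min_aa, max_aa))

    preferred = config.resolved_preferred()
    aa_probs = _aa_probs(config, theta)
    tau = _solve_tau(aa_probs, preferred, bias, theta)
    body_aas = rng.choice(len(_AA20), size=length_aa - 1, p=aa_probs)
    codons = np.empty(length_aa - 1, dtype=object)
    for ai, aa in enumerate(_AA20):
        idx = np.nonzero(body_aas == ai)[0]
        if idx.size == 0:
            continue
        fam = FAMILIES[aa]
        if len(fam) == 1:
            codons[idx] = fam[0]
            continue
        w = _family_weights(fam, preferred.get(aa), bias, tau)
        codons[idx] = rng.choice(fam, size=idx.size, p=w / w.sum())
    stop = str(rng.choice(STOP_CODONS))
    cds = CodingSequence(
        id=f"g{gene_index:05d}",
        codons=("ATG", *codons.tolist(), stop),
        length_aa=length_aa,
    )
    truth = {
        "id": cds.id,
        "length_aa": length_aa,
        "target_gc3": theta,
        "bias_strength": bias,
        "latent_expression": expression,
    }
    return cds, truth


@dataclass
class SyntheticDataset:
    genes: list[CodingSequence]
    truth: pd.DataFrame
    preferred_codons: dict[str, str]
    config: GeneratorConfig = field(repr=False)

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(self.genes, path)

    def truth_to_tsv(self, path: str | Path) -> None:
        df = self.truth.copy()
        df["preferred_codons"] = ";".join(
            f"{aa}={c}" for aa, c in sorted(self.preferred_codons.items())
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def realized_gc3(self) -> pd.Series:
        """Per-gene realized synonymous third-position GC (the target scale)."""
        return pd.Series({g.id: gc3s_of(g) for g in self.genes}, name="gc3s")


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the full gene set with its ground-truth table."""
    genes, rows = [], []
    for i in range(config.n_genes):
        cds, truth = generate_gene(config, i)
        genes.append(cds)
        rows.append(truth)
    return SyntheticDataset(
        genes=genes,
        truth=pd.DataFrame(rows),
        preferred_codons=config.resolved_preferred(),
        config=config,
    )
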