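"""Shared fixtures and helpers for the cubkit test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cubkit import CodingSequence, CodonUsageAnalysis, GeneratorConfig, generate_dataset
from cubkit.datasets import load_rpalmatum_highlow
from cubkit.genetic_code import SENSE_CODONS, STOP_CODONS


def make_cds(body: str, gene_id: str = "g1", start: bool = True, stop: str = "TGA") -> CodingSequence:
    """Build a CodingSequence from a space-separated codon string.

    ``body`` is the codon sequence between the (optional) ATG start and the
    appended stop; QC is bypassed so degenerate test genes are allowed.
    """
    codons = tuple(body.split())
    if start:
        codons = ("ATG",) + codons
    codons = codons + (stop,)
    return CodingSequence(id=gene_id, codons=codons, length_aa=len(codons) - 1)


def random_sense_codons(rng: np.random.Generator, n: int) -> tuple[str, ...]:
    """n codons drawn uniformly from the 61 sense codons."""
    return tuple(rng.choice(SENSE_CODONS, size=n))


def random_cds(rng: np.random.Generator, n_codons: int = 300, gene_id: str = "r1") -> CodingSequence:
    body = random_sense_codons(rng, n_codons)
    stop = str(rng.choice(STOP_CODONS))
    return CodingSequence(
        id=gene_id, codons=("ATG",) + body + (stop,), length_aa=n_codons + 1
    )


@pytest.fixture(scope="session")
def highlow():
    """Bundled high/low expression-pool codon counts (worked example)."""
    return load_rpalmatum_highlow()


@pytest.fixture(scope="session")
def small_dataset():
    """200 synthetic genes at default study conditions."""
    return generate_dataset(GeneratorConfig(n_genes=200, seed=11))


@pytest.fixture(scope="session")
def fitted_results(small_dataset):
    """Full model fit of the 200-gene synthetic set."""
    return CodonUsageAnalysis(small_dataset.genes).fit()
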