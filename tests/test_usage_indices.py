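"""RSCU, ENc, expected ENc and CAI."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubkit import (
    CodonCountTable,
    cai,
    cai_weights,
    count_codons,
    enc,
    enc_deviation,
    expected_enc,
    rscu,
)
from cubkit.genetic_code import (
    DEGENERACY,
    ENC_CLASS_SIZES,
    FAMILIES,
    SYNONYMOUS_AA,
)
from cubkit._report import round_half_up

from conftest import random_cds


# ---------------------------------------------------------------------- RSCU
class TestRscu:
    def test_phe_pool_value(self):
        r = rscu(CodonCountTable({"TTT": 1118, "TTC": 567}))
        assert round_half_up(r["TTC"], 2) == 0.67

    def test_sixfold_ser_pool_value(self):
        r = rscu(
            CodonCountTable(
                {"TCT": 1103, "TCC": 349, "TCA": 976, "TCG": 146, "AGT": 669, "AGC": 373}
            )
        )
        assert round_half_up(r["TCC"], 2) == 0.58

    def test_equal_counts_give_unit_rscu(self):
        counts = CodonCountTable({c: 7 for c in FAMILIES["L"]})
        r = rscu(counts)
        assert all(r[c] == pytest.approx(1.0) for c in FAMILIES["L"])

    def test_absent_family_is_missing_not_zero(self):
        r = rscu(CodonCountTable({"TTT": 5, "TTC": 5}))
        assert math.isnan(r["GGG"])

    def test_single_codon_aa_is_one_when_present(self):
        r = rscu(CodonCountTable({"ATG": 3, "TGG": 1}))
        assert r["ATG"] == 1.0 and r["TGG"] == 1.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_family_sums_equal_degeneracy(self, seed):
        rng = np.random.default_rng(seed)
        counts = CodonCountTable(
            {c: int(rng.integers(0, 200)) for aa in SYNONYMOUS_AA for c in FAMILIES[aa]}
        )
        r = rscu(counts)
        for aa in SYNONYMOUS_AA:
            total = sum(counts[c] for c in FAMILIES[aa])
            family_sum = sum(r[c] for c in FAMILIES[aa])
            if total == 0:
                assert math.isnan(family_sum)
            else:
                assert family_sum == pytest.approx(DEGENERACY[aa], abs=1e-6)
            assert all(r[c] >= 0 or math.isnan(r[c]) for c in FAMILIES[aa])


# ----------------------------------------------------------------------- ENc
def enc_oracle(counts: CodonCountTable) -> float:
    """Independent re-derivation of Wright's estimator (loop-and-list style)."""
    per_class: dict[int, list[float]] = {}
    for aa in SYNONYMOUS_AA:
        family = FAMILIES[aa]
        n = sum(counts[c] for c in family)
        if n < 2:
            continue
        sum_p2 = 0.0
        for c in family:
            sum_p2 += (counts[c] / n) ** 2
        f = (n * sum_p2 - 1.0) / (n - 1.0)
        per_class.setdefault(len(family), []).append(f)
    fbar = {k: sum(v) / len(v) for k, v in per_class.items()}
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    total = 2.0
    for k, f in fbar.items():
        if f > 0:
            total += ENC_CLASS_SIZES[k] / f
    return min(61.0, max(20.0, total))


class TestEnc:
    def test_one_codon_per_amino_acid(self):
        counts = CodonCountTable({FAMILIES[aa][0]: 100 for aa in SYNONYMOUS_AA})
        value = enc(counts)
        # every family homozygosity is exactly 1 -> 2 + 9 + 1 + 5 + 3
        assert value.enc == pytest.approx(20.0)
        assert all(f == pytest.approx(1.0) for f in value.f_bar.values())

    def test_uniform_usage_approaches_61(self):
        counts = CodonCountTable(
            {c: 100 for aa in SYNONYMOUS_AA for c in FAMILIES[aa]}
        )
        assert abs(enc(counts).enc - 61.0) < 0.5

    def test_matches_bruteforce_oracle_on_synthetic_genes(self):
        rng = np.random.default_rng(31)
        for i in range(50):
            counts = count_codons(random_cds(rng, int(rng.integers(100, 400)), f"g{i}"))
            got = enc(counts).enc
            assert got == pytest.approx(enc_oracle(counts), abs=1e-9)
            assert 20.0 <= got <= 61.0

    def test_concentration_never_increases_enc(self):
        """Majorizing usage within a family (more concentrated) lowers ENc."""
        base = {c: 100 for aa in SYNONYMOUS_AA for c in FAMILIES[aa]}
        spread = enc(CodonCountTable(base)).enc
        skew = dict(base)
        skew["TTT"], skew["TTC"] = 180, 20
        mid = enc(CodonCountTable(skew)).enc
        skew["TTT"], skew["TTC"] = 200, 0
        tight = enc(CodonCountTable(skew)).enc
        assert spread > mid > tight

    def test_uninformative_gene_is_missing(self):
        assert math.isnan(enc(CodonCountTable({"TTT": 1, "GGA": 1})).enc)

    def test_missing_threefold_class_is_imputed(self):
        counts = {c: 50 for aa in SYNONYMOUS_AA for c in FAMILIES[aa] if aa != "I"}
        value = enc(CodonCountTable(counts))
        assert 3 in value.f_bar
        assert value.f_bar[3] == pytest.approx((value.f_bar[2] + value.f_bar[4]) / 2)


class TestExpectedEnc:
    def test_closed_form_values(self):
        assert expected_enc(0.5) == pytest.approx(60.5)
        assert expected_enc(0.0) == pytest.approx(31.0)
        # 2 + 0.466 + 29 / (0.466^2 + 0.534^2)
        s = 0.466
        assert expected_enc(s) == pytest.approx(2 + s + 29 / (s**2 + (1 - s) ** 2))

    def test_symmetric_about_half_up_to_linear_term(self):
        for s in np.linspace(0.0, 1.0, 21):
            assert expected_enc(s) - s == pytest.approx(
                expected_enc(1 - s) - (1 - s), abs=1e-12
            )

    def test_domain_check(self):
        with pytest.raises(ValueError):
            expected_enc(1.5)


class TestEncDeviation:
    def test_identity_and_arithmetic(self):
        assert enc_deviation(60.0, 60.0) == 0.0
        assert enc_deviation(54.0, 60.0) == pytest.approx(0.1)

    def test_positive_expected_required(self):
        with pytest.raises(ValueError):
            enc_deviation(50.0, 0.0)


# ----------------------------------------------------------------------- CAI
class TestCai:
    def test_weight_definition(self):
        w = cai_weights(CodonCountTable({"TTT": 4, "TTC": 2}))
        assert w["TTT"] == 1.0 and w["TTC"] == 0.5

    def test_uniform_reference_gives_cai_one(self):
        ref = CodonCountTable({c: 10 for aa in SYNONYMOUS_AA for c in FAMILIES[aa]})
        w = cai_weights(ref)
        rng = np.random.default_rng(41)
        gene = count_codons(random_cds(rng, 200))
        assert cai(gene, w).cai == pytest.approx(1.0)

    def test_zero_count_codons_are_floored_not_zeroed(self):
        w = cai_weights(CodonCountTable({"TTT": 10, "TTC": 0}))
        assert w["TTC"] == pytest.approx(0.05)

    def test_empty_family_gets_unit_weights(self, caplog):
        w = cai_weights(CodonCountTable({"TTT": 10, "TTC": 5}))
        assert all(w[c] == 1.0 for c in FAMILIES["G"])

    def test_planted_preferred_codon_has_max_weight(self):
        rng = np.random.default_rng(42)
        planted = {aa: str(rng.choice(FAMILIES[aa])) for aa in SYNONYMOUS_AA}
        counts = {}
        for aa in SYNONYMOUS_AA:
            for c in FAMILIES[aa]:
                counts[c] = 90 if c == planted[aa] else 10
        w = cai_weights(CodonCountTable(counts))
        for aa in SYNONYMOUS_AA:
            assert max(FAMILIES[aa], key=lambda c: w[c]) == planted[aa]

    def test_two_codon_geometric_mean(self):
        w = {"TTT": 1.0, "TTC": 0.25}
        value = cai(CodonCountTable({"TTT": 1, "TTC": 1}), w)
        assert value.cai == pytest.approx(0.5)

    def test_matches_product_then_root_oracle(self):
        rng = np.random.default_rng(43)
        gene = count_codons(random_cds(rng, 150))
        ref = count_codons(random_cds(rng, 400, "ref"))
        w = cai_weights(ref)
        product, n = 1.0, 0
        for codon, count in gene.counts.items():
            aa = __import__("cubkit.genetic_code", fromlist=["CODON_TO_AA"]).CODON_TO_AA[codon]
            if aa in ("M", "W", "*") or DEGENERACY[aa] < 2:
                continue
            product *= w[codon] ** count
            n += count
        assert cai(gene, w).cai == pytest.approx(product ** (1 / n), rel=1e-9)

    def test_weight_scale_invariance(self):
        # multiplying all family counts by a constant leaves weights unchanged
        a = cai_weights(CodonCountTable({"TTT": 8, "TTC": 2}))
        b = cai_weights(CodonCountTable({"TTT": 80, "TTC": 20}))
        assert a["TTC"] == pytest.approx(b["TTC"])

    def test_met_trp_and_stops_excluded(self):
        w = cai_weights(CodonCountTable({"TTT": 10, "TTC": 10}))
        gene = CodonCountTable({"ATG": 5, "TGG": 5, "TAA": 1, "TTT": 2})
        assert cai(gene, w).cai == pytest.approx(1.0)
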