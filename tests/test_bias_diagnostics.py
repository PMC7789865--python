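"""Neutrality regression, ENc-GC3s table, PR2 analysis, correlation matrix."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from cubkit import (
    correlation_matrix,
    enc_gc3s_table,
    neutrality_regression,
    pr2_analysis,
)
from cubkit.bias_diagnostics import _quadrant
from cubkit.composition import CompositionRecord, ThirdPositionCounts


def make_comp(gene_id: str, a3: int, u3: int, g3: int, c3: int) -> CompositionRecord:
    counts = ThirdPositionCounts(a3, u3, g3, c3, "fourfold_only")
    return CompositionRecord(
        id=gene_id, frac_a=0.25, frac_t=0.25, frac_g=0.25, frac_c=0.25,
        gc1=0.5, gc2=0.5, gc3=0.5, gc12=0.5, gc_all=0.5, gc3s=0.5,
        third_fourfold=counts, third_synonymous=counts,
    )


class TestNeutralityRegression:
    def test_identity_line(self):
        pts = [(x, x) for x in (0.2, 0.4, 0.6, 0.8)]
        fit = neutrality_regression(pts)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)

    def test_flat_line(self):
        fit = neutrality_regression([(0.2, 0.4), (0.5, 0.4), (0.7, 0.4)])
        assert fit.slope == pytest.approx(0.0)

    def test_matches_normal_equations_on_hand_points(self):
        pts = [(0.21, 0.40), (0.35, 0.43), (0.50, 0.41), (0.66, 0.47), (0.89, 0.52)]
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        slope_oracle = ((x * y).mean() - x.mean() * y.mean()) / (
            (x * x).mean() - x.mean() ** 2
        )
        intercept_oracle = y.mean() - slope_oracle * x.mean()
        fit = neutrality_regression(pts)
        assert fit.slope == pytest.approx(slope_oracle, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept_oracle, abs=1e-12)
        assert fit.n == 5

    def test_slope_invariant_under_gc12_shift_and_r2_identity(self):
        rng = np.random.default_rng(61)
        x = rng.uniform(0.2, 0.8, 40)
        y = 0.3 + 0.2 * x + rng.normal(0, 0.02, 40)
        a = neutrality_regression(list(zip(x, y)))
        b = neutrality_regression(list(zip(x, y + 0.1)))
        assert b.slope == pytest.approx(a.slope, abs=1e-12)
        fitted = a.intercept + a.slope * x
        r2 = ((fitted - y.mean()) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert a.r**2 == pytest.approx(r2, abs=1e-9)

    def test_recovers_generating_slope(self):
        rng = np.random.default_rng(62)
        beta = 0.171
        x = rng.uniform(0.21, 0.89, 200)
        y = 0.35 + beta * x + rng.normal(0, 0.02, 200)
        fit = neutrality_regression(list(zip(x, y)))
        assert abs(fit.slope - beta) <= fit.stderr

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            neutrality_regression([(0.5, 0.1), (0.5, 0.2), (0.5, 0.3)])


class TestEncGc3sTable:
    def test_gene_on_curve_has_zero_deviation(self):
        from cubkit import expected_enc

        df = pd.DataFrame({"id": ["a", "b", "c"],
                           "GC3s": [0.3, 0.5, 0.7],
                           "ENc": [expected_enc(0.3), 50.0, 62.0]})
        table, hist = enc_gc3s_table(df)
        row = table.set_index("id").loc["a"]
        assert row["deviation"] == pytest.approx(0.0)
        assert not row["below_curve"]
        assert table.set_index("id").loc["b", "below_curve"]
        assert hist["n_genes"].sum() == 3

    def test_null_deviations_concentrate_near_zero(self):
        from cubkit import expected_enc

        rng = np.random.default_rng(63)
        gc3s = rng.uniform(0.3, 0.7, 200)
        obs = np.array([expected_enc(s) for s in gc3s]) + rng.normal(0, 0.5, 200)
        df = pd.DataFrame({"id": [f"g{i}" for i in range(200)], "GC3s": gc3s, "ENc": obs})
        table, _ = enc_gc3s_table(df)
        assert (table["deviation"].abs() <= 0.05).mean() >= 0.5

    def test_selected_genes_have_positive_median_deviation(self):
        from cubkit import expected_enc

        rng = np.random.default_rng(64)
        gc3s = rng.uniform(0.3, 0.7, 100)
        obs = np.array([expected_enc(s) for s in gc3s]) - rng.uniform(3, 10, 100)
        df = pd.DataFrame({"id": [f"g{i}" for i in range(100)], "GC3s": gc3s, "ENc": obs})
        table, _ = enc_gc3s_table(df)
        assert table["deviation"].median() > 0
        assert table["below_curve"].all()


class TestPr2:
    def test_balanced_gene_sits_at_centre(self):
        points, summary = pr2_analysis([make_comp("g", 5, 5, 7, 7)])
        assert (points[0].x, points[0].y) == (0.5, 0.5)
        assert points[0].on_boundary
        assert points[0].quadrant == 1  # boundary ties go to the lowest index

    def test_hand_computed_coordinates(self):
        points, _ = pr2_analysis([make_comp("g", 8, 2, 6, 4)])
        p = points[0]
        assert (p.x, p.y) == (0.6, 0.8)
        assert p.quadrant == 1 and not p.on_boundary

    def test_coordinates_invariant_under_count_scaling(self):
        a, _ = pr2_analysis([make_comp("g", 8, 2, 6, 4)])
        b, _ = pr2_analysis([make_comp("g", 40, 10, 30, 20)])
        assert (a[0].x, a[0].y) == (b[0].x, b[0].y)

    def test_degenerate_genes_are_excluded(self):
        points, summary = pr2_analysis(
            [make_comp("ok", 3, 4, 5, 6), make_comp("no_at", 0, 0, 5, 6)]
        )
        assert [p.id for p in points] == ["ok"]
        assert summary["excluded"] == ["no_at"]

    def test_quadrant_assignment_convention(self):
        assert _quadrant(0.7, 0.7)[0] == 1
        assert _quadrant(0.3, 0.7)[0] == 2
        assert _quadrant(0.3, 0.3)[0] == 3
        assert _quadrant(0.7, 0.3)[0] == 4

    def test_strand_symmetric_set_fills_quadrants_uniformly(self):
        rng = np.random.default_rng(65)
        comps = []
        for i in range(400):
            # iid counts around a symmetric centre; odd totals avoid ties
            a, u = 10 + rng.poisson(15), 10 + rng.poisson(15)
            g, c = 10 + rng.poisson(15), 10 + rng.poisson(15)
            comps.append(make_comp(f"g{i}", a, u, g, c))
        points, summary = pr2_analysis(comps)
        interior = [p for p in points if not p.on_boundary]
        counts = [sum(p.quadrant == q for p in interior) for q in (1, 2, 3, 4)]
        assert chisquare(counts).pvalue > 0.001


class TestCorrelationMatrix:
    @pytest.fixture()
    def gene_table(self):
        rng = np.random.default_rng(66)
        n = 20
        gc3 = rng.uniform(0.2, 0.8, n)
        df = pd.DataFrame(
            {
                "GC12": 0.3 + 0.2 * gc3 + rng.normal(0, 0.02, n),
                "GC3": gc3,
                "GCall": 0.4 + 0.1 * gc3 + rng.normal(0, 0.01, n),
                "ENc": rng.uniform(35, 61, n),
                "CAI": rng.uniform(0.2, 0.9, n),
                "Axis1": 1.2 * gc3 + rng.normal(0, 0.05, n),
            }
        )
        return df

    def test_matches_covariance_oracle(self, gene_table):
        cm = correlation_matrix(gene_table)
        for a in cm.parameters:
            for b in cm.parameters:
                xa, xb = gene_table[a], gene_table[b]
                oracle = (
                    ((xa - xa.mean()) * (xb - xb.mean())).mean()
                    / (xa.std(ddof=0) * xb.std(ddof=0))
                )
                assert cm.r.loc[a, b] == pytest.approx(oracle, abs=1e-9)

    def test_diagonal_and_symmetry(self, gene_table):
        cm = correlation_matrix(gene_table)
        assert np.allclose(np.diag(cm.r), 1.0)
        assert np.allclose(cm.r, cm.r.T, equal_nan=True)
        assert np.allclose(cm.p, cm.p.T, equal_nan=True)

    def test_exact_negatives_give_minus_one(self, gene_table):
        gene_table = gene_table.copy()
        gene_table["CAI"] = -gene_table["ENc"]
        cm = correlation_matrix(gene_table)
        assert cm.r.loc["ENc", "CAI"] == pytest.approx(-1.0)

    def test_constant_parameter_warns_and_is_missing(self, gene_table):
        gene_table = gene_table.copy()
        gene_table["CAI"] = 0.5
        with pytest.warns(UserWarning, match="constant"):
            cm = correlation_matrix(gene_table)
        assert math.isnan(cm.r.loc["CAI", "GC3"])

    def test_spearman_option(self, gene_table):
        cm = correlation_matrix(gene_table, method="spearman")
        assert cm.method == "spearman"
        assert abs(cm.r.loc["Axis1", "GC3"]) <= 1
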