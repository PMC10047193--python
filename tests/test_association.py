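"""Contingency building, Monte-Carlo chi-squared, Pearson residual bands."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from deppipe.association import (
    CategoryAssociation,
    build_contingency,
    monte_carlo_chisq,
    pearson_residual_bands,
)
from deppipe.datamodel import AnnotationTable
from deppipe.simulate import generate_annotation_table

# independent oracle: exact fixed-margin null for table [[20,5],[10,15]]
# (hypergeometric enumeration over the free cell): P(chi2 >= 8.3333) =
# 0.0085785081504691; asymptotic df=1 tail = 0.0038924171227786
EXACT_P_2X2 = 0.00857850815046912
ASYMPTOTIC_P_2X2 = 0.0038924171227786


def table(rows, index=None):
    return pd.DataFrame(
        np.array(rows), index=index or [f"c{i}" for i in range(len(rows))],
        columns=["up", "down"],
    )


class TestBuildContingency:
    def ann(self, records):
        return AnnotationTable(
            records=pd.DataFrame(records, columns=["id", "ontology", "category"])
        )

    def test_counts_per_direction(self):
        ann = self.ann(
            [("A", "GO-CC", "nucleus"), ("B", "GO-CC", "nucleus"),
             ("C", "GO-CC", "nucleus")]
        )
        t, dropped = build_contingency(["A", "B"], ["C"], ann, "GO-CC")
        assert t.loc["nucleus", "up"] == 2
        assert t.loc["nucleus", "down"] == 1
        assert dropped == 0

    def test_multi_category_protein_counts_once_per_category(self):
        ann = self.ann(
            [("A", "GO-BP", "translation"), ("A", "GO-BP", "splicing")]
        )
        t, _ = build_contingency(["A"], [], ann, "GO-BP")
        assert t["up"].tolist() == [1, 1]

    def test_empty_direction_column_is_valid(self):
        ann = self.ann([("A", "KOG", "metabolism")])
        t, _ = build_contingency(["A"], [], ann, "KOG")
        assert t["down"].sum() == 0
        # and the test handles the zero column by trimming it
        chi2, p = monte_carlo_chisq(t, n_sim=100, seed=0)
        assert chi2 == 0.0 and p == 1.0

    def test_disjoint_id_spaces_rejected(self):
        ann = self.ann([("X", "GO-CC", "nucleus")])
        with pytest.raises(ValueError, match="intersect"):
            build_contingency(["A"], ["B"], ann, "GO-CC")

    def test_unannotated_deps_dropped_and_counted(self):
        ann = self.ann([("A", "GO-CC", "nucleus")])
        t, dropped = build_contingency(["A", "Z"], [], ann, "GO-CC")
        assert dropped == 1
        assert t.values.sum() == 1


class TestMonteCarloChisq:
    def test_homogeneous_table_is_null(self):
        chi2, p = monte_carlo_chisq(table([[10, 10], [10, 10]]), seed=0)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_worked_example_statistic_and_p(self):
        chi2, p = monte_carlo_chisq(table([[20, 5], [10, 15]]), n_sim=2000, seed=1)
        assert chi2 == pytest.approx(25.0 / 3.0, abs=1e-12)
        # n_sim=2000 Monte-Carlo error around the exact 0.00858
        assert 0.004 <= p <= 0.015
        assert abs(p - EXACT_P_2X2) < 0.006

    def test_large_n_sim_approaches_asymptotic_tail(self):
        _, p = monte_carlo_chisq(table([[20, 5], [10, 15]]), n_sim=100_000, seed=2)
        assert abs(p - ASYMPTOTIC_P_2X2) < 0.01

    def test_row_and_column_permutation_invariance(self):
        t = table([[12, 3], [5, 9], [7, 21]])
        chi2_a, p_a = monte_carlo_chisq(t, n_sim=4000, seed=3)
        perm = t.iloc[[2, 0, 1], [1, 0]]
        chi2_b, p_b = monte_carlo_chisq(perm, n_sim=4000, seed=3)
        assert chi2_a == pytest.approx(chi2_b, abs=1e-9)
        assert abs(p_a - p_b) < 0.02  # same distribution, independent draws

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            monte_carlo_chisq(table([[0, 0], [0, 0]]), seed=0)

    def test_seeded_determinism(self):
        t = table([[8, 2], [3, 7]])
        assert monte_carlo_chisq(t, seed=9) == monte_carlo_chisq(t, seed=9)


class TestPearsonResiduals:
    def test_worked_residual_example(self):
        t = table([[20, 5], [10, 15]])
        residuals, bands, significant = pearson_residual_bands(t)
        np.testing.assert_allclose(
            residuals.to_numpy(),
            [[5 / np.sqrt(15), -5 / np.sqrt(10)],
             [-5 / np.sqrt(15), 5 / np.sqrt(10)]],
            atol=1e-9,
        )
        assert significant == []  # |r| < 2 everywhere
        # |5/sqrt(15)| = 1.291 and |5/sqrt(10)| = 1.581, both below 1.645
        assert (bands.to_numpy() == "n.s.").all()

    def test_band_edges(self):
        # craft residual magnitudes around each band edge via direct check
        t = table([[20, 5], [10, 15]])
        residuals, bands, _ = pearson_residual_bands(t)
        for cat in t.index:
            for col in t.columns:
                r = abs(residuals.loc[cat, col])
                b = bands.loc[cat, col]
                if r < 1.6448536269514722:
                    assert b == "n.s."
                elif r < 1.959963984540054:
                    assert b == "•"
                elif r < 2.241402727604947:
                    assert b == "*"
                else:
                    assert b == "**"

    def test_exact_fit_all_ns(self):
        t = table([[10, 20], [5, 10]])  # obs == expected
        residuals, bands, significant = pearson_residual_bands(t)
        np.testing.assert_allclose(residuals.to_numpy(), 0.0, atol=1e-12)
        assert (bands.to_numpy() == "n.s.").all()
        assert significant == []

    def test_residual_square_sum_equals_chi2(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            t = table(rng.integers(1, 40, size=(4, 2)).tolist(),
                      index=[f"c{i}" for i in range(4)])
            chi2, _ = monte_carlo_chisq(t, n_sim=10, seed=0)
            residuals, _, _ = pearson_residual_bands(t)
            assert np.nansum(residuals.to_numpy() ** 2) == pytest.approx(
                chi2, abs=1e-9
            )


class TestCalibrationAndPower:
    def test_enriched_cell_residual_detected(self):
        # strong planted enrichment on 200 DEPs lights up the enriched cell
        deps = {f"P{i}": (1.0 if i < 100 else -1.0) for i in range(200)}
        hits = 0
        n_runs = 50
        for seed in range(n_runs):
            ann, truth = generate_annotation_table(
                list(deps), deps, enrichment_factor=5.0, seed=seed
            )
            up = [p for p, d in deps.items() if d > 0]
            down = [p for p, d in deps.items() if d < 0]
            t, _ = build_contingency(up, down, ann, "GO-CC")
            residuals, _, _ = pearson_residual_bands(t)
            cat = truth.enriched_categories["GO-CC"]["up"]
            if residuals.loc[cat, "up"] > 2:
                hits += 1
        assert hits / n_runs >= 0.95

    def test_null_annotation_gives_uniformish_p(self):
        deps = {f"P{i}": (1.0 if i < 100 else -1.0) for i in range(200)}
        rejections = 0
        n_runs = 100
        for seed in range(n_runs):
            ann, _ = generate_annotation_table(
                list(deps), deps, enrichment_factor=1.0, seed=seed
            )
            up = [p for p, d in deps.items() if d > 0]
            down = [p for p, d in deps.items() if d < 0]
            res = CategoryAssociation(up, down, ann, "GO-MF").fit(
                n_sim=500, seed=seed + 1000
            )
            rejections += res.mc_p_value < 0.05
        assert 0.0 <= rejections / n_runs <= 0.11  # loose small-n band


class TestModelResultsSurface:
    def test_fit_returns_complete_result(self):
        deps = {f"P{i}": (1.0 if i < 30 else -1.0) for i in range(60)}
        ann, _ = generate_annotation_table(list(deps), deps, 3.0, seed=5)
        up = [p for p, d in deps.items() if d > 0]
        down = [p for p, d in deps.items() if d < 0]
        res = CategoryAssociation(up, down, ann, "GO-BP").fit(n_sim=999, seed=7)
        assert res.ontology == "GO-BP"
        assert res.n_sim == 999
        assert 0 < res.mc_p_value <= 1
        assert res.contingency.values.sum() == 60
        assert "chi-squared statistic" in res.summary()
        d = res.to_dict()
        assert set(d) >= {"contingency", "chi2_statistic", "mc_p_value", "residuals"}
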