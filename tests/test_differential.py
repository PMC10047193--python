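"""Welch statistics, Cohen's d, DEP classification, |FC| outliers."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_dataset
from deppipe.differential import (
    DepRecord,
    DifferentialExpression,
    classify_deps,
    dep_statistics,
    detect_outliers,
    volcano_table,
)
from deppipe.simulate import SimulationParams, generate_abundance_dataset

# oracle values computed independently in R:
#   t.test(3:8, 1:6)  ->  t = 1.851640199545103, df = 10, p = 0.093792551579223
R_WELCH_T = 1.851640199545103
R_WELCH_P = 0.093792551579223


def single_protein(control, case):
    values = np.array([list(control) + list(case)], dtype=float)
    ds = make_dataset(values, n_control=len(control))
    return dep_statistics(ds)[0]


class TestDepStatistics:
    def test_worked_welch_example(self):
        r = single_protein([1, 2, 3, 4, 5, 6], [3, 4, 5, 6, 7, 8])
        assert r.fc == pytest.approx(2.0, abs=1e-12)
        assert r.pooled_sd == pytest.approx(np.sqrt(3.5), abs=1e-12)
        assert r.cohen_d == pytest.approx(2.0 / np.sqrt(3.5), abs=1e-12)
        assert r.p_value == pytest.approx(R_WELCH_P, abs=1e-10)
        assert r.direction == "ns"

    def test_identical_groups_are_null(self):
        r = single_protein([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.fc == 0.0
        assert r.cohen_d == 0.0
        assert r.p_value == pytest.approx(1.0)
        assert r.direction == "ns"

    def test_equal_sds_give_pooled_equal_to_either(self):
        r = single_protein([0, 2, 4], [10, 12, 14])  # both SDs = 2
        assert r.pooled_sd == pytest.approx(r.sd_control, abs=1e-12)
        assert r.sd_control == pytest.approx(r.sd_case, abs=1e-12)

    def test_degenerate_zero_variance_flagged_not_called(self):
        r = single_protein([5, 5, 5], [9, 9, 9])
        assert r.degenerate
        assert r.direction == "ns"
        assert np.isnan(r.cohen_d)

    def test_missing_values_rejected(self, two_group_dataset):
        with pytest.raises(ValueError, match="missing"):
            DifferentialExpression(two_group_dataset)

    def test_label_swap_antisymmetry(self):
        ds, _ = generate_abundance_dataset(
            SimulationParams(n_proteins=150, missing_rate=0.0,
                             n_exclusive_per_group=0, seed=13)
        )
        fwd = dep_statistics(ds)
        rev = dep_statistics(
            ds, control_group=ds.groups[1], case_group=ds.groups[0]
        )
        for a, b in zip(fwd, rev):
            assert a.fc == pytest.approx(-b.fc, abs=1e-12)
            assert a.cohen_d == pytest.approx(-b.cohen_d, abs=1e-12)
            assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_student_option_differs_from_welch_under_unequal_variance(self):
        control = [0.0, 0.1, 0.2, 0.0, 0.1, 0.2]
        case = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]
        values = np.array([control + case])
        ds = make_dataset(values, n_control=6)
        welch = dep_statistics(ds, test="welch")[0]
        student = dep_statistics(ds, test="student")[0]
        assert welch.p_value != pytest.approx(student.p_value, rel=1e-6)


class TestClassifyDeps:
    def mk(self, d, p):
        return DepRecord(
            protein_id="P", mean_control=0, mean_case=d, sd_control=1,
            sd_case=1, fc=d, pooled_sd=1, cohen_d=d, p_value=p,
        )

    @pytest.mark.parametrize(
        "d, p, expected",
        [
            (2.5, 0.01, "up"),
            (2.5, 0.2, "ns"),  # p gate
            (-2.0, 0.01, "ns"),  # boundary is strict
            (2.0, 0.01, "ns"),
            (-2.5, 0.04, "down"),
            (1.9, 0.001, "ns"),
            (2.1, 0.05, "ns"),  # p boundary strict
        ],
    )
    def test_cutoffs(self, d, p, expected):
        up, down, ns = classify_deps([self.mk(d, p)])
        got = ("up" if up else "down" if down else "ns")
        assert got == expected

    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(0)
        records = [self.mk(float(d), float(p))
                   for d, p in zip(rng.normal(0, 3, 200), rng.uniform(0, 1, 200))]
        up, down, ns = classify_deps(records)
        assert len(up) + len(down) + len(ns) == len(records)
        ids = [id(r) for r in up + down + ns]
        assert len(set(ids)) == len(ids)


class TestDetectOutliers:
    def mk(self, pid, fc):
        return DepRecord(
            protein_id=pid, mean_control=0, mean_case=fc, sd_control=0.1,
            sd_case=0.1, fc=fc, pooled_sd=0.1, cohen_d=fc / 0.1,
            p_value=0.001, direction="up" if fc > 0 else "down",
        )

    def test_worked_arithmetic_example(self):
        # |fc| = {2 x9, 12}: mean 3, sd sqrt(10), cutoff 3 + 2*sqrt(10)
        records = [self.mk(f"P{i}", 2.0) for i in range(9)] + [self.mk("P9", 12.0)]
        rep = detect_outliers(records)
        assert rep.mean_abs_lfc == pytest.approx(3.0)
        assert rep.sd_abs_lfc == pytest.approx(np.sqrt(10.0))
        assert rep.cutoff == pytest.approx(3.0 + 2.0 * np.sqrt(10.0))
        assert rep.outlier_ids == ["P9"]
        assert rep.up_outliers == ["P9"] and rep.down_outliers == []

    def test_constant_abs_fc_flags_nothing(self):
        records = [self.mk(f"P{i}", 2.5) for i in range(5)]
        rep = detect_outliers(records)
        assert rep.cutoff == pytest.approx(rep.mean_abs_lfc)
        assert rep.outlier_ids == []

    def test_fewer_than_two_deps_rejected(self):
        with pytest.raises(ValueError, match="2 DEPs"):
            detect_outliers([self.mk("P0", 2.0)])

    def test_planted_extreme_effect_flagged(self):
        params = SimulationParams(
            n_proteins=1500, frac_dep=0.04, missing_rate=0.0,
            n_exclusive_per_group=0, effect_size_range=(3.0, 4.0),
            frac_outlier_dep=0.02, outlier_effect_range=(15.0, 18.0), seed=42,
        )
        ds, truth = generate_abundance_dataset(params)
        res = DifferentialExpression(ds).fit()
        rep = res.detect_outliers()
        assert truth.outlier_ids  # something was planted
        assert set(truth.outlier_ids) <= set(rep.outlier_ids)


class TestVolcanoTable:
    def test_coordinates_and_direction_consistency(self):
        ds, _ = generate_abundance_dataset(
            SimulationParams(n_proteins=200, missing_rate=0.0,
                             n_exclusive_per_group=0, seed=2)
        )
        res = DifferentialExpression(ds).fit()
        table = res.volcano_table()
        assert len(table) == len(res.records)
        by_id = {r.protein_id: r for r in res.records}
        for row in table.itertuples(index=False):
            r = by_id[row.protein_id]
            assert row.neg_log10_p == pytest.approx(-np.log10(r.p_value))
            assert row.direction == r.direction
        assert np.isfinite(table["neg_log10_p"]).all()

    def test_simple_p_mappings(self):
        records = [
            DepRecord("A", 0, 1, 1, 1, 1, 1, 1.0, 0.01),
            DepRecord("B", 0, 1, 1, 1, 1, 1, 1.0, 1.0),
        ]
        t = volcano_table(records)
        assert t["neg_log10_p"].tolist() == pytest.approx([2.0, 0.0])


class TestRecoveryAndCalibration:
    def test_planted_deps_recovered_with_low_false_positives(self):
        sens_num = sens_den = fp_num = fp_den = 0
        for seed in range(5):
            params = SimulationParams(
                n_proteins=2000, missing_rate=0.0, n_exclusive_per_group=0,
                effect_size_range=(3.0, 5.0), frac_outlier_dep=0.0, seed=seed,
            )
            ds, truth = generate_abundance_dataset(params)
            res = DifferentialExpression(ds).fit()
            called = {r.protein_id: r.direction for r in res.deps}
            for pid, d in truth.dep_effects.items():
                sens_den += 1
                want = "up" if d > 0 else "down"
                sens_num += called.get(pid) == want
            planted = set(truth.dep_effects)
            nulls = [p for p in ds.protein_ids if p not in planted]
            fp_den += len(nulls)
            fp_num += sum(1 for p in nulls if p in called)
        assert sens_num / sens_den >= 0.90
        assert fp_num / fp_den <= 0.01

    def test_null_p_values_calibrated(self):
        params = SimulationParams(
            n_proteins=5000, frac_dep=0.0, missing_rate=0.0,
            n_exclusive_per_group=0, seed=17,
        )
        ds, _ = generate_abundance_dataset(params)
        res = DifferentialExpression(ds).fit()
        frac = np.mean([r.p_value < 0.05 for r in res.records])
        assert 0.04 <= frac <= 0.06
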