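import math

import numpy as np
import pandas as pd
import pytest

from matrisig.diffabund import (
    combined_signature,
    differential_proteins,
    normalize_intensities,
    student_t_test,
)
from matrisig.io import SampleGroup, ValidationError

from conftest import NAN, make_table


def _two_group_design(n=5):
    design = {}
    for i in range(1, n + 1):
        design[f"L{i}"] = SampleGroup("MA", "CD8lo", i)
    for i in range(1, n + 1):
        design[f"H{i}"] = SampleGroup("MB", "CD8hi", i)
    return design


class TestNormalization:
    def test_hand_scaling_to_median_sum(self, small_design):
        # sample sums 100 and 200; median target 150 -> factors 1.5 and 0.75
        table = make_table({"P": [40.0, 120.0], "Q": [60.0, 80.0]}, small_design)
        out = normalize_intensities(table)
        assert out.intensities["A1"].sum() == pytest.approx(150.0)
        assert out.intensities["A2"].sum() == pytest.approx(150.0)
        assert out.intensities.loc["P", "A1"] == pytest.approx(60.0)
        assert out.intensities.loc["P", "A2"] == pytest.approx(90.0)

    def test_none_is_identity(self, small_design):
        table = make_table({"P": [1.0, 2.0]}, small_design)
        out = normalize_intensities(table, method="none")
        assert out.intensities.equals(table.intensities)

    def test_equal_sums_fixed_point(self, small_design):
        table = make_table({"P": [30.0, 70.0], "Q": [70.0, 30.0]}, small_design)
        out = normalize_intensities(table)
        assert np.allclose(out.intensities.to_numpy(), table.intensities.to_numpy())

    def test_missing_stays_missing(self, small_design):
        table = make_table({"P": [NAN, 10.0], "Q": [5.0, 10.0]}, small_design)
        out = normalize_intensities(table)
        assert np.isnan(out.intensities.loc["P", "A1"])

    def test_all_missing_sample_error(self, small_design):
        table = make_table({"P": [NAN, 10.0]}, small_design)
        with pytest.raises(ValidationError, match="A1"):
            normalize_intensities(table)


class TestStudentT:
    def test_identical_groups(self):
        t, p = student_t_test([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_pooled_computation(self):
        x = [10, 12, 11, 13, 12]
        y = [14, 15, 16, 15, 14]
        # independent closed-form pooled-variance computation
        mx, my = sum(x) / 5, sum(y) / 5
        ssx = sum((v - mx) ** 2 for v in x)
        ssy = sum((v - my) ** 2 for v in y)
        sp2 = (ssx + ssy) / 8
        t_expected = (mx - my) / math.sqrt(sp2 * (1 / 5 + 1 / 5))
        t, p = student_t_test(x, y)
        assert t == pytest.approx(t_expected, rel=1e-12)
        assert t == pytest.approx(-5.059644, rel=1e-5)
        assert 0 < p < 0.01

    def test_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        t1, p1 = student_t_test(x, y)
        t2, p2 = student_t_test(y, x)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_insufficient_values(self):
        with pytest.raises(ValidationError):
            student_t_test([1.0], [1.0, 2.0])


class TestDifferentialCalls:
    def _table(self, rows, design=None):
        design = design or _two_group_design()
        return make_table(rows, design)

    def test_equal_means_unchanged(self):
        # hi values are a permutation of lo: ratio exactly 1 -> unchanged
        table = self._table({"P": [1.0, 2.0, 3.0, 4.0, 5.0, 5.0, 4.0, 3.0, 2.0, 1.0]})
        res = differential_proteins(table, {"P"})
        assert res.table.iloc[0]["ratio"] == pytest.approx(1.0)
        assert res.table.iloc[0]["call"] == "unchanged"

    def test_strong_shift_called_up_in_hi(self):
        lo = [100.0, 101, 99, 100, 100]
        hi = [200.0, 201, 199, 200, 200]
        table = self._table({"P": lo + hi})
        res = differential_proteins(table, {"P"}, alpha=0.05, up=1.2, down=0.8)
        assert res.table.iloc[0]["call"] == "up_in_hi"
        assert res.up_in_hi == {"P"}

    def test_group_swap_antisymmetry(self):
        rng = np.random.default_rng(11)
        rows = {f"P{i}": list(rng.lognormal(5, 0.3, 10)) for i in range(12)}
        design = _two_group_design()
        table = make_table(rows, design)
        res = differential_proteins(table, set(rows), group_lo="CD8lo", group_hi="CD8hi")
        # swap the group labels: up_in_hi and up_in_lo exchange exactly
        res_swapped = differential_proteins(table, set(rows), group_lo="CD8hi", group_hi="CD8lo")
        assert res.up_in_hi == res_swapped.up_in_lo
        assert res.up_in_lo == res_swapped.up_in_hi

    def test_global_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        rows = {f"P{i}": list(rng.lognormal(5, 0.4, 10)) for i in range(10)}
        table = make_table(rows, _two_group_design())
        scaled = make_table({k: [v * 37.5 for v in vals] for k, vals in rows.items()},
                            _two_group_design())
        res = differential_proteins(table, set(rows))
        res_scaled = differential_proteins(scaled, set(rows))
        assert list(res.table["call"]) == list(res_scaled.table["call"])
        np.testing.assert_allclose(res.table["p"], res_scaled.table["p"], rtol=1e-9)

    def test_untestable_reported_separately(self):
        table = self._table({"P": [1.0, NAN, NAN, NAN, NAN, 2.0, 2.0, 2.0, 2.0, 2.0]})
        res = differential_proteins(table, {"P"})
        assert res.untestable == ["P"]
        assert len(res.table) == 0

    def test_missing_shared_protein_error(self):
        table = self._table({"P": [1.0] * 10})
        with pytest.raises(ValidationError, match="NOPE"):
            differential_proteins(table, {"P", "NOPE"})

    def test_planted_effect_sensitivity_and_null_rate(self):
        """2-fold planted effects at 20% CV (n=5/group) are recovered with
        sensitivity > 0.9 and planted nulls produce about an alpha-level
        joint false-call rate."""
        rng = np.random.default_rng(42)
        n_null, n_effect = 600, 100
        rows = {}
        for i in range(n_null):
            rows[f"N{i}"] = list(rng.normal(1000, 200, 10))
        for i in range(n_effect):
            rows[f"E{i}"] = list(np.concatenate(
                [rng.normal(1000, 200, 5), rng.normal(2000, 400, 5)]
            ))
        table = make_table(rows, _two_group_design())
        res = differential_proteins(table, set(rows))
        calls = res.table.set_index("gene_symbol")["call"]
        sens = (calls.loc[[f"E{i}" for i in range(n_effect)]] == "up_in_hi").mean()
        fpr = (calls.loc[[f"N{i}" for i in range(n_null)]] != "unchanged").mean()
        assert sens > 0.9
        assert abs(fpr - 0.05) <= 0.03


class TestCombinedSignature:
    def _diff(self, up_lo, up_hi):
        table = pd.DataFrame(
            {
                "gene_symbol": list(up_lo) + list(up_hi),
                "call": ["up_in_lo"] * len(up_lo) + ["up_in_hi"] * len(up_hi),
            }
        )
        from matrisig.diffabund import DifferentialResult

        return DifferentialResult(
            table=table, alpha=0.05, up_threshold=1.2, down_threshold=0.8,
            group_lo="CD8lo", group_hi="CD8hi",
        )

    def test_union_with_source_tags(self):
        diff = self._diff({"S1", "S2"}, {"T1"})
        combined = combined_signature({"E1", "E2", "E3"}, diff, "lo")
        assert combined.proteins == {"E1", "E2", "E3", "S1", "S2"}
        assert combined.source["E1"] == "exclusive"
        assert combined.source["S1"] == "differential"

    def test_empty_differential(self):
        combined = combined_signature({"E1"}, self._diff(set(), set()), "hi")
        assert combined.proteins == {"E1"}

    def test_bad_direction(self):
        with pytest.raises(ValueError):
            combined_signature(set(), self._diff(set(), set()), "sideways")
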