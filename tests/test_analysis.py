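"""Classification, aggregation, curves and statistics tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from virotrace3d.analysis import (
    SPATIAL_CLASSES,
    aggregate_cells,
    boxplot_summary,
    categorize_expression,
    classify_particle,
    cumulative_curve,
    distribution_table,
    mann_whitney_u,
    nuclear_fraction,
)


class TestClassification:
    @pytest.mark.parametrize(
        "nr, x, expected",
        [
            (1.0, 0.0, "inside_nucleus"),
            (0.5, 0.0, "nuclear_boundary"),
            (0.0, 0.0, "perinuclear"),
            (0.0, 0.01, "perinuclear"),
            (0.0, 0.010001, "cytoplasmic"),
            (0.0, 1.0, "cytoplasmic"),
        ],
    )
    def test_four_class_rules(self, nr, x, expected):
        assert classify_particle(nr, x) == expected

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_particle(0.5, 0.2)
        with pytest.raises(ValueError):
            classify_particle(1.2, 0.0)

    @given(
        nr=st.floats(0, 1, allow_nan=False),
        x=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=300, derandomize=True)
    def test_partition_property(self, nr, x):
        """Every consistent (NR, x) pair lands in exactly one class."""
        if nr > 0:
            x = 0.0
        assert classify_particle(nr, x) in SPATIAL_CLASSES


class TestNuclearFraction:
    def test_quoted_arithmetic_example(self):
        counts = {
            "inside_nucleus": 2, "nuclear_boundary": 1,
            "perinuclear": 1, "cytoplasmic": 8,
        }
        assert nuclear_fraction(counts) == pytest.approx(3 / 12)

    def test_extremes(self):
        assert nuclear_fraction({"cytoplasmic": 5}) == 0.0
        assert nuclear_fraction({"inside_nucleus": 5}) == 1.0
        assert nuclear_fraction({}) == 0.0


class TestAggregateCells:
    def _particles(self):
        rows = []
        for cls, n in [("inside_nucleus", 2), ("nuclear_boundary", 1), ("cytoplasmic", 3)]:
            rows += [{"timepoint": 0, "cell_label": 1, "spatial_class": cls}] * n
        rows.append({"timepoint": 0, "cell_label": 2, "spatial_class": "cytoplasmic"})
        return pd.DataFrame(rows)

    def _cell_info(self):
        return pd.DataFrame(
            {
                "timepoint": [0, 0, 0],
                "cell_label": [1, 2, 3],
                "track_id": [0, 1, 2],
                "cell_volume_vox": [1000, 1200, 900],
                "nucleus_volume_vox": [100, 120, 90],
                "mean_egfp": [500.0, 200.0, 900.0],
            }
        )

    def test_class_counts_sum_to_totals(self):
        out = aggregate_cells(self._particles(), self._cell_info())
        assert (out[list(SPATIAL_CLASSES)].sum(axis=1) == out["total_particles"]).all()
        cell1 = out[out.cell_label == 1].iloc[0]
        assert cell1["total_particles"] == 6
        assert cell1["nuclear_fraction"] == pytest.approx(3 / 6)

    def test_zero_particle_cell_flagged_with_zero_fraction(self):
        out = aggregate_cells(self._particles(), self._cell_info())
        cell3 = out[out.cell_label == 3].iloc[0]
        assert cell3["total_particles"] == 0
        assert cell3["nuclear_fraction"] == 0.0
        assert bool(cell3["zero_particle_flag"])

    def test_strict_nuclear_count_switch(self):
        strict = aggregate_cells(
            self._particles(), self._cell_info(),
            nuclear_counts_boundary_inclusive=False,
        )
        cell1 = strict[strict.cell_label == 1].iloc[0]
        assert cell1["particles_in_nucleus"] == 2  # NR = 1 only


class TestCumulativeCurve:
    def test_nine_of_twelve_is_75_percent(self):
        values = [0.0] * 3 + [0.2] * 6 + [0.8, 0.9, 0.95]
        curve = cumulative_curve(values)
        assert curve(0.5) == pytest.approx(0.75)

    def test_all_at_zero_curve_starts_at_one(self):
        assert cumulative_curve([0.0, 0.0])(0.0) == 1.0

    def test_matches_counting_oracle_and_is_monotone(self, rng):
        values = rng.uniform(0, 1, 200)
        curve = cumulative_curve(values)
        for x in rng.uniform(0, 1, 25):
            assert curve(x) == pytest.approx((values <= x).sum() / 200)
        grid = curve(np.linspace(0, 1, 50))
        assert np.all(np.diff(grid) >= 0)
        assert curve(1.0) == 1.0

    def test_empty_group_yields_empty_curve(self):
        curve = cumulative_curve([])
        assert curve.x.size == 0
        with pytest.raises(ValueError):
            curve(0.5)


class TestExpressionCategories:
    def _cells(self, intensities, timepoints=None):
        n = len(intensities)
        return pd.DataFrame(
            {
                "timepoint": timepoints if timepoints is not None else [0] * n,
                "track_id": list(range(n)) if timepoints is None else None,
                "mean_egfp": intensities,
            }
        ).assign(
            track_id=lambda d: d["track_id"]
            if d["track_id"].notna().all()
            else d.index
        )

    def test_hundred_distinct_values_split_50_25_25(self):
        cells = pd.DataFrame(
            {
                "timepoint": [0] * 100,
                "track_id": range(100),
                "mean_egfp": np.arange(1.0, 101.0),
            }
        )
        out, thresholds = categorize_expression(cells)
        counts = out["egfp_category"].value_counts().to_dict()
        assert counts == {"non": 50, "low": 25, "high": 25}
        assert thresholds.p50 == pytest.approx(50.5)
        assert thresholds.p75 == pytest.approx(75.25)

    def test_identical_values_all_non(self):
        cells = pd.DataFrame(
            {"timepoint": [0] * 8, "track_id": range(8), "mean_egfp": [7.0] * 8}
        )
        out, _ = categorize_expression(cells)
        assert (out["egfp_category"] == "non").all()

    def test_final_timepoint_category_propagates_longitudinally(self):
        cells = pd.DataFrame(
            {
                "timepoint": [0, 1, 0, 1],
                "track_id": [0, 0, 1, 1],
                "mean_egfp": [1.0, 100.0, 2.0, 3.0],
            }
        )
        out, _ = categorize_expression(cells)
        track0 = out[out.track_id == 0]
        assert set(track0["egfp_category_final"]) == {"high"}

    def test_too_few_values_rejected(self):
        cells = pd.DataFrame(
            {"timepoint": [0], "track_id": [0], "mean_egfp": [1.0]}
        )
        with pytest.raises(ValueError):
            categorize_expression(cells)


class TestMannWhitney:
    def test_exact_enumeration_textbook_example(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)
        assert res.u_statistic == 0.0

    def test_identical_groups_p_near_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_symmetry_in_group_order(self, rng):
        for _ in range(10):
            a, b = rng.normal(0, 1, 7), rng.normal(0.5, 1, 6)
            assert mann_whitney_u(a, b).p_value == pytest.approx(
                mann_whitney_u(b, a).p_value
            )

    def test_exact_matches_scipy_enumeration(self, rng):
        for _ in range(10):
            a, b = rng.normal(0, 1, 6), rng.normal(0.3, 1, 7)
            mine = mann_whitney_u(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert mine.method == "exact"
            assert mine.p_value == pytest.approx(ref.pvalue)

    def test_exact_and_asymptotic_agree_at_8_plus_8(self, rng):
        for _ in range(10):
            a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
            exact = mann_whitney_u(a, b, method="exact").p_value
            approx = mann_whitney_u(a, b, method="asymptotic").p_value
            assert abs(exact - approx) <= 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestBoxplotSummary:
    def test_textbook_median(self):
        assert boxplot_summary(np.arange(1, 101))["median"] == pytest.approx(50.5)

    def test_constant_sample_collapses(self):
        s = boxplot_summary([3.0] * 10)
        assert len({round(v, 12) for v in s.values()}) == 1

    def test_matches_sorted_percentile_oracle(self, rng):
        v = rng.normal(0, 1, 137)
        s = boxplot_summary(v)
        for key, q in [("p10", 10), ("p25", 25), ("median", 50), ("p75", 75), ("p90", 90)]:
            assert s[key] == pytest.approx(np.percentile(np.sort(v), q))


class TestDistributionTable:
    def _particles(self):
        rows = []
        for cond, classes in [
            ("ref", {"cytoplasmic": 70, "perinuclear": 10, "inside_nucleus": 15, "nuclear_boundary": 5}),
            ("treat", {"cytoplasmic": 50, "perinuclear": 20, "inside_nucleus": 20, "nuclear_boundary": 10}),
        ]:
            for cls, n in classes.items():
                rows += [{"condition": cond, "timepoint": 4, "spatial_class": cls}] * n
        return pd.DataFrame(rows)

    def test_reference_deltas_are_zero(self):
        table = distribution_table(self._particles(), "ref")
        ref_row = table[table.condition == "ref"].iloc[0]
        for col in ("cytoplasmic_delta", "perinuclear_delta", "nuclear_delta"):
            assert ref_row[col] == pytest.approx(0.0)

    def test_percentages_and_row_sum(self):
        table = distribution_table(self._particles(), "ref")
        ref_row = table[table.condition == "ref"].iloc[0]
        assert ref_row["cytoplasmic_pct"] == pytest.approx(70.0)
        assert ref_row["perinuclear_pct"] == pytest.approx(10.0)
        assert ref_row["nuclear_pct"] == pytest.approx(20.0)
        sums = table[["cytoplasmic_pct", "perinuclear_pct", "nuclear_pct"]].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=0.01)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            distribution_table(self._particles(), "nope")
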