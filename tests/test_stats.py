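"""Agreement statistics against hand-computed and published values."""

import numpy as np
import pytest

from coroflow import reference_data
from coroflow.stats import (BlandAltmanResult, PairedSeries, SensitivityRow,
                            SensitivityTable, bland_altman,
                            cohort_mean_relative_difference,
                            linear_regression, relative_difference,
                            report_from_dataframe, sensitivity_select)


def _table_from_df(df):
    rows = [SensitivityRow(str(r.face_size_mm), int(r.elements),
                           float(r.outlet_pressure_mmhg), float(r.wss_pa))
            for r in df.itertuples()]
    return SensitivityTable(rows)


class TestLinearRegression:
    def test_identity_series(self):
        ps = PairedSeries(np.arange(5.0) + 1, np.arange(5.0) + 1)
        reg = linear_regression(ps)
        assert reg.slope == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.r_squared == pytest.approx(1.0)

    def test_exact_line(self):
        reg = linear_regression(PairedSeries([1, 2, 3], [2, 4, 6]))
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.r_squared == pytest.approx(1.0)

    def test_against_sum_of_squares_arithmetic(self):
        # brute-force SS decomposition for x=[1,2,3], y=[1.9,4.1,5.9]:
        # slope 2, intercept -1/30, SSres = 0.0266667, SStot = 8.0266667,
        # hence r^2 = 1 - SSres/SStot = 0.9966778
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.9, 4.1, 5.9])
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        ssres = np.sum((y - slope * x - intercept) ** 2)
        sstot = np.sum((y - y.mean()) ** 2)
        expected_r2 = 1.0 - ssres / sstot
        assert expected_r2 == pytest.approx(0.9966778, abs=1e-6)
        reg = linear_regression(PairedSeries(x, y))
        assert reg.slope == pytest.approx(slope)
        assert reg.intercept == pytest.approx(intercept)
        assert reg.r_squared == pytest.approx(expected_r2, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            linear_regression(PairedSeries([1.0, 1.0, 1.0], [1, 2, 3]))


class TestBlandAltman:
    def test_identical_series_is_degenerate_zero(self):
        ba = bland_altman(PairedSeries([100.0, 101, 99], [100.0, 101, 99]))
        assert ba.mean_difference == 0
        assert ba.loa_low == ba.loa_high == 0

    def test_hand_arithmetic_case(self):
        # diffs [1, -1, 1]: mean 1/3, SD (n-1) = 1.1547,
        # limits 0.3333 +/- 2.2632
        ba = bland_altman(PairedSeries([100.0, 102, 98], [101.0, 101, 99]))
        assert ba.mean_difference == pytest.approx(1 / 3)
        assert ba.sd_difference == pytest.approx(1.1547, abs=1e-4)
        assert ba.loa_low == pytest.approx(1 / 3 - 2.2632, abs=1e-4)
        assert ba.loa_high == pytest.approx(1 / 3 + 2.2632, abs=1e-4)

    def test_limit_ordering_invariant(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(100, 5, 40)
        test = ref + rng.normal(0.5, 1.0, 40)
        ba = bland_altman(PairedSeries(ref, test))
        assert ba.loa_low <= ba.mean_difference <= ba.loa_high
        assert ba.fraction_within >= 0.9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            PairedSeries([1.0, 2.0], [1.0, 2.0])


class TestRelativeDifference:
    @pytest.mark.parametrize("x,ref,expected", [
        (7.14, 8.01, 10.86),   # published lumen-ladder WSS cells
        (6.31, 8.01, 21.22),
        (6.38, 8.14, 21.62),   # wall ladder
        (7.19, 8.14, 11.67),
        (105.516, 105.460, 0.053),
        (8.01, 8.01, 0.0),
    ])
    def test_reproduces_printed_cells(self, x, ref, expected):
        assert round(relative_difference(x, ref),
                     2 if expected >= 1 else 3) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_difference(1.0, 0.0)


class TestSensitivitySelection:
    def test_lumen_ladder_selects_the_400k_row(self):
        table = _table_from_df(reference_data.mesh_sensitivity_lumen())
        idx = sensitivity_select(table, wss_threshold=5.0)
        assert idx == 2
        assert table.rows[idx].elements == 400000
        assert table.wss_differences()[idx] == pytest.approx(2.87, abs=0.005)
        # outlet pressure is insensitive: <0.05% on the selected mesh
        assert table.pressure_differences()[idx] < 0.05

    def test_wall_ladder_selects_the_582k_row(self):
        table = _table_from_df(reference_data.mesh_sensitivity_wall())
        idx = sensitivity_select(table, wss_threshold=5.0)
        assert idx == 2
        assert table.rows[idx].elements == 582000
        assert table.pressure_differences()[idx] < 0.05

    def test_no_row_qualifying_requests_refinement(self):
        rows = [SensitivityRow("a", 10, 100.0, 5.0),
                SensitivityRow("b", 20, 100.0, 7.0),
                SensitivityRow("c", 40, 100.0, 10.0)]
        assert sensitivity_select(SensitivityTable(rows), 5.0) is None


class TestCohortStatistics:
    def test_rigid_vs_fsi_transient_mean_is_026(self):
        report = report_from_dataframe(reference_data.cohort_pressures())
        diff = cohort_mean_relative_difference(
            report, ("rigid_transient", "fsi_transient"))
        assert round(diff, 2) == 0.26

    def test_identical_columns_give_zero(self):
        report = report_from_dataframe(reference_data.cohort_pressures())
        assert cohort_mean_relative_difference(
            report, ("fsi_steady", "fsi_steady")) == 0.0

    def test_mean_definition(self):
        report = report_from_dataframe(reference_data.cohort_pressures())
        report.vessels = ["a", "b"]
        report.pressures = {"a": {"x": 101.0, "y": 100.0},
                            "b": {"x": 103.0, "y": 100.0}}
        assert cohort_mean_relative_difference(report, ("x", "y")) == \
            pytest.approx(2.0)

    def test_velocity_ratio_table_orders_pressures(self):
        # distal pressure rises as the assumed profile mean drops
        df = reference_data.velocity_ratio_pressures()
        assert (df.p_vmax_mmhg <= df.p_076vmax_mmhg).all()
        assert (df.p_076vmax_mmhg <= df.p_05vmax_mmhg).all()
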