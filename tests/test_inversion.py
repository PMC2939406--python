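import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycokinetics.conversion import round_half_away
from glycokinetics.inversion import (
    TABLE_HBMIX_ANCHORS,
    TABLE_MPG1_ANCHORS,
    error_grid,
    estimation_error,
    invert_hbx,
    invert_mpgx,
    percent_change,
    time_course,
)
from glycokinetics.kinetics import MixtureScenario, hb_mix

hb_levels = st.floats(min_value=3.0, max_value=16.0)
months_open = st.floats(min_value=1e-3, max_value=4.0)


class TestInvertHbx:
    def test_recovers_new_curve_from_worked_forward_step(self):
        res = invert_hbx(7.6875, hb1=9, m=1)
        assert res.hbx == pytest.approx(6.0, abs=1e-12)
        assert not res.non_physiological

    def test_two_week_measurement(self):
        # (16*11 - 12*12.25) / 3.75
        res = invert_hbx(11, hb1=12, m=0.5)
        assert res.hbx == pytest.approx(29 / 3.75)

    @given(hb_levels, months_open)
    def test_steady_state_inverts_to_itself(self, h, m):
        assert invert_hbx(h, h, m).hbx == pytest.approx(h, rel=1e-12)

    @given(hb_levels, hb_levels, months_open)
    def test_inverse_identity_against_forward_mixture(self, y, hb1, m):
        hbx = invert_hbx(y, hb1, m).hbx
        if hbx <= 0:
            return
        assert hb_mix(MixtureScenario(hb1=hb1, hbx=hbx, m=m)) == pytest.approx(y, abs=1e-9)

    def test_non_physiological_result_flagged_not_clamped(self):
        res = invert_hbx(2.0, hb1=14, m=0.5)
        assert res.hbx < 0  # algebraic value preserved
        assert res.non_physiological
        assert res.mpgx is None

    def test_m_zero_raises(self):
        with pytest.raises(ValueError):
            invert_hbx(7, 9, 0)


class TestInvertMpgx:
    def test_worked_inversion_in_glucose_space(self):
        res = invert_mpgx(7.6875, mpg1=244, m=1, constant_mode="paper")
        assert res.mpgx == pytest.approx(135.696, abs=5e-4)

    def test_tabulated_regime_with_low_measurement(self):
        res = invert_mpgx(5, mpg1=208, m=2, constant_mode="paper")
        assert res.mpgx == pytest.approx(65.17, abs=0.01)

    @given(st.floats(min_value=4, max_value=14), st.floats(min_value=100, max_value=420),
           st.floats(min_value=1.0, max_value=4.0))
    def test_paper_and_exact_constants_agree(self, hbmix, mpg1, m):
        paper = invert_mpgx(hbmix, mpg1, m, constant_mode="paper").mpgx
        exact = invert_mpgx(hbmix, mpg1, m, constant_mode="exact").mpgx
        assert paper == pytest.approx(exact, abs=1.5)

    def test_constant_rounding_amplified_at_short_intervals(self):
        # the 1/(8m - m^2) factor amplifies the rounded constants; at two
        # weeks the worst-case corner deviation grows to just over 1.5 mg/dl
        paper = invert_mpgx(14, 100, 0.5, constant_mode="paper").mpgx
        exact = invert_mpgx(14, 100, 0.5, constant_mode="exact").mpgx
        assert abs(paper - exact) < 2.0

    def test_fixed_point_when_no_change_occurred(self):
        # choose hb_mix consistent with an unchanged curve (exact mode)
        mpg1 = 244.0
        hbmix = mpg1 / 35.6 + 77.3 / 35.6
        res = invert_mpgx(hbmix, mpg1, 2, constant_mode="exact", intercept_mode="exact")
        assert res.mpgx == pytest.approx(mpg1, abs=1e-9)

    def test_negative_recovered_glucose_flagged(self):
        res = invert_mpgx(5, mpg1=420, m=2, constant_mode="paper")
        assert res.mpgx < 0
        assert res.non_physiological


class TestPercentChange:
    @pytest.mark.parametrize("m, expected", [(0, 0), (1, 43.75), (2, 75.0), (4, 100.0)])
    def test_values(self, m, expected):
        assert percent_change(m) == pytest.approx(expected)

    def test_first_month_rounds_to_table_value(self):
        assert round_half_away(percent_change(1)) == 44

    def test_independent_of_endpoints(self):
        # the endpoints cancel: the time-related fraction via any scenario
        for hb1, hbx in [(9, 6), (12, 6.93), (5, 14)]:
            tc = time_course(hb1, hbx, [1.0])
            frac = 100 * (hb1 - tc.hb_mix_values[0]) / (hb1 - hbx)
            assert frac == pytest.approx(percent_change(1), rel=1e-12)

    @given(st.floats(min_value=0.01, max_value=3.95), st.floats(min_value=0.01, max_value=0.5))
    def test_strictly_increasing_and_decelerating(self, m, dm):
        m2 = min(m + dm, 4.0)
        assert percent_change(m2) > percent_change(m)
        # second difference negative: the transition decelerates
        h = 0.05
        if m + 2 * h <= 4:
            d2 = percent_change(m + 2 * h) - 2 * percent_change(m + h) + percent_change(m)
            assert d2 < 0


class TestTimeCourse:
    def test_endpoint_reaches_new_curve(self):
        tc = time_course(12, 6.93, [4.0])
        assert tc.hb_mix_values[0] == pytest.approx(6.93)
        assert tc.percent_complete[0] == pytest.approx(100.0)

    def test_worked_point_and_midpoint(self):
        tc = time_course(9, 6, [1.0])
        assert tc.hb_mix_values[0] == pytest.approx(7.6875)
        tc2 = time_course(12, 6.93, [2.0])
        assert tc2.hb_mix_values[0] == pytest.approx((6.93 * 12 + 12 * 4) / 16)

    def test_default_grid_and_frame(self):
        tc = time_course(9, 6)
        assert tc.grid[0] == pytest.approx(0.1)
        assert tc.grid[-1] == pytest.approx(4.0)
        frame = tc.to_frame()
        assert list(frame.columns) == ["m_months", "hb_mix_percent", "percent_complete"]
        # monotone fall between the two curves
        assert (np.diff(tc.hb_mix_values) < 0).all()

    def test_empty_or_out_of_range_grid_raises(self):
        with pytest.raises(ValueError):
            time_course(9, 6, [])
        with pytest.raises(ValueError):
            time_course(9, 6, [0.0, 1.0])
        with pytest.raises(ValueError):
            time_course(9, 6, [4.5])


class TestEstimationError:
    def test_zero_when_no_change_occurred_exact_mode(self):
        mpg1 = 35.6 * 6 - 77.3
        est = estimation_error(6, mpg1, 2, constant_mode="exact", intercept_mode="exact")
        assert est.error == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "hbmix, mpg1, expected",
        [
            (5, 208, -54.53),  # 100*(1 - 100.7/65.17)
            (6, 101, 8.11),  # 100*(1 - 136.3/148.33)
        ],
    )
    def test_tabulated_regimes_paper_constants(self, hbmix, mpg1, expected):
        est = estimation_error(hbmix, mpg1, 2, constant_mode="paper")
        assert est.error == pytest.approx(expected, abs=0.01)

    def test_flag_propagates_from_inversion(self):
        est = estimation_error(5, 420, 2, constant_mode="paper")
        assert "non-physiological" in est.flags

    @given(hb_levels, hb_levels, st.floats(min_value=0.25, max_value=3.75))
    def test_sign_convention_exact_mode(self, hb1, hbx, m):
        # overestimation (hbx < hb1) gives negative error, and vice versa
        if abs(hb1 - hbx) < 1e-6 or min(hb1, hbx) < 3.5:
            return
        mpg1 = 35.6 * hb1 - 77.3
        hbmix = hb_mix(MixtureScenario(hb1=hb1, hbx=hbx, m=m))
        est = estimation_error(hbmix, mpg1, m, constant_mode="exact", intercept_mode="exact")
        if est.mpgx <= 0:
            return
        assert np.sign(est.error) == np.sign(hbx - hb1)


class TestErrorGrid:
    def test_diagonal_near_zero_paper_constants(self):
        for m in (2.0, 3.0):
            grid = error_grid(m, constant_mode="paper")
            # default anchors align crudely: 5%<->101 ... 14%<->420
            diag = np.diagonal(grid.cells)
            assert np.all(np.abs(diag) < 0.25)

    def test_diagonal_exactly_zero_exact_constants(self):
        mpg1 = [35.6 * h - 77.3 for h in TABLE_HBMIX_ANCHORS]
        grid = error_grid(2.0, mpg1_values=mpg1, constant_mode="exact", intercept_mode="exact")
        assert np.all(np.abs(np.diagonal(grid.cells)) < 1e-9)

    def test_sign_pattern_off_diagonal(self):
        grid = error_grid(2.0)
        cells, mask = grid.cells, grid.mask
        for i in range(len(TABLE_HBMIX_ANCHORS)):
            for j in range(len(TABLE_MPG1_ANCHORS)):
                if mask[i, j] or i == j:
                    continue
                # mpg1 above the measurement's own level => control improved
                # => crude conversion overestimates => negative error
                assert (cells[i, j] < 0) == (j > i)

    def test_magnitude_grows_with_distance_from_diagonal(self):
        grid = error_grid(2.0)
        for i in range(len(TABLE_HBMIX_ANCHORS)):
            row = np.abs(grid.cells[i])
            ok = ~grid.mask[i]
            right = row[(np.arange(len(row)) >= i) & ok]
            assert (np.diff(right) > -1e-9).all()
            left = row[(np.arange(len(row)) <= i) & ok][::-1]
            assert (np.diff(left) > -1e-9).all()

    def test_three_month_errors_smaller_than_two_month(self):
        # diagonal cells are sub-0.25 rounding residues of the published
        # constants, not genuine errors; the decay claim is about the rest
        g2, g3 = error_grid(2.0), error_grid(3.0)
        both = ~(g2.mask | g3.mask) & (np.abs(g2.cells) > 0.25)
        assert np.all(np.abs(g3.cells[both]) < np.abs(g2.cells[both]))

    def test_implausible_corners_masked(self):
        grid = error_grid(2.0)
        # very low measurement with very high prior glycemia is implausible
        assert grid.mask[0, -1]
        assert not grid.mask[0, 0]

    def test_csv_export_blanks_masked_cells(self, tmp_path):
        path = tmp_path / "grid.csv"
        grid = error_grid(2.0)
        grid.to_csv(path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + len(TABLE_HBMIX_ANCHORS)
        first_row = lines[1].split(",")
        assert first_row[-1] == ""  # masked cell serialized empty

    def test_empty_anchors_raise(self):
        with pytest.raises(ValueError):
            error_grid(2.0, mpg1_values=[])
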