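import numpy as np
import pytest

from maizephen import (
    ClimatologyStack,
    Raster,
    apply_mask,
    evaluate_rate,
    generate_raster_stack,
    map_phase_duration,
    map_total_cycle,
    read_ascii_grid,
    synthesize_daily_series,
    write_ascii_grid,
)

# degree-day curve with r(25 °C) = 0.02/day
DD = np.array([5.0, 1000.0])


def uniform_stack(tmin=20.0, tmax=30.0, nrows=3, ncols=3):
    stack, _ = generate_raster_stack(nrows=nrows, ncols=ncols,
                                     south_north_gradient=0.0,
                                     base_tmin=tmin, base_tmax=tmax,
                                     seasonal_amplitude=0.0, seed=0)
    return stack


class TestAsciiGrid:
    def test_round_trip_exact(self, tmp_path):
        r = Raster(values=np.array([[1.5, -9999.0], [3.25, 4.0]]),
                   xllcorner=34.0, yllcorner=-1.0, cellsize=0.5)
        p = tmp_path / "g.asc"
        write_ascii_grid(r, p)
        r2 = read_ascii_grid(p)
        assert r2.values.shape == (2, 2)
        np.testing.assert_allclose(r2.values, r.values, atol=1e-6)
        assert (r2.xllcorner, r2.yllcorner, r2.cellsize) == (34.0, -1.0, 0.5)
        assert r2.mask[0, 1] and not r2.mask[0, 0]  # nodata sentinel preserved

    def test_ragged_row_rejected(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 3\nnrows 2\nxllcorner 0\nyllcorner 0\n"
                     "cellsize 1\nNODATA_value -9999\n1 2\n3 4 5\n")
        with pytest.raises(ValueError, match="line 7"):
            read_ascii_grid(p)

    def test_malformed_header_rejected(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 2\nnrows 1\nbogus 0\nyllcorner 0\n"
                     "cellsize 1\nNODATA_value -9999\n1 2\n")
        with pytest.raises(ValueError, match="line 3"):
            read_ascii_grid(p)

    def test_row_count_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 2\nnrows 3\nxllcorner 0\nyllcorner 0\n"
                     "cellsize 1\nNODATA_value -9999\n1 2\n3 4\n")
        with pytest.raises(ValueError, match="nrows"):
            read_ascii_grid(p)


class TestSynthesizeDailySeries:
    def test_constant_climatology_gives_constant_series(self):
        stack = uniform_stack()
        s = synthesize_daily_series(stack, 0, 0, sowing_day_of_year=1)
        assert np.all(s.tmin == 20.0) and np.all(s.tmax == 30.0)

    def test_step_mode_holds_january_through_the_month(self):
        stack, _ = generate_raster_stack(nrows=2, ncols=2,
                                         south_north_gradient=0.0,
                                         seasonal_amplitude=2.0, seed=0)
        s = synthesize_daily_series(stack, 0, 0, sowing_day_of_year=1, mode="step")
        jan_tmin = stack.tmin[0].values[0, 0]
        assert np.all(s.tmin[:31] == jan_tmin)
        assert s.tmin[31] == stack.tmin[1].values[0, 0]

    def test_smooth_mode_passes_through_month_midpoints(self):
        stack, _ = generate_raster_stack(nrows=2, ncols=2,
                                         south_north_gradient=0.0,
                                         seasonal_amplitude=2.0, seed=0)
        s = synthesize_daily_series(stack, 0, 0, sowing_day_of_year=1, mode="smooth")
        # mid-January is day-of-year 15.5 -> index 15 with the half-day grid
        assert s.tmin[15] == pytest.approx(stack.tmin[0].values[0, 0])

    def test_nodata_cell_returns_none(self):
        stack, _ = generate_raster_stack(nrows=3, ncols=3, nodata_fraction=0.3, seed=1)
        bad = np.argwhere(stack.nodata_mask())
        assert len(bad) > 0
        i, j = bad[0]
        assert synthesize_daily_series(stack, int(i), int(j)) is None


class TestMapPhaseDuration:
    @pytest.mark.parametrize("mode", ["inverse_rate", "accumulation"])
    def test_uniform_grid_inverts_rate(self, mode):
        out = map_phase_duration(uniform_stack(), "linear_dd", DD, mode=mode)
        np.testing.assert_allclose(out.values, 50.0, atol=1e-9)

    def test_modes_agree_on_constant_climate(self):
        stack = uniform_stack()
        a = map_phase_duration(stack, "linear_dd", DD, mode="accumulation")
        b = map_phase_duration(stack, "linear_dd", DD, mode="inverse_rate")
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_cell_at_base_temperature_is_nodata(self):
        # mean temperature equals Tb of the briere curve -> r = 0
        stack = uniform_stack(tmin=4.0, tmax=14.0)
        out = map_phase_duration(stack, "briere1", [2e-5, 9.0, 40.0],
                                 mode="inverse_rate")
        assert np.all(out.mask)

    def test_nodata_absorbs_through_chain(self):
        stack, suit = generate_raster_stack(nrows=4, ncols=4, nodata_fraction=0.25,
                                            suitable_fraction=1.0, seed=3)
        out = map_phase_duration(stack, "linear_dd", DD, mode="inverse_rate")
        assert np.array_equal(out.mask, stack.nodata_mask())
        masked = apply_mask(out, suit)
        assert np.all(masked.mask[stack.nodata_mask()])

    def test_gradient_durations_decrease_toward_warm_edge(self):
        # south (higher row index) is warmer; all temps below the optimum
        stack, _ = generate_raster_stack(nrows=3, ncols=3,
                                         south_north_gradient=2.0,
                                         base_tmin=13.0, base_tmax=23.0,
                                         seasonal_amplitude=0.0, seed=0)
        theta = [2e-5, 9.0, 40.0]
        out = map_phase_duration(stack, "briere1", theta, mode="inverse_rate")
        col = out.values[:, 0]
        assert col[0] > col[1] > col[2]
        # hand evaluation of one cell: duration = 1/r(mean T)
        t_mean = (13.0 + 23.0) / 2.0
        assert col[0] == pytest.approx(1.0 / evaluate_rate("briere1", np.array(theta), t_mean))

    def test_output_geometry_matches_input(self):
        stack = uniform_stack()
        out = map_phase_duration(stack, "linear_dd", DD, mode="inverse_rate")
        assert out.same_geometry(stack.geometry)


class TestApplyMask:
    def _duration(self):
        return map_phase_duration(uniform_stack(nrows=4, ncols=4), "linear_dd",
                                  DD, mode="inverse_rate")

    def test_all_ones_is_identity(self):
        d = self._duration()
        ones = d.with_values(np.ones_like(d.values))
        np.testing.assert_array_equal(apply_mask(d, ones).values, d.values)

    def test_all_zeros_blanks_everything(self):
        d = self._duration()
        zeros = d.with_values(np.zeros_like(d.values))
        assert np.all(apply_mask(d, zeros).mask)

    def test_checkerboard_keeps_half(self):
        d = self._duration()
        board = np.indices(d.values.shape).sum(axis=0) % 2
        masked = apply_mask(d, d.with_values(board.astype(float)))
        assert int((~masked.mask).sum()) == d.values.size // 2

    def test_geometry_mismatch_rejected(self):
        d = self._duration()
        other = Raster(values=np.ones((2, 2)), cellsize=d.cellsize)
        with pytest.raises(ValueError, match="co-registered"):
            apply_mask(d, other)

    def test_255_dialect_counts_as_suitable(self):
        d = self._duration()
        m = d.with_values(np.full_like(d.values, 255.0))
        np.testing.assert_array_equal(apply_mask(d, m).values, d.values)


class TestMapTotalCycle:
    def test_uniform_total_is_offset_plus_phase_inverses(self):
        stack = uniform_stack()
        vp, rp = np.array([5.0, 1000.0]), np.array([5.0, 800.0])
        out = map_total_cycle(stack, "linear_dd", vp, rp, emergence_offset=7,
                              mode="inverse_rate")
        np.testing.assert_allclose(out.values, 7.0 + 50.0 + 40.0, atol=1e-9)
        acc = map_total_cycle(stack, "linear_dd", vp, rp, emergence_offset=7,
                              mode="accumulation")
        np.testing.assert_allclose(acc.values, out.values, atol=1e-9)

    def test_total_bounds_each_component(self):
        stack = uniform_stack()
        total = map_total_cycle(stack, "linear_dd", DD, emergence_offset=7)
        phase = map_phase_duration(stack, "linear_dd", DD)
        assert np.all(total.values >= phase.values)

    def test_nodata_propagates_from_climatology(self):
        stack, _ = generate_raster_stack(nrows=4, ncols=4, nodata_fraction=0.25, seed=5)
        total = map_total_cycle(stack, "linear_dd", DD)
        assert np.all(total.mask[stack.nodata_mask()])


class TestStackValidation:
    def test_misregistered_stack_rejected(self):
        stack = uniform_stack()
        shifted = Raster(values=stack.tmin[0].values, xllcorner=99.0,
                         yllcorner=-1.0, cellsize=stack.geometry.cellsize)
        with pytest.raises(ValueError, match="co-registered"):
            ClimatologyStack(tmin=(shifted,) + stack.tmin[1:], tmax=stack.tmax)
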