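"""Rate-table parsing, RCCR computation, scaling, and threshold crossings."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from diffscan.rccr import (
    RateCurve,
    RccrCurve,
    ScalingParams,
    compute_rccr,
    crossing_time,
    divergence_estimate,
    read_rate_table,
    scale_ne,
    scale_time,
    write_rate_table,
)


def _curve(left, right, w1, c, w2):
    return RateCurve(np.asarray(left), np.asarray(right), np.asarray(w1),
                     np.asarray(c), np.asarray(w2))


class TestRateTableIO:
    def test_two_bin_round_trip(self, tmp_path):
        curve = _curve([0.0, 1e-5], [1e-5, 3e-5], [100.0, 200.0],
                       [10.0, 150.0], [120.0, 210.0])
        path = tmp_path / "rates.txt"
        write_rate_table(curve, path)
        back = read_rate_table(path)
        for f in ("left", "right", "lam_within1", "lam_cross", "lam_within2"):
            np.testing.assert_array_equal(getattr(back, f), getattr(curve, f))

    def test_writer_reader_round_trip_bit_identical(self, tmp_path):
        # re-writing the parsed curve reproduces the file byte for byte
        curve = _curve([0.0, 1.234e-5], [1.234e-5, 7.7e-5],
                       [123.456, 0.1], [0.0, 0.05], [99.9, 0.2])
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        write_rate_table(curve, p1)
        write_rate_table(read_rate_table(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_shuffled_rows_rejected(self, tmp_path):
        path = tmp_path / "rates.txt"
        lines = [
            "time_index\tleft_time_boundary\tright_time_boundary\tlambda_00\tlambda_01\tlambda_11",
            "1\t1e-5\t2e-5\t1.0\t1.0\t1.0",
            "0\t0\t1e-5\t1.0\t1.0\t1.0",
        ]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="out of order"):
            read_rate_table(path)

    def test_malformed_columns_rejected(self, tmp_path):
        path = tmp_path / "rates.txt"
        path.write_text("a\tb\n1\t2\n")
        with pytest.raises(ValueError, match="columns"):
            read_rate_table(path)

    def test_non_monotone_bins_rejected(self):
        with pytest.raises(ValueError):
            _curve([0.0, 0.5e-5], [2e-5, 1e-5], [1, 1], [1, 1], [1, 1])


class TestComputeRccr:
    def test_panmixia_is_one(self):
        c = _curve([0, 1], [1, 2], [5.0, 5.0], [5.0, 5.0], [5.0, 5.0])
        np.testing.assert_allclose(compute_rccr(c).values, 1.0)

    def test_full_separation_is_zero(self):
        c = _curve([0, 1], [1, 2], [5.0, 5.0], [0.0, 0.0], [5.0, 5.0])
        np.testing.assert_allclose(compute_rccr(c).values, 0.0)

    def test_elementwise_hand_computation(self):
        c = _curve([0, 1, 2], [1, 2, 3], [2.0, 4.0, 1.0], [1.0, 3.0, 2.0],
                   [6.0, 2.0, 3.0])
        np.testing.assert_allclose(
            compute_rccr(c).values, [2 * 1 / 8, 2 * 3 / 6, 2 * 2 / 4]
        )

    def test_zero_within_sum_flagged_undefined(self):
        c = _curve([0, 1], [1, 2], [0.0, 5.0], [1.0, 5.0], [0.0, 5.0])
        vals = compute_rccr(c).values
        assert np.isnan(vals[0]) and vals[1] == pytest.approx(1.0)

    def test_all_undefined_rejected(self):
        c = _curve([0, 1], [1, 2], [0.0, 0.0], [1.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            compute_rccr(c)


class TestScaling:
    def setup_method(self):
        self.params = ScalingParams(nu=4.3e-10, g=29.0)

    def test_mu_is_nu_times_g(self):
        assert self.params.mu == pytest.approx(4.3e-10 * 29)

    def test_zero_time_maps_to_zero(self):
        assert scale_time(0.0, self.params) == 0.0

    def test_division_example(self):
        assert scale_time(4.3e-5, self.params) == pytest.approx(100_000.0)

    @given(a=st.floats(0, 1e-3), b=st.floats(0, 1e-3))
    def test_linearity(self, a, b):
        p = ScalingParams(nu=4.3e-10, g=29.0)
        assert scale_time(a + b, p) == pytest.approx(
            scale_time(a, p) + scale_time(b, p), rel=1e-12, abs=1e-6
        )

    def test_ne_inversion(self):
        mu = self.params.mu
        lam = 1 / (2 * mu * 10_000)
        assert scale_ne(lam, self.params) == pytest.approx(10_000.0)

    def test_doubling_rate_halves_ne(self):
        assert scale_ne(2.0, self.params) == pytest.approx(scale_ne(1.0, self.params) / 2)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            scale_ne(0.0, self.params)
        with pytest.raises(ValueError):
            ScalingParams(nu=-1, g=29)


class TestCrossingTimes:
    def test_linear_ramp_crossings(self):
        # midpoint values rise linearly 0 -> 1 over t in [0, 100]
        times = np.linspace(0, 100, 201)
        values = times / 100.0
        for th, expect in [(0.25, 25.0), (0.5, 50.0), (0.75, 75.0)]:
            t, _ = crossing_time(times, values, th)
            assert t == pytest.approx(expect, rel=1e-9)

    def test_step_curve_crossing_within_jump_bin(self):
        # RCCR 0 up to T = 10, then 1: all crossings land between the
        # midpoints bracketing the jump, and the 0.5 crossing at T exactly
        # when the midpoints are symmetric around it
        times = np.array([2.0, 6.0, 9.5, 10.5, 14.0])
        values = np.array([0.0, 0.0, 0.0, 1.0, 1.0])
        t50, _ = crossing_time(times, values, 0.5)
        assert t50 == pytest.approx(10.0)
        for th in (0.25, 0.75):
            t, _ = crossing_time(times, values, th)
            assert 9.5 < t < 10.5

    def test_never_crossing_reported_undefined(self):
        times = np.array([1.0, 2.0, 3.0])
        t, _ = crossing_time(times, np.array([0.1, 0.2, 0.3]), 0.5)
        assert np.isnan(t)

    def test_already_above_threshold_at_present_undefined(self):
        times = np.array([1.0, 2.0, 3.0])
        t, _ = crossing_time(times, np.array([0.9, 0.95, 1.0]), 0.5)
        assert np.isnan(t)

    def test_extra_crossings_logged_not_reported(self):
        times = np.array([1.0, 2, 3, 4, 5, 6])
        values = np.array([0.1, 0.6, 0.2, 0.7, 0.4, 0.9])
        t, extras = crossing_time(times, values, 0.5)
        assert t < 2.0
        assert len(extras) == 2

    def test_invariance_to_uniform_rate_rescaling(self):
        rng = np.random.default_rng(8)
        n = 30
        edges = np.linspace(0, 3e-4, n + 1)
        w = rng.uniform(1, 5, n)
        cross = np.linspace(0, 1, n) * w  # rising RCCR
        base = _curve(edges[:-1], edges[1:], w, cross, w)
        scaled = _curve(edges[:-1], edges[1:], 7.3 * w, 7.3 * cross, 7.3 * w)
        p = ScalingParams()
        e1 = divergence_estimate(compute_rccr(base), p)
        e2 = divergence_estimate(compute_rccr(scaled), p)
        assert e1.t50 == pytest.approx(e2.t50, rel=1e-12)


class TestDivergenceEstimate:
    def test_report_string_convention(self):
        from diffscan.rccr import DivergenceEstimate

        est = DivergenceEstimate(t25=59_000.0, t50=100_000.0, t75=160_000.0)
        assert est.report() == "~100 (160–59) kya"

    def test_undefined_crossings_are_nan_not_fabricated(self):
        c = _curve([0, 1e-5], [1e-5, 2e-5], [5.0, 5.0], [5.0, 5.0], [5.0, 5.0])
        est = divergence_estimate(compute_rccr(c), ScalingParams())
        assert np.isnan(est.t50)
        assert "NA" in est.report()
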