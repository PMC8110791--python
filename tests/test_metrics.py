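"""Hemodynamic metric unit and property tests.

Piecewise-constant waveforms are integrated exactly by a segment-sum
oracle independent of the trapezoidal implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graftmech.metrics import (
    AreaSeries,
    InvalidInputError,
    WssSeries,
    compute_osi,
    compute_strain,
    compute_tawss,
    in_percentile_window,
    read_areas_csv,
    read_wss_csv,
    summarize,
)

from conftest import make_wss

T = 1.0


def piecewise_grid(breakpoint=0.5, eps=1e-15, n=101):
    """Uniform grid over [0, T] refined to straddle a jump at `breakpoint`."""
    t = np.linspace(0.0, T, n)
    return np.sort(np.unique(np.concatenate([t, [breakpoint - eps, breakpoint]])))


def piecewise_wss(hi=2.0, lo=-1.0, breakpoint=0.5):
    t = piecewise_grid(breakpoint)
    tau = np.where(t < breakpoint, hi, lo)
    vec = np.zeros((t.size, 3))
    vec[:, 0] = tau
    return make_wss(t, vec, period=T)


def exact_piecewise_integrals(hi, lo, breakpoint):
    """Oracle: exact segment-sum integrals of the two-level waveform."""
    int_signed = hi * breakpoint + lo * (T - breakpoint)
    int_abs = abs(hi) * breakpoint + abs(lo) * (T - breakpoint)
    return int_signed, int_abs


class TestTawss:
    def test_constant_vector(self):
        t = np.linspace(0, T, 7)
        s = make_wss(t, np.tile([3.0, 0, 0], (7, 1)))
        assert compute_tawss(s)[0] == pytest.approx(3.0, abs=1e-14)

    @pytest.mark.parametrize("amplitude", [1.0, 2.5])
    def test_rectified_sine_mean(self, amplitude):
        t = np.linspace(0, T, 4001)
        vec = np.zeros((t.size, 3))
        vec[:, 0] = amplitude * np.sin(2 * np.pi * t / T)
        s = make_wss(t, vec)
        assert compute_tawss(s)[0] == pytest.approx(2 * amplitude / np.pi, rel=1e-5)

    def test_piecewise_matches_exact_oracle(self):
        s = piecewise_wss()
        _, int_abs = exact_piecewise_integrals(2.0, -1.0, 0.5)
        assert compute_tawss(s)[0] == pytest.approx(int_abs / T, abs=1e-12)
        assert compute_tawss(s)[0] == pytest.approx(1.5, abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            make_wss([0.0, 1.0], np.zeros((2, 3)))

    def test_nonfinite_rejected(self):
        vec = np.zeros((5, 3))
        vec[2, 0] = np.nan
        with pytest.raises(InvalidInputError):
            make_wss(np.linspace(0, 1, 5), vec)


class TestOsi:
    def test_unidirectional_limit(self):
        t = np.linspace(0, T, 11)
        s = make_wss(t, np.tile([1.0, 0, 0], (11, 1)))
        assert compute_osi(s)[0] == pytest.approx(0.0, abs=1e-12)

    def test_purely_oscillatory_limit(self):
        t = np.linspace(0, T, 1001)
        vec = np.zeros((t.size, 3))
        vec[:, 0] = np.sin(2 * np.pi * t / T)
        s = make_wss(t, vec)
        assert compute_osi(s)[0] == pytest.approx(0.5, abs=1e-12)

    def test_piecewise_matches_exact_oracle(self):
        s = piecewise_wss()
        int_signed, int_abs = exact_piecewise_integrals(2.0, -1.0, 0.5)
        expected = 0.5 * (1 - abs(int_signed) / int_abs)
        assert expected == pytest.approx(1.0 / 3.0, abs=1e-15)
        assert compute_osi(s)[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_wss_element_is_missing_not_zero(self):
        t = np.linspace(0, T, 9)
        vecs = np.zeros((9, 2, 3))
        vecs[:, 1, 0] = 1.0
        s = WssSeries(np.array(["dead", "live"]), t, vecs)
        osi = compute_osi(s)
        assert np.isnan(osi[0]) and osi[1] == pytest.approx(0.0, abs=1e-12)

    def test_quadrature_convergence_on_refinement(self):
        def metrics(n):
            t = np.linspace(0, T, n)
            vec = np.zeros((t.size, 3))
            vec[:, 0] = 1.2 + np.sin(2 * np.pi * t / T)
            vec[:, 1] = 0.5 * np.cos(4 * np.pi * t / T)
            s = make_wss(t, vec)
            return compute_tawss(s)[0], compute_osi(s)[0]

        c1, o1 = metrics(400)
        c2, o2 = metrics(800)
        assert abs(c2 - c1) / c1 < 1e-3
        assert abs(o2 - o1) < 1e-3

    def test_time_origin_invariance(self):
        def metrics(phase):
            t = np.linspace(0, T, 1200)
            vec = np.zeros((t.size, 3))
            vec[:, 0] = 0.7 + np.sin(2 * np.pi * t / T + phase)
            vec[:, 2] = 0.3 * np.cos(2 * np.pi * t / T + phase)
            s = make_wss(t, vec)
            return compute_tawss(s)[0], compute_osi(s)[0]

        base = metrics(0.0)
        shifted = metrics(1.234)
        assert base[0] == pytest.approx(shifted[0], rel=1e-5)
        assert base[1] == pytest.approx(shifted[1], abs=1e-5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounds_and_mean_vector_inequality(self, seed):
        """OSI in [0, 0.5]; TAWSS dominates the cycle-mean vector norm."""
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 60)
        t = np.sort(rng.uniform(0, T, n - 2))
        t = np.concatenate([[0.0], t, [T]])
        t = np.unique(t)
        if t.size < 3:
            t = np.linspace(0, T, 3)
        vecs = rng.normal(0, 2, (t.size, 3, 3))
        s = WssSeries(np.arange(3), t, vecs)
        osi = compute_osi(s)
        tawss = compute_tawss(s)
        span = t[-1] - t[0]
        mean_vec = np.trapezoid(vecs, t, axis=0) / span
        ok = ~np.isnan(osi)
        assert np.all(osi[ok] >= 0.0) and np.all(osi[ok] <= 0.5)
        assert np.all(tawss + 1e-12 >= np.linalg.norm(mean_vec, axis=1))


class TestStrain:
    def test_undeformed_is_zero(self):
        t = np.linspace(0, T, 21)
        A0 = np.array([1.0])
        s = AreaSeries(np.array(["e0"]), t, A0, np.ones((21, 1)))
        assert compute_strain(s)[0] == 0.0

    def test_constant_dilation(self):
        t = np.linspace(0, T, 21)
        s = AreaSeries(np.array(["e0"]), t, np.array([1.0]), np.full((21, 1), 1.04))
        assert compute_strain(s)[0] == pytest.approx(0.2, abs=1e-12)

    def test_scale_invariance(self):
        t = np.linspace(0, T, 33)
        A0 = np.array([1.0, 2.0])
        An = 1.04 * np.tile(A0, (33, 1))
        s = AreaSeries(np.array(["a", "b"]), t, A0, An)
        eps = compute_strain(s)
        assert eps[0] == pytest.approx(eps[1], abs=1e-14)

    def test_compression_clamps_with_warning_or_raises(self):
        t = np.linspace(0, T, 5)
        An = np.full((5, 1), 0.99)
        s = AreaSeries(np.array(["e0"]), t, np.array([1.0]), An)
        with pytest.warns(RuntimeWarning):
            assert compute_strain(s)[0] == 0.0
        with pytest.raises(InvalidInputError):
            compute_strain(s, negative_policy="strict")


class TestSummaries:
    def test_median_of_small_set(self):
        s = summarize(np.array([1, 2, 3, 4, 5.0]), probe_percentiles=[50])
        assert s.values[0] == pytest.approx(3.0)

    def test_evenly_spread_quantile(self):
        s = summarize(np.arange(101.0), probe_percentiles=[15])
        assert s.values[0] == pytest.approx(15.0)

    def test_percentile_curve_monotone_and_counts_complete(self, rng):
        vals = rng.lognormal(0, 1, 500)
        s = summarize(vals, bins=17)
        assert np.all(np.diff(s.values) >= 0)
        assert s.counts.sum() == 500

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            summarize(np.array([np.nan]))

    def test_window_membership(self):
        data = np.arange(1.0, 101.0)
        inside, lo, hi = in_percentile_window(float(np.median(data)), data, 15, 100)
        assert inside
        assert not in_percentile_window(0.5, data, 0, 100)[0]
        inside10, lo15, _ = in_percentile_window(10.0, data, 15, 100)
        assert lo15 == pytest.approx(15.85)
        assert not inside10

    def test_window_validation(self):
        with pytest.raises(ValueError):
            in_percentile_window(1.0, np.arange(5.0), 50, 20)
        with pytest.raises(InvalidInputError):
            in_percentile_window(1.0, np.array([]), 15, 100)


class TestCsvRoundTrip:
    def test_wss_and_areas(self, tmp_path, rng):
        import pandas as pd

        t = np.linspace(0, T, 5)
        rows = []
        for e in ("a", "b"):
            for i, ti in enumerate(t):
                rows.append(
                    {"element_id": e, "time_s": ti, "tau_x": float(i), "tau_y": 0.0, "tau_z": 1.0}
                )
        f = tmp_path / "wss.csv"
        pd.DataFrame(rows).to_csv(f, index=False)
        s = read_wss_csv(f)
        assert s.n_elements == 2 and s.vectors[3, 0, 0] == 3.0

        rows = [
            {"element_id": "a", "time_s": ti, "A0_mm2": 1.0, "An_mm2": 1.0 + 0.01 * i}
            for i, ti in enumerate(t)
        ]
        g = tmp_path / "areas.csv"
        pd.DataFrame(rows).to_csv(g, index=False)
        a = read_areas_csv(g)
        assert a.An[2, 0] == pytest.approx(1.02)
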