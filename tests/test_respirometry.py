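"""Gas equations, window search, drift correction, and trace reduction."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from avitherm import respirometry as resp
from avitherm import synthetic as syn


class TestGasEquations:
    @pytest.mark.parametrize("fio2,feo2,fr,rq,expected", [
        (0.2095, 0.2095, 1000.0, 0.70, 0.0),
        # hand arithmetic: 1000*0.001 / (1 - 0.2095*0.3)
        (0.2095, 0.2085, 1000.0, 0.70, 1.0670650376140436),
        # RQ = 1 collapses the denominator to 1
        (0.2095, 0.2085, 1000.0, 1.0, 1.0),
    ])
    def test_vo2_values(self, fio2, feo2, fr, rq, expected):
        assert resp.vo2_from_fractions(fio2, feo2, fr, rq) == \
            pytest.approx(expected, rel=1e-12)

    def test_vo2_rejects_negative_consumption(self):
        with pytest.raises(ValueError):
            resp.vo2_from_fractions(0.2085, 0.2095, 1000.0)

    @given(depletion=st.floats(1e-6, 5e-3), extra=st.floats(1e-6, 5e-3))
    def test_vo2_monotone_in_depletion(self, depletion, extra):
        fio2 = 0.2095
        lo = resp.vo2_from_fractions(fio2, fio2 - depletion, 1000.0)
        hi = resp.vo2_from_fractions(fio2, fio2 - depletion - extra, 1000.0)
        assert hi > lo

    @pytest.mark.parametrize("wvp_in,wvp_ex,bp,fr,expected", [
        (0.4, 0.4, 101.0, 1000.0, 0.0),
        # hand arithmetic: 3000*0.005/0.995 * 0.803 * 60
        (0.0, 0.505, 101.0, 3000.0, 726.3316582914574),
    ])
    def test_ewl_values(self, wvp_in, wvp_ex, bp, fr, expected):
        assert resp.ewl_from_wvp(wvp_in, wvp_ex, bp, fr) == \
            pytest.approx(expected, rel=1e-12)

    def test_ewl_linear_in_flow(self):
        one = resp.ewl_from_wvp(0.1, 0.8, 101.0, 1000.0)
        two = resp.ewl_from_wvp(0.1, 0.8, 101.0, 2000.0)
        assert two == pytest.approx(2.0 * one, rel=1e-12)

    def test_ewl_rejects_saturation(self):
        with pytest.raises(ValueError):
            resp.ewl_from_wvp(0.0, 102.0, 101.0, 1000.0)


class TestLowestStableWindow:
    def test_constant_series(self):
        win = resp.lowest_stable_window(np.full(300, 2.5))
        assert win == (0, 2.5, 0.0, True)

    def test_decreasing_then_flat(self):
        series = np.concatenate([np.linspace(3.0, 1.0, 200), np.full(200, 1.0)])
        win = resp.lowest_stable_window(series)
        assert win.start_index >= 200 - 120  # window inside the flat tail
        assert win.mean == pytest.approx(1.0, rel=1e-3)

    def test_matches_bruteforce_scan(self, rng):
        """Sawtooth-plus-noise series: agrees with an exhaustive scan
        over every start index."""
        t = np.arange(600)
        series = 2.0 + 0.5 * np.abs((t % 200) - 100) / 100 + \
            0.01 * rng.standard_normal(600)
        win = resp.lowest_stable_window(series)

        best = None  # independent O(n*w) oracle
        for start in range(600 - 120 + 1):
            chunk = series[start:start + 120]
            m, s = chunk.mean(), chunk.std()
            if s <= 0.05 * abs(m) and (best is None or m < best[1]):
                best = (start, m, s)
        assert win.stable
        assert win.start_index == best[0]
        assert win.mean == pytest.approx(best[1])
        assert win.sd == pytest.approx(best[2])

    def test_no_stable_window_flagged(self, rng):
        series = rng.standard_normal(300) * 10 + 1.0
        win = resp.lowest_stable_window(series)
        assert not win.stable

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            resp.lowest_stable_window(np.ones(100), duration=120.0)


def _trace(population, drift_o2=0.0, drift_wvp=0.0, noise_o2=0.0,
           noise_wvp=0.0, flow=3000.0, vo2=1.2, ewl=500.0, seed=11):
    tc = syn.TraceConfig(flow_rate=flow, drift_rate_o2=drift_o2,
                         drift_rate_wvp=drift_wvp,
                         analyzer_noise_sd_o2=noise_o2,
                         analyzer_noise_sd_wvp=noise_wvp,
                         n_animal_segments=8 if flow < 3000 else 4)
    return syn.generate_trace(population[0], 40.0, vo2, ewl, tc,
                              rng=np.random.default_rng(seed))


class TestDriftCorrect:
    def test_identity_without_drift(self, population):
        trace = _trace(population)
        corrected = resp.drift_correct(trace)
        assert np.allclose(corrected.o2, trace.o2, atol=1e-9)
        assert np.allclose(corrected.wvp, trace.wvp, atol=1e-9)

    def test_linear_drift_removed(self, population):
        """+0.0005 O2-fraction/h of drift: corrected baselines sit on
        the nominal incurrent value to 1e-6."""
        trace = _trace(population, drift_o2=5e-4, drift_wvp=0.02)
        corrected = resp.drift_correct(trace)
        for seg in np.unique(trace.segment_id[trace.is_baseline]):
            mask = (trace.segment_id == seg) & trace.is_baseline
            inner = np.where(mask)[0][30:-30]
            assert np.mean(corrected.o2[inner]) == \
                pytest.approx(trace.fio2, abs=1e-6)
            assert np.mean(corrected.wvp[inner]) == \
                pytest.approx(trace.incurrent_wvp, abs=1e-6)

    def test_spline_matches_hermite_oracle(self, population):
        """Parabolic baseline anchors: the applied correction equals an
        independently coded cubic-Hermite (Catmull-Rom) evaluation."""
        trace = _trace(population)
        # impose a parabola in time on the O2 channel
        bump = 1e-3 * (trace.time / trace.time[-1]) ** 2
        warped = dataclasses.replace(trace, o2=trace.o2 + bump)
        tk, pk = resp.baseline_anchors(warped, warped.o2)
        assert tk.size == 3
        corrected = resp.drift_correct(warped)

        def hermite(t):  # textbook Hermite basis, independent of scipy
            m = np.empty(3)
            m[0] = (pk[1] - pk[0]) / (tk[1] - tk[0])
            m[2] = (pk[2] - pk[1]) / (tk[2] - tk[1])
            m[1] = (pk[2] - pk[0]) / (tk[2] - tk[0])
            i = 0 if t <= tk[1] else 1
            h = tk[i + 1] - tk[i]
            s = (t - tk[i]) / h
            h00 = 2 * s**3 - 3 * s**2 + 1
            h10 = s**3 - 2 * s**2 + s
            h01 = -2 * s**3 + 3 * s**2
            h11 = s**3 - s**2
            return (h00 * pk[i] + h10 * h * m[i]
                    + h01 * pk[i + 1] + h11 * h * m[i + 1])

        mid = np.argmin(np.abs(warped.time - 0.5 * (tk[1] + tk[2])))
        applied = warped.o2[mid] - corrected.o2[mid] + warped.fio2
        assert applied == pytest.approx(hermite(warped.time[mid]), abs=1e-12)

    def test_single_baseline_offset_fallback(self, population):
        trace = _trace(population)
        keep = trace.segment_id <= 1
        short = dataclasses.replace(
            trace, time=trace.time[keep], o2=trace.o2[keep],
            wvp=trace.wvp[keep], segment_id=trace.segment_id[keep],
            is_baseline=trace.is_baseline[keep])
        corrected = resp.drift_correct(short)
        assert "single_baseline_offset_correction" in corrected.flags


class TestReduceTrace:
    def test_roundtrip_zero_noise_hot_flow(self, population):
        """A clean forward-modeled trace reduces back to the generator's
        steady rates within 0.5% once the chamber has washed out."""
        measure = resp.reduce_trace(_trace(population, flow=3000.0))
        assert abs(measure.vo2 - 1.2) / 1.2 < 0.005
        assert abs(measure.ewl - 500.0) / 500.0 < 0.005

    def test_roundtrip_zero_noise_cold_flow(self, population):
        measure = resp.reduce_trace(
            _trace(population, flow=1000.0, vo2=1.3, ewl=150.0))
        assert abs(measure.vo2 - 1.3) / 1.3 < 0.01
        assert abs(measure.ewl - 150.0) / 150.0 < 0.01

    def test_drift_invariance(self, population):
        """A common linear drift on both channels changes the reduced
        rates by <1% (the spline correction removes it)."""
        clean = resp.reduce_trace(_trace(population))
        drifted = resp.reduce_trace(
            _trace(population, drift_o2=5e-4, drift_wvp=0.05))
        assert abs(drifted.vo2 - clean.vo2) / clean.vo2 < 0.01
        assert abs(drifted.ewl - clean.ewl) / clean.ewl < 0.01

    def test_deterministic(self, population):
        a = resp.reduce_trace(_trace(population, noise_o2=5e-6, seed=42))
        b = resp.reduce_trace(_trace(population, noise_o2=5e-6, seed=42))
        assert a == b

    def test_rates_non_negative_under_noise(self, population):
        measure = resp.reduce_trace(
            _trace(population, noise_o2=2e-5, noise_wvp=0.01, seed=5))
        assert measure.vo2 >= 0.0 and measure.ewl >= 0.0

    def test_window_excludes_washout_transient(self, population):
        trace = _trace(population)
        measure = resp.reduce_trace(trace)
        assert measure.window_start >= 5.0 * trace.washout_tau
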