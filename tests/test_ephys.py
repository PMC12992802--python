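"""Tonic-current decomposition, sIPSC detection, regression and reversal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cereb import ephys, synthdata


class TestDrugShift:
    def test_noise_free_staircase_step(self):
        truth = synthdata.TraceGroundTruth(
            component_shifts={"base->TTX": 5.0, "TTX->GBZ": 5.0}, noise_sd=0.0
        )
        trace, _ = synthdata.gen_tonic_trace(
            ("TTX", "GBZ"), truth, duration=900, rate=100,
            event_times=(300.0, 600.0),
        )
        d = ephys.drug_shift(trace, ("base", "TTX"), settle=120.0)
        assert abs(d - 5.0) < 1e-3

    def test_flat_trace_zero_shift(self):
        truth = synthdata.TraceGroundTruth(
            component_shifts={"base->TTX": 0.0, "TTX->GBZ": 0.0}, noise_sd=0.0
        )
        trace, _ = synthdata.gen_tonic_trace(("TTX", "GBZ"), truth)
        assert ephys.drug_shift(trace, ("base", "TTX")) == pytest.approx(0.0, abs=1e-9)

    def test_shift_matches_ground_truth_masked_mean_oracle(self):
        """Mode-of-histogram baseline vs averaging only IPSC-free samples."""
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(1, 419, int(3 * 420)))
        times = times[np.diff(times, prepend=-1.0) > 2e-2]
        truth = synthdata.TraceGroundTruth(
            component_shifts={"base->TTX": 8.0, "TTX->GBZ": 5.0},
            ipsc_times=times,
            ipsc_amplitudes=np.full(len(times), 30.0),
            noise_sd=2.0,
        )
        trace, _ = synthdata.gen_tonic_trace(("TTX", "GBZ"), truth, seed=4)
        d = ephys.drug_shift(trace, ("base", "TTX"))

        # oracle: mean over samples > 60 ms away from any injected event
        def clean_mean(t0, t1):
            sel = (trace.t >= t0) & (trace.t < t1)
            for te in times[(times > t0 - 0.1) & (times < t1)]:
                sel &= ~((trace.t >= te) & (trace.t < te + 0.06))
            return trace.I[sel].mean()

        t_ev = trace.event_time("TTX")
        oracle = clean_mean(t_ev + 60, t_ev + 90) - clean_mean(t_ev - 30, t_ev)
        assert abs(d - 8.0) < 0.5
        assert abs(d - oracle) < 0.5

    def test_window_overlapping_event_raises(self, noisy_trace):
        trace, _ = noisy_trace
        with pytest.raises(ephys.WindowingError):
            ephys.drug_shift(trace, ("base", "TTX"), settle=5.0, post_window=300.0)


class TestDecomposeTonic:
    def test_fraction_arithmetic(self):
        truth = synthdata.TraceGroundTruth(
            component_shifts={"base->TTX": 6.35, "TTX->GBZ": 3.65}, noise_sd=0.0
        )
        trace, _ = synthdata.gen_tonic_trace(
            ("TTX", "GBZ"), truth, duration=900, rate=100,
            event_times=(300.0, 600.0),
        )
        dec = ephys.decompose_tonic(trace, settle=120.0)
        assert dec.ttx_sensitive_fraction == pytest.approx(0.635, abs=1e-3)

    def test_zero_sensitive_component(self):
        truth = synthdata.TraceGroundTruth(
            component_shifts={"base->TTX": 0.0, "TTX->GBZ": 10.0}, noise_sd=0.0
        )
        trace, _ = synthdata.gen_tonic_trace(
            ("TTX", "GBZ"), truth, duration=900, rate=100,
            event_times=(300.0, 600.0),
        )
        dec = ephys.decompose_tonic(trace, settle=120.0)
        assert dec.ttx_sensitive_fraction == pytest.approx(0.0, abs=1e-3)

    def test_randomized_shifts_recovered_and_additive(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            s1, s2 = rng.uniform(2, 14), rng.uniform(2, 12)
            truth = synthdata.TraceGroundTruth(
                component_shifts={"base->TTX": s1, "TTX->GBZ": s2}, noise_sd=2.0
            )
            trace, _ = synthdata.gen_tonic_trace(
                ("TTX", "GBZ"), truth, seed=int(rng.integers(2**31))
            )
            dec = ephys.decompose_tonic(trace)
            assert abs(dec.ttx_sensitive_pA - s1) < 0.5
            assert abs(dec.ttx_insensitive_pA - s2) < 0.5
            # additivity is exact by construction
            assert dec.ttx_sensitive_pA + dec.ttx_insensitive_pA == dec.total_tonic_pA

    def test_npa_protocol_reads_post_npa_transitions(self):
        truth = synthdata.TraceGroundTruth(
            component_shifts={"base->NPA": 4.0, "NPA->TTX": 7.0, "TTX->GBZ": 3.0},
            noise_sd=0.0,
        )
        trace, _ = synthdata.gen_tonic_trace(
            ("NPA", "TTX", "GBZ"), truth, duration=1200, rate=100,
            event_times=(300.0, 600.0, 900.0),
        )
        dec = ephys.decompose_tonic(trace, protocol="npa-ttx-gbz", settle=120.0)
        assert dec.ttx_sensitive_pA == pytest.approx(7.0, abs=0.05)
        assert dec.total_tonic_pA == pytest.approx(10.0, abs=0.1)

    def test_missing_events_raise(self, noisy_trace):
        trace, _ = noisy_trace
        with pytest.raises(ephys.ProtocolError):
            ephys.decompose_tonic(trace, protocol="npa-ttx-gbz")


class TestDetectIPSCs:
    def test_flat_trace_no_events(self):
        truth = synthdata.TraceGroundTruth(
            component_shifts={"base->TTX": 0.0, "TTX->GBZ": 0.0}, noise_sd=0.0
        )
        trace, _ = synthdata.gen_tonic_trace(("TTX", "GBZ"), truth)
        assert len(ephys.detect_ipscs(trace, window=(0, 130)).times) == 0

    def test_detection_sensitivity_and_false_positives(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(1, 59, 50))
        times = times[np.diff(times, prepend=-1.0) > 2e-2]
        truth = synthdata.TraceGroundTruth(
            component_shifts={"base->TTX": 8.0, "TTX->GBZ": 6.0},
            ipsc_times=times,
            ipsc_amplitudes=np.full(len(times), 30.0),
            noise_sd=2.0,
        )
        trace, _ = synthdata.gen_tonic_trace(("TTX", "GBZ"), truth, seed=100)
        ev = ephys.detect_ipscs(trace, window=(0.0, 62.0))
        matched = sum(np.min(np.abs(ev.times - t0)) < 5e-3 for t0 in times)
        false_pos = sum(np.min(np.abs(times - te)) > 5e-3 for te in ev.times)
        assert matched >= len(times) - 2
        assert false_pos <= 1

    def test_train_frequency(self):
        tt = np.arange(0.25, 60.25, 0.5)
        truth = synthdata.TraceGroundTruth(
            component_shifts={"base->TTX": 0.0, "TTX->GBZ": 0.0},
            ipsc_times=tt,
            ipsc_amplitudes=np.full(len(tt), 30.0),
            noise_sd=2.0,
        )
        trace, _ = synthdata.gen_tonic_trace(
            ("TTX", "GBZ"), truth, duration=200, event_times=(70.0, 140.0), seed=3
        )
        ev = ephys.detect_ipscs(trace, window=(0.0, 60.5))
        assert ev.frequency_Hz == pytest.approx(2.0, abs=0.1)

    def test_window_after_blockade_raises(self, noisy_trace):
        trace, _ = noisy_trace
        with pytest.raises(ephys.ProtocolError):
            ephys.detect_ipscs(trace, window=(0.0, 400.0))


class TestRegression:
    def test_collinear_points(self):
        slope, intercept, r2, p = ephys.fit_freq_current_regression(
            [(1, 2), (2, 4), (3, 6)]
        )
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_response(self):
        slope, _, r2, _ = ephys.fit_freq_current_regression([(1, 5), (2, 5), (3, 5)])
        assert slope == 0.0
        assert r2 == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 5, 30)
        y = 1.7 * x - 3.0 + rng.standard_normal(30)
        slope, intercept, r2, _ = ephys.fit_freq_current_regression(
            list(zip(x, y))
        )
        X = np.stack([x, np.ones(30)], axis=1)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2_oracle = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert abs(slope - beta[0]) < 1e-10
        assert abs(intercept - beta[1]) < 1e-10
        assert abs(r2 - r2_oracle) < 1e-10

    def test_degenerate_predictor_raises(self):
        with pytest.raises(ValueError):
            ephys.fit_freq_current_regression([(1, 2), (1, 4), (1, 6)])


class TestReversal:
    @pytest.mark.parametrize(
        "func,expected",
        [(lambda v: v + 65.0, -65.0), (lambda v: 2 * (v + 80.0), -80.0)],
    )
    def test_linear_iv_crossings(self, func, expected):
        v = np.arange(-100, -40, 5.0)
        assert ephys.reversal_from_iv(list(zip(v, func(v)))) == pytest.approx(expected)

    def test_noisy_crossing_within_1mV(self):
        rng = np.random.default_rng(2)
        v = np.arange(-90, -40, 2.0)
        errs = []
        for _ in range(20):
            i = (v + 65.0) + rng.normal(0, 1.0, len(v))
            errs.append(ephys.reversal_from_iv(list(zip(v, i))) + 65.0)
        assert np.abs(np.mean(errs)) < 1.0

    def test_no_sign_change_raises(self):
        v = np.arange(-100, -80, 5.0)
        with pytest.raises(ValueError):
            ephys.reversal_from_iv(list(zip(v, v + 200.0)))

    @settings(max_examples=30, derandomize=True)
    @given(
        e_rev=st.floats(-95, -45),
        slope=st.floats(0.5, 5.0),
    )
    def test_exact_recovery_property(self, e_rev, slope):
        v = np.linspace(-110, -30, 17)
        i = slope * (v - e_rev)
        assert ephys.reversal_from_iv(list(zip(v, i))) == pytest.approx(
            e_rev, abs=1e-9
        )


class TestExGABA:
    @pytest.mark.parametrize(
        "vm,df,expected", [(-80, 15, -95), (-80, 0, -80), (-80, -15, -65)]
    )
    def test_convention(self, vm, df, expected):
        assert ephys.estimate_exgaba(vm, df).E_xGABA_mV == expected

    def test_alternate_convention(self):
        assert ephys.estimate_exgaba(-80, 15, "e_minus_vm").E_xGABA_mV == -65

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ephys.estimate_exgaba(float("nan"), 10.0)


class TestTraceIO:
    @pytest.mark.parametrize("ext", [".csv", ".h5"])
    def test_roundtrip(self, tmp_path, noisy_trace, ext):
        trace, _ = noisy_trace
        path = tmp_path / f"trace{ext}"
        ephys.save_trace(trace, path)
        back = ephys.load_trace(path)
        assert np.allclose(back.t, trace.t)
        assert np.allclose(back.I, trace.I)
        assert [lb for lb, _ in back.events] == [lb for lb, _ in trace.events]
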