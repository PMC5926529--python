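"""Filtering, differentiation and event detection."""

import numpy as np
import pytest
from scipy import signal

from antisaccade.trace_processing import (
    DIFF_COEFFS,
    EDGE_INVALID,
    GazeTrace,
    NonUniformSamplingError,
    ProcessingConfig,
    RawEvent,
    TraceTooShortError,
    detect_events,
    differentiate_8pt,
    extract_saccades,
    lowpass_filter,
    measure_event,
    process_many,
)

from conftest import make_trace, padded_saccade_trace

FS = 240.0


class TestLowpassFilter:
    def test_unit_dc_gain(self):
        tr = make_trace(np.full(400, 5.0))
        out = lowpass_filter(tr)
        np.testing.assert_allclose(out.x, 5.0, atol=1e-9)

    def test_linearity(self, rng):
        x1, x2 = rng.normal(size=(2, 500))
        a, b = 2.5, -1.3
        combo = lowpass_filter(make_trace(a * x1 + b * x2)).x
        sep = a * lowpass_filter(make_trace(x1)).x + b * lowpass_filter(make_trace(x2)).x
        np.testing.assert_allclose(combo, sep, atol=1e-9)

    @pytest.mark.parametrize("freq", [5.0, 25.0])
    def test_causal_gain_matches_design(self, freq):
        # steady-state amplitude of a single-pass filtered sinusoid equals the
        # designed transfer function magnitude at that frequency (~ -3 dB at 25 Hz)
        t = np.arange(4800) / FS
        tr = make_trace(np.sin(2 * np.pi * freq * t))
        out = lowpass_filter(tr, mode="causal")
        measured = np.max(np.abs(out.x[2400:]))
        sos = signal.butter(3, 25.0, fs=FS, output="sos")
        _, h = signal.sosfreqz(sos, worN=[freq], fs=FS)
        assert measured == pytest.approx(abs(h[0]), rel=0.01)
        if freq == 25.0:
            assert measured == pytest.approx(10 ** (-3 / 20), abs=0.01)

    def test_short_trace_rejected(self):
        with pytest.raises(TraceTooShortError):
            lowpass_filter(make_trace(np.zeros(20)))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(make_trace(np.zeros(400)), mode="sideways")


class TestDifferentiator:
    def test_constant_gives_zero(self):
        v = differentiate_8pt(make_trace(np.full(100, 3.0)))
        np.testing.assert_allclose(v.vx[v.valid_mask], 0.0, atol=1e-12)

    def test_edge_samples_flagged(self):
        v = differentiate_8pt(make_trace(np.zeros(50)))
        assert not v.valid_mask[:EDGE_INVALID].any()
        assert not v.valid_mask[-EDGE_INVALID:].any()
        assert v.valid_mask[EDGE_INVALID:-EDGE_INVALID].all()

    @pytest.mark.parametrize("degree", [0, 1, 2, 3, 4])
    def test_exact_on_polynomials(self, degree):
        # central differences of this order are exact on low-degree polynomials
        t = np.arange(481) / FS
        coeffs = np.array([0.7, -1.1, 0.9, 0.4, -0.2])[: degree + 1]
        x = np.polyval(coeffs[::-1], t)
        truth = np.polyval(np.polyder(coeffs[::-1]), t)
        v = differentiate_8pt(make_trace(x))
        np.testing.assert_allclose(
            v.vx[v.valid_mask], truth[v.valid_mask], atol=1e-9
        )

    def test_ramp_exact(self):
        t = np.arange(100) / FS
        v = differentiate_8pt(make_trace(5.0 * t))
        np.testing.assert_allclose(v.vx[v.valid_mask], 5.0, atol=1e-9)

    def test_sinusoid_peak_near_analytic(self):
        # 30 Hz unit sinusoid: estimated peak speed within 3 dB of 2*pi*30
        t = np.arange(2400) / FS
        v = differentiate_8pt(make_trace(np.sin(2 * np.pi * 30 * t)))
        peak = np.max(np.abs(v.vx[v.valid_mask]))
        analytic = 2 * np.pi * 30
        assert peak > analytic * 10 ** (-3 / 20)
        assert peak < analytic * 10 ** (3 / 20)

    def test_stencil_bandwidth_exceeds_70hz(self):
        # |H(f)| of the stencil vs the ideal differentiator 2*pi*f up to 70 Hz
        freqs = np.linspace(1, 70, 70)
        omega = 2 * np.pi * freqs / FS
        h = FS * 2 * sum(
            c * np.sin((k + 1) * omega) for k, c in enumerate(DIFF_COEFFS)
        )
        ideal = 2 * np.pi * freqs
        ratio_db = 20 * np.log10(np.abs(h) / ideal)
        assert np.all(ratio_db > -3.0)

    def test_non_uniform_time_rejected(self):
        t = np.arange(50) / FS
        t[20] += 0.002
        with pytest.raises(NonUniformSamplingError):
            GazeTrace(t=t, x=np.zeros(50), y=np.zeros(50))


def _brute_force_runs(speed, valid, threshold):
    """Naive per-sample scan for supra-threshold runs (test oracle)."""
    runs, start = [], None
    for i, s in enumerate(speed):
        above = s >= threshold and valid[i]
        if above and start is None:
            start = i
        elif not above and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(speed)))
    return runs


class TestDetection:
    def test_no_events_on_silence(self):
        v = differentiate_8pt(make_trace(np.zeros(200)))
        assert detect_events(v) == []

    def test_matches_brute_force_scan(self, rng):
        # 50 noise-free synthetic saccades: onset/offset equal the naive scan
        for _ in range(50):
            amp = rng.uniform(3, 18)
            dur = 20 + 3.4 * amp
            vp = rng.uniform(1.8, 2.0) * amp / (dur / 1000.0)
            trace, _ = padded_saccade_trace(amp, dur, vp)
            v = differentiate_8pt(trace)
            events = detect_events(v, merge_gap_ms=4.0, min_duration_ms=12.0)
            runs = [
                r
                for r in _brute_force_runs(v.speed, v.valid_mask, 10.0)
                if (r[1] - r[0]) / FS * 1000.0 >= 12.0
            ]
            assert [(e.onset_idx, e.offset_idx) for e in events] == runs

    def test_nearby_runs_merged_with_10ms_gap(self):
        speed = np.zeros(120)
        speed[40:50] = 50.0
        speed[51:60] = 50.0  # 1-sample gap ~ 4 ms
        valid = np.ones(120, bool)
        v_trace = type("V", (), {})()
        from antisaccade.trace_processing import VelocityTrace

        v = VelocityTrace(
            t=np.arange(120) / FS, vx=speed, vy=np.zeros(120),
            speed=speed, valid_mask=valid, fs=FS,
        )
        merged = detect_events(v, merge_gap_ms=10.0)
        assert [(e.onset_idx, e.offset_idx) for e in merged] == [(40, 60)]
        split = detect_events(v, merge_gap_ms=4.0)
        assert [(e.onset_idx, e.offset_idx) for e in split] == [(40, 50), (51, 60)]

    def test_short_runs_discarded(self):
        from antisaccade.trace_processing import VelocityTrace

        speed = np.zeros(100)
        speed[50:52] = 40.0  # 2 samples ~ 8.3 ms < 12 ms
        v = VelocityTrace(
            t=np.arange(100) / FS, vx=speed, vy=np.zeros(100),
            speed=speed, valid_mask=np.ones(100, bool), fs=FS,
        )
        assert detect_events(v) == []

    def test_positive_threshold_required(self):
        v = differentiate_8pt(make_trace(np.zeros(100)))
        with pytest.raises(ValueError):
            detect_events(v, threshold=0.0)


class TestMeasureEvent:
    def test_amplitude_sign_and_angle(self):
        x = np.concatenate([np.zeros(50), np.linspace(0, -10, 20), np.full(50, -10.0)])
        tr = make_trace(x)
        v = differentiate_8pt(tr)
        ev = detect_events(v, merge_gap_ms=4.0)[0]
        m = measure_event(tr, v, ev, target_onset_s=0.1)
        assert m.amplitude_deg < -9
        assert m.direction_angle_deg == pytest.approx(0.0, abs=1.0)

    def test_duration_arithmetic(self):
        tr = make_trace(np.zeros(100))
        v = differentiate_8pt(tr)
        m = measure_event(tr, v, RawEvent(10, 26), target_onset_s=0.0)
        assert m.duration_ms == pytest.approx(16 / FS * 1000.0)  # 66.67 ms

    def test_peak_is_exhaustive_max(self, rng):
        trace, _ = padded_saccade_trace(12.0, 60.0, 380.0)
        v = differentiate_8pt(trace)
        ev = detect_events(v, merge_gap_ms=4.0)[0]
        m = measure_event(trace, v, ev, target_onset_s=0.0)
        assert m.peak_velocity_deg_s == np.max(v.speed[ev.onset_idx : ev.offset_idx])
        assert m.mean_velocity_deg_s == pytest.approx(
            np.mean(v.speed[ev.onset_idx : ev.offset_idx])
        )

    def test_latency_can_be_negative(self):
        trace, _ = padded_saccade_trace(10.0, 55.0, 330.0)
        v = differentiate_8pt(trace)
        ev = detect_events(v, merge_gap_ms=4.0)[0]
        m = measure_event(trace, v, ev, target_onset_s=10.0)
        assert m.latency_ms < 0


class TestBatchProcessing:
    def test_process_many_matches_single_trace_path(self, rng):
        cfg = ProcessingConfig()
        n = 500
        traces = []
        for _ in range(6):
            amp = rng.uniform(-15, 15)
            if abs(amp) < 3:
                amp = 5.0
            dur = 25 + 3.0 * abs(amp)
            vp = 1.9 * abs(amp) / (dur / 1000.0)
            tr, _ = padded_saccade_trace(amp, dur, vp, pad=150)
            x = np.full(n, tr.x[-1])
            x[: min(n, tr.x.size)] = tr.x[: min(n, tr.x.size)]
            noisy = x + rng.normal(0, 0.05, n)
            traces.append(make_trace(noisy))
        t = traces[0].t
        xs = np.vstack([tr.x for tr in traces])
        ys = np.vstack([tr.y for tr in traces])
        batch = process_many(t, xs, ys, target_onset_s=0.1, config=cfg)
        for tr, events in zip(traces, batch):
            single = extract_saccades(tr, 0.1, cfg)
            assert len(single) == len(events)
            for a, b in zip(single, events):
                assert a.onset_s == b.onset_s
                assert a.amplitude_deg == pytest.approx(b.amplitude_deg, abs=1e-9)
                assert a.peak_velocity_deg_s == pytest.approx(
                    b.peak_velocity_deg_s, abs=1e-9
                )
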