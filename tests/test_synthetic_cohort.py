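"""Generator: profiles, schedules, waveforms, trial traces, cohorts."""

import math

import numpy as np
import pytest
from scipy import stats

from antisaccade.synthetic_cohort import (
    FS_HZ,
    SubjectProfile,
    TrialSpec,
    UnknownGroupError,
    default_profiles,
    generate_cohort,
    generate_trial_schedule,
    generate_trial_trace,
    study_cohort_profiles,
    synthesize_saccade_waveform,
)
from antisaccade.trace_processing import differentiate_8pt

from conftest import make_trace, padded_saccade_trace


class TestDefaultProfiles:
    def test_control_latency_parameters(self):
        prof = default_profiles("CTR")
        assert prof.ecc[10].anti_latency_mean == pytest.approx(268.7)
        assert prof.ecc[10].anti_latency_sd == pytest.approx(30.8)
        assert prof.ecc[10].isi_mean == pytest.approx(127.5)

    def test_group_error_probabilities(self):
        assert default_profiles("LOCA").directional_error_prob == pytest.approx(0.654)
        assert default_profiles("SCA2").directional_error_prob == pytest.approx(0.396)
        assert default_profiles("CTR").directional_error_prob == pytest.approx(0.193)

    def test_main_sequence_parameters(self):
        sca2 = default_profiles("SCA2")
        assert sca2.mainseq_vmax == pytest.approx(496.0)
        assert sca2.mainseq_c == pytest.approx(34.6)
        ctr = default_profiles("CTR")
        assert (ctr.mainseq_k, ctr.mainseq_b) == (22.5, 3.4)

    def test_unknown_group_rejected(self):
        with pytest.raises(UnknownGroupError):
            default_profiles("XYZ")

    def test_invalid_probability_rejected(self):
        prof = default_profiles("CTR")
        with pytest.raises(ValueError):
            SubjectProfile(**{**vars(prof), "directional_error_prob": 1.5})


class TestTrialSchedule:
    def test_empty(self):
        assert generate_trial_schedule(0, seed=1) == []

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            generate_trial_schedule(-1, seed=1)

    def test_session_of_80_trials(self):
        specs = generate_trial_schedule(80, seed=1)
        assert len(specs) == 80
        assert all(s.eccentricity_deg in (10, 18) for s in specs)
        assert all(s.target_direction in (-1, 1) for s in specs)
        # timeline invariants are enforced by the TrialSpec constructor
        assert all(
            s.target_onset_s - s.fixation_onset_s == pytest.approx(0.5)
            and s.target_offset_s - s.target_onset_s == pytest.approx(2.5)
            for s in specs
        )

    def test_condition_cells_uniform(self):
        # binomial oracle: each of the 4 cells should hit 1/4 +- 0.03 at n=4000
        specs = generate_trial_schedule(4000, seed=1)
        for d in (-1, 1):
            for e in (10, 18):
                f = sum(
                    s.target_direction == d and s.eccentricity_deg == e
                    for s in specs
                ) / 4000.0
                assert abs(f - 0.25) < 0.03


class TestWaveform:
    def test_zero_amplitude_flat(self):
        w = synthesize_saccade_waveform(0.0, 50.0, 300.0, start_position_deg=2.5)
        assert np.all(w.position == 2.5)

    @pytest.mark.parametrize(
        "amp,dur,vp",
        [(10.0, 55.8, 319.8), (-10.0, 55.8, 319.8), (17.3, 81.3, 388.6), (5.0, 39.5, 234.2)],
    )
    def test_attainable_triples_honoured(self, amp, dur, vp):
        trace, w = padded_saccade_trace(amp, dur, vp)
        assert not w.relaxed
        # displacement within 1% (trapezoidal integration oracle on velocity)
        assert w.position[-1] - w.position[0] == pytest.approx(amp, rel=0.01)
        vel = differentiate_8pt(trace)
        sp = vel.speed[vel.valid_mask]
        assert np.max(sp) == pytest.approx(vp, rel=0.05)
        supra_ms = np.sum(sp >= 10.0) / FS_HZ * 1000.0
        assert abs(supra_ms - dur) <= 2.0 / FS_HZ * 1000.0

    def test_unattainable_peak_relaxed_but_flagged(self):
        # implied peak/mean ratio beyond the profile family
        trace, w = padded_saccade_trace(10.0, 64.0, 339.0)
        assert w.relaxed
        assert w.position[-1] - w.position[0] == pytest.approx(10.0, rel=0.01)
        vel = differentiate_8pt(trace)
        sp = vel.speed[vel.valid_mask]
        supra_ms = np.sum(sp >= 10.0) / FS_HZ * 1000.0
        assert abs(supra_ms - 64.0) <= 2.0 / FS_HZ * 1000.0
        # nearest attainable stays within 5% of the request here
        assert np.max(sp) == pytest.approx(339.0, rel=0.05)

    def test_random_triples_fidelity(self, rng):
        # 300 random attainable requests: displacement <=1%, peak <=5%
        for _ in range(300):
            amp = rng.uniform(2, 20) * rng.choice([-1, 1])
            dur = 20 + 3.5 * abs(amp) + rng.uniform(0, 15)
            ratio = rng.uniform(1.75, 2.05)
            vp = ratio * abs(amp) / (dur / 1000.0)
            w = synthesize_saccade_waveform(amp, dur, vp)
            assert w.position[-1] - w.position[0] == pytest.approx(amp, rel=0.01)
            if not w.relaxed:
                fine = np.diff(w.position) * FS_HZ
                assert np.max(np.abs(fine)) <= vp * 1.05

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            synthesize_saccade_waveform(10.0, 0.0, 300.0)


def _quiet_profile(group="CTR", **overrides):
    prof = default_profiles(group)
    prof.noise_sd = 0.0
    prof.vertical_component_sd = 0.0
    prof.anticipatory_prob = 0.0
    prof.oblique_prob = 0.0
    prof.directional_error_prob = 0.0
    for k, v in overrides.items():
        setattr(prof, k, v)
    return prof


class TestTrialTrace:
    def test_noise_free_single_antisaccade(self, trial_spec_right_10):
        prof = _quiet_profile()
        trace, truth = generate_trial_trace(prof, trial_spec_right_10, seed=7)
        assert truth.label == "correct_anti"
        # mirror direction: target right -> saccade left
        assert truth.amplitude_deg < 0
        # the drawn latency is recorded at 1/240 s resolution
        assert truth.latency_ms * FS_HZ / 1000.0 == pytest.approx(
            round(truth.latency_ms * FS_HZ / 1000.0), abs=1e-6
        )
        # position still at fixation up to target onset (sample 120)
        onset_idx = int(round(trial_spec_right_10.target_onset_s * FS_HZ))
        assert onset_idx == 120
        assert np.all(np.abs(trace.x[: onset_idx + 1]) < 1e-9)

    def test_error_with_correction_has_two_opposite_movements(
        self, trial_spec_right_10
    ):
        prof = _quiet_profile(directional_error_prob=1.0, correction_prob=1.0)
        trace, truth = generate_trial_trace(prof, trial_spec_right_10, seed=3)
        assert truth.label == "error_corrected"
        assert np.sign(truth.amplitude_deg) == trial_spec_right_10.target_direction
        assert np.sign(truth.corrective_amplitude_deg) == -np.sign(
            truth.amplitude_deg
        )
        assert truth.isi_ms > 0

    def test_trace_covers_fixation_through_target_offset(self, trial_spec_right_10):
        trace, _ = generate_trial_trace(
            _quiet_profile(), trial_spec_right_10, seed=0
        )
        assert trace.t[0] == pytest.approx(0.0)
        assert trace.t[-1] == pytest.approx(3.0)
        assert len(trace) == int(round(3.0 * FS_HZ)) + 1

    def test_quantization_step(self, trial_spec_right_10):
        prof = _quiet_profile()
        prof.quantize = True
        trace, _ = generate_trial_trace(prof, trial_spec_right_10, seed=0)
        steps = np.round(trace.x / 0.16) * 0.16
        assert np.allclose(trace.x, steps, atol=1e-12)

    def test_error_rate_matches_binomial_interval(self, trial_spec_right_10):
        # realized directional-error fraction within the exact binomial 99% CI
        prof = default_profiles("CTR")
        prof.anticipatory_prob = 0.0
        prof.oblique_prob = 0.0
        n = 3000
        errors = 0
        for i in range(n):
            _, truth = generate_trial_trace(
                prof, trial_spec_right_10, np.random.SeedSequence([11, i])
            )
            errors += truth.label.startswith("error")
        p = prof.directional_error_prob
        lo = stats.binom.ppf(0.005, n, p)
        hi = stats.binom.ppf(0.995, n, p)
        assert lo <= errors <= hi


class TestCohort:
    def test_requires_profiles(self):
        with pytest.raises(ValueError):
            generate_cohort([], 5, seed=0)

    def test_determinism(self):
        prof = default_profiles("CTR", subject_id="c1")
        a = generate_cohort([prof], 3, seed=0)
        b = generate_cohort([prof], 3, seed=0)
        assert a.truth.equals(b.truth)
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.x, tb.x)
            np.testing.assert_array_equal(ta.y, tb.y)

    def test_different_seeds_differ(self):
        prof = default_profiles("CTR", subject_id="c1")
        a = generate_cohort([prof], 4, seed=0)
        b = generate_cohort([prof], 4, seed=1)
        assert not np.allclose(
            a.truth["latency_ms"].to_numpy(), b.truth["latency_ms"].to_numpy(),
            equal_nan=True,
        )

    def test_study_design_counts(self):
        profiles = study_cohort_profiles()
        groups = [p.group for p in profiles]
        assert groups.count("CTR") == 34
        assert groups.count("SCA2") == 12
        assert groups.count("LOCA") == 10
        # patient ICARS scores populated from the published per-patient values
        sca2 = [p.icars for p in profiles if p.group == "SCA2"]
        assert sca2[:3] == [26, 36, 59]
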