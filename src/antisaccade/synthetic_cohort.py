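"""Synthetic anti-saccade cohorts with known ground truth.

The generator emulates the anti-saccade protocol of the study population it
is parameterised from: 240 Hz horizontal/vertical eye position in degrees,
a 500 ms central fixation followed by a peripheral target at +-10 or
+-18 deg shown for 2,500 ms, and three behavioural groups (healthy controls,
SCA2, LOCA) whose latency distributions, directional-error and correction
probabilities, saccade dynamics and gain are taken from the published group
values.

Saccade waveforms use a unimodal velocity profile v(tau) proportional to
sin^{2p}(pi*tau/T).  The exponent p and the envelope duration T are solved
per saccade so that (i) the total displacement equals the requested
amplitude, (ii) the time spent above the 10 deg/s detection threshold
equals the requested duration, and (iii) the peak velocity matches the
request whenever the implied peak/mean-velocity ratio is attainable by the
family (roughly 1.65-2.12 after threshold windowing); otherwise amplitude
and duration are honoured and the peak velocity is relaxed to the nearest
attainable value and flagged.

The drawn latency of a saccade is realised as the instant its speed crosses
the detection threshold, snapped to the sampling grid, so that ground truth
is defined exactly as the measurement pipeline measures it.

Seeding: one integer master seed; the stream for subject ``i`` is
``SeedSequence([seed, i])``, its trial schedule ``SeedSequence([seed, i, 10**6])``
and trial ``j`` uses ``SeedSequence([seed, i, j])``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import betainc, gammaln

from .trace_processing import (
    SACCADE_THRESHOLD_DEG_S,
    GazeTrace,
    _butter_sos,
    _detect_from_speed,
    _differentiate,
)
from scipy.signal import sosfiltfilt

__all__ = [
    "FS_HZ",
    "FIXATION_DURATION_S",
    "TARGET_DURATION_S",
    "GROUPS",
    "EccentricityParams",
    "SubjectProfile",
    "TrialSpec",
    "GroundTruth",
    "SaccadeWaveform",
    "CohortData",
    "UnknownGroupError",
    "default_profiles",
    "generate_trial_schedule",
    "synthesize_saccade_waveform",
    "generate_trial_trace",
    "generate_cohort",
    "study_cohort_profiles",
]

FS_HZ = 240.0
FIXATION_DURATION_S = 0.5
TARGET_DURATION_S = 2.5
#: eye-tracker position sensitivity, deg (optional quantisation step)
QUANTIZATION_DEG = 0.16

GROUPS = ("CTR", "SCA2", "LOCA")

_SCHEDULE_STREAM = 10**6  # spawn key for the per-subject schedule stream
_P_MAX = 40.0  # cap on the velocity-profile exponent


class UnknownGroupError(ValueError):
    pass


@dataclass
class EccentricityParams:
    """Trial-level parameter distributions at one target eccentricity (ms, -)."""

    anti_latency_mean: float
    anti_latency_sd: float
    pro_latency_mean: float
    pro_latency_sd: float
    isi_mean: float
    isi_sd: float
    gain_mean: float
    gain_sd: float

    def __post_init__(self) -> None:
        for name in ("anti_latency_sd", "pro_latency_sd", "isi_sd", "gain_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("anti_latency_mean", "pro_latency_mean"):
            if getattr(self, name) <= 100.0:
                raise ValueError(f"{name} must exceed the 100 ms anticipatory bound")


@dataclass
class SubjectProfile:
    """Generative parameters of one simulated subject."""

    subject_id: str
    group: str
    icars: int
    ecc: dict[int, EccentricityParams]
    directional_error_prob: float
    correction_prob: float
    mainseq_vmax: float  # deg/s
    mainseq_c: float  # deg
    mainseq_k: float  # ms
    mainseq_b: float  # ms/deg
    noise_sd: float = 0.05  # deg, horizontal white position noise
    anticipatory_prob: float = 0.02
    oblique_prob: float = 0.02
    vertical_component_sd: float = 0.05  # deg
    pro_gain_mean: float = 0.95
    pro_gain_sd: float = 0.10
    quantize: bool = False

    def __post_init__(self) -> None:
        for name in (
            "directional_error_prob",
            "correction_prob",
            "anticipatory_prob",
            "oblique_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mainseq_vmax <= 0 or self.mainseq_c <= 0 or self.mainseq_b <= 0:
            raise ValueError("main-sequence parameters vmax, c, b must be positive")
        if self.noise_sd < 0 or self.vertical_component_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0 <= self.icars <= 100:
            raise ValueError("icars must lie in [0, 100]")


@dataclass(frozen=True)
class TrialSpec:
    """Timeline and target of one trial (times in seconds)."""

    trial_id: int
    fixation_onset_s: float
    target_onset_s: float
    target_direction: int  # -1 left, +1 right
    eccentricity_deg: int  # 10 or 18
    target_offset_s: float

    def __post_init__(self) -> None:
        if self.target_direction not in (-1, 1):
            raise ValueError("target_direction must be -1 or +1")
        if self.eccentricity_deg not in (10, 18):
            raise ValueError("eccentricity_deg must be 10 or 18")
        if abs(self.target_onset_s - self.fixation_onset_s - FIXATION_DURATION_S) > 1e-9:
            raise ValueError("target onset must follow fixation onset by 500 ms")
        if abs(self.target_offset_s - self.target_onset_s - TARGET_DURATION_S) > 1e-9:
            raise ValueError("target must be shown for 2,500 ms")


@dataclass
class GroundTruth:
    """Per-trial generative record; the oracle for classification tests."""

    trial_id: int
    label: str  # correct_anti | error_corrected | error_uncorrected | anticipatory | oblique
    target_direction: int
    eccentricity_deg: int
    latency_ms: float
    amplitude_deg: float
    gain: float
    isi_ms: float = math.nan
    corrective_latency_ms: float = math.nan
    corrective_amplitude_deg: float = math.nan
    peak_velocity_deg_s: float = math.nan
    duration_ms: float = math.nan
    vpeak_relaxed: bool = False


@dataclass
class SaccadeWaveform:
    """Sampled position segment of one synthetic saccade."""

    t: np.ndarray  # seconds from envelope start
    position: np.ndarray
    p: float  # profile exponent
    envelope_s: float  # total envelope duration T
    lead_s: float  # sub-threshold time before the 10 deg/s crossing
    peak_velocity_deg_s: float  # realised peak velocity
    relaxed: bool  # True if the requested peak velocity was unattainable


# ---------------------------------------------------------------------------
# sin^{2p} profile machinery


def _profile_mean(p: float) -> float:
    """Mean of sin^{2p} over a half period: Gamma(p+1/2)/(sqrt(pi) Gamma(p+1))."""
    return math.exp(gammaln(p + 0.5) - gammaln(p + 1.0)) / math.sqrt(math.pi)


def _supra_fraction(p: float, r: float) -> float:
    """Fraction of the envelope with v >= r*Vp (0 < r < 1)."""
    return 1.0 - (2.0 / math.pi) * math.asin(r ** (1.0 / (2.0 * p)))


def _amp_ratio(p: float, r: float) -> float:
    """A / (Vp * D_threshold) achieved by exponent p at relative threshold r."""
    return _profile_mean(p) / _supra_fraction(p, r)


def _solve_profile(
    amp: float, dur_s: float, vpeak: float, threshold: float
) -> tuple[float, float, float, bool]:
    """Solve (p, T) for requested (|A|, supra-threshold duration, Vp).

    Returns (p, envelope T, realised Vp, relaxed flag).  When the requested
    peak velocity is unattainable for the sin^{2p} family it is moved to the
    nearest attainable value (amplitude and duration are always honoured).
    """
    if amp <= 0 or dur_s <= 0:
        raise ValueError("amplitude and duration must be positive")

    def amp_at(p: float, v: float) -> float:
        # displacement implied by (p, v) once the supra-threshold time is dur_s
        return v * dur_s * _amp_ratio(p, threshold / v)

    vp = max(vpeak, threshold * 1.5)  # profile needs a genuinely supra-threshold peak
    relaxed = vp != vpeak
    a_shallow, a_peaky = amp_at(1.0, vp), amp_at(_P_MAX, vp)  # a_shallow >= a_peaky
    if a_peaky <= amp <= a_shallow:
        p = brentq(lambda q: amp_at(q, vp) - amp, 1.0, _P_MAX, xtol=1e-12)
    elif amp > a_shallow:
        # requested Vp too slow for the shallowest profile: raise it (p = 1)
        p, relaxed = 1.0, True
        hi = vp
        while amp_at(1.0, hi) < amp:
            hi *= 2.0
        vp = brentq(lambda v: amp_at(1.0, v) - amp, vp, hi, xtol=1e-12)
    else:
        # requested Vp too fast even for the peakiest profile: lower it.
        # amp_at(PMAX, v) is not monotone in v (the envelope blows up as v
        # approaches the threshold), so step down until a bracket is found.
        p, relaxed = _P_MAX, True
        v_hi, a_hi = vp, a_peaky
        found = False
        while v_hi * 0.96 > threshold * 1.05:
            v_lo = v_hi * 0.96
            a_lo = amp_at(_P_MAX, v_lo)
            if a_lo <= amp:
                vp = brentq(lambda v: amp_at(_P_MAX, v) - amp, v_lo, v_hi, xtol=1e-12)
                found = True
                break
            if a_lo > a_hi:  # past the minimum and rising: no solution below
                break
            v_hi, a_hi = v_lo, a_lo
        if not found:
            # (A, D, Vp) jointly unattainable: honour amplitude and peak
            # velocity, accept that the supra-threshold time runs short
            target_m = min(max(amp / (vp * dur_s), _profile_mean(_P_MAX)), 0.5)
            if target_m >= 0.5:
                p = 1.0
            elif target_m <= _profile_mean(_P_MAX):
                p = _P_MAX
            else:
                p = brentq(lambda q: _profile_mean(q) - target_m, 1.0, _P_MAX, xtol=1e-12)
            return p, dur_s, vp, True
    T = dur_s / _supra_fraction(p, threshold / vp)
    return p, T, vp, relaxed


def _cum_profile(u: np.ndarray, p: float) -> np.ndarray:
    """Normalised displacement fraction F(u) of the sin^{2p} profile, u in [0,1]."""
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    theta = np.pi * u
    folded = np.minimum(theta, np.pi - theta)
    half = betainc(p + 0.5, 0.5, np.sin(folded) ** 2) / 2.0
    return np.where(theta <= np.pi / 2.0, half, 1.0 - half)


def synthesize_saccade_waveform(
    amplitude_deg: float,
    duration_ms: float,
    peak_velocity_deg_s: float,
    start_position_deg: float = 0.0,
    fs: float = FS_HZ,
    threshold_deg_s: float = SACCADE_THRESHOLD_DEG_S,
) -> SaccadeWaveform:
    """Sample one saccade's position at ``fs``.

    The returned segment spans the full velocity envelope; its displacement
    equals ``amplitude_deg`` (signed), the time its speed exceeds
    ``threshold_deg_s`` equals ``duration_ms`` within sampling resolution,
    and the peak speed matches ``peak_velocity_deg_s`` where attainable.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    if amplitude_deg == 0.0:
        n = max(2, int(round(duration_ms / 1000.0 * fs)) + 1)
        t = np.arange(n) / fs
        return SaccadeWaveform(
            t=t,
            position=np.full(n, start_position_deg),
            p=1.0,
            envelope_s=duration_ms / 1000.0,
            lead_s=0.0,
            peak_velocity_deg_s=0.0,
            relaxed=False,
        )
    amp = abs(amplitude_deg)
    p, T, vp, relaxed = _solve_profile(
        amp, duration_ms / 1000.0, peak_velocity_deg_s, threshold_deg_s
    )
    lead = (T / math.pi) * math.asin((threshold_deg_s / vp) ** (1.0 / (2.0 * p)))
    n = int(math.ceil(T * fs)) + 1
    t = np.arange(n) / fs
    pos = start_position_deg + amplitude_deg * _cum_profile(t / T, p)
    return SaccadeWaveform(
        t=t,
        position=pos,
        p=p,
        envelope_s=T,
        lead_s=lead,
        peak_velocity_deg_s=vp,
        relaxed=relaxed,
    )


# ---------------------------------------------------------------------------
# group parameter tables (published group values)

_GROUP_TABLES: dict[str, dict] = {
    "CTR": dict(
        icars=0,
        ecc={
            10: EccentricityParams(268.7, 30.8, 184.2, 23.3, 127.5, 44.5, 0.98, 0.31),
            18: EccentricityParams(267.3, 28.3, 204.9, 39.8, 93.2, 45.2, 0.96, 0.14),
        },
        directional_error_prob=0.193,
        correction_prob=0.986,  # mean of 97.2% (10 deg) and 100% (18 deg)
        mainseq_vmax=424.4,
        mainseq_c=7.0,
        mainseq_k=22.5,
        mainseq_b=3.4,
    ),
    "SCA2": dict(
        icars=37,
        ecc={
            10: EccentricityParams(376.3, 83.8, 260.4, 88.9, 252.6, 87.3, 1.08, 0.41),
            18: EccentricityParams(412.3, 133.8, 264.3, 49.1, 219.4, 46.7, 0.83, 0.27),
        },
        directional_error_prob=0.396,
        correction_prob=1.0,
        mainseq_vmax=496.0,
        mainseq_c=34.6,
        mainseq_k=104.8,
        mainseq_b=3.7,
    ),
    "LOCA": dict(
        icars=34,
        ecc={
            10: EccentricityParams(396.3, 109.3, 213.8, 35.6, 240.4, 117.7, 1.22, 0.41),
            18: EccentricityParams(393.1, 61.34, 236.9, 29.9, 223.4, 77.9, 0.94, 0.34),
        },
        directional_error_prob=0.654,
        correction_prob=0.977,  # mean of 98% and 97.4%
        mainseq_vmax=551.4,
        mainseq_c=11.4,
        mainseq_k=41.1,
        mainseq_b=2.0,
    ),
}

#: published per-patient ICARS scores, used to populate simulated cohorts
_ICARS_SCORES = {
    "SCA2": (26, 36, 59, 42, 15, 30, 56, 36, 35, 37, 23, 48),
    "LOCA": (28, 40, 35, 25, 43, 27, 27, 34, 41, 38),
}

#: study design: subjects per group
STUDY_N_SUBJECTS = {"CTR": 34, "SCA2": 12, "LOCA": 10}


def default_profiles(group: str, subject_id: str | None = None) -> SubjectProfile:
    """A group-typical subject profile pre-filled with the published values."""
    if group not in _GROUP_TABLES:
        raise UnknownGroupError(
            f"unknown group {group!r}; expected one of {GROUPS}"
        )
    tab = _GROUP_TABLES[group]
    return SubjectProfile(
        subject_id=subject_id or f"{group}-0",
        group=group,
        icars=tab["icars"],
        ecc={k: replace(v) for k, v in tab["ecc"].items()},
        directional_error_prob=tab["directional_error_prob"],
        correction_prob=tab["correction_prob"],
        mainseq_vmax=tab["mainseq_vmax"],
        mainseq_c=tab["mainseq_c"],
        mainseq_k=tab["mainseq_k"],
        mainseq_b=tab["mainseq_b"],
    )


def study_cohort_profiles(seed: int = 0) -> list[SubjectProfile]:
    """Profiles matching the study design: 34 CTR, 12 SCA2, 10 LOCA.

    Patient ICARS scores follow the published per-patient values; controls
    score 0.  All other parameters are the group defaults.
    """
    profiles: list[SubjectProfile] = []
    for group in GROUPS:
        scores = _ICARS_SCORES.get(group)
        for i in range(STUDY_N_SUBJECTS[group]):
            prof = default_profiles(group, subject_id=f"{group}-{i + 1}")
            if scores is not None:
                prof.icars = scores[i % len(scores)]
            profiles.append(prof)
    return profiles


# ---------------------------------------------------------------------------
# trial schedule


def generate_trial_schedule(
    n_trials: int,
    seed: int | np.random.SeedSequence,
    eccentricities: tuple[int, ...] = (10, 18),
) -> list[TrialSpec]:
    """Randomised trial list: direction and eccentricity uniform and independent."""
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    rng = np.random.default_rng(seed)
    dirs = rng.choice((-1, 1), size=n_trials)
    eccs = rng.choice(eccentricities, size=n_trials)
    return [
        TrialSpec(
            trial_id=i,
            fixation_onset_s=0.0,
            target_onset_s=FIXATION_DURATION_S,
            target_direction=int(dirs[i]),
            eccentricity_deg=int(eccs[i]),
            target_offset_s=FIXATION_DURATION_S + TARGET_DURATION_S,
        )
        for i in range(n_trials)
    ]


# ---------------------------------------------------------------------------
# trial trace generation


def _snap(time_s: float, fs: float) -> float:
    return round(time_s * fs) / fs


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    x = rng.normal(mean, sd)
    return float(min(max(x, lo), hi))


_CAL_PAD = 48  # flat samples around the envelope in the onset-calibration buffer


def _detected_lead_samples(
    wave: SaccadeWaveform, fs: float, threshold: float
) -> int:
    """Samples from envelope start to the onset the measurement chain detects.

    The drawn latency is defined as the onset reported by the standard
    processing pipeline (zero-phase 25 Hz Butterworth, eight-point
    differentiator, 10 deg/s threshold).  Filtering smears the velocity
    pulse, so the detected crossing differs deterministically from the
    analytic one; this measures that shift on a padded copy of the waveform
    so the generator can pre-compensate it.
    """
    n_env = wave.position.size
    buf = np.concatenate(
        [
            np.full(_CAL_PAD, wave.position[0]),
            wave.position,
            np.full(_CAL_PAD, wave.position[-1]),
        ]
    )
    sos = _butter_sos(25.0, 3, fs)
    filt = sosfiltfilt(sos, buf)
    speed = np.abs(_differentiate(filt, fs))
    valid = np.ones(buf.size, dtype=bool)
    valid[:4] = False
    valid[-4:] = False
    events = _detect_from_speed(speed, valid, fs, threshold, 12.0, 4.0)
    if not events:
        return int(round(wave.lead_s * fs))
    peaks = [np.max(speed[e.onset_idx : e.offset_idx]) for e in events]
    main = events[int(np.argmax(peaks))]
    return main.onset_idx - _CAL_PAD


@lru_cache(maxsize=8192)
def _cached_lead_samples(
    amp_rounded: float, k: float, b: float, vmax: float, c: float, fs: float
) -> int:
    """Detected-onset lead for a main-sequence saccade of ~|A| = amp_rounded.

    Amplitude is pre-rounded (0.02 deg) by the caller so repeated draws hit
    the cache; the lead is an integer sample count and varies slowly with
    amplitude, so the rounding is inconsequential.
    """
    dur_ms = k + b * amp_rounded
    vpeak = vmax * (1.0 - math.exp(-amp_rounded / c))
    wave = synthesize_saccade_waveform(amp_rounded, dur_ms, vpeak, 0.0, fs)
    return _detected_lead_samples(wave, fs, SACCADE_THRESHOLD_DEG_S)


def _superpose(x: np.ndarray, t: np.ndarray, t0: float, amplitude: float,
               envelope_s: float, p: float) -> None:
    """Add the saccade displacement profile in place (envelope window only)."""
    i0 = int(np.searchsorted(t, t0))
    i1 = int(np.searchsorted(t, t0 + envelope_s))
    if i0 < i1:
        u = (t[i0:i1] - t0) / envelope_s
        x[i0:i1] += amplitude * _cum_profile(u, p)
    x[i1:] += amplitude


def _add_saccade(
    x: np.ndarray,
    t: np.ndarray,
    crossing_s: float,
    amplitude: float,
    profile: SubjectProfile,
    fs: float,
) -> tuple[float, float, SaccadeWaveform]:
    """Superpose one main-sequence saccade whose *detected* onset falls at
    ``crossing_s``.  Returns (envelope start, analytic down-crossing, waveform)."""
    amp = abs(amplitude)
    dur_ms = profile.mainseq_k + profile.mainseq_b * amp
    vpeak = profile.mainseq_vmax * (1.0 - math.exp(-amp / profile.mainseq_c))
    wave = synthesize_saccade_waveform(amplitude, dur_ms, vpeak, 0.0, fs)
    lead = _cached_lead_samples(
        round(amp, 2), profile.mainseq_k, profile.mainseq_b,
        profile.mainseq_vmax, profile.mainseq_c, fs,
    ) / fs
    t0 = crossing_s - lead
    _superpose(x, t, t0, amplitude, wave.envelope_s, wave.p)
    down = t0 + wave.lead_s + dur_ms / 1000.0
    return t0, down, wave


def generate_trial_trace(
    profile: SubjectProfile,
    spec: TrialSpec,
    seed: int | np.random.SeedSequence,
    fs: float = FS_HZ,
) -> tuple[GazeTrace, GroundTruth]:
    """Simulate one trial and its ground truth.

    Draw order (fixed for reproducibility): anticipatory flag, oblique flag,
    error flag, correction flag, then latencies/gains/intervals as needed.
    With probability ``directional_error_prob`` the trial contains a
    target-directed pro-saccade, followed (with probability
    ``correction_prob``, window permitting) by a mirror-directed corrective
    anti-saccade after the drawn intersaccadic interval; otherwise a single
    mirror-directed anti-saccade.
    """
    rng = np.random.default_rng(seed)
    ep = profile.ecc[spec.eccentricity_deg]
    n = int(round((spec.target_offset_s - spec.fixation_onset_s) * fs)) + 1
    t = spec.fixation_onset_s + np.arange(n) / fs
    x = np.zeros(n)
    y = np.zeros(n)
    d = spec.target_direction
    ecc = float(spec.eccentricity_deg)

    is_anticipatory = rng.random() < profile.anticipatory_prob
    is_oblique = rng.random() < profile.oblique_prob
    is_error = rng.random() < profile.directional_error_prob
    corrects = rng.random() < profile.correction_prob

    trace_end = float(t[-1])
    truth = GroundTruth(
        trial_id=spec.trial_id,
        label="correct_anti",
        target_direction=d,
        eccentricity_deg=spec.eccentricity_deg,
        latency_ms=math.nan,
        amplitude_deg=math.nan,
        gain=math.nan,
    )

    if is_anticipatory:
        latency = float(rng.uniform(0.0, 100.0))
        gain = _truncnorm(rng, ep.gain_mean, ep.gain_sd, 0.15, 2.5)
        amplitude = -d * ecc * gain
        crossing = _snap(spec.target_onset_s + latency / 1000.0, fs)
        # the classification window is open at target onset
        crossing = max(crossing, _snap(spec.target_onset_s, fs) + 1.0 / fs)
        primary_t0, _, wave = _add_saccade(x, t, crossing, amplitude, profile, fs)
        primary_wave = wave
        truth.latency_ms = (crossing - spec.target_onset_s) * 1000.0
        # label from the emitted (snapped) latency, consistent with the
        # classifier's < 100 ms rule
        truth.label = "anticipatory" if truth.latency_ms < 100.0 else "correct_anti"
        truth.amplitude_deg = amplitude
        truth.gain = gain
        truth.peak_velocity_deg_s = wave.peak_velocity_deg_s
        truth.duration_ms = profile.mainseq_k + profile.mainseq_b * abs(amplitude)
        truth.vpeak_relaxed = wave.relaxed
    elif is_error:
        pro_latency = _truncnorm(
            rng, ep.pro_latency_mean, ep.pro_latency_sd, 105.0, 2000.0
        )
        pro_gain = _truncnorm(rng, profile.pro_gain_mean, profile.pro_gain_sd, 0.5, 1.4)
        pro_amp = d * ecc * pro_gain
        crossing = _snap(spec.target_onset_s + pro_latency / 1000.0, fs)
        t0, down, wave = _add_saccade(x, t, crossing, pro_amp, profile, fs)
        primary_t0, primary_wave = t0, wave
        truth.label = "error_uncorrected"
        truth.latency_ms = (crossing - spec.target_onset_s) * 1000.0
        truth.amplitude_deg = pro_amp
        truth.gain = pro_gain
        truth.peak_velocity_deg_s = wave.peak_velocity_deg_s
        truth.duration_ms = profile.mainseq_k + profile.mainseq_b * abs(pro_amp)
        truth.vpeak_relaxed = wave.relaxed
        if corrects:
            isi = _truncnorm(rng, ep.isi_mean, ep.isi_sd, 80.0, 2000.0)
            corr_gain = _truncnorm(rng, ep.gain_mean, ep.gain_sd, 0.15, 2.5)
            # corrective lands near the mirror position
            corr_amp = (-d * ecc * corr_gain) - pro_amp
            corr_cross = _snap(down + isi / 1000.0, fs)
            # keep the two envelopes disjoint
            min_cross = t0 + wave.envelope_s + 2.0 / fs
            if corr_cross < min_cross:
                corr_cross = _snap(min_cross, fs) + 1.0 / fs
            dur2 = profile.mainseq_k + profile.mainseq_b * abs(corr_amp)
            fits_window = corr_cross < spec.target_offset_s
            if fits_window:
                t02, _, wave2 = _add_saccade(x, t, corr_cross, corr_amp, profile, fs)
                fits_window = t02 + wave2.envelope_s <= trace_end - 5.0 / fs
                if not fits_window:
                    # undo: saccade would be clipped by the trace end
                    _superpose(x, t, t02, -corr_amp, wave2.envelope_s, wave2.p)
            if fits_window:
                truth.label = "error_corrected"
                truth.isi_ms = (corr_cross - down) * 1000.0
                truth.corrective_latency_ms = (corr_cross - spec.target_onset_s) * 1000.0
                truth.corrective_amplitude_deg = corr_amp
    else:
        latency = _truncnorm(
            rng, ep.anti_latency_mean, ep.anti_latency_sd, 105.0, 2000.0
        )
        gain = _truncnorm(rng, ep.gain_mean, ep.gain_sd, 0.15, 2.5)
        amplitude = -d * ecc * gain
        crossing = _snap(spec.target_onset_s + latency / 1000.0, fs)
        primary_t0, _, wave = _add_saccade(x, t, crossing, amplitude, profile, fs)
        primary_wave = wave
        truth.latency_ms = (crossing - spec.target_onset_s) * 1000.0
        truth.amplitude_deg = amplitude
        truth.gain = gain
        truth.peak_velocity_deg_s = wave.peak_velocity_deg_s
        truth.duration_ms = profile.mainseq_k + profile.mainseq_b * abs(amplitude)
        truth.vpeak_relaxed = wave.relaxed

    if is_oblique and truth.label in ("correct_anti", "error_uncorrected", "error_corrected"):
        # deliberately oblique primary: add a vertical component > 30 deg
        angle = float(rng.uniform(35.0, 55.0))
        v_sign = 1.0 if rng.random() < 0.5 else -1.0
        vert = v_sign * math.tan(math.radians(angle)) * abs(truth.amplitude_deg)
        # same temporal profile and placement as the primary saccade
        _superpose(y, t, primary_t0, vert, primary_wave.envelope_s, primary_wave.p)
        truth.label = "oblique"

    if profile.noise_sd > 0:
        x += rng.normal(0.0, profile.noise_sd, n)
    if profile.vertical_component_sd > 0:
        y += rng.normal(0.0, profile.vertical_component_sd, n)
    if profile.quantize:
        x = np.round(x / QUANTIZATION_DEG) * QUANTIZATION_DEG
        y = np.round(y / QUANTIZATION_DEG) * QUANTIZATION_DEG

    trace = GazeTrace(t=t, x=x, y=y, subject_id=profile.subject_id, trial_id=spec.trial_id)
    return trace, truth


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortData:
    """A simulated cohort: tables plus per-trial traces and ground truth."""

    subjects: pd.DataFrame  # subject_id, group, icars
    trials: pd.DataFrame  # subject_id + TrialSpec fields
    traces: list[GazeTrace]
    truth: pd.DataFrame  # subject_id + GroundTruth fields
    specs: dict[tuple[str, int], TrialSpec] = field(default_factory=dict)


def trial_seed(seed: int, subject_index: int, trial_id: int) -> np.random.SeedSequence:
    """Deterministic per-trial stream (documented counter scheme)."""
    return np.random.SeedSequence([seed, subject_index, trial_id])


def generate_cohort(
    profiles: list[SubjectProfile],
    n_trials: int,
    seed: int,
    eccentricities: tuple[int, ...] = (10, 18),
) -> CohortData:
    """Simulate ``n_trials`` trials for every profile.

    Per-subject and per-trial substreams are derived deterministically from
    the master seed, so identical inputs give bit-identical datasets and
    subjects can be regenerated independently.
    """
    if not profiles:
        raise ValueError("at least one subject profile is required")
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    subj_rows = []
    trial_rows = []
    truth_rows = []
    traces: list[GazeTrace] = []
    specs: dict[tuple[str, int], TrialSpec] = {}
    for i, prof in enumerate(profiles):
        subj_rows.append(
            dict(subject_id=prof.subject_id, group=prof.group, icars=prof.icars)
        )
        schedule = generate_trial_schedule(
            n_trials,
            np.random.SeedSequence([seed, i, _SCHEDULE_STREAM]),
            eccentricities,
        )
        for spec in schedule:
            trace, truth = generate_trial_trace(
                prof, spec, trial_seed(seed, i, spec.trial_id)
            )
            traces.append(trace)
            specs[(prof.subject_id, spec.trial_id)] = spec
            trial_rows.append(
                dict(
                    subject_id=prof.subject_id,
                    trial_id=spec.trial_id,
                    fixation_onset_s=spec.fixation_onset_s,
                    target_onset_s=spec.target_onset_s,
                    target_direction=spec.target_direction,
                    eccentricity_deg=spec.eccentricity_deg,
                    target_offset_s=spec.target_offset_s,
                )
            )
            row = dict(subject_id=prof.subject_id)
            row.update(vars(truth))
            truth_rows.append(row)
    return CohortData(
        subjects=pd.DataFrame(subj_rows),
        trials=pd.DataFrame(trial_rows),
        traces=traces,
        truth=pd.DataFrame(truth_rows),
        specs=specs,
    )
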