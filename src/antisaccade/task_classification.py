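"""Trial-level interpretation of detected saccades in the anti-saccade task.

A trial's primary saccade is the first detected movement after target onset
with at least ``min_amplitude_deg`` of horizontal displacement.  Primaries
with latency under 100 ms are excluded as anticipatory; primaries whose
displacement vector deviates more than 30 degrees from the horizontal plane
are excluded as oblique.  A primary away from the target is a correct
anti-saccade; toward the target it is a directional error, corrected if a
subsequent opposite-sign saccade starts before target offset.

Direction is judged on the sign of the horizontal displacement alone,
consistent with the obliqueness gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_cohort import TrialSpec
from .trace_processing import SaccadeEvent

__all__ = [
    "ClassifyConfig",
    "ClassifiedTrial",
    "SubjectSummary",
    "ExclusionRateWarning",
    "NotCorrectedError",
    "AllTrialsExcludedError",
    "classify_trial",
    "compute_gain",
    "corrective_latency",
    "subject_summary",
]

#: QC cap on the excluded fraction of a subject's trials
MAX_EXCLUSION_FRACTION = 0.15

LABELS = (
    "correct_anti",
    "error_corrected",
    "error_uncorrected",
    "excluded",
    "no_saccade",
)


class ExclusionRateWarning(UserWarning):
    """More than 15% of a subject's trials failed the inclusion criteria."""


class NotCorrectedError(ValueError):
    pass


class AllTrialsExcludedError(ValueError):
    pass


@dataclass
class ClassifyConfig:
    min_amplitude_deg: float = 1.0
    anticipatory_latency_ms: float = 100.0
    max_oblique_angle_deg: float = 30.0


@dataclass
class ClassifiedTrial:
    trial_id: int
    eccentricity_deg: int
    target_direction: int
    label: str
    exclusion_reason: str = "none"  # anticipatory | oblique | none
    primary: SaccadeEvent | None = None
    corrective: SaccadeEvent | None = None
    gain: float = float("nan")
    intersaccadic_latency_ms: float | None = None
    corrective_latency_ms: float | None = None


def compute_gain(primary: SaccadeEvent, spec: TrialSpec) -> float:
    """Ratio of primary saccade amplitude to target eccentricity."""
    return abs(primary.amplitude_deg) / spec.eccentricity_deg


def classify_trial(
    spec: TrialSpec,
    events: list[SaccadeEvent],
    config: ClassifyConfig | None = None,
) -> ClassifiedTrial:
    """Assign the trial one of the task-level categories.

    Only events whose onset falls strictly inside the target-presentation
    window are considered.  See the module docstring for the decision rules.
    """
    cfg = config or ClassifyConfig()
    out = ClassifiedTrial(
        trial_id=spec.trial_id,
        eccentricity_deg=spec.eccentricity_deg,
        target_direction=spec.target_direction,
        label="no_saccade",
    )
    considered = [
        e
        for e in events
        if spec.target_onset_s < e.onset_s < spec.target_offset_s
        and abs(e.amplitude_deg) >= cfg.min_amplitude_deg
    ]
    if not considered:
        return out
    primary = considered[0]
    out.primary = primary
    out.gain = compute_gain(primary, spec)
    if primary.latency_ms < cfg.anticipatory_latency_ms:
        out.label = "excluded"
        out.exclusion_reason = "anticipatory"
        return out
    if primary.direction_angle_deg > cfg.max_oblique_angle_deg:
        out.label = "excluded"
        out.exclusion_reason = "oblique"
        return out
    toward_target = np.sign(primary.amplitude_deg) == spec.target_direction
    if not toward_target:
        out.label = "correct_anti"
        return out
    out.label = "error_uncorrected"
    for e in considered[1:]:
        if np.sign(e.amplitude_deg) != np.sign(primary.amplitude_deg):
            out.label = "error_corrected"
            out.corrective = e
            out.intersaccadic_latency_ms = (e.onset_s - primary.offset_s) * 1000.0
            out.corrective_latency_ms = (e.onset_s - spec.target_onset_s) * 1000.0
            break
    return out


def corrective_latency(trial: ClassifiedTrial) -> float:
    """Latency of the corrective anti-saccade from target onset, ms.

    By construction it equals the erroneous pro-saccade's latency plus its
    duration plus the intersaccadic latency, up to sampling resolution.
    """
    if trial.label != "error_corrected":
        raise NotCorrectedError(
            f"trial {trial.trial_id} is {trial.label!r}, not error_corrected"
        )
    assert trial.corrective_latency_ms is not None
    return trial.corrective_latency_ms


# ---------------------------------------------------------------------------
# per-subject aggregation


@dataclass
class SubjectSummary:
    """Per-subject analog of the study's group tables.

    ``stats`` is tidy: one row per (eccentricity, saccade_class, parameter)
    with the subject's mean, SD and trial count.  ``error_rate`` is the
    percentage of directional errors among classified responses;
    ``correction_rate`` the percentage of errors that were corrected
    (None when the subject made no errors).
    """

    subject_id: str
    n_trials: int
    n_excluded: int
    exclusion_fraction: float
    n_no_saccade: int
    error_rate: float
    correction_rate: float | None
    qc_exclusion_flag: bool
    stats: pd.DataFrame


_PARAMS = (
    ("duration_ms", lambda e: e.duration_ms),
    ("peak_velocity_deg_s", lambda e: e.peak_velocity_deg_s),
    ("mean_velocity_deg_s", lambda e: e.mean_velocity_deg_s),
    ("latency_ms", lambda e: e.latency_ms),
)


def _collect(rows, ecc, klass, values_by_param):
    for param, vals in values_by_param.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            continue
        rows.append(
            dict(
                eccentricity_deg=ecc,
                saccade_class=klass,
                parameter=param,
                mean=float(np.mean(vals)),
                sd=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                n=int(vals.size),
            )
        )


def subject_summary(
    trials: list[ClassifiedTrial],
    subject_id: str = "",
) -> SubjectSummary:
    """Aggregate one subject's classified trials.

    Raises :class:`AllTrialsExcludedError` when nothing survives the
    exclusion rules, and emits :class:`ExclusionRateWarning` when the
    excluded fraction exceeds the 15% QC cap.
    """
    if not trials:
        raise AllTrialsExcludedError("no trials to summarise")
    n_trials = len(trials)
    counts = {lab: sum(t.label == lab for t in trials) for lab in LABELS}
    n_classified = (
        counts["correct_anti"] + counts["error_corrected"] + counts["error_uncorrected"]
    )
    if n_classified == 0:
        raise AllTrialsExcludedError("all trials excluded or without saccades")
    n_errors = counts["error_corrected"] + counts["error_uncorrected"]
    error_rate = 100.0 * n_errors / n_classified
    correction_rate = (
        100.0 * counts["error_corrected"] / n_errors if n_errors > 0 else None
    )
    exclusion_fraction = counts["excluded"] / n_trials
    qc_flag = exclusion_fraction > MAX_EXCLUSION_FRACTION
    if qc_flag:
        warnings.warn(
            f"subject {subject_id!r}: {exclusion_fraction:.0%} of trials excluded "
            f"(QC cap {MAX_EXCLUSION_FRACTION:.0%})",
            ExclusionRateWarning,
            stacklevel=2,
        )

    rows: list[dict] = []
    eccs = sorted({t.eccentricity_deg for t in trials})
    for ecc in eccs:
        at_ecc = [t for t in trials if t.eccentricity_deg == ecc]
        correct = [t.primary for t in at_ecc if t.label == "correct_anti"]
        errors = [
            t.primary
            for t in at_ecc
            if t.label in ("error_corrected", "error_uncorrected")
        ]
        corrective = [t.corrective for t in at_ecc if t.label == "error_corrected"]
        for klass, evs in (
            ("correct_anti", correct),
            ("erroneous_pro", errors),
            ("corrective_anti", corrective),
        ):
            values = {param: [fn(e) for e in evs] for param, fn in _PARAMS}
            _collect(rows, ecc, klass, values)
        # gain of the primary response saccade
        _collect(
            rows,
            ecc,
            "correct_anti",
            {"gain": [t.gain for t in at_ecc if t.label == "correct_anti"]},
        )
        _collect(
            rows,
            ecc,
            "erroneous_pro",
            {
                "gain": [
                    t.gain
                    for t in at_ecc
                    if t.label in ("error_corrected", "error_uncorrected")
                ]
            },
        )
        _collect(
            rows,
            ecc,
            "corrective_anti",
            {
                "intersaccadic_latency_ms": [
                    t.intersaccadic_latency_ms
                    for t in at_ecc
                    if t.intersaccadic_latency_ms is not None
                ],
                "corrective_latency_ms": [
                    t.corrective_latency_ms
                    for t in at_ecc
                    if t.corrective_latency_ms is not None
                ],
            },
        )
    stats = pd.DataFrame(
        rows,
        columns=["eccentricity_deg", "saccade_class", "parameter", "mean", "sd", "n"],
    )
    return SubjectSummary(
        subject_id=subject_id,
        n_trials=n_trials,
        n_excluded=counts["excluded"],
        exclusion_fraction=exclusion_fraction,
        n_no_saccade=counts["no_saccade"],
        error_rate=error_rate,
        correction_rate=correction_rate,
        qc_exclusion_flag=qc_flag,
        stats=stats,
    )
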