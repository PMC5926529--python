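"""End-to-end orchestration: simulate -> detect -> classify -> fit -> test.

Every constant defaults to the protocol value (240 Hz sampling, 25 Hz
third-order low-pass, 10 deg/s threshold, 100 ms anticipatory bound, 30 deg
obliqueness bound, 500 ms fixation, 2,500 ms target, 40-trial blocks x 2,
95% prediction level, alpha = 0.05).  Given the same configuration snapshot
the pipeline reproduces its outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, io, main_sequence
from .synthetic_cohort import (
    FS_HZ,
    GROUPS,
    CohortData,
    SubjectProfile,
    TrialSpec,
    default_profiles,
    generate_trial_schedule,
    generate_trial_trace,
    study_cohort_profiles,
    trial_seed,
    _SCHEDULE_STREAM,
)
from .task_classification import (
    ClassifiedTrial,
    ClassifyConfig,
    SubjectSummary,
    classify_trial,
    subject_summary,
)
from .trace_processing import GazeTrace, ProcessingConfig, process_many

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "EmptyCohortError",
    "run",
    "simulate_subject_trials",
    "classify_cohort",
    "read_dataset",
    "write_tables",
]

log = logging.getLogger("antisaccade")

STAGES = ("simulate", "detect", "classify", "mainseq", "stats")

#: saccadic parameters entering the group comparisons
COMPARED_PARAMETERS = (
    "duration_ms",
    "peak_velocity_deg_s",
    "mean_velocity_deg_s",
    "gain",
    "latency_ms",
)


class EmptyCohortError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Complete, serialisable configuration of one pipeline run."""

    seed: int = 0
    n_subjects: dict = field(
        default_factory=lambda: {"CTR": 34, "SCA2": 12, "LOCA": 10}
    )
    n_trials: int = 80  # two blocks of 40
    eccentricities: tuple = (10, 18)
    use_study_icars: bool = True
    profile_overrides: dict = field(default_factory=dict)  # group -> {field: value}
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    prediction_level: float = 0.95
    alpha: float = 0.05
    stages: tuple = STAGES
    write_traces: bool = True
    input_dir: str | None = None  # read an existing dataset when not simulating

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in raw.items():
            if key == "processing":
                cfg.processing = ProcessingConfig(**value)
            elif key == "classify":
                cfg.classify = ClassifyConfig(**value)
            elif key in ("eccentricities", "stages"):
                setattr(cfg, key, tuple(value))
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown configuration key {key!r}")
        return cfg

    def snapshot(self) -> dict:
        snap = dataclasses.asdict(self)
        snap["eccentricities"] = list(self.eccentricities)
        snap["stages"] = list(self.stages)
        return snap


@dataclass
class ReportBundle:
    """All output tables plus QC flags and the resolved configuration."""

    tables: dict[str, pd.DataFrame]
    stats_report: dict
    qc: dict
    config_snapshot: dict


def _profiles_from_config(config: PipelineConfig) -> list[SubjectProfile]:
    if config.use_study_icars and config.n_subjects == {
        "CTR": 34,
        "SCA2": 12,
        "LOCA": 10,
    } and not config.profile_overrides:
        return study_cohort_profiles()
    profiles = []
    for group, count in config.n_subjects.items():
        for i in range(count):
            prof = default_profiles(group, subject_id=f"{group}-{i + 1}")
            for name, value in config.profile_overrides.get(group, {}).items():
                if not hasattr(prof, name):
                    raise ValueError(f"unknown profile field {name!r}")
                setattr(prof, name, value)
            profiles.append(prof)
    return profiles


def simulate_subject_trials(
    profile: SubjectProfile,
    n_trials: int,
    seed: int,
    subject_index: int,
    eccentricities: tuple = (10, 18),
) -> tuple[list[TrialSpec], np.ndarray, np.ndarray, np.ndarray, list]:
    """One subject's schedule and stacked traces (t, X, Y) plus ground truth."""
    schedule = generate_trial_schedule(
        n_trials,
        np.random.SeedSequence([seed, subject_index, _SCHEDULE_STREAM]),
        eccentricities,
    )
    t = None
    xs, ys, truths = [], [], []
    for spec in schedule:
        trace, truth = generate_trial_trace(
            profile, spec, trial_seed(seed, subject_index, spec.trial_id)
        )
        if t is None:
            t = trace.t
        xs.append(trace.x)
        ys.append(trace.y)
        truths.append(truth)
    x = np.vstack(xs) if xs else np.empty((0, 0))
    y = np.vstack(ys) if ys else np.empty((0, 0))
    return schedule, t, x, y, truths


def classify_cohort(
    profiles: list[SubjectProfile],
    n_trials: int,
    seed: int,
    eccentricities: tuple = (10, 18),
    processing: ProcessingConfig | None = None,
    classify_cfg: ClassifyConfig | None = None,
    keep_traces: bool = False,
):
    """Simulate and fully process a cohort, subject by subject.

    Returns (subjects_df, trials_df, truth_df, events_df, classified_df,
    classified trials per subject, summaries, traces).  Traces are retained
    only when ``keep_traces`` is set, to bound memory on large cohorts.
    """
    if not profiles:
        raise EmptyCohortError("no subject profiles")
    if n_trials <= 0:
        raise EmptyCohortError("empty cohort: n_trials must be positive")
    proc = processing or ProcessingConfig()
    ccfg = classify_cfg or ClassifyConfig()
    subj_rows, trial_rows, truth_rows, event_rows, class_rows = [], [], [], [], []
    per_subject: dict[str, list[ClassifiedTrial]] = {}
    summaries: list[SubjectSummary] = []
    traces: list[GazeTrace] = []
    for i, prof in enumerate(profiles):
        schedule, t, x, y, truths = simulate_subject_trials(
            prof, n_trials, seed, i, eccentricities
        )
        subj_rows.append(
            dict(subject_id=prof.subject_id, group=prof.group, icars=prof.icars)
        )
        events_by_trial = process_many(t, x, y, schedule[0].target_onset_s, proc)
        classified: list[ClassifiedTrial] = []
        for spec, truth, events in zip(schedule, truths, events_by_trial):
            ct = classify_trial(spec, events, ccfg)
            classified.append(ct)
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
            for e in events:
                event_rows.append(
                    dict(
                        subject_id=prof.subject_id,
                        trial_id=spec.trial_id,
                        onset_s=e.onset_s,
                        offset_s=e.offset_s,
                        amplitude_deg=e.amplitude_deg,
                        angle_deg=e.direction_angle_deg,
                        duration_ms=e.duration_ms,
                        vpeak=e.peak_velocity_deg_s,
                        vmean=e.mean_velocity_deg_s,
                        latency_ms=e.latency_ms,
                    )
                )
            class_rows.append(_classified_row(prof.subject_id, ct))
        per_subject[prof.subject_id] = classified
        summaries.append(subject_summary(classified, subject_id=prof.subject_id))
        if keep_traces:
            for spec, xi, yi in zip(schedule, x, y):
                traces.append(
                    GazeTrace(
                        t=t, x=xi, y=yi,
                        subject_id=prof.subject_id, trial_id=spec.trial_id,
                    )
                )
        log.info(
            "subject %s: %d trials, %d events, %d excluded",
            prof.subject_id,
            len(schedule),
            sum(len(ev) for ev in events_by_trial),
            sum(ct.label == "excluded" for ct in classified),
        )
    return (
        pd.DataFrame(subj_rows),
        pd.DataFrame(trial_rows),
        pd.DataFrame(truth_rows),
        pd.DataFrame(event_rows),
        pd.DataFrame(class_rows),
        per_subject,
        summaries,
        traces,
    )


def _classified_row(subject_id: str, ct: ClassifiedTrial) -> dict:
    p = ct.primary
    return dict(
        subject_id=subject_id,
        trial_id=ct.trial_id,
        eccentricity_deg=ct.eccentricity_deg,
        target_direction=ct.target_direction,
        label=ct.label,
        exclusion_reason=ct.exclusion_reason,
        gain=ct.gain,
        latency_ms=p.latency_ms if p else np.nan,
        amplitude_deg=p.amplitude_deg if p else np.nan,
        duration_ms=p.duration_ms if p else np.nan,
        peak_velocity_deg_s=p.peak_velocity_deg_s if p else np.nan,
        mean_velocity_deg_s=p.mean_velocity_deg_s if p else np.nan,
        intersaccadic_latency_ms=(
            ct.intersaccadic_latency_ms
            if ct.intersaccadic_latency_ms is not None
            else np.nan
        ),
        corrective_latency_ms=(
            ct.corrective_latency_ms
            if ct.corrective_latency_ms is not None
            else np.nan
        ),
    )


# ---------------------------------------------------------------------------
# stage: main sequence


def fit_main_sequences(
    classified: pd.DataFrame,
    subjects: pd.DataFrame,
    level: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-group main-sequence fits on correct anti-saccades.

    Amplitudes are pooled as absolute values across directions and
    eccentricities.  Prediction bounds are computed around the control-group
    fits and every group's fraction of points outside them is reported.
    """
    merged = classified.merge(subjects[["subject_id", "group"]], on="subject_id")
    correct = merged[merged["label"] == "correct_anti"].copy()
    fits = {}
    fit_rows = []
    for group, sub in correct.groupby("group"):
        amps = sub["amplitude_deg"].abs().to_numpy()
        exp_fit = main_sequence.fit_exponential_vpeak(
            amps, sub["peak_velocity_deg_s"].to_numpy()
        )
        lin_fit = main_sequence.fit_linear_duration(
            amps, sub["duration_ms"].to_numpy()
        )
        fits[group] = (exp_fit, lin_fit)
        for f in (exp_fit, lin_fit):
            row = dict(group=group, model=f.model, n=f.n_points,
                       residual_sd=f.residual_sd)
            for name, value in f.params.items():
                row[name] = value
                row[f"{name}_se"] = f.se[name]
            fit_rows.append(row)
    bound_rows = []
    if "CTR" in fits:
        exp_ctr, lin_ctr = fits["CTR"]
        grid = np.linspace(
            min(exp_ctr.amp_min, lin_ctr.amp_min),
            max(exp_ctr.amp_max, lin_ctr.amp_max),
            50,
        )
        for model, f in (("exp_velocity", exp_ctr), ("linear_duration", lin_ctr)):
            pb = main_sequence.prediction_bounds(f, grid, level)
            for a, lo, hi in zip(pb.amplitudes, pb.lower, pb.upper):
                bound_rows.append(
                    dict(model=model, amplitude_deg=float(a),
                         lower=float(lo), upper=float(hi), level=level)
                )
        outside = {}
        for group, sub in correct.groupby("group"):
            amps = sub["amplitude_deg"].abs().to_numpy()
            outside[group] = dict(
                vpeak=main_sequence.outside_bounds_fraction(
                    exp_ctr, amps, sub["peak_velocity_deg_s"].to_numpy(), level
                ),
                duration=main_sequence.outside_bounds_fraction(
                    lin_ctr, amps, sub["duration_ms"].to_numpy(), level
                ),
            )
    else:
        outside = {}
    return pd.DataFrame(fit_rows), pd.DataFrame(bound_rows), outside


# ---------------------------------------------------------------------------
# stage: statistics


def _subject_means(
    classified: pd.DataFrame, subjects: pd.DataFrame
) -> pd.DataFrame:
    merged = classified.merge(subjects[["subject_id", "group"]], on="subject_id")
    correct = merged[merged["label"] == "correct_anti"]
    out = (
        correct.groupby(["group", "subject_id", "eccentricity_deg"])[
            list(COMPARED_PARAMETERS)
        ]
        .agg(["mean", "std"])
        .reset_index()
    )
    out.columns = [
        "_".join(c) if isinstance(c, tuple) and c[1] else (c[0] if isinstance(c, tuple) else c)
        for c in out.columns
    ]
    return out


def run_statistics(
    classified: pd.DataFrame,
    subjects: pd.DataFrame,
    summaries: list[SubjectSummary],
    alpha: float = 0.05,
) -> dict:
    """The full group-comparison battery on a classified cohort."""
    report: dict = {"alpha": alpha}
    means = _subject_means(classified, subjects)
    groups_present = [g for g in GROUPS if g in set(subjects["group"])]

    comparisons = []
    for ecc in sorted(classified["eccentricity_deg"].unique()):
        at_ecc = means[means["eccentricity_deg"] == ecc]
        for param in COMPARED_PARAMETERS:
            col = f"{param}_mean"
            by_group = {
                g: at_ecc.loc[at_ecc["group"] == g, col].dropna().to_numpy()
                for g in groups_present
            }
            if len(by_group) < 2 or any(v.size < 2 for v in by_group.values()):
                continue
            gc = cohort_stats.compare_groups(
                by_group, parameter=param, eccentricity=int(ecc)
            )
            comparisons.append(
                dict(
                    parameter=param,
                    eccentricity=int(ecc),
                    levene_p=gc.levene_p,
                    test_used=gc.test_used,
                    statistic=gc.statistic,
                    p_value=gc.p_value,
                    posthoc=gc.posthoc.to_dict(orient="records"),
                )
            )
    report["group_comparisons"] = comparisons

    merged = classified.merge(subjects[["subject_id", "group"]], on="subject_id")
    correct = merged[merged["label"] == "correct_anti"]
    latencies = {
        g: correct.loc[correct["group"] == g, "latency_ms"].to_numpy()
        for g in groups_present
    }
    if all(v.size >= 2 for v in latencies.values()) and len(latencies) >= 2:
        report["ks_latency"] = {
            f"{g1} vs {g2}": dict(D=d, p=p)
            for (g1, g2), (d, p) in cohort_stats.ks_pairwise(latencies).items()
        }

    counts = merged[merged["label"].isin(
        ["correct_anti", "error_corrected", "error_uncorrected"]
    )]
    if len(groups_present) == 3 and not counts.empty:
        err = {
            g: int(
                counts[
                    (counts["group"] == g)
                    & counts["label"].str.startswith("error")
                ].shape[0]
            )
            for g in groups_present
        }
        tot = {
            g: int(counts[counts["group"] == g].shape[0]) for g in groups_present
        }
        if all(tot[g] > 0 for g in groups_present):
            pr = cohort_stats.proportion_tests(err, tot, alpha=alpha)
            report["error_rate_tests"] = dict(
                proportions={g: float(p) for g, p in zip(pr.groups, pr.proportions)},
                chi2=pr.chi2,
                df=pr.df,
                p_value=pr.p_value,
                marascuilo=pr.marascuilo.to_dict(orient="records"),
            )
        n_err = {
            g: int(counts[(counts["group"] == g) & counts["label"].str.startswith("error")].shape[0])
            for g in groups_present
        }
        n_corrected = {
            g: int(counts[(counts["group"] == g) & (counts["label"] == "error_corrected")].shape[0])
            for g in groups_present
        }
        if all(n_err[g] > 0 for g in groups_present):
            pc = cohort_stats.proportion_tests(n_corrected, n_err, alpha=alpha)
            report["correction_rate_tests"] = dict(
                proportions={g: float(p) for g, p in zip(pc.groups, pc.proportions)},
                chi2=pc.chi2,
                df=pc.df,
                p_value=pc.p_value,
                marascuilo=pc.marascuilo.to_dict(orient="records"),
            )

    # ICARS correlations within each patient group
    icars = dict(zip(subjects["subject_id"], subjects["icars"]))
    spearman = {}
    for group in ("SCA2", "LOCA"):
        sub = means[means["group"] == group]
        if sub["subject_id"].nunique() < 3:
            continue
        tidy = sub.melt(
            id_vars=["subject_id"],
            value_vars=[f"{p}_mean" for p in COMPARED_PARAMETERS],
            var_name="parameter",
            value_name="value",
        )
        tidy["parameter"] = tidy["parameter"].str.removesuffix("_mean")
        res = cohort_stats.spearman_vs_icars(tidy, icars)
        spearman[group] = res.to_dict(orient="records")
    if spearman:
        report["spearman_icars"] = spearman

    # variability: group comparison of per-subject SDs
    sd_rows = []
    group_of = dict(zip(subjects["subject_id"], subjects["group"]))
    for s in summaries:
        sub = s.stats
        sel = sub[(sub["saccade_class"] == "correct_anti") & (sub["n"] >= 2)]
        for _, row in sel.iterrows():
            sd_rows.append(
                dict(
                    subject_id=s.subject_id,
                    group=group_of.get(s.subject_id, ""),
                    eccentricity_deg=row["eccentricity_deg"],
                    parameter=row["parameter"],
                    sd=row["sd"],
                )
            )
    if sd_rows:
        var_tab = cohort_stats.variability_summary(pd.DataFrame(sd_rows))
        report["variability"] = var_tab.to_dict(orient="records")
    return report


def _process_trace_list(
    traces: list[GazeTrace], trials: pd.DataFrame, config: PipelineConfig
):
    """Detect and classify pre-recorded traces against their trial table."""
    from .trace_processing import extract_saccades

    spec_of = {}
    for _, row in trials.iterrows():
        spec_of[(str(row["subject_id"]), int(row["trial_id"]))] = TrialSpec(
            trial_id=int(row["trial_id"]),
            fixation_onset_s=float(row["fixation_onset_s"]),
            target_onset_s=float(row["target_onset_s"]),
            target_direction=int(row["target_direction"]),
            eccentricity_deg=int(row["eccentricity_deg"]),
            target_offset_s=float(row["target_offset_s"]),
        )
    event_rows, class_rows = [], []
    per_subject: dict[str, list[ClassifiedTrial]] = {}
    for tr in traces:
        key = (tr.subject_id, tr.trial_id)
        if key not in spec_of:
            raise io.SchemaError(
                f"trace for {key} has no matching row in trials table"
            )
        spec = spec_of[key]
        events = extract_saccades(tr, spec.target_onset_s, config.processing)
        ct = classify_trial(spec, events, config.classify)
        per_subject.setdefault(tr.subject_id, []).append(ct)
        for e in events:
            event_rows.append(
                dict(
                    subject_id=tr.subject_id, trial_id=tr.trial_id,
                    onset_s=e.onset_s, offset_s=e.offset_s,
                    amplitude_deg=e.amplitude_deg,
                    angle_deg=e.direction_angle_deg,
                    duration_ms=e.duration_ms, vpeak=e.peak_velocity_deg_s,
                    vmean=e.mean_velocity_deg_s, latency_ms=e.latency_ms,
                )
            )
        class_rows.append(_classified_row(tr.subject_id, ct))
    summaries = [
        subject_summary(cts, subject_id=sid) for sid, cts in per_subject.items()
    ]
    return (
        pd.DataFrame(event_rows),
        pd.DataFrame(class_rows),
        per_subject,
        summaries,
    )


# ---------------------------------------------------------------------------
# top-level run


def run(config: PipelineConfig, out_dir: str | Path | None = None) -> ReportBundle:
    """Execute the selected stages in order and collect every output table."""
    stages = tuple(config.stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")

    qc: dict = {"stages_run": list(stages)}
    tables: dict[str, pd.DataFrame] = {}
    truth = None
    if "simulate" in stages:
        profiles = _profiles_from_config(config)
        if not profiles or config.n_trials <= 0:
            raise EmptyCohortError("empty cohort: no subjects or no trials configured")
        (
            subjects,
            trials,
            truth,
            events,
            classified,
            per_subject,
            summaries,
            traces,
        ) = classify_cohort(
            profiles,
            config.n_trials,
            config.seed,
            config.eccentricities,
            config.processing,
            config.classify,
            keep_traces=config.write_traces and out_dir is not None,
        )
    else:
        if config.input_dir is None:
            raise FileNotFoundError(
                "no inputs: enable the simulate stage or set input_dir"
            )
        root = Path(config.input_dir)
        required = {k: root / n for k, n in
                    [("subjects", "subjects.tsv"), ("trials", "trials.tsv"),
                     ("traces", "traces.csv")]}
        missing = [str(p) for p in required.values() if not p.exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        ds = read_dataset(required)
        subjects, trials = ds["subjects"], ds["trials"]
        subjects["subject_id"] = subjects["subject_id"].astype(str)
        trials["subject_id"] = trials["subject_id"].astype(str)
        traces = ds["traces"]
        events, classified, per_subject, summaries = _process_trace_list(
            traces, trials, config
        )
    tables["subjects"] = subjects
    tables["trials"] = trials
    if truth is not None:
        tables["truth"] = truth
    if "detect" in stages:
        tables["events"] = events
    if "classify" in stages:
        tables["classified"] = classified
        summary_rows = []
        for s in summaries:
            summary_rows.append(
                dict(
                    subject_id=s.subject_id,
                    n_trials=s.n_trials,
                    n_excluded=s.n_excluded,
                    exclusion_fraction=s.exclusion_fraction,
                    error_rate=s.error_rate,
                    correction_rate=(
                        s.correction_rate if s.correction_rate is not None else np.nan
                    ),
                )
            )
        tables["subject_summary"] = pd.DataFrame(summary_rows)
        per_param = pd.concat(
            [s.stats.assign(subject_id=s.subject_id) for s in summaries],
            ignore_index=True,
        )
        tables["subject_parameters"] = per_param
        flagged = [s.subject_id for s in summaries if s.qc_exclusion_flag]
        qc["exclusion_cap_violations"] = flagged
    stats_report: dict = {}
    if "mainseq" in stages and "classify" in stages:
        fit_tab, bound_tab, outside = fit_main_sequences(
            classified, subjects, config.prediction_level
        )
        tables["mainseq_fits"] = fit_tab
        tables["mainseq_bounds"] = bound_tab
        stats_report["outside_ctr_bounds"] = outside
    if "stats" in stages and "classify" in stages:
        stats_report.update(
            run_statistics(classified, subjects, summaries, config.alpha)
        )
    else:
        qc["stats_skipped"] = "stats stage not selected"
    bundle = ReportBundle(
        tables=tables,
        stats_report=stats_report,
        qc=qc,
        config_snapshot=config.snapshot(),
    )
    if out_dir is not None:
        write_tables(bundle, out_dir, traces=traces)
    return bundle


def write_tables(
    bundle: ReportBundle, out_dir: str | Path, traces: list[GazeTrace] | None = None
) -> Path:
    """Persist every table, the stats report and the config snapshot."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = {
        "subjects": "subjects.tsv",
        "trials": "trials.tsv",
        "truth": "truth.tsv",
        "events": "events.tsv",
        "classified": "classified.tsv",
        "subject_summary": "subject_summary.tsv",
        "subject_parameters": "subject_parameters.tsv",
        "mainseq_fits": "mainseq_fits.tsv",
        "mainseq_bounds": "mainseq_bounds.tsv",
    }
    for key, df in bundle.tables.items():
        io.write_table(df, out / names.get(key, f"{key}.tsv"))
    if traces:
        io.write_traces(traces, out / "traces.csv")
    (out / "stats_report.json").write_text(
        json.dumps(bundle.stats_report, indent=2, default=float)
    )
    (out / "config_snapshot.json").write_text(
        json.dumps(bundle.config_snapshot, indent=2, default=str)
    )
    (out / "qc.json").write_text(json.dumps(bundle.qc, indent=2, default=str))
    return out


def read_dataset(paths: dict[str, str | Path]) -> dict:
    """Load a previously written dataset (subjects/trials/traces/...)."""
    out = {}
    for kind, path in paths.items():
        if kind == "traces":
            out["traces"] = io.read_traces(path)
        else:
            out[kind] = io.read_table(path, kind=kind if kind in io.REQUIRED_COLUMNS else None)
    return out
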