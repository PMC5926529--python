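# antisaccade

Simulation and analysis of anti-saccade eye-movement experiments, built for
oculomotor studies that compare patient groups (here: spinocerebellar ataxia
type 2, late-onset cerebellar ataxia, and healthy controls) on saccadic
latency, accuracy, directional-error and correction behaviour.

In the anti-saccade task a subject must suppress the reflexive pro-saccade
toward a suddenly appearing peripheral target and instead look at its mirror
position. The package covers the complete quantitative chain of such a
study:

- **Synthetic cohorts with ground truth** (`antisaccade.synthetic_cohort`).
  Because clinical eye-tracking recordings are rarely shareable, the package
  simulates them: 240 Hz two-dimensional gaze position in degrees, a 500 ms
  central fixation followed by a target at ±10/±18 deg shown for 2,500 ms,
  blocks of 40 trials. Group profiles (latency distributions per
  eccentricity, gain, per-trial directional-error and correction
  probabilities, main-sequence dynamics) default to the published group
  values, so simulated cohorts statistically emulate the study populations.
  Saccade waveforms follow a unimodal sin^2p velocity profile solved per
  saccade to honour the requested amplitude, duration and peak velocity.
- **Signal processing** (`antisaccade.trace_processing`). Third-order
  Butterworth low-pass at 25 Hz (zero-phase by default), eye velocity from
  the eight-point central-difference derivative (bandwidth > 70 Hz at
  240 Hz), saccade detection at a 10 deg/s speed threshold.
- **Trial classification** (`antisaccade.task_classification`). Correct
  anti-saccade / erroneous pro-saccade / corrective anti-saccade semantics,
  anticipatory (< 100 ms) and oblique (> 30° off-horizontal) exclusions, a
  15% exclusion QC cap, and per-subject summaries of duration, peak/mean
  velocity, gain, latency, intersaccadic latency, error and correction
  rates.
- **Main sequence** (`antisaccade.main_sequence`). Peak velocity saturates
  with amplitude as `Vpeak = Vmax (1 − e^(−A/c))`; duration grows linearly
  as `Duration = k + b·A`. Both are fitted by least squares with standard
  errors and 95% prediction bounds (exact OLS intervals for the linear
  model, delta-method intervals for the exponential one).
- **Group statistics** (`antisaccade.cohort_stats`). Brown–Forsythe Levene
  gate, Kruskal–Wallis or Welch ANOVA on ranks, Dunn–Bonferroni post hocs,
  pairwise two-sample Kolmogorov–Smirnov tests on latency distributions,
  χ² (2 df) tests of equal proportions with the Marascuilo procedure, and
  Spearman correlations against the ICARS disability score.
- **Pipeline and CLI** (`antisaccade.pipeline`, `antisaccade` command).
  simulate → detect → classify → mainseq → stats with a YAML-configurable,
  fully reproducible run: same config snapshot, bit-identical outputs.

## Worked example

```python
from antisaccade import PipelineConfig, run

cfg = PipelineConfig(
    n_subjects={"CTR": 6, "SCA2": 4, "LOCA": 4}, n_trials=40, seed=1,
    write_traces=False,
)
bundle = run(cfg)

summary = bundle.tables["subject_summary"]
print(summary.groupby(summary["subject_id"].str.split("-").str[0])
      [["error_rate", "exclusion_fraction"]].mean().round(2))

fits = bundle.tables["mainseq_fits"]
print(fits[fits["model"] == "exp_velocity"][["group", "vmax", "vmax_se", "c"]]
      .round(1).to_string(index=False))

err = bundle.stats_report["error_rate_tests"]
print({g: round(100 * p, 1) for g, p in err["proportions"].items()})
```

prints

```
            error_rate  exclusion_fraction
subject_id
CTR              15.35                0.04
LOCA             71.87                0.02
SCA2             38.05                0.07
group  vmax  vmax_se    c
  CTR 453.6      1.4  9.1
 LOCA 619.2      4.7 15.2
 SCA2 471.4      8.9 32.0
{'CTR': 15.2, 'SCA2': 38.3, 'LOCA': 71.8}
```

Reading: with only 4–6 simulated subjects per group the per-group error
rates already order as expected (controls lowest, LOCA highest; the
generative rates are 19.3%, 39.6% and 65.4%), subjects stay under the 15%
exclusion cap, and the fitted exponential main sequences show the
characteristic SCA2 pattern — a large amplitude constant `c`, i.e. peak
velocity that keeps rising instead of saturating within the tested
amplitude range. Pipeline-measured `vmax` runs somewhat above the
generative asymptote because the fit extrapolates from amplitudes below
saturation. `bundle.stats_report` carries the full battery (omnibus tests,
Dunn post hocs, KS tests, Marascuilo ranges).

The same run is available from the shell:

```sh
antisaccade all --seed 1 --out results/run1
```

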