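# fvtp — two-point force-velocity profiling

`fvtp` implements a complete two-point force-velocity (F-V) profiling
pipeline for three standard lower-limb tests:

- **Jump** — countermovement-jump vertical ground-reaction force:
  causal 2nd-order 10 Hz Butterworth filtering, signal-driven phase
  segmentation (onset, lowest center-of-mass position, takeoff),
  impulse–momentum integration, and independent maxima of force,
  velocity and power over the concentric phase.
- **Cycling** — maximal 6-s friction-braked sprint: pedal velocity from
  cadence and crank length (`v = 2πLf`), force as power over velocity,
  peak metrics with cadence smoothing.
- **Isokinetic** — knee-extension force-time curves: zero-phase 5 Hz
  Butterworth filtering, peak force outside the device's
  acceleration/deceleration windows, angular-to-linear velocity
  conversion via the individual lever arm.

Each test performed under two load conditions yields two (force,
velocity) points; the line through them is extrapolated to the force
intercept `F0`, velocity intercept `V0`, slope magnitude `a = F0/V0`,
and maximal power `P0 = F0·V0/4`. The statistics layer provides Pearson
correlations with Fisher-z 95% confidence intervals, dependent-samples t
tests, Shapiro-Wilk screening, magnitude-averaged correlations, and
cross-test comparison tables. A synthetic cohort generator
forward-simulates all three tests from known ground-truth profiles so
the whole chain is verifiable end to end.

## Command line

```bash
# single-trial extraction
fvtp jump    --input trial.csv --mass 67.4 --load 24
fvtp cycling --input sprint.csv --load 6
fvtp iso     --input extension.csv --omega-deg-s 60 --lever-m 0.3

# fit an F-V profile through observations
fvtp fit --point 1500 1.0 --point 500 3.0

# simulate a synthetic cohort and run the full study on it
fvtp simulate --config cohort.yaml --out cohort/ --seed 1
fvtp run --manifest cohort/ --out report/

# statistics from previously extracted values
fvtp stats --profiles report/profiles.csv --standard report/standard_metrics.csv --out stats/
```

Trial CSV schemas: jump/isokinetic `time_s,force_N`; cycling
`time_s,power_W,cadence_rpm`. A manifest directory contains
`subjects.csv` (subject_id, body_mass_kg, lever_arm_m, crank_length_m)
and `trials.csv` (subject_id, test, condition_label, load, standard,
path). `fvtp run` writes `profiles.csv`, `table1.csv`, `figure3.csv`,
`comparisons.csv`, `standard_metrics.csv`, `run.log` and
`effective_config.yaml`; reruns on identical inputs are byte-identical.
Processing defaults (filter cutoffs, onset/flight thresholds, crank
length, smoothing window, exclusion fraction) can be overridden with a
YAML config passed via `--config`.

## Package layout

| Module | Contents |
| --- | --- |
| `fvtp.model` | `FVPoint`, `FVProfile`, `TrialMetrics`, two-point/least-squares fits, line evaluation, power apex |
| `fvtp.jump` | force-trace filtering, phase detection, kinematics, concentric maxima, best-trial selection |
| `fvtp.cycling` | pedal velocity, force from power, sprint metrics |
| `fvtp.isokinetic` | zero-phase filtering, angular-to-linear conversion, peak metrics |
| `fvtp.stats` | correlations, Fisher CIs, paired t, Shapiro-Wilk, comparison tables |
| `fvtp.synthetic` | trial simulators and correlated-cohort generation |
| `fvtp.study` / `fvtp.cli` | batch orchestration, manifest I/O, report bundle, CLI |
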