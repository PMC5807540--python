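# somnotype

Whole-night high-density sleep-EEG analysis: automated sleep-spindle
detection with the integrated-spindle-activity statistic (ISAs),
period-amplitude slow-wave analysis, Welch spectral power, hypnogram-based
sleep-architecture metrics, and topographic two-group permutation statistics
— plus a synthetic staged-EEG generator so the whole chain can be validated
by parameter recovery and statistical calibration without clinical
recordings.

## Who this is for

Sleep researchers comparing NREM oscillatory activity between groups —
e.g. patients vs. controls, or unaffected first-degree relatives vs.
controls in endophenotype studies — from overnight multichannel EEG scored
in 30-s epochs.

## The measures

**Sleep spindles.** The sigma-band (11–16 Hz) signal is rectified and its
sequence of amplitude fluctuations forms the detection time series. Channel
thresholds are relative: an event is triggered when a fluctuation exceeds
8× the channel's mean rectified amplitude and extends to the nearest
fluctuations below 2× the mean on either side; events shorter than 0.25 s
are discarded. Per channel and frequency range (whole 12–16, slow 12–14,
fast 14–16 Hz, classified by each event's zero-crossing frequency):

- *density* — events per minute of analysed NREM (N2/N3) sleep,
- *duration* — mean event duration (s),
- *ISAs* — integrated spindle activity,

```
ISAs = Σ_events [ ∫ |x_σ(t)| dt / duration ] / NREM minutes   (µV/min)
```

an amplitude-weighted spindle burden that combines amplitude, number and
duration in one number.

**Slow waves.** Period-amplitude analysis of the 0.5–4 Hz signal: every
negative half-wave between consecutive zero crossings with duration
0.25–1 s is an event, with no amplitude criterion. Parameters: NPAMP (most
negative point, µV), average down-/up-slope (ADS/AUS = |NPAMP| over the
time from/to the zero crossing, µV/s), maximal down-/up-slope (MDS/MUS =
max |derivative| after a 50-ms moving average, µV/s), and density per NREM
minute.

**Group statistics.** Per-channel topographies are compared with unpaired
t-tests and statistical non-parametric mapping: supra-threshold cluster
permutation tests (cluster-forming threshold = the two-tailed critical t at
α = 0.05 for the design's degrees of freedom, e.g. 2.042 at df = 30),
with family-wise error controlled by the permutation distribution of the
maximum cluster statistic. Spearman rank correlations link metrics to
behavioural scores.

## Worked example

Simulate a small two-group cohort in which group B has a 30 % spindle
amplitude deficit but identical spindle density, then run the pipeline:

```python
import numpy as np
from somnotype import (AnalysisParams, EffectConfig, StageProfile,
                       analyze_cohort, build_adjacency, generate_cohort,
                       make_montage)

montage = make_montage(8)
profile = StageProfile(
    targets={"W": .05, "N1": .08, "N2": .55, "N3": .22, "REM": .10},
    initial_wake_min=2.0, rem_embargo_min=15.0)          # short-night profile
cohort = generate_cohort(16, EffectConfig(spindle_amplitude=0.7),
                         seed=11, montage=montage, total_min=30.0,
                         profile=profile)
report = analyze_cohort(cohort, build_adjacency(montage),
                        AnalysisParams(windows=("wholenight_n2n3",),
                                       n_perm=1024, seed=5))
cl = report.clusters
for metric in ("isas_whole", "spindle_density_whole"):
    rows = cl[cl.metric == metric]
    p = rows.p_corrected.min() if len(rows) else float("nan")
    print(f"{metric:24s} min corrected p = {p}")
```

Output from this exact run:

```
isas_whole               min corrected p = 0.0009765625
spindle_density_whole    min corrected p = nan
```

The ISAs deficit is detected as a significant cluster (corrected
p ≈ 0.001), while spindle density — which the generator kept identical
between groups — produces no supra-threshold cluster at all. This is the
dissociation the pipeline is designed to resolve: an amplitude deficit
without a change in spindle number.

A command-line layer covers the same flow for data on disk:

```bash
somnotype simulate cohort_dir --preset tiny --seed 0
somnotype run cohort_dir/config.yaml
somnotype detect --in eeg.edf --hypnogram hyp.csv --out events.csv
```

## Layout

- `somnotype.io_formats` — EDF read/write (16-bit, µV), hypnogram CSV,
  montage JSON, electrode adjacency (distance or Delaunay).
- `somnotype.synthetic_data` — staged semi-Markov hypnograms, 1/f^α
  multichannel background, spindle bursts and slow-wave pulses with ground
  truth, two-group cohorts with configurable deficits.
- `somnotype.preprocess` — 0.1 Hz high-pass, resampling to 128 Hz, 0.5–40 Hz
  band-pass, average reference; per-channel epoch artifact rejection by
  band power (0.8–4.48 and 20–30 Hz).
- `somnotype.hypnogram_metrics` — architecture metrics (TST, WASO,
  efficiency, latencies, stage percentages), NREM-cycle detection, analysis
  masks.
- `somnotype.spectral` — Welch PSD (five 6-s Hamming segments per 30-s
  epoch, 1/6-Hz bins), band power.
- `somnotype.spindles`, `somnotype.slow_waves` — the detectors and metrics.
- `somnotype.stats_topo` — t statistics, Spearman correlation, SnPM cluster
  permutation test.
- `somnotype.pipeline` / `somnotype.cli` — orchestration, fixtures, reports.

See `docs/methods.md` for the modelling and numerical choices.
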