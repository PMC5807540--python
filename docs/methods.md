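# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic validation does and does not
establish about real recordings.

## Signal conditioning

The chain is: zero-phase high-pass at 0.1 Hz → polyphase resampling to
128 Hz → zero-phase band-pass 0.5–40 Hz → re-reference to the instantaneous
average of all channels. All filters are forward–backward Butterworth of
order 4 (an effective order of 8 with zero phase), so slow-wave slopes are
not distorted by phase lag. The order and cutoffs are arguments throughout.

Artifact screening is per channel and per 30-s epoch: band power in
0.8–4.48 Hz and 20–30 Hz (computed with the same Welch segmentation as the
spectra) is compared against that channel's mean over NREM (N2/N3) epochs,
and the epoch is dropped on that channel when either band exceeds
`factor × mean`. The multiplier is not fixed by the semi-automatic
procedures this screen emulates, so it is exposed (`factor_low`,
`factor_high`, default 4.0). Rejection is deliberately per channel rather
than global: on high-density nets most artifacts are local, and discarding
whole epochs would waste data. Every downstream metric therefore uses each
channel's own retained time as its denominator.

## Spindle detection and ISAs

Detection operates on the rectified 11–16 Hz signal. Because a rectified
narrowband signal touches zero twice per carrier cycle, thresholds are
applied to its sequence of local maxima — the amplitude fluctuations, one
per half cycle — rather than to raw samples; otherwise every event would
fragment at the carrier zero crossings. Thresholds are relative to the
channel's mean rectified amplitude over the analysed window (upper 8×,
lower 2×): an event is any fluctuation above the upper threshold, extended
to the nearest sub-lower fluctuations on both sides. Overlapping detections
merge; events shorter than 0.25 s are discarded; events whose boundary
search crosses the edge of a contiguous analysed run are dropped rather
than truncated. The mean over retained samples is recomputed inside each
analysis window (whole night vs. first cycle), keeping thresholds internal
to the analysed data.

Each event's mean frequency is the zero-crossing rate of the (unrectified)
band-passed signal across the event; events are then binned into whole
[12, 16], slow [12, 14) and fast [14, 16] Hz ranges — the 14-Hz boundary is
assigned to fast, 16 Hz to whole/fast, so slow and fast partition the whole
set. ISAs per channel is Σ over events of (envelope integral / duration) —
i.e. each event's mean rectified amplitude — divided by the channel's
retained NREM minutes. The integral uses the raw envelope, not the
above-threshold excess; both are simple to compute but the raw integral is
the one that makes a rectangular 10-µV event in 10 min yield exactly
1.0 µV/min.

## Slow-wave (period-amplitude) analysis

The slow-wave scan takes every negative half-wave between consecutive zero
crossings of the 0.5–4 Hz signal with duration inside 0.25–1.0 s; there is
no amplitude criterion, since amplitude and slope are the outcome measures.
Zero crossings are located with linear interpolation between samples, which
stabilises the slope denominators at 128 Hz. NPAMP is the minimum between
the crossings; ADS/AUS divide |NPAMP| by the time from the down-crossing to
the peak and peak to up-crossing; MDS/MUS take the maximum of the absolute
first-difference derivative after a centred 50-ms moving average, on the
corresponding segment. At 128 Hz the 50-ms window rounds to 6 samples
(46.9 ms); for a 1-Hz half-sine of 80 µV this predicts a maximal slope of
≈ 501 µV/s (2π·80 × the sinc attenuation of the moving average), and the
implementation lands within ~1.5 % of it — boundary effects of the moving
average account for the difference.

Two practical caveats, both visible in the tests:

- A zero-phase 0.5-Hz high-pass materially attenuates an *isolated*
  half-wave (its spectrum reaches toward DC): −80 µV inserted becomes
  ≈ −56 µV measured, at any filter order. Waves embedded in a 1–2 Hz
  oscillatory context are essentially transparent to the filter. The
  detector therefore accepts `band=None` to skip its own filtering when
  the input has already been conditioned; amplitude-recovery validation
  against inserted pulses uses that path.
- Without an amplitude criterion the count of detected half-waves is
  dominated by background zero crossings (tens per minute), which is the
  expected behaviour of threshold-free period-amplitude analysis. Detected
  density is then *not* guaranteed to be unaffected by an amplitude
  manipulation: large inserted waves absorb background crossings, so group
  amplitude effects can leak into detected density even when the inserted
  wave rate is identical. The spindle-side dissociation (density preserved
  under an amplitude deficit) does not have this complication because
  spindle detection has an explicit threshold.

## Sleep architecture and cycles

TST counts N1/N2/N3/REM between lights off and on; sleep onset is the first
non-wake epoch after lights off; WASO counts wake between onset and the
final awakening (trailing wake is excluded from WASO but stays in the
efficiency denominator); efficiency is 100·TST over the lights interval;
stage percentages are of TST, including the first-cycle percentages (a
switch computes them as percentages of cycle duration instead). Cycles
follow the classical rule — a NREM period of ≥ 15 min followed by a REM
period of ≥ 5 min, the REM minimum waived for the first cycle — with both
thresholds configurable; a night without qualifying REM yields one cycle
flagged incomplete.

## Spectral estimation

Each retained 30-s epoch is split into five non-overlapping 6-s segments,
Hamming-windowed and averaged — giving the 1/6-Hz (~0.16 Hz) grid — with
one-sided density normalisation, so Σ power·Δf recovers the variance (the
suite asserts this within 5 % for sinusoids). No detrending is applied
beyond the conditioning high-pass. Band comparisons default to delta
1–4 Hz and sigma 12–16 Hz, and group tests run on log10 power by default
(`log_power=False` for raw), since band power is approximately log-normal
across subjects.

## Cluster permutation statistics

Per-channel two-sample t-maps (pooled variance) are thresholded at the
two-tailed critical t for the design's df (2.042 for 16 + 16); connected
components over the montage adjacency are formed separately for positive
and negative t, and each cluster's statistic — mass Σ|t| by default, size
optional — is referred to the permutation distribution of the maximum
cluster statistic over random relabelings of group membership, the observed
labeling always included. This controls family-wise error over channels
and both signs simultaneously; every cluster is assigned a corrected p
against the same max-null. The default 65,536 random relabelings stand in
for the full two-sample relabeling space, which is infeasible to enumerate
at n = 16 + 16 (an `exact=True` switch enumerates tiny designs). The
permutation engine computes all relabeled t-maps in one vectorised batch
and finds per-permutation components by iterative minimum-label propagation
on the adjacency matrix; a test cross-checks it against an independent
graph-library component search.

Electrode adjacency defaults to the distance rule with radius 1.3× the
median nearest-neighbour distance — robust on irregular geodesic-like nets
— with Delaunay triangulation of the 2-D projection as the alternative.

## The synthetic generator

The generator reproduces the *statistical structure* the analyses depend
on, not thalamocortical biophysics:

- **Hypnograms**: a semi-Markov chain over {W, N1, N2, N3, REM}; next-stage
  probabilities are proportional to `target share / mean bout length`, so
  realised time-in-stage tracks the configured targets (the suite checks
  ±5 points over 200 nights). REM is embargoed for the first 60 min under
  the overnight defaults; nights start with a wake bout (sleep latency).
  Defaults (W 6 %, N1 8 %, N2 48 %, N3 17 %, REM 21 %) sit in the range of
  healthy middle-aged sleep. Short test nights use a compressed profile —
  2-min latency, 15-min embargo, and bout lengths scaled down to 1–4 min —
  so 20–30-min recordings contain the full stage repertoire and several
  bouts of each stage; with whole-night bout lengths a short recording
  would be one or two bouts and per-subject stage mix would be bimodal,
  inflating between-subject variance in everything stage-dependent.
- **Background**: per-channel 1/f^α noise (α = 1.0 wake/REM, 1.5 NREM)
  spectrally shaped above 0.5 Hz — stage RMS refers to the high-passed
  signal, and sub-0.5-Hz drift would otherwise dominate α > 1 variance —
  with stage-dependent RMS (defaults 7–10 µV) and ~1-s cross-fades at
  stage transitions, because hard splices would inject broadband
  transients that band-pass filters turn into spurious oscillatory bursts.
- **Spindles**: independent per-channel Poisson event streams in N2/N3
  (3.0/min in N2, 1.5/min in N3), 13.5 ± 0.6 Hz carriers under a
  raised-cosine envelope (1.0 ± 0.2 s), envelope peak 40 ± 3 µV scaled by
  a centroparietal Gaussian gain map with floor 0.7. Per-channel
  independence keeps the average reference from cancelling the events (a
  waveform common to all channels is common-mode) and reflects the partly
  local nature of spindles. With the default background the 8× detection
  threshold sits near 9–12 µV, so events clear it comfortably in both
  groups even under a 0.7 amplitude deficit — the regime in which an
  amplitude deficit leaves detected density intact.
- **Slow waves**: isolated negative half-sines (0.3–0.7 s, −85 ± 15 µV,
  frontal gain map), so NPAMP and slopes have analytic ground truth.
- **Artifacts**: broadband bursts (6/h, 3 s, 8× the stage RMS) on single
  channels, the material the artifact screen must catch.
- **Cohorts**: two groups with per-subject seeds spawned deterministically
  from a master seed; group-B deficits are multiplicative on spindle
  envelope amplitude, slow-wave amplitude, and slow-wave slope (the last
  implemented by shortening half-wave durations). A per-subject lognormal
  amplitude factor (SD 0.10) scales background and events together,
  creating realistic between-subject metric variance while leaving
  relative detection thresholds untouched.

What passing the synthetic suite shows: the detectors recover inserted
events and their parameters (sensitivity ≥ 95 % at high SNR, density
within ±10 % at default SNR), the permutation test is calibrated (empirical
FWER 0.05 ± 0.02 on null topographies), and the full pipeline resolves an
amplitude-without-density deficit in cohorts of realistic size. What it
does not show: robustness to real artifact diversity (ocular, cardiac,
electrode pops), to inter-subject spectral variability beyond a global
amplitude factor, to non-sinusoidal spindle morphology, or to staging
error — hypnograms are treated as ground truth throughout.

## Problem sizes in the validation suite

Simulation-based checks run at reduced scale chosen to keep the suite
practical while leaving the statistics meaningful: calibration uses 1000
null datasets × 1024 permutations at full design size (16 + 16 subjects,
64 channels); power/dissociation uses 20 replicate cohorts of 16 + 16
subjects with 8 channels and 30-min nights. The full-scale cohort preset
(`paperlike`: 16 + 16, 64 channels, 6-h nights) is available for longer
runs.

## Degenerate inputs and tie-breaking

Zero-variance t-tests return t = 0 (equal means) or signed infinity;
constant vectors give NaN Spearman rho; channels with no events report
NaN means and enter group maps as zeros on channels excluded for
everyone; empty stage/cycle/artifact intersections raise with the name of
the constraint that emptied them. Envelope plateau maxima contribute their
first sample; exact zeros in the slow-wave signal count as positive, so
every crossing is a strict sign change. EDF physical ranges are symmetric
per channel and round-tripped through the 8-character header field before
quantisation, bounding the write/read error by half a quantisation step.
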