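"""Synthetic staged sleep-EEG with ground truth, for testing and calibration.

The generator emulates the statistical structure the downstream analyses
depend on rather than thalamocortical biophysics:

* hypnograms from a semi-Markov chain over {W, N1, N2, N3, REM} with
  configurable mean bout lengths and stationary stage targets (REM embargoed
  for the first 60 min under defaults);
* per-channel 1/f^α background noise with stage-dependent exponent and RMS;
* sleep spindles inserted in N2/N3 as sinusoid bursts under a raised-cosine
  (Hann) envelope, with a centroparietal topographic gain profile, so the
  analytic envelope of every inserted event is known in closed form;
* slow waves inserted in N2/N3 as isolated negative half-sine deflections
  with a frontal gain profile, so NPAMP and slopes are analytic;
* occasional broadband high-power artifact bursts;
* two-group cohorts with multiplicative group-B deficits in spindle envelope
  amplitude and slow-wave amplitude/slope while densities stay shared — the
  amplitude-not-density effect pattern.

Every inserted event is returned as ground truth, per channel, with its true
onset, offset, peak amplitude and frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import Hypnogram, Montage, Recording

EPOCH_S = 30.0

DEFAULT_STAGE_TARGETS = {"W": 0.06, "N1": 0.08, "N2": 0.48, "N3": 0.17, "REM": 0.21}
DEFAULT_BOUT_MIN = {"W": 1.5, "N1": 2.0, "N2": 10.0, "N3": 8.0, "REM": 12.0}
REM_EMBARGO_MIN = 60.0


@dataclass
class StageProfile:
    """Semi-Markov stage dynamics: stationary targets and mean bout lengths."""

    targets: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STAGE_TARGETS))
    bout_min: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BOUT_MIN))
    initial_wake_min: float = 10.0
    rem_embargo_min: float = REM_EMBARGO_MIN

    def __post_init__(self) -> None:
        if all(v <= 0 for v in self.bout_min.values()):
            raise ValueError("degenerate profile: all dwell times are zero")
        tot = sum(self.targets.values())
        if tot <= 0:
            raise ValueError("degenerate profile: all stage targets are zero")
        self.targets = {k: v / tot for k, v in self.targets.items()}


@dataclass
class SpindleModel:
    density_per_min: dict[str, float] = field(
        default_factory=lambda: {"N2": 3.0, "N3": 1.5})
    center_freq_hz: float = 13.5
    freq_sd_hz: float = 0.6
    duration_mean_s: float = 1.0
    duration_sd_s: float = 0.2
    duration_range_s: tuple[float, float] = (0.5, 1.8)
    envelope_peak_uv: float = 40.0
    envelope_peak_sd_uv: float = 3.0


@dataclass
class SlowWaveModel:
    density_per_min: dict[str, float] = field(
        default_factory=lambda: {"N2": 2.0, "N3": 6.0})
    halfwave_dur_s: tuple[float, float] = (0.3, 0.7)
    npamp_mean_uv: float = -85.0
    npamp_sd_uv: float = 15.0


@dataclass
class ArtifactModel:
    rate_per_h: float = 6.0
    gain: float = 8.0
    duration_s: float = 3.0


@dataclass
class SynthConfig:
    """All knobs of the synthetic recording generator (units in names)."""

    fs: float = 128.0
    background_rms_uv: dict[str, float] = field(default_factory=lambda: {
        "W": 10.0, "N1": 8.0, "N2": 7.0, "N3": 9.0, "REM": 8.0})
    alpha_wake: float = 1.0     # 1/f exponent in W/REM
    alpha_nrem: float = 1.5     # 1/f exponent in N1/N2/N3
    spindles: SpindleModel = field(default_factory=SpindleModel)
    slow_waves: SlowWaveModel = field(default_factory=SlowWaveModel)
    artifacts: ArtifactModel = field(default_factory=ArtifactModel)
    spindle_gain_floor: float = 0.7
    sw_gain_floor: float = 0.7
    gain_sigma: float = 0.8     # width of the topographic Gaussian bump (radians)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for d in (self.spindles.density_per_min, self.slow_waves.density_per_min):
            if any(v < 0 for v in d.values()):
                raise ValueError("densities must be non-negative")
        if not self.spindles.duration_mean_s > 0:
            raise ValueError("durations must be positive")


@dataclass
class TrueEvent:
    channel: str
    kind: str           # "spindle" | "slow_wave" | "artifact"
    start: float
    end: float
    amplitude: float    # envelope peak (spindle, µV) or NPAMP (slow wave)
    frequency: float    # Hz (NaN for slow waves/artifacts)

    @property
    def duration(self) -> float:
        return self.end - self.start

    def features(self) -> dict[str, float]:
        return {"amplitude": self.amplitude, "frequency": self.frequency}


@dataclass
class GroundTruth:
    events: list[TrueEvent]

    def by_kind(self, kind: str) -> list[TrueEvent]:
        return [e for e in self.events if e.kind == kind]

    def on_channel(self, channel: str, kind: str | None = None) -> list[TrueEvent]:
        return [e for e in self.events
                if e.channel == channel and (kind is None or e.kind == kind)]

    def density_per_min(self, channel: str, kind: str, minutes: float) -> float:
        return len(self.on_channel(channel, kind)) / minutes


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

def make_montage(n_channels: int = 64) -> Montage:
    """Geodesic-like layout: Fibonacci lattice on the upper hemisphere.

    Axes: +x right, +y anterior, +z up (unit sphere).  Labels E1..En.
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    i = np.arange(n_channels)
    # z from just above equator to the vertex
    z = 0.05 + 0.95 * (i + 0.5) / n_channels
    r = np.sqrt(1.0 - z ** 2)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = i * golden
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    labels = [f"E{k + 1}" for k in i]
    return Montage(labels=labels, positions=pos)


def _gain_map(montage: Montage, center_xyz: np.ndarray, floor: float,
              sigma: float) -> np.ndarray:
    """Gaussian bump on great-circle distance from ``center_xyz``; in [floor, 1]."""
    c = np.asarray(center_xyz, float)
    c = c / np.linalg.norm(c)
    p = montage.positions / np.linalg.norm(montage.positions, axis=1, keepdims=True)
    ang = np.arccos(np.clip(p @ c, -1.0, 1.0))
    return floor + (1.0 - floor) * np.exp(-0.5 * (ang / sigma) ** 2)


CENTROPARIETAL = np.array([0.0, -0.25, 0.97])
FRONTAL = np.array([0.0, 0.8, 0.6])


def spindle_gains(montage: Montage, config: SynthConfig) -> np.ndarray:
    return _gain_map(montage, CENTROPARIETAL, config.spindle_gain_floor,
                     config.gain_sigma)


def slow_wave_gains(montage: Montage, config: SynthConfig) -> np.ndarray:
    return _gain_map(montage, FRONTAL, config.sw_gain_floor, config.gain_sigma)


# ---------------------------------------------------------------------------
# Hypnogram
# ---------------------------------------------------------------------------

def generate_hypnogram(total_min: float, seed: int | np.random.Generator,
                       profile: StageProfile | None = None) -> Hypnogram:
    """Semi-Markov staged hypnogram on 30-s epochs.

    Bout lengths are geometric with the profile's mean (in epochs); the next
    stage is drawn with probability proportional to ``target/bout`` so the
    chain's stationary time-in-stage fractions approximate the targets.  REM
    is embargoed (redirected to N2) before ``rem_embargo_min``; the night
    starts with a wake bout of mean ``initial_wake_min``.
    """
    if total_min < 5:
        raise ValueError("total_min must be at least 5")
    profile = profile or StageProfile()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_epochs = int(round(total_min * 60.0 / EPOCH_S))
    epm = 60.0 / EPOCH_S  # epochs per minute

    stages_all = [s for s, t in profile.targets.items()
                  if t > 0 and profile.bout_min.get(s, 0) > 0]
    entry_w = np.array([profile.targets[s] / profile.bout_min[s] for s in stages_all])

    out: list[str] = []

    def draw_bout(stage: str) -> int:
        mean_ep = max(profile.bout_min[stage] * epm, 1.0)
        return int(rng.geometric(1.0 / mean_ep))

    # initial wake (sleep latency)
    if profile.initial_wake_min > 0 and "W" in stages_all:
        k = max(1, int(rng.geometric(1.0 / max(profile.initial_wake_min * epm, 1.0))))
        out.extend(["W"] * k)

    current = None
    while len(out) < n_epochs:
        w = entry_w.copy()
        if current is not None and len(stages_all) > 1:
            w[stages_all.index(current)] = 0.0
        nxt = stages_all[rng.choice(len(stages_all), p=w / w.sum())]
        if nxt == "REM" and len(out) / epm < profile.rem_embargo_min:
            nxt = "N2" if "N2" in stages_all else nxt
        out.extend([nxt] * draw_bout(nxt))
        current = nxt
    stages = out[:n_epochs]
    return Hypnogram(stages=stages, lights_off=0.0,
                     lights_on=n_epochs * EPOCH_S)


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

def _one_over_f(n: int, alpha: float, rng: np.random.Generator,
                fs: float = 128.0, f_lo: float = 0.5) -> np.ndarray:
    """Unit-RMS 1/f^alpha noise by spectral shaping of white noise.

    The power law is applied above ``f_lo`` (Hz) with the spectrum zeroed
    below it: EEG background RMS conventionally refers to the high-passed
    signal, and without the cutoff almost all α > 1 variance would sit in
    sub-0.5-Hz drift that the conditioning chain removes anyway.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    nz = f >= f_lo
    shape[nz] = f[nz] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _hann_burst(t: np.ndarray, t0: float, dur: float, freq: float,
                peak: float, phase: float) -> np.ndarray:
    """Sinusoid under a raised-cosine envelope peaking at ``peak`` µV."""
    rel = (t - t0) / dur
    env = np.where((rel >= 0) & (rel <= 1),
                   0.5 * (1.0 - np.cos(2.0 * np.pi * rel)), 0.0)
    return peak * env * np.sin(2.0 * np.pi * freq * (t - t0) + phase)


def _neg_halfwave(t: np.ndarray, t0: float, dur: float, npamp: float) -> np.ndarray:
    """Isolated negative half-sine of duration ``dur`` and minimum ``npamp``."""
    rel = (t - t0) / dur
    return np.where((rel >= 0) & (rel <= 1),
                    npamp * np.sin(np.pi * np.clip(rel, 0, 1)), 0.0)


def generate_recording(hyp: Hypnogram, montage: Montage, config: SynthConfig,
                       seed: int | np.random.Generator,
                       spindle_amplitude_scale: float = 1.0,
                       sw_amplitude_scale: float = 1.0,
                       sw_slope_scale: float = 1.0,
                       ) -> tuple[Recording, GroundTruth]:
    """Render a staged multichannel recording with known inserted events.

    Spindles and slow waves are generated as global events (one time course,
    per-channel topographic gain) placed in N2/N3 epochs; the ground truth
    lists the event on every channel with its channel-specific amplitude.
    The three ``*_scale`` arguments implement group-level deficits: spindle
    envelope amplitude, slow-wave amplitude, and slow-wave slope (realised by
    dividing half-wave durations, which steepens or flattens slopes at fixed
    amplitude).
    """
    if spindle_amplitude_scale <= 0 or sw_amplitude_scale <= 0 or sw_slope_scale <= 0:
        raise ValueError("effect multipliers must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = config.fs
    n_ch = montage.n_channels
    spe = int(round(EPOCH_S * fs))
    n_samples = len(hyp) * spe
    stages = hyp.as_array()

    # --- background: wake-like and NREM-like 1/f beds, cross-faded at stage
    # transitions (hard splices would inject broadband transients that the
    # band-pass filters turn into spurious oscillatory bursts)
    is_nrem = np.array([st in ("N1", "N2", "N3") for st in stages], float)
    rms_ep = np.array([config.background_rms_uv.get(st, 8.0) for st in stages])
    w = np.repeat(is_nrem, spe)
    r = np.repeat(rms_ep, spe)
    ramp = np.hanning(max(int(fs), 3))
    ramp /= ramp.sum()
    if len(stages) > 1:
        w = np.convolve(w, ramp, mode="same")
        r = np.convolve(r, ramp, mode="same")
    data = np.empty((n_ch, n_samples))
    for ci in range(n_ch):
        wake_bed = _one_over_f(n_samples, config.alpha_wake, rng, fs)
        nrem_bed = _one_over_f(n_samples, config.alpha_nrem, rng, fs)
        data[ci] = (w * nrem_bed + (1.0 - w) * wake_bed) * r

    t = np.arange(n_samples) / fs
    sp_gain = spindle_gains(montage, config)
    sw_gain = slow_wave_gains(montage, config)
    truth: list[TrueEvent] = []

    # --- spindles: independent per-channel event streams (spindles are in
    # part local events; independence also keeps the average reference from
    # cancelling them, since a waveform common to all channels would be
    # common-mode)
    spm = config.spindles
    for ci, lb in enumerate(montage.labels):
        for ei, st in enumerate(stages):
            dens = spm.density_per_min.get(st, 0.0)
            if dens <= 0:
                continue
            for _ in range(rng.poisson(dens * EPOCH_S / 60.0)):
                dur = float(np.clip(
                    rng.normal(spm.duration_mean_s, spm.duration_sd_s),
                    *spm.duration_range_s))
                t0 = ei * EPOCH_S + rng.uniform(0, EPOCH_S - dur)
                freq = float(np.clip(rng.normal(spm.center_freq_hz, spm.freq_sd_hz),
                                     11.5, 15.5))
                peak = max(rng.normal(spm.envelope_peak_uv,
                                      spm.envelope_peak_sd_uv), 5.0)
                peak *= spindle_amplitude_scale * sp_gain[ci]
                phase = rng.uniform(0, 2 * np.pi)
                lo = int(t0 * fs)
                hi = min(int((t0 + dur) * fs) + 2, n_samples)
                data[ci, lo:hi] += _hann_burst(t[lo:hi], t0, dur, freq, peak, phase)
                truth.append(TrueEvent(lb, "spindle", t0, t0 + dur, peak, freq))

    # --- slow waves: likewise per channel
    swm = config.slow_waves
    for ci, lb in enumerate(montage.labels):
        for ei, st in enumerate(stages):
            dens = swm.density_per_min.get(st, 0.0)
            if dens <= 0:
                continue
            for _ in range(rng.poisson(dens * EPOCH_S / 60.0)):
                dur = rng.uniform(*swm.halfwave_dur_s) / sw_slope_scale
                t0 = ei * EPOCH_S + rng.uniform(0, EPOCH_S - dur)
                npamp = min(rng.normal(swm.npamp_mean_uv, swm.npamp_sd_uv), -20.0)
                npamp *= sw_amplitude_scale * sw_gain[ci]
                lo = int(t0 * fs)
                hi = min(int((t0 + dur) * fs) + 2, n_samples)
                data[ci, lo:hi] += _neg_halfwave(t[lo:hi], t0, dur, npamp)
                truth.append(TrueEvent(lb, "slow_wave", t0, t0 + dur,
                                       npamp, float("nan")))

    # --- artifacts: broadband bursts on a random subset of channels/times
    am = config.artifacts
    n_art = rng.poisson(am.rate_per_h * len(hyp) * EPOCH_S / 3600.0)
    for _ in range(n_art):
        t0 = rng.uniform(0, max(n_samples / fs - am.duration_s, 1.0))
        lo = int(t0 * fs)
        hi = min(int((t0 + am.duration_s) * fs), n_samples)
        ci = int(rng.integers(n_ch))
        st = stages[min(lo // spe, len(stages) - 1)]
        rms = config.background_rms_uv.get(st, 8.0)
        data[ci, lo:hi] += am.gain * rms * rng.standard_normal(hi - lo)
        truth.append(TrueEvent(montage.labels[ci], "artifact",
                               t0, t0 + am.duration_s, am.gain * rms, float("nan")))

    rec = Recording(data=data, fs=fs, labels=list(montage.labels),
                    reference="average")
    return rec, GroundTruth(events=truth)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class EffectConfig:
    """Multiplicative group-B deficits (1.0 = null everywhere)."""

    spindle_amplitude: float = 1.0
    sw_amplitude: float = 1.0
    sw_slope: float = 1.0
    subject_scale_sd: float = 0.10   # between-subject overall amplitude factor

    def __post_init__(self) -> None:
        if min(self.spindle_amplitude, self.sw_amplitude, self.sw_slope) <= 0:
            raise ValueError("effect multipliers must be positive")


@dataclass
class Subject:
    subject_id: str
    group: str
    recording: Recording
    hypnogram: Hypnogram
    truth: GroundTruth


def generate_cohort(n_per_group: int, effect: EffectConfig,
                    seed: int, montage: Montage | None = None,
                    config: SynthConfig | None = None,
                    total_min: float = 360.0,
                    profile: StageProfile | None = None) -> list[Subject]:
    """Two labelled groups of synthetic subjects, deterministic per seed.

    Group "A" is unaffected; group "B" carries the configured multiplicative
    deficits.  A per-subject overall amplitude factor (lognormal-ish, SD
    ``effect.subject_scale_sd``) scales background and events together, so
    detection thresholds — relative to each channel's mean amplitude — are
    unaffected while between-subject metric variance is realistic.
    Per-subject seeds are spawned deterministically from the master seed.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    montage = montage or make_montage(64)
    config = config or SynthConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_group)
    subjects: list[Subject] = []
    for gi, group in enumerate(("A", "B")):
        for si in range(n_per_group):
            rng = np.random.default_rng(children[gi * n_per_group + si])
            hyp = generate_hypnogram(total_min, rng, profile)
            subj_scale = float(np.exp(rng.normal(0.0, effect.subject_scale_sd)))
            cfg = replace(
                config,
                background_rms_uv={k: v * subj_scale
                                   for k, v in config.background_rms_uv.items()},
                spindles=replace(config.spindles,
                                 envelope_peak_uv=config.spindles.envelope_peak_uv * subj_scale,
                                 envelope_peak_sd_uv=config.spindles.envelope_peak_sd_uv * subj_scale),
                slow_waves=replace(config.slow_waves,
                                   npamp_mean_uv=config.slow_waves.npamp_mean_uv * subj_scale,
                                   npamp_sd_uv=config.slow_waves.npamp_sd_uv * subj_scale),
            )
            if group == "B":
                rec, truth = generate_recording(
                    hyp, montage, cfg, rng,
                    spindle_amplitude_scale=effect.spindle_amplitude,
                    sw_amplitude_scale=effect.sw_amplitude,
                    sw_slope_scale=effect.sw_slope)
            else:
                rec, truth = generate_recording(hyp, montage, cfg, rng)
            subjects.append(Subject(
                subject_id=f"{group}{si + 1:02d}", group=group,
                recording=rec, hypnogram=hyp, truth=truth))
    return subjects
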