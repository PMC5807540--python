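"""Period-amplitude slow-wave detection on negative half-waves.

The signal is band-pass filtered 0.5–4 Hz and scanned for consecutive zero
crossings (located with linear interpolation for sub-sample timing).  Every
negative half-wave — a negative-going crossing followed by a positive-going
crossing — whose duration falls in a configurable window (default 0.25–1 s)
becomes an event, with no amplitude criterion: amplitude and slope are the
outcome measures, not a filter.

Per event: NPAMP, the most negative point between the crossings (µV, ≤ 0);
ADS/AUS, |NPAMP| divided by the time from the negative-going crossing to the
peak / peak to the positive-going crossing (average down-/up-slope, µV/s);
MDS/MUS, the maximum absolute first-difference derivative after a 50-ms
centred moving average, on the down- and up-going segment respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io_formats import Recording
from .hypnogram_metrics import EpochSelection

SW_BAND = (0.5, 4.0)
HALFWAVE_DUR = (0.25, 1.0)
DERIV_SMOOTH_S = 0.05

SW_FEATURES = ("npamp", "ads", "mds", "aus", "mus")


@dataclass
class SlowWaveEvent:
    channel: str
    t_down: float   # s, negative-going zero crossing
    t_peak: float   # s, most negative point
    t_up: float     # s, positive-going zero crossing
    npamp: float    # µV, <= 0
    ads: float      # µV/s
    aus: float      # µV/s
    mds: float      # µV/s
    mus: float      # µV/s

    @property
    def start(self) -> float:
        return self.t_down

    @property
    def end(self) -> float:
        return self.t_up

    @property
    def duration(self) -> float:
        return self.t_up - self.t_down

    def features(self) -> dict[str, float]:
        return {"npamp": self.npamp, "ads": self.ads, "mds": self.mds,
                "aus": self.aus, "mus": self.mus}


@dataclass
class SlowWaveMetrics:
    labels: list[str]
    density: np.ndarray
    means: dict[str, np.ndarray]  # feature -> per-channel mean (NaN if none)

    def to_frame(self) -> pd.DataFrame:
        d = {"channel": self.labels, "density": self.density}
        for k in SW_FEATURES:
            d[k] = self.means[k]
        return pd.DataFrame(d)


def sw_filter(rec: Recording, band: tuple[float, float] | None = SW_BAND,
              order: int = 4) -> np.ndarray:
    """Zero-phase slow-wave band-pass; ``band=None`` skips filtering.

    Skipping is appropriate when the conditioning chain has already
    high-passed the data: a zero-phase 0.5-Hz high-pass substantially
    attenuates an isolated half-wave (its spectrum extends toward DC), which
    matters when validating amplitude measurements against inserted pulses.
    """
    if band is None:
        return np.asarray(rec.data, float)
    sos = signal.butter(order, band, btype="bandpass", fs=rec.fs, output="sos")
    return signal.sosfiltfilt(sos, rec.data, axis=1)


def _zero_crossings(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sub-sample negative-going and positive-going zero crossing times.

    Crossing positions are in fractional sample units, interpolated linearly
    between the bracketing samples.  Exact zeros are treated as positive so
    every crossing is a strict sign change.
    """
    s = x < 0
    idx = np.nonzero(s[1:] != s[:-1])[0]
    if len(idx) == 0:
        return np.empty(0), np.empty(0)
    frac = idx + x[idx] / (x[idx] - x[idx + 1])
    down = frac[s[idx + 1]]       # + -> −
    up = frac[~s[idx + 1]]        # − -> +
    return down, up


def smoothed_derivative(x: np.ndarray, fs: float) -> np.ndarray:
    """|first difference × fs| after a centred 50-ms moving average.

    Element i covers the step x[i] -> x[i+1]; length len(x) − 1.
    """
    d = np.diff(x) * fs
    w = max(1, int(round(DERIV_SMOOTH_S * fs)))
    if w > 1:
        kernel = np.ones(w) / w
        d = np.convolve(d, kernel, mode="same")
    return np.abs(d)


def detect_halfwaves_1d(x: np.ndarray, fs: float, offset_samples: int = 0,
                        halfwave_dur: tuple[float, float] = HALFWAVE_DUR,
                        channel: str = "") -> list[SlowWaveEvent]:
    """Scan one contiguous filtered segment for negative half-waves."""
    lo_s, hi_s = halfwave_dur
    down, up = _zero_crossings(x)
    if len(down) == 0 or len(up) == 0:
        return []
    dsm = smoothed_derivative(x, fs)
    events: list[SlowWaveEvent] = []
    ui = 0
    for d in down:
        while ui < len(up) and up[ui] <= d:
            ui += 1
        if ui >= len(up):
            break
        u = up[ui]
        dur = (u - d) / fs
        if not lo_s <= dur <= hi_s:
            continue
        a = int(np.ceil(d))
        b = int(np.floor(u))
        if b <= a:
            continue
        seg = x[a:b + 1]
        pk = a + int(np.argmin(seg))
        npamp = float(x[pk])
        if npamp >= 0:
            continue
        t_down = (offset_samples + d) / fs
        t_up = (offset_samples + u) / fs
        t_peak = (offset_samples + pk) / fs
        dt_down = max(t_peak - t_down, 1.0 / fs)
        dt_up = max(t_up - t_peak, 1.0 / fs)
        events.append(SlowWaveEvent(
            channel=channel, t_down=t_down, t_peak=t_peak, t_up=t_up,
            npamp=npamp,
            ads=abs(npamp) / dt_down,
            aus=abs(npamp) / dt_up,
            mds=float(dsm[a:pk].max()) if pk > a else float("nan"),
            mus=float(dsm[pk:b].max()) if b > pk else float("nan"),
        ))
    return events


def detect_slow_waves(rec: Recording, selection: EpochSelection,
                      band: tuple[float, float] | None = SW_BAND,
                      halfwave_dur: tuple[float, float] = HALFWAVE_DUR,
                      order: int = 4) -> list[SlowWaveEvent]:
    """Detect negative half-waves over the selected NREM samples.

    Filtering is applied to the whole continuous recording; half-waves are
    accepted only when fully inside a contiguous run of retained samples, so
    events never straddle rejected epochs or stage boundaries.
    """
    filt = sw_filter(rec, band, order)
    return detect_slow_waves_filtered(filt, rec.labels, rec.fs, selection,
                                      halfwave_dur)


def detect_slow_waves_filtered(filt: np.ndarray, labels: list[str], fs: float,
                               selection: EpochSelection,
                               halfwave_dur: tuple[float, float] = HALFWAVE_DUR
                               ) -> list[SlowWaveEvent]:
    """Half-wave scan on an already band-passed multichannel array."""
    if not selection.mask.any():
        raise ValueError("empty selection")
    smask = selection.sample_mask(fs, filt.shape[1])
    from .spindles import _runs

    events: list[SlowWaveEvent] = []
    for ci, label in enumerate(labels):
        for lo, hi in _runs(smask[ci]):
            events.extend(detect_halfwaves_1d(
                filt[ci, lo:hi], fs, offset_samples=lo,
                halfwave_dur=halfwave_dur, channel=label))
    return events


def slow_wave_metrics(events: list[SlowWaveEvent],
                      selection: EpochSelection,
                      labels: list[str]) -> SlowWaveMetrics:
    """Per-channel density and mean NPAMP/ADS/MDS/AUS/MUS."""
    minutes = selection.minutes()
    if np.all(minutes <= 0):
        raise ValueError("zero retained NREM time")
    by_ch: dict[str, list[SlowWaveEvent]] = {lb: [] for lb in labels}
    for ev in events:
        if ev.channel in by_ch:
            by_ch[ev.channel].append(ev)

    n = len(labels)
    density = np.zeros(n)
    means = {k: np.full(n, np.nan) for k in SW_FEATURES}
    for i, lb in enumerate(labels):
        evs = by_ch[lb]
        if minutes[i] <= 0:
            density[i] = np.nan
            continue
        density[i] = len(evs) / minutes[i]
        if evs:
            for k in SW_FEATURES:
                means[k][i] = float(np.mean([getattr(ev, k) for ev in evs]))
    return SlowWaveMetrics(labels=list(labels), density=density, means=means)
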