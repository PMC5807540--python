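"""Amplitude-threshold sleep-spindle detection and the ISAs statistic.

The signal is band-pass filtered in the sigma range (11–16 Hz) and rectified;
the rectified amplitude is the detection time series.  Thresholds are
relative to each channel's mean rectified amplitude over the analysed NREM
samples: an event is triggered whenever the amplitude exceeds eight times the
mean, and extends to the nearest points on either side of that maximum where
the amplitude drops below twice the mean.  Events shorter than 0.25 s are
discarded and overlapping detections are merged.

Reported per-channel metrics are density (events per minute of analysed NREM
sleep), mean duration, and integrated spindle activity (ISAs): for each
spindle the time-integral of the rectified amplitude divided by its duration
(i.e. its mean rectified amplitude), summed over spindles and divided by the
analysed NREM minutes — an amplitude-weighted spindle burden in µV/min.
Spindles are classed as slow ([12, 14) Hz) or fast ([14, 16] Hz) by their
mean zero-crossing frequency; detection always runs on the full 11–16 band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io_formats import Recording
from .hypnogram_metrics import EpochSelection

SIGMA_BAND = (11.0, 16.0)
WHOLE_RANGE = (12.0, 16.0)
SLOW_RANGE = (12.0, 14.0)
FAST_RANGE = (14.0, 16.0)


@dataclass
class DetectionParams:
    band: tuple[float, float] = SIGMA_BAND
    lower_factor: float = 2.0
    upper_factor: float = 8.0
    min_duration_s: float = 0.25
    filter_order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.lower_factor < self.upper_factor:
            raise ValueError("require 0 < lower_factor < upper_factor")
        if not self.band[0] < self.band[1]:
            raise ValueError("band must be increasing")


@dataclass
class SpindleEvent:
    channel: str
    start: float            # s
    end: float              # s
    peak_amplitude: float   # µV, max rectified amplitude
    mean_amplitude: float   # µV, mean rectified amplitude over the event
    mean_frequency: float   # Hz, from zero crossings of the band-passed signal

    @property
    def duration(self) -> float:
        return self.end - self.start

    def features(self) -> dict[str, float]:
        return {
            "duration_s": self.duration,
            "peak_amplitude_uv": self.peak_amplitude,
            "mean_amplitude_uv": self.mean_amplitude,
            "mean_frequency_hz": self.mean_frequency,
        }


@dataclass
class SpindleMetrics:
    labels: list[str]
    density: np.ndarray       # events / min
    mean_duration: np.ndarray  # s (NaN when no events)
    isas: np.ndarray          # µV / min
    band: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": self.labels,
            "density": self.density,
            "duration": self.mean_duration,
            "isas": self.isas,
            "range": [f"{self.band[0]:g}-{self.band[1]:g}"] * len(self.labels),
        })


def sigma_filter(rec: Recording, band: tuple[float, float] = SIGMA_BAND,
                 order: int = 4) -> np.ndarray:
    """Zero-phase band-pass of every channel in the sigma band."""
    if band[1] >= rec.fs / 2:
        raise ValueError("band upper edge at or above Nyquist")
    sos = signal.butter(order, band, btype="bandpass", fs=rec.fs, output="sos")
    return signal.sosfiltfilt(sos, rec.data, axis=1)


def sigma_envelope(rec: Recording, band: tuple[float, float] = SIGMA_BAND,
                   order: int = 4) -> np.ndarray:
    """Rectified sigma-band amplitude time series (no smoothing)."""
    return np.abs(sigma_filter(rec, band, order))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True in a 1-D boolean mask."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    stops = np.nonzero(d == -1)[0] + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, len(mask)]
    return list(zip(starts.tolist(), stops.tolist()))


def envelope_peaks(envelope: np.ndarray) -> np.ndarray:
    """Indices of the local maxima of a rectified envelope.

    The rectified band-passed signal touches zero every half carrier cycle;
    its sequence of local maxima ("amplitude fluctuations", one per half
    cycle) is the series the thresholds are applied to.  Plateau maxima
    contribute their first sample.
    """
    x = envelope
    if len(x) < 3:
        return np.empty(0, dtype=np.intp)
    prev = x[1:-1] > x[:-2]
    nxt = x[1:-1] >= x[2:]
    return np.nonzero(prev & nxt)[0] + 1


def detect_events_1d(envelope: np.ndarray, lower: float, upper: float,
                     fs: float, min_duration_s: float = 0.25) -> list[tuple[int, int]]:
    """Threshold detection on one contiguous rectified-envelope segment.

    An event is triggered by any amplitude fluctuation (local envelope
    maximum) exceeding ``upper``; it extends from the nearest preceding
    fluctuation whose amplitude is below ``lower`` to the nearest following
    one.  Events sharing boundaries or overlapping are merged; events whose
    search would cross the segment edge (no sub-lower fluctuation on one
    side) are discarded, as are events shorter than ``min_duration_s``.
    Returns half-open sample index pairs [start, end).
    """
    peaks = envelope_peaks(envelope)
    if len(peaks) == 0:
        return []
    vals = envelope[peaks]
    below = vals < lower
    supra = np.nonzero(vals > upper)[0]
    events: list[tuple[int, int]] = []
    for k in supra:
        pre = np.nonzero(below[:k])[0]
        post = np.nonzero(below[k + 1:])[0]
        if len(pre) == 0 or len(post) == 0:
            continue  # spans the segment edge
        start = int(peaks[pre[-1]])
        end = int(peaks[post[0] + k + 1]) + 1
        events.append((start, end))
    events.sort()
    merged: list[tuple[int, int]] = []
    for s, e in events:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    min_samples = min_duration_s * fs
    return [(s, e) for s, e in merged if (e - s) >= min_samples]


def _mean_frequency(filtered: np.ndarray, fs: float) -> float:
    """Zero-crossing frequency estimate of a band-passed segment."""
    s = np.signbit(filtered)
    crossings = int(np.count_nonzero(s[1:] != s[:-1]))
    dur = len(filtered) / fs
    return crossings / (2.0 * dur) if dur > 0 else float("nan")


def detect_spindles(rec: Recording, selection: EpochSelection,
                    params: DetectionParams | None = None) -> list[SpindleEvent]:
    """Run the amplitude-threshold detector over the selected NREM samples.

    The channel mean rectified amplitude (threshold anchor) is computed over
    the retained samples only; detection runs independently within each
    contiguous retained run, so events never straddle rejected epochs.
    """
    params = params or DetectionParams()
    filtered = sigma_filter(rec, params.band, params.filter_order)
    return detect_spindles_filtered(filtered, rec.labels, rec.fs,
                                    selection, params)


def detect_spindles_filtered(filtered: np.ndarray, labels: list[str],
                             fs: float, selection: EpochSelection,
                             params: DetectionParams | None = None
                             ) -> list[SpindleEvent]:
    """Detection on an already sigma-filtered multichannel array."""
    params = params or DetectionParams()
    if not selection.mask.any():
        raise ValueError("empty selection")
    envelope = np.abs(filtered)
    smask = selection.sample_mask(fs, filtered.shape[1])

    events: list[SpindleEvent] = []
    for ci, label in enumerate(labels):
        m = smask[ci]
        if not m.any():
            continue
        mean_amp = envelope[ci, m].mean()
        if mean_amp <= 0:
            continue
        lower = params.lower_factor * mean_amp
        upper = params.upper_factor * mean_amp
        for lo, hi in _runs(m):
            seg = envelope[ci, lo:hi]
            for s, e in detect_events_1d(seg, lower, upper, fs,
                                         params.min_duration_s):
                ev_env = seg[s:e]
                ev_filt = filtered[ci, lo + s:lo + e]
                events.append(SpindleEvent(
                    channel=label,
                    start=(lo + s) / fs,
                    end=(lo + e) / fs,
                    peak_amplitude=float(ev_env.max()),
                    mean_amplitude=float(ev_env.mean()),
                    mean_frequency=_mean_frequency(ev_filt, fs),
                ))
    return events


def filter_by_frequency(events: list[SpindleEvent],
                        frange: tuple[float, float]) -> list[SpindleEvent]:
    """Keep events whose mean frequency lies in the metric range.

    Ranges are half-open [lo, hi) except the top of the sigma range (16 Hz),
    which is included so slow [12, 14) and fast [14, 16] partition the whole
    12–16 Hz set.
    """
    lo, hi = frange
    closed_top = hi >= WHOLE_RANGE[1]
    return [ev for ev in events
            if (lo <= ev.mean_frequency < hi) or (closed_top and ev.mean_frequency == hi)]


def spindle_metrics(events: list[SpindleEvent], selection: EpochSelection,
                    labels: list[str],
                    frange: tuple[float, float] = WHOLE_RANGE) -> SpindleMetrics:
    """Per-channel density, mean duration and ISAs for one frequency range."""
    minutes = selection.minutes()
    if np.all(minutes <= 0):
        raise ValueError("zero retained NREM time")
    kept = filter_by_frequency(events, frange)
    by_ch: dict[str, list[SpindleEvent]] = {lb: [] for lb in labels}
    for ev in kept:
        if ev.channel in by_ch:
            by_ch[ev.channel].append(ev)

    n = len(labels)
    density = np.zeros(n)
    duration = np.full(n, np.nan)
    isas = np.zeros(n)
    for i, lb in enumerate(labels):
        evs = by_ch[lb]
        mins = minutes[i]
        if mins <= 0:
            density[i] = duration[i] = isas[i] = np.nan
            continue
        density[i] = len(evs) / mins
        if evs:
            duration[i] = float(np.mean([ev.duration for ev in evs]))
            isas[i] = float(sum(ev.mean_amplitude for ev in evs)) / mins
    return SpindleMetrics(labels=list(labels), density=density,
                          mean_duration=duration, isas=isas, band=frange)
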