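"""Welch power spectral density on 30-s epochs.

Each retained 30-s epoch is split into five non-overlapping 6-s segments,
each Hamming-windowed; periodograms are averaged within and across epochs.
The 6-s segment length yields a uniform 1/6 Hz (~0.16 Hz) frequency grid.
Densities are one-sided and normalised so that Σ power·Δf recovers the
signal variance (µV²/Hz on the power axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Recording
from .hypnogram_metrics import EpochSelection

SEGMENT_S = 6.0
SEGMENTS_PER_EPOCH = 5
PSD_DF = 1.0 / SEGMENT_S  # Hz


@dataclass
class PSD:
    freqs: np.ndarray          # (n_freq,)
    power: np.ndarray          # (n_channels, n_freq), µV²/Hz
    n_epochs: np.ndarray       # per-channel epochs averaged
    labels: list[str]

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, lb in enumerate(self.labels):
            for f, p in zip(self.freqs, self.power[ci]):
                rows.append((lb, f, p))
        return pd.DataFrame(rows, columns=["channel", "freq_hz", "power"])


def _epoch_psd(x: np.ndarray, fs: float, n_epochs: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch one-sided Welch PSD of a single channel.

    Returns (freqs, pxx) with pxx of shape (n_epochs, n_freq); each epoch's
    estimate averages its five 6-s Hamming segments.
    """
    nseg = int(round(SEGMENT_S * fs))
    spe = nseg * SEGMENTS_PER_EPOCH  # samples per 30-s epoch
    segs = x[:n_epochs * spe].reshape(n_epochs, SEGMENTS_PER_EPOCH, nseg)
    win = np.hamming(nseg)
    spec = np.fft.rfft(segs * win, axis=-1)
    # one-sided density: |X|² / (fs · Σw²), doubling all bins but DC/Nyquist
    pxx = (spec.real ** 2 + spec.imag ** 2) / (fs * (win ** 2).sum())
    pxx[..., 1:-1] *= 2.0
    freqs = np.fft.rfftfreq(nseg, d=1.0 / fs)
    return freqs, pxx.mean(axis=1)


def welch_psd(rec: Recording, selection: EpochSelection) -> PSD:
    """Average Welch periodogram over the selected 30-s epochs per channel."""
    if selection.n_channels != rec.n_channels:
        raise ValueError("selection channel count does not match recording")
    n_ep = min(rec.n_epochs, selection.n_epochs)
    if n_ep == 0 or not selection.mask[:, :n_ep].any():
        raise ValueError("no retained epochs to average")
    nseg = int(round(SEGMENT_S * rec.fs))
    n_freq = nseg // 2 + 1
    power = np.full((rec.n_channels, n_freq), np.nan)
    counts = np.zeros(rec.n_channels, dtype=int)
    freqs = np.fft.rfftfreq(nseg, d=1.0 / rec.fs)
    for ci in range(rec.n_channels):
        keep = np.nonzero(selection.mask[ci, :n_ep])[0]
        if len(keep) == 0:
            continue
        _, pxx = _epoch_psd(rec.data[ci], rec.fs, n_ep)
        power[ci] = pxx[keep].mean(axis=0)
        counts[ci] = len(keep)
    return PSD(freqs=freqs, power=power, n_epochs=counts, labels=list(rec.labels))


def band_power(psd: PSD, band: tuple[float, float]) -> np.ndarray:
    """Σ power·Δf over bins whose centres lie in [lo, hi); µV² per channel."""
    lo, hi = band
    sel = (psd.freqs >= lo) & (psd.freqs < hi)
    if not sel.any():
        raise ValueError(f"band {band} contains no frequency bins")
    return psd.power[:, sel].sum(axis=1) * psd.df


def band_table(psd: PSD, bands: dict[str, tuple[float, float]]) -> pd.DataFrame:
    rows = []
    for name, band in bands.items():
        bp = band_power(psd, band)
        for lb, v in zip(psd.labels, bp):
            rows.append((lb, name, v))
    return pd.DataFrame(rows, columns=["channel", "band", "power"])
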