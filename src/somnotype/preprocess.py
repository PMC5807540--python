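"""Signal conditioning and epoch-level artifact rejection.

The conditioning chain is: zero-phase high-pass at 0.1 Hz, downsampling to
128 Hz, zero-phase band-pass 0.5–40 Hz, and re-referencing to the average of
all channels.  Artifactual 30-s epochs are then rejected per channel when
their band power in the 0.8–4.48 Hz or 20–30 Hz range exceeds a multiple of
that channel's mean power over NREM epochs — a semi-automatic screen for
movement/sweat (low band) and muscle (high band) contamination.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .io_formats import Hypnogram, Recording
from .hypnogram_metrics import NREM_STAGES

TARGET_FS = 128.0


def _sos_highpass(cut: float, fs: float, order: int = 4):
    return signal.butter(order, cut, btype="highpass", fs=fs, output="sos")


def _sos_bandpass(lo: float, hi: float, fs: float, order: int = 4):
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def preprocess_recording(rec: Recording, hp_hz: float = 0.1,
                         band: tuple[float, float] = (0.5, 40.0),
                         target_fs: float = TARGET_FS,
                         average_reference: bool = True,
                         order: int = 4) -> Recording:
    """High-pass, downsample to 128 Hz, band-pass, average-reference.

    All filters are zero-phase (forward–backward Butterworth of the given
    order); resampling uses a polyphase rational resampler.  Requires the
    input rate to be at least the target rate.
    """
    if rec.fs < target_fs:
        raise ValueError(f"sampling rate {rec.fs} Hz below target {target_fs} Hz")

    x = signal.sosfiltfilt(_sos_highpass(hp_hz, rec.fs, order), rec.data, axis=1)

    if abs(rec.fs - target_fs) > 1e-9:
        frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator, axis=1)

    x = signal.sosfiltfilt(_sos_bandpass(band[0], band[1], target_fs, order),
                           x, axis=1)
    if average_reference:
        x = x - x.mean(axis=0, keepdims=True)
    return Recording(data=x, fs=target_fs, labels=list(rec.labels),
                     reference="average" if average_reference else rec.reference,
                     start_time=rec.start_time)


def epoch_band_powers(rec: Recording, bands) -> np.ndarray:
    """Band power (µV²) per channel and 30-s epoch for each requested band.

    Uses the same Welch segmentation as the spectral module (five 6-s
    Hamming-windowed segments per epoch) so thresholds are consistent with
    the reported spectra.  Returns shape (n_bands, n_channels, n_epochs).
    """
    from .spectral import _epoch_psd, PSD_DF

    n_ep = rec.n_epochs
    if n_ep == 0:
        raise ValueError("recording shorter than one 30-s epoch")
    out = np.empty((len(bands), rec.n_channels, n_ep))
    for ci in range(rec.n_channels):
        freqs, pxx = _epoch_psd(rec.data[ci], rec.fs, n_ep)  # (n_ep, n_freq)
        for bi, (lo, hi) in enumerate(bands):
            sel = (freqs >= lo) & (freqs < hi)
            out[bi, ci] = pxx[:, sel].sum(axis=1) * PSD_DF
    return out


def reject_artifacts(rec: Recording, hyp: Hypnogram,
                     low_band: tuple[float, float] = (0.8, 4.48),
                     high_band: tuple[float, float] = (20.0, 30.0),
                     factor_low: float = 4.0,
                     factor_high: float = 4.0) -> np.ndarray:
    """Per-channel epoch mask; True = retained.

    Only NREM (N2/N3) epochs enter the channel means and only they can be
    rejected: an NREM epoch is dropped on a channel when its power exceeds
    ``factor × mean`` over that channel's NREM epochs in either band.
    """
    n_ep = min(rec.n_epochs, len(hyp))
    nrem = np.isin(hyp.as_array()[:n_ep], NREM_STAGES)
    if nrem.sum() < 2:
        raise ValueError("need at least 2 NREM epochs for artifact thresholds")

    powers = epoch_band_powers(rec, [low_band, high_band])[:, :, :n_ep]
    mask = np.ones((rec.n_channels, len(hyp)), dtype=bool)
    for bi, factor in enumerate((factor_low, factor_high)):
        if not np.isfinite(factor):
            continue
        p = powers[bi][:, nrem]  # (n_ch, n_nrem)
        thresh = factor * p.mean(axis=1, keepdims=True)
        rejected = p > thresh
        cols = np.nonzero(nrem)[0]
        mask[:, cols] &= ~rejected
    return mask
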