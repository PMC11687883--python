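"""Preprocessing: rate reduction to 1 kHz and 25–400 Hz band-pass filtering.

Heart-sound energy of interest lies below ~400 Hz, so recordings are
resampled to 1000 Hz (halving the cost of all later spectral analysis) and
band-pass filtered to 25–400 Hz to strip baseline wander and high-frequency
noise.  The filter is a 4th-order Butterworth applied forward-backward
(zero phase), so S1/S2 onsets are not shifted for segmentation.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .signals import PcgSignal

__all__ = ["resample_signal", "bandpass_filter", "preprocess"]


def resample_signal(signal: PcgSignal, target_rate: float = 1000.0) -> PcgSignal:
    """Resample by polyphase rational resampling to ``target_rate``.

    A signal already at the target rate is returned unchanged.
    """
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if signal.sample_rate == target_rate:
        return signal
    ratio = Fraction(target_rate / signal.sample_rate).limit_denominator(10_000)
    resampled = sps.resample_poly(signal.samples, ratio.numerator, ratio.denominator)
    return signal.replace(samples=resampled, sample_rate=target_rate)


def bandpass_filter(
    signal: PcgSignal, low: float = 25.0, high: float = 400.0, order: int = 4
) -> PcgSignal:
    """Zero-phase Butterworth band-pass between ``low`` and ``high`` Hz.

    The forward-backward pass squares the magnitude response, giving well
    over 20 dB of rejection one octave outside the band while leaving the
    pass band essentially flat.
    """
    nyq = signal.sample_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz); "
            f"got low={low}, high={high}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=signal.sample_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, signal.samples)
    return signal.replace(samples=filtered)


def preprocess(
    signal: PcgSignal,
    target_rate: float = 1000.0,
    low: float = 25.0,
    high: float = 400.0,
    normalize: bool = False,
) -> PcgSignal:
    """Resample then band-pass filter; optionally scale to unit variance.

    Amplitude normalization is off by default: the log compression in the
    cepstral features makes overall scale largely irrelevant.
    """
    out = bandpass_filter(resample_signal(signal, target_rate), low, high)
    if normalize:
        sd = float(np.std(out.samples))
        if sd > 0:
            out = out.replace(samples=out.samples / sd)
    return out
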