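"""Segment-wise Mel-frequency cepstral coefficients for heart beats.

Each of the four intervals of a beat (S1, systole, S2, diastole) is divided
into 24 ms frames hopping by 6 ms (18 ms overlap), each frame is Hamming
windowed, zero-padded to a 64-point DFT, and its power is accumulated through
a bank of M = 20 triangular Mel-scale filters spanning 0–400 Hz:

    P[m] = 10 log10( (1/N) * sum_{k=0..N/2} |X[k]|^2 |H_m[k]| )

A type-II discrete cosine transform (unnormalized),

    C[k'] = sum_{m=0..M-1} P[m] cos(pi/M (m + 1/2) k'),

decorrelates the log filter powers; the first 13 coefficients (C[0]..C[12],
including the overall log-energy term C[0]) are averaged across a segment's
frames.  Concatenating the four 13-coefficient segment descriptors in the
order S1, systole, S2, diastole gives the 52-dimensional beat feature vector.

Note the filter response enters the power sum at its first power, |H_m[k]|,
not the more common |H_m[k]|^2; ``response_power=2`` selects the
conventional variant for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .segment import Beat
from .signals import PcgSignal

__all__ = [
    "FrameSpec",
    "MelFilterbank",
    "BeatFeatureVector",
    "hz_to_mel",
    "mel_to_hz",
    "design_filterbank",
    "frame_segment",
    "frame_dft",
    "mel_log_powers",
    "dct2_coefficients",
    "segment_mfcc",
    "beat_feature_vector",
    "signal_features",
]

#: Floor applied to the mean weighted power before the log (guards log(0)).
POWER_FLOOR = 1e-12


@dataclass(frozen=True)
class FrameSpec:
    """Short-time analysis geometry: 24 ms Hamming frames, 6 ms hop, N=64."""

    frame_length: float = 0.024
    hop: float = 0.006
    dft_size: int = 64

    def __post_init__(self) -> None:
        if not 0 < self.hop <= self.frame_length:
            raise ValueError("require 0 < hop <= frame_length")
        if self.dft_size < 1:
            raise ValueError("dft_size must be positive")

    def frame_samples(self, sample_rate: float) -> int:
        return max(1, int(round(self.frame_length * sample_rate)))

    def hop_samples(self, sample_rate: float) -> int:
        return max(1, int(round(self.hop * sample_rate)))


def hz_to_mel(f):
    """Mel scale: 2595 log10(1 + f/700).  Strictly increasing for f >= 0."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = 2595.0 * np.log10(1.0 + f / 700.0)
    return float(out) if out.ndim == 0 else out


def mel_to_hz(m):
    """Inverse Mel scale: 700 (10^(m/2595) - 1)."""
    m = np.asarray(m, dtype=float)
    out = 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class MelFilterbank:
    """M triangular filters on DFT bins 0..N/2.

    ``center_bins`` holds the M+2 boundary/center bin indices (filter m rises
    over [center_bins[m], center_bins[m+1]] and falls over
    [center_bins[m+1], center_bins[m+2]]); ``responses`` is the M x (N/2+1)
    matrix of frequency responses with peak value 1.
    """

    n_filters: int
    f_min: float
    f_max: float
    sample_rate: float
    dft_size: int
    center_bins: np.ndarray
    responses: np.ndarray = field(repr=False)


def design_filterbank(
    n_filters: int = 20,
    f_min: float = 0.0,
    f_max: float = 400.0,
    sample_rate: float = 1000.0,
    dft_size: int = 64,
    bin_rule: str = "floor",
) -> MelFilterbank:
    """Design M triangular filters at Mel-equispaced center frequencies.

    M+2 equally spaced points on the Mel axis between ``f_min`` and ``f_max``
    are mapped back to Hz and then to DFT bin indices k = [f/fs * N] (floor
    by default; ``bin_rule="round"`` for round-to-nearest).  Adjacent centers
    may land on the same bin at coarse resolutions; the response is defined
    so each filter still peaks at 1.
    """
    if n_filters < 1:
        raise ValueError("n_filters must be >= 1")
    if f_max > sample_rate / 2.0:
        raise ValueError(f"f_max={f_max} exceeds Nyquist ({sample_rate / 2.0} Hz)")
    if not 0 <= f_min < f_max:
        raise ValueError("require 0 <= f_min < f_max")
    if bin_rule not in ("floor", "round"):
        raise ValueError("bin_rule must be 'floor' or 'round'")

    mels = np.linspace(hz_to_mel(f_min), hz_to_mel(f_max), n_filters + 2)
    freqs = mel_to_hz(mels)
    raw = freqs / sample_rate * dft_size
    bins = np.floor(raw).astype(int) if bin_rule == "floor" else np.rint(raw).astype(int)

    n_bins = dft_size // 2 + 1
    responses = np.zeros((n_filters, n_bins))
    k = np.arange(n_bins)
    for m in range(n_filters):
        lo, center, hi = bins[m], bins[m + 1], bins[m + 2]
        rise = (lo <= k) & (k < center)
        if center > lo:
            responses[m, rise] = (k[rise] - lo) / (center - lo)
        fall = (center <= k) & (k <= hi)
        if hi > center:
            responses[m, fall] = (hi - k[fall]) / (hi - center)
        else:
            responses[m, fall] = 1.0  # degenerate triangle: keep the unit peak
    return MelFilterbank(
        n_filters=n_filters,
        f_min=f_min,
        f_max=f_max,
        sample_rate=sample_rate,
        dft_size=dft_size,
        center_bins=bins,
        responses=responses,
    )


def frame_segment(
    segment_samples: np.ndarray, spec: FrameSpec, sample_rate: float
) -> np.ndarray:
    """Split a segment into Hamming-windowed frames (rows).

    Frames start at multiples of the hop from the segment onset and only
    frames fully inside the segment are emitted; a segment shorter than one
    frame yields a single whole-segment frame.  Windowing precedes the
    zero-padding done at DFT time.
    """
    x = np.asarray(segment_samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty segment")
    length = spec.frame_samples(sample_rate)
    hop = spec.hop_samples(sample_rate)
    if x.size < length:
        return (x * np.hamming(x.size))[np.newaxis, :]
    n_frames = (x.size - length) // hop + 1
    starts = np.arange(n_frames) * hop
    frames = x[starts[:, None] + np.arange(length)]
    return frames * np.hamming(length)


def frame_dft(frame: np.ndarray, dft_size: int) -> np.ndarray:
    """N-point DFT of (windowed) frames, bins 0..N/2; zero-pads to N.

    Accepts a single frame (1-D) or a stack of frames (2-D, one per row).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape[-1] > dft_size:
        raise ValueError(
            f"frame length {frame.shape[-1]} exceeds DFT size {dft_size}"
        )
    return np.fft.rfft(frame, n=dft_size, axis=-1)


def mel_log_powers(
    frames: np.ndarray,
    fb: MelFilterbank,
    power_floor: float = POWER_FLOOR,
    response_power: int = 1,
) -> np.ndarray:
    """Log power per Mel band: P[m] = 10 log10((1/N) sum_k |X[k]|^2 |H_m[k]|).

    Accepts one frame (1-D) or a stack of frames (2-D, one per row) and
    returns a matching (M,) or (n_frames, M) array.  ``response_power=2``
    squares the filter response (the conventional variant); the mean power is
    floored at ``power_floor`` before the log so silent frames stay finite.
    """
    frames = np.asarray(frames, dtype=float)
    single = frames.ndim == 1
    frames = np.atleast_2d(frames)
    spectrum = np.fft.rfft(frames, n=fb.dft_size, axis=-1)
    power = np.abs(spectrum) ** 2
    weights = fb.responses**response_power
    banded = power @ weights.T / fb.dft_size
    out = 10.0 * np.log10(np.maximum(banded, power_floor))
    return out[0] if single else out


@lru_cache(maxsize=8)
def _dct2_matrix(m: int) -> np.ndarray:
    k = np.arange(m)[:, None]
    n = np.arange(m)[None, :]
    return np.cos(np.pi / m * (n + 0.5) * k)


def dct2_coefficients(log_powers: np.ndarray) -> np.ndarray:
    """Unnormalized DCT-II: C[k'] = sum_m P[m] cos(pi/M (m+1/2) k').

    Accepts (M,) or (n_frames, M); no orthonormalization scaling is applied,
    so a constant input c maps to C[0] = M*c with all other coefficients 0.
    """
    p = np.asarray(log_powers, dtype=float)
    return p @ _dct2_matrix(p.shape[-1]).T


def segment_mfcc(
    segment_samples: np.ndarray,
    spec: FrameSpec,
    fb: MelFilterbank,
    n_keep: int = 13,
    response_power: int = 1,
) -> np.ndarray:
    """MFCC descriptor of one segment: per-frame cepstra averaged, first
    ``n_keep`` coefficients kept (C[0]..C[n_keep-1])."""
    frames = frame_segment(segment_samples, spec, fb.sample_rate)
    cepstra = dct2_coefficients(
        mel_log_powers(frames, fb, response_power=response_power)
    )
    return cepstra.mean(axis=0)[:n_keep]


@dataclass
class BeatFeatureVector:
    """52 MFCCs for one beat, ordered [S1 | systole | S2 | diastole]."""

    values: np.ndarray
    beat_index: int
    signal_id: str
    label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (52,):
            raise ValueError(f"expected 52 values, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("beat feature vector contains non-finite values")


def beat_feature_vector(
    signal: PcgSignal,
    beat: Beat,
    spec: FrameSpec | None = None,
    fb: MelFilterbank | None = None,
    beat_index: int = 0,
    n_keep: int = 13,
) -> BeatFeatureVector:
    """Assemble the 52-dimensional feature vector of one beat."""
    spec = spec or FrameSpec()
    fb = fb or design_filterbank(sample_rate=signal.sample_rate)
    if beat.diastole[1] > len(signal):
        raise ValueError("beat extends past the end of the signal")
    blocks = [
        segment_mfcc(signal.samples[a:b], spec, fb, n_keep=n_keep)
        for a, b in beat.segments().values()
    ]
    return BeatFeatureVector(
        values=np.concatenate(blocks),
        beat_index=beat_index,
        signal_id=signal.id,
        label=signal.label,
    )


def signal_features(
    signal: PcgSignal,
    beats: list[Beat],
    spec: FrameSpec | None = None,
    fb: MelFilterbank | None = None,
    n_keep: int = 13,
) -> list[BeatFeatureVector]:
    """Feature vectors for a list of beats, indexed in order."""
    spec = spec or FrameSpec()
    fb = fb or design_filterbank(sample_rate=signal.sample_rate)
    return [
        beat_feature_vector(signal, beat, spec, fb, beat_index=i, n_keep=n_keep)
        for i, beat in enumerate(beats)
    ]
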