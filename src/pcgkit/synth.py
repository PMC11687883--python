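"""Synthetic phonocardiogram generation with ground-truth segmentation.

The generator emulates the gross acoustic structure of a heart beat: S1 and
S2 are short Gaussian-enveloped tone bursts in the low audible range, systole
and diastole are quiet, and an abnormal beat carries a systolic murmur
modelled as band-limited noise confined to systole.  Every generated sample
comes with its ground-truth state (1=S1, 2=systole, 3=S2, 4=diastole), so the
whole downstream pipeline — preprocessing, segmentation, feature extraction,
classification, evaluation — can be exercised and validated without any
external recordings.

Defaults describe a ~75 bpm beat (0.12 s S1 at 30+45 Hz, 0.2 s systole,
0.1 s S2 at 50+70 Hz, 0.38 s diastole), all inside the 25–400 Hz analysis
band.  The murmur band defaults to 150–400 Hz, the typical range of a harsh
systolic murmur.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .signals import PcgSignal, StateSequence

__all__ = [
    "BeatTemplate",
    "SyntheticDatasetConfig",
    "generate_beat",
    "generate_signal",
    "generate_dataset",
]


@dataclass
class BeatTemplate:
    """Morphology of one synthetic heart beat.

    Durations are in seconds, frequencies in Hz, amplitudes on the linear
    scale of the (unit-peak) S1/S2 bursts.  ``murmur_amplitude = 0`` yields a
    normal beat; positive values inject band-limited noise into systole.
    ``jitter_fraction`` scales each segment duration by an independent
    uniform factor in ``1 ± jitter_fraction`` per beat, breaking exact beat
    alignment as in real recordings.
    """

    s1_duration: float = 0.12
    systole_duration: float = 0.20
    s2_duration: float = 0.10
    diastole_duration: float = 0.38
    s1_freqs: tuple[float, ...] = (30.0, 45.0)
    s2_freqs: tuple[float, ...] = (50.0, 70.0)
    murmur_band: tuple[float, float] = (150.0, 400.0)
    murmur_amplitude: float = 0.0
    noise_sd: float = 0.0
    jitter_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("s1_duration", "systole_duration", "s2_duration", "diastole_duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.murmur_amplitude < 0:
            raise ValueError("murmur_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.jitter_fraction < 1:
            raise ValueError("jitter_fraction must be in [0, 1)")
        lo, hi = self.murmur_band
        if not 0 < lo < hi:
            raise ValueError("murmur_band must satisfy 0 < low < high")

    @property
    def beat_duration(self) -> float:
        """Nominal (unjittered) duration of one beat in seconds."""
        return (
            self.s1_duration
            + self.systole_duration
            + self.s2_duration
            + self.diastole_duration
        )

    def replace(self, **kwargs) -> "BeatTemplate":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticDatasetConfig:
    """Design of a balanced-by-construction synthetic dataset.

    Abnormal signals are generated with ``murmur_amplitude``; normal signals
    with zero murmur.  ``beats_per_signal`` defaults to 10 so that taking the
    first 9 complete beats never depends on the final diastole; signals meant
    to enter classification must have at least 9 beats.
    """

    n_abnormal: int = 10
    n_normal: int = 10
    beats_per_signal: int = 10
    sample_rate: float = 2000.0
    seed: int = 0
    murmur_amplitude: float = 0.5
    noise_sd: float = 0.05
    jitter_fraction: float = 0.1
    template: BeatTemplate | None = None

    def __post_init__(self) -> None:
        if self.n_abnormal < 0 or self.n_normal < 0:
            raise ValueError("signal counts must be non-negative")
        if self.beats_per_signal < 1:
            raise ValueError("beats_per_signal must be >= 1")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    def template_for(self, label: str) -> BeatTemplate:
        """Beat template for the given class label."""
        base = self.template or BeatTemplate()
        return base.replace(
            murmur_amplitude=self.murmur_amplitude if label == "abnormal" else 0.0,
            noise_sd=self.noise_sd,
            jitter_fraction=self.jitter_fraction,
        )


def _tone_burst(
    freqs: tuple[float, ...], n: int, sample_rate: float
) -> np.ndarray:
    """Gaussian-enveloped sum of sinusoids spanning ``n`` samples."""
    t = np.arange(n) / sample_rate
    dur = n / sample_rate
    envelope = np.exp(-0.5 * ((t - dur / 2.0) / (dur / 6.0)) ** 2)
    tone = np.zeros(n)
    for f in freqs:
        tone += np.sin(2.0 * np.pi * f * t)
    if freqs:
        tone /= len(freqs)
    return envelope * tone


def _murmur_noise(
    n: int, band: tuple[float, float], sample_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS band-limited noise.  Scaled by the caller, so an amplitude of
    zero stays exactly zero."""
    white = rng.standard_normal(n)
    nyq = sample_rate / 2.0
    hi = min(band[1], 0.99 * nyq)
    sos = sps.butter(2, [band[0], hi], btype="bandpass", fs=sample_rate, output="sos")
    shaped = sps.sosfiltfilt(sos, white, padlen=min(n - 1, 24))
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def generate_beat(
    template: BeatTemplate,
    rng: np.random.Generator,
    sample_rate: float = 2000.0,
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Synthesize one beat.

    Returns the waveform and four ``(state, start, end)`` half-open index
    ranges that partition it in the order S1, systole, S2, diastole.
    """
    durations = np.array(
        [
            template.s1_duration,
            template.systole_duration,
            template.s2_duration,
            template.diastole_duration,
        ]
    )
    if template.jitter_fraction > 0:
        jitter = rng.uniform(
            1.0 - template.jitter_fraction, 1.0 + template.jitter_fraction, size=4
        )
    else:
        jitter = np.ones(4)
    lengths = np.maximum(1, np.rint(durations * jitter * sample_rate).astype(int))

    n_s1, n_sys, n_s2, n_dia = lengths
    parts = [
        _tone_burst(template.s1_freqs, n_s1, sample_rate),
        template.murmur_amplitude
        * _murmur_noise(n_sys, template.murmur_band, sample_rate, rng),
        _tone_burst(template.s2_freqs, n_s2, sample_rate),
        np.zeros(n_dia),
    ]
    waveform = np.concatenate(parts)
    waveform = waveform + template.noise_sd * rng.standard_normal(waveform.size)

    bounds = np.concatenate(([0], np.cumsum(lengths)))
    intervals = [
        (state, int(bounds[i]), int(bounds[i + 1])) for i, state in enumerate((1, 2, 3, 4))
    ]
    return waveform, intervals


def generate_signal(
    template: BeatTemplate,
    n_beats: int,
    label: str = "unknown",
    seed: int = 0,
    sample_rate: float = 2000.0,
    signal_id: str = "",
) -> tuple[PcgSignal, StateSequence]:
    """Concatenate ``n_beats`` generated beats into one labeled signal.

    The returned state sequence assigns 1/2/3/4 per sample, consistent with
    the generated segment boundaries; it is the ground truth against which
    segmentation can be scored.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    rng = np.random.default_rng(seed)
    chunks: list[np.ndarray] = []
    state_chunks: list[np.ndarray] = []
    for _ in range(n_beats):
        wave, intervals = generate_beat(template, rng, sample_rate)
        states = np.empty(wave.size, dtype=np.int64)
        for state, a, b in intervals:
            states[a:b] = state
        chunks.append(wave)
        state_chunks.append(states)
    samples = np.concatenate(chunks)
    sig = PcgSignal(samples, sample_rate, id=signal_id, label=label)
    return sig, StateSequence(np.concatenate(state_chunks))


def generate_dataset(config: SyntheticDatasetConfig, out_dir: str | Path):
    """Write a balanced synthetic dataset to ``out_dir``.

    Produces one WAV and one ground-truth state CSV per signal plus a
    ``manifest.csv`` with columns ``path,states_path,label``.  Fully
    reproducible from ``config.seed``.  Returns the manifest.
    """
    from . import io as pio  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plan = [("abnormal", i) for i in range(config.n_abnormal)] + [
        ("normal", i) for i in range(config.n_normal)
    ]
    seed_rng = np.random.default_rng(config.seed)
    seeds = seed_rng.integers(0, 2**31 - 1, size=len(plan))
    records = []
    for (label, i), s in zip(plan, seeds):
        sig_id = f"{label[:3]}{i:04d}"
        template = config.template_for(label)
        sig, states = generate_signal(
            template,
            config.beats_per_signal,
            label=label,
            seed=int(s),
            sample_rate=config.sample_rate,
            signal_id=sig_id,
        )
        wav_path = out_dir / f"{sig_id}.wav"
        states_path = out_dir / f"{sig_id}_states.csv"
        pio.save_signal(sig, wav_path)
        pio.save_states(states, states_path)
        records.append(
            pio.ManifestRecord(
                path=wav_path.name, states_path=states_path.name, label=label
            )
        )
    manifest = pio.DatasetManifest(records=records, root=out_dir)
    pio.save_manifest(manifest, out_dir / "manifest.csv")
    return manifest
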