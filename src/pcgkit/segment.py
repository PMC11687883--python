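"""Heart-sound segmentation: per-sample states and beat enumeration.

Two routes produce state sequences.  External labels (e.g. from a trained
hidden semi-Markov segmenter) can be ingested as state CSVs and, if needed,
resampled to the analysis rate.  For clean signals — in particular the
synthetic generator's output — a simplified envelope segmenter is built in:
it thresholds the smoothed Shannon-energy envelope to find sound lobes,
disambiguates S1 from S2 by the rule that the gap after S2 (diastole) is on
average longer than the gap after S1 (systole), and fills the intervals in
between with states 2 and 4.

Index convention is 0-based half-open ``[start, end)`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .signals import PcgSignal, StateSequence

__all__ = [
    "Beat",
    "SegmentationError",
    "InsufficientBeatsError",
    "shannon_envelope",
    "segment_states",
    "extract_beats",
    "resample_states",
]


class SegmentationError(RuntimeError):
    """The envelope segmenter could not find enough sound lobes."""


class InsufficientBeatsError(ValueError):
    """A signal has fewer complete beats than required (excluded from analysis)."""


@dataclass(frozen=True)
class Beat:
    """One cardiac cycle as four contiguous half-open index ranges."""

    s1: tuple[int, int]
    systole: tuple[int, int]
    s2: tuple[int, int]
    diastole: tuple[int, int]

    def __post_init__(self) -> None:
        segs = (self.s1, self.systole, self.s2, self.diastole)
        for a, b in segs:
            if b < a:
                raise ValueError("segment end before start")
        if self.s1[1] - self.s1[0] == 0 or self.s2[1] - self.s2[0] == 0:
            raise ValueError("S1 and S2 must be non-empty")
        for left, right in zip(segs, segs[1:]):
            if left[1] != right[0]:
                raise ValueError("beat segments must be contiguous and ordered")

    @property
    def span(self) -> tuple[int, int]:
        return (self.s1[0], self.diastole[1])

    def segments(self) -> dict[str, tuple[int, int]]:
        return {
            "s1": self.s1,
            "systole": self.systole,
            "s2": self.s2,
            "diastole": self.diastole,
        }


def shannon_envelope(
    samples: np.ndarray, sample_rate: float, window: float = 0.02
) -> np.ndarray:
    """Smoothed Shannon-energy envelope.

    The signal is normalized to unit peak amplitude, the per-sample Shannon
    energy ``-x^2 * ln(x^2)`` (defined as 0 at x=0) is computed, and the
    result is averaged in a sliding window of the given width (seconds).
    The envelope emphasises medium-intensity sound lobes over both silence
    and isolated extreme peaks.
    """
    x = np.asarray(samples, dtype=float)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    x2 = x * x
    energy = np.zeros_like(x2)
    nz = x2 > 0
    energy[nz] = -x2[nz] * np.log(x2[nz])
    size = max(1, int(round(window * sample_rate)))
    return uniform_filter1d(energy, size=size, mode="nearest")


def _find_lobes(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(a), int(b)) for a, b in zip(idx[0::2], idx[1::2])]


def segment_states(
    signal: PcgSignal,
    threshold_frac: float = 0.2,
    low_frac: float = 0.02,
    merge_gap: float = 0.05,
    min_lobe: float = 0.02,
    window: float = 0.02,
) -> StateSequence:
    """Assign a state (1–4) to every sample via envelope thresholding.

    Expects a preprocessed signal (1 kHz, band-passed).  Lobes are regions
    where the envelope exceeds ``threshold_frac`` of its maximum, extended
    outward (hysteresis) while the envelope stays above ``low_frac`` of the
    maximum — kept above the noise floor, estimated as twice the median
    envelope — so the quiet tails of a sound burst are attributed to the
    burst.  Lobes separated by less than ``merge_gap`` seconds are merged
    and lobes shorter than ``min_lobe`` seconds are discarded.  Alternate
    lobes are paired into S1/S2 by comparing the two inter-lobe gap
    populations: the longer mean gap follows S2 (diastole); ties label the
    first lobe S1.
    """
    env = shannon_envelope(signal.samples, signal.sample_rate, window=window)
    if env.max() <= 0:
        raise SegmentationError("flat signal: no envelope lobes")
    mask = env >= threshold_frac * env.max()
    lobes = _find_lobes(mask)

    low = max(low_frac * env.max(), 2.0 * float(np.median(env)))
    low_runs = _find_lobes(env >= low)
    extended: list[tuple[int, int]] = []
    for a, b in lobes:
        for la, lb in low_runs:
            if la <= a and b <= lb:
                a, b = la, lb
                break
        if extended and a <= extended[-1][1]:
            extended[-1] = (extended[-1][0], max(b, extended[-1][1]))
        else:
            extended.append((a, b))
    lobes = extended

    merged: list[tuple[int, int]] = []
    gap_samples = merge_gap * signal.sample_rate
    for lobe in lobes:
        if merged and lobe[0] - merged[-1][1] < gap_samples:
            merged[-1] = (merged[-1][0], lobe[1])
        else:
            merged.append(lobe)
    min_samples = min_lobe * signal.sample_rate
    lobes = [l for l in merged if l[1] - l[0] >= min_samples]
    if len(lobes) < 2:
        raise SegmentationError(f"found {len(lobes)} sound lobes; need at least 2")

    gaps = np.array([lobes[i + 1][0] - lobes[i][1] for i in range(len(lobes) - 1)], float)
    even = gaps[0::2]
    odd = gaps[1::2]
    # Gap after S1 is systole (short); after S2, diastole (long).  If the
    # even-indexed gaps (those following lobe 0) are strictly longer on
    # average, lobe 0 is S2; otherwise (including ties) lobe 0 is S1.
    if odd.size and even.size and even.mean() > odd.mean():
        first_is_s1 = False
    else:
        first_is_s1 = True

    states = np.empty(len(signal), dtype=np.int64)
    lobe_state = lambda j: 1 if (j % 2 == 0) == first_is_s1 else 3
    for j, (a, b) in enumerate(lobes):
        states[a:b] = lobe_state(j)
    for j in range(len(lobes) - 1):
        a = lobes[j][1]
        b = lobes[j + 1][0]
        states[a:b] = 2 if lobe_state(j) == 1 else 4
    # Leading samples precede the first lobe; trailing samples follow the last.
    states[: lobes[0][0]] = 4 if lobe_state(0) == 1 else 2
    states[lobes[-1][1] :] = 2 if lobe_state(len(lobes) - 1) == 1 else 4
    return StateSequence(states)


def extract_beats(states: StateSequence, n: int = 9) -> list[Beat]:
    """Return the first ``n`` complete beats of a state sequence.

    A complete beat starts at an S1 onset and runs through the end of the
    following diastole (state runs 1,2,3,4 in order).  A leading partial
    cycle is skipped.  Raises :class:`InsufficientBeatsError` when fewer
    than ``n`` complete beats exist — such signals are excluded from
    classification.
    """
    runs = states.runs()
    beats: list[Beat] = []
    j = 0
    while j + 3 < len(runs):
        if [r[0] for r in runs[j : j + 4]] == [1, 2, 3, 4]:
            r1, r2, r3, r4 = runs[j : j + 4]
            beats.append(
                Beat(
                    s1=(r1[1], r1[2]),
                    systole=(r2[1], r2[2]),
                    s2=(r3[1], r3[2]),
                    diastole=(r4[1], r4[2]),
                )
            )
            if len(beats) == n:
                return beats
            j += 4
        else:
            j += 1
            while j < len(runs) and runs[j][0] != 1:
                j += 1
    raise InsufficientBeatsError(
        f"found {len(beats)} complete beats; {n} required"
    )


def count_beats(states: StateSequence) -> int:
    """Number of complete S1→diastole cycles in a state sequence."""
    runs = states.runs()
    count = 0
    j = 0
    while j + 3 < len(runs):
        if [r[0] for r in runs[j : j + 4]] == [1, 2, 3, 4]:
            count += 1
            j += 4
        else:
            j += 1
    return count


def resample_states(
    states: StateSequence, orig_rate: float, target_rate: float, n_target: int | None = None
) -> StateSequence:
    """Map per-sample states onto a different sampling rate.

    Used when ingesting external labels produced at the recording's native
    rate for a signal that has since been resampled.  Sample ``i`` at the
    target rate takes the state of the nearest source index.
    """
    if n_target is None:
        n_target = int(round(len(states) * target_rate / orig_rate))
    src = np.minimum(
        (np.arange(n_target) * orig_rate / target_rate).round().astype(int),
        len(states) - 1,
    )
    return StateSequence(states.states[src])
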