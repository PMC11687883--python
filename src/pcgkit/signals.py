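"""Core in-memory containers for phonocardiogram data.

A phonocardiogram (PCG) is the acoustic recording of the cardiac cycle.
Each beat comprises four intervals: the first heart sound (S1), systole,
the second heart sound (S2), and diastole.  Per-sample interval labels use
the conventional integer coding 1=S1, 2=systole, 3=S2, 4=diastole.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Class labels a signal may carry.
SIGNAL_LABELS = ("normal", "abnormal", "unknown")

#: Integer state codes for the four intervals of a heart beat.
STATE_S1, STATE_SYSTOLE, STATE_S2, STATE_DIASTOLE = 1, 2, 3, 4
STATE_NAMES = {1: "s1", 2: "systole", 3: "s2", 4: "diastole"}


@dataclass
class PcgSignal:
    """A sampled phonocardiogram with its rate, identity and class label."""

    samples: np.ndarray
    sample_rate: float
    id: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.label not in SIGNAL_LABELS:
            raise ValueError(f"label must be one of {SIGNAL_LABELS}, got {self.label!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.sample_rate

    def replace(self, **kwargs) -> "PcgSignal":
        """Return a copy with the given fields replaced."""
        out = {
            "samples": self.samples,
            "sample_rate": self.sample_rate,
            "id": self.id,
            "label": self.label,
        }
        out.update(kwargs)
        return PcgSignal(**out)


@dataclass
class StateSequence:
    """Per-sample heart-sound states (1=S1, 2=systole, 3=S2, 4=diastole)."""

    states: np.ndarray = field()

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1 or self.states.size == 0:
            raise ValueError("states must be a non-empty 1-D array")
        bad = ~np.isin(self.states, (1, 2, 3, 4))
        if bad.any():
            raise ValueError(
                f"states must take values in {{1,2,3,4}}; "
                f"found {np.unique(self.states[bad])}"
            )

    def __len__(self) -> int:
        return self.states.size

    def runs(self) -> list[tuple[int, int, int]]:
        """Maximal constant runs as ``(state, start, end)`` half-open triples."""
        s = self.states
        boundaries = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [s.size]))
        return [(int(s[a]), int(a), int(b)) for a, b in zip(starts, ends)]
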