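"""File formats: WAV signals, per-sample state CSVs, manifests, feature tables.

All text artifacts are plain CSV.  An optional ``# key=value`` comment line
may be prepended to any CSV written here (used by the pipeline to embed the
configuration hash); readers skip ``#`` comment lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .signals import PcgSignal, StateSequence

#: Labels allowed at the manifest layer.  "uncertain" marks noisy recordings
#: that are excluded before classification and never reaches the classifiers.
MANIFEST_LABELS = ("normal", "abnormal", "uncertain")

FEATURE_COLUMNS = [f"f{i:02d}" for i in range(1, 53)] + [
    "beat_index",
    "signal_id",
    "label",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def load_signal(path: str | Path, label: str = "unknown") -> PcgSignal:
    """Read a mono WAV file into a :class:`PcgSignal`.

    Integer PCM is rescaled to [-1, 1); float data is passed through.
    Multi-channel audio is rejected.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # corrupt / non-WAV
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise FormatError(f"{path}: expected mono audio, got {data.ndim} channels")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        samples = data.astype(float) / scale
    else:
        samples = data.astype(float)
    return PcgSignal(samples, float(rate), id=path.stem, label=label)


def save_signal(signal: PcgSignal, path: str | Path) -> None:
    """Write a signal as a mono float32 WAV (lossless for our amplitudes)."""
    wavfile.write(Path(path), int(round(signal.sample_rate)), signal.samples.astype(np.float32))


def save_states(
    states: StateSequence, path: str | Path, header_comment: str | None = None
) -> None:
    """Write per-sample states as CSV with columns ``sample_index,state``."""
    df = pd.DataFrame(
        {"sample_index": np.arange(len(states)), "state": states.states}
    )
    _write_csv(df, path, header_comment)


def load_states(path: str | Path) -> StateSequence:
    df = pd.read_csv(path, comment="#")
    if not {"sample_index", "state"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns sample_index,state")
    df = df.sort_values("sample_index")
    return StateSequence(df["state"].to_numpy())


@dataclass
class ManifestRecord:
    """One dataset entry: audio path, optional state-file path, class label."""

    path: str
    states_path: str | None
    label: str

    def __post_init__(self) -> None:
        if self.label not in MANIFEST_LABELS:
            raise ValueError(
                f"manifest label must be one of {MANIFEST_LABELS}, got {self.label!r}"
            )


@dataclass
class DatasetManifest:
    """Ordered list of dataset records, with the directory they resolve in."""

    records: list[ManifestRecord]
    root: Path = field(default_factory=Path)

    def __len__(self) -> int:
        return len(self.records)

    def resolve(self, record: ManifestRecord) -> tuple[Path, Path | None]:
        wav = self.root / record.path
        states = self.root / record.states_path if record.states_path else None
        return wav, states


def save_manifest(
    manifest: DatasetManifest, path: str | Path, header_comment: str | None = None
) -> None:
    df = pd.DataFrame(
        {
            "path": [r.path for r in manifest.records],
            "states_path": [r.states_path or "" for r in manifest.records],
            "label": [r.label for r in manifest.records],
        }
    )
    _write_csv(df, path, header_comment)


def load_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    df = pd.read_csv(path, comment="#", keep_default_na=False)
    if not {"path", "label"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns path,states_path,label")
    records = [
        ManifestRecord(
            path=row["path"],
            states_path=row.get("states_path") or None,
            label=row["label"],
        )
        for _, row in df.iterrows()
    ]
    return DatasetManifest(records=records, root=path.parent)


def filter_manifest(
    manifest: DatasetManifest,
    min_beats: int = 9,
    beat_counter=None,
) -> DatasetManifest:
    """Apply the dataset inclusion rules.

    Records labeled ``uncertain`` (noisy recordings) are dropped, and — when
    ``beat_counter`` is given — so are records whose signal yields fewer than
    ``min_beats`` complete beats.  ``beat_counter`` maps a
    :class:`ManifestRecord` to its beat count, so callers decide whether
    counting needs the audio, the state file, or cached metadata.  Order is
    preserved and the operation is idempotent.
    """
    kept = []
    for rec in manifest.records:
        if rec.label == "uncertain":
            continue
        if beat_counter is not None and beat_counter(rec) < min_beats:
            continue
        kept.append(rec)
    return DatasetManifest(records=kept, root=manifest.root)


def save_features(
    features: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a beat-feature table (columns ``f01..f52,beat_index,signal_id,label``)."""
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    _write_csv(features[FEATURE_COLUMNS], path, header_comment)


def load_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: feature table missing columns {missing}")
    return df


def _write_csv(df: pd.DataFrame, path: str | Path, header_comment: str | None) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, lineterminator="\n")
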