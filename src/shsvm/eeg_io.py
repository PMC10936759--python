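"""Reading Bonn-style EEG segment files and assembling classification tasks.

The Bonn corpus distributes each recording as a plain-text file with one
sample value per line (about 23.6 s at 173.61 Hz, i.e. 4097 samples).  Five
groups are distinguished: A and B from healthy volunteers (eyes open /
closed), C and D interictal recordings from epilepsy patients, and E ictal
(during-seizure) recordings.  Binary tasks are formed by pooling groups on
each side, e.g. "AB vs CDE"; the healthy side is always labeled -1 and the
epileptic side +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "EEGSegment",
    "TaskSpec",
    "TASKS",
    "SCENARIOS",
    "read_segment",
    "load_group_dir",
    "assemble_task",
]

BONN_FS = 173.61
"""Nominal sampling rate (Hz) of the Bonn recordings."""


@dataclass
class EEGSegment:
    """One single-channel recording (microvolts) with its sampling rate."""

    samples: np.ndarray
    fs: float = BONN_FS
    group: str = "synthetic"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or len(self.samples) < 1:
            raise ValueError("samples must be a non-empty one-dimensional series")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class TaskSpec:
    """A binary task: which groups form the negative and positive class."""

    negative_groups: Tuple[str, ...]
    positive_groups: Tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        neg, pos = set(self.negative_groups), set(self.positive_groups)
        if not neg or not pos:
            raise ValueError("both sides of a task must be non-empty")
        if neg & pos:
            raise ValueError(f"groups {sorted(neg & pos)} appear on both sides")


def _task(neg: str, pos: str) -> TaskSpec:
    return TaskSpec(tuple(neg), tuple(pos), name=f"{neg}_vs_{pos}")


TASKS: Dict[str, TaskSpec] = {
    "AB_vs_CDE": _task("AB", "CDE"),
    "AB_vs_CD": _task("AB", "CD"),
    "AB_vs_DE": _task("AB", "DE"),
    "AB_vs_CE": _task("AB", "CE"),
}
"""The binary healthy-vs-epileptic tasks used in the two-view scenarios."""

SCENARIOS: List[Tuple[str, str, str, str]] = [
    ("DS1", "AB_vs_CDE", "WPD", "STFT"),
    ("DS2", "AB_vs_CDE", "WPD", "KPCA"),
    ("DS3", "AB_vs_CDE", "STFT", "KPCA"),
    ("DS4", "AB_vs_CD", "WPD", "STFT"),
    ("DS5", "AB_vs_CD", "WPD", "KPCA"),
    ("DS6", "AB_vs_CD", "STFT", "KPCA"),
    ("DS7", "AB_vs_DE", "WPD", "STFT"),
    ("DS8", "AB_vs_DE", "WPD", "KPCA"),
    ("DS9", "AB_vs_DE", "STFT", "KPCA"),
    ("DS10", "AB_vs_CE", "WPD", "STFT"),
    ("DS11", "AB_vs_DE", "WPD", "KPCA"),
    ("DS12", "AB_vs_CE", "STFT", "KPCA"),
]
"""The twelve (task, view-A, view-B) two-view learning scenarios."""


def read_segment(path, fs: float = BONN_FS, group: str = "synthetic") -> EEGSegment:
    """Parse a Bonn-style plain-text file: one sample per non-empty line.

    Raises ``ValueError`` (naming the offending line) on non-numeric content
    and on empty files.
    """
    path = Path(path)
    values: List[float] = []
    with path.open("r") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric value {text!r} on line {lineno}"
                ) from exc
    if not values:
        raise ValueError(f"{path}: file contains no samples")
    return EEGSegment(np.asarray(values), fs=fs, group=group, source_id=path.stem)


def load_group_dir(directory, group: str, fs: float = BONN_FS) -> List[EEGSegment]:
    """Read every ``*.txt``/``*.TXT`` file of one group directory, sorted by name."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".txt")
    if not paths:
        raise ValueError(f"{directory}: no .txt segment files found")
    return [read_segment(p, fs=fs, group=group) for p in paths]


def assemble_task(
    segments_by_group: Dict[str, Sequence[EEGSegment]], spec: TaskSpec
) -> Tuple[List[EEGSegment], np.ndarray]:
    """Concatenate the named groups into one labeled segment list.

    Negative groups receive label -1, positive groups +1.  The output order
    is deterministic: sorted by (group letter, source_id).
    """
    for g in spec.negative_groups + spec.positive_groups:
        if g not in segments_by_group or len(segments_by_group[g]) == 0:
            raise ValueError(f"group {g!r} is missing or empty")
    rows: List[Tuple[str, str, EEGSegment, float]] = []
    for g in spec.negative_groups:
        rows += [(g, s.source_id, s, -1.0) for s in segments_by_group[g]]
    for g in spec.positive_groups:
        rows += [(g, s.source_id, s, 1.0) for s in segments_by_group[g]]
    rows.sort(key=lambda r: (r[0], r[1]))
    segments = [r[2] for r in rows]
    labels = np.array([r[3] for r in rows])
    return segments, labels
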