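"""Block-design experimental timeline for two-level mental-workload sessions.

A session consists of an initial resting baseline, then for each workload
level a fixed number of alternating task/rest trials, with a short resting
delay separating the levels.  The schedule is the single source of truth for
sample labelling, epoching, the quality-control reference signal and the
synthetic-data generator.

Block intervals are half-open ``[onset, onset + duration)`` on a 0-based
time axis in seconds, so every sample of the 8 Hz grid belongs to exactly
one block.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Label",
    "TASK_LABELS",
    "Block",
    "ParadigmSchedule",
    "build_default_paradigm",
    "label_vector",
]


class Label(str, Enum):
    """Block/sample label: resting state or one of two workload levels."""

    REST = "rest"
    MWL1 = "mwl1"
    MWL2 = "mwl2"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Labels that denote an active mental-arithmetic task.
TASK_LABELS: tuple[Label, ...] = (Label.MWL1, Label.MWL2)


def _as_label(value: "Label | str") -> Label:
    if isinstance(value, Label):
        return value
    try:
        return Label(str(value))
    except ValueError as exc:
        raise ValueError(f"unknown block label: {value!r}") from exc


@dataclass(frozen=True)
class Block:
    """One contiguous labeled interval ``[onset, onset + duration)``."""

    label: Label
    onset: float
    duration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", _as_label(self.label))
        if self.onset < 0:
            raise ValueError(f"block onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"block duration must be > 0, got {self.duration}")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class ParadigmSchedule:
    """Ordered, contiguous, non-overlapping blocks on a shared time base."""

    blocks: tuple[Block, ...]
    sampling_rate: float = 8.0

    def __post_init__(self) -> None:
        blocks = tuple(self.blocks)
        object.__setattr__(self, "blocks", blocks)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not blocks:
            raise ValueError("schedule needs at least one block")
        t = 0.0
        for b in blocks:
            if not np.isclose(b.onset, t):
                raise ValueError(
                    f"blocks must be contiguous: expected onset {t}, got {b.onset}"
                )
            t = b.end

    @property
    def total_duration(self) -> float:
        """Total session length in seconds (sum of block durations)."""
        return float(sum(b.duration for b in self.blocks))

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sampling_rate))

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds on the acquisition grid."""
        return np.arange(self.n_samples) / self.sampling_rate

    @property
    def levels(self) -> tuple[Label, ...]:
        """Workload levels present, in order of first appearance."""
        seen: list[Label] = []
        for b in self.blocks:
            if b.label in TASK_LABELS and b.label not in seen:
                seen.append(b.label)
        return tuple(seen)

    def task_blocks(self, level: "Label | str | None" = None) -> tuple[Block, ...]:
        if level is not None:
            level = _as_label(level)
        return tuple(
            b
            for b in self.blocks
            if b.label in TASK_LABELS and (level is None or b.label == level)
        )

    def label_vector(self) -> np.ndarray:
        """Per-sample labels (string array of length ``n_samples``).

        The sample at time ``t`` takes the label of the block whose
        half-open interval contains ``t``; a sample exactly at a block
        boundary therefore belongs to the later block.
        """
        onsets = np.array([b.onset for b in self.blocks])
        idx = np.searchsorted(onsets, self.times, side="right") - 1
        labels = np.array([b.label.value for b in self.blocks], dtype=object)
        return labels[idx].astype("U4")

    def sample_slice(self, block: Block) -> slice:
        """Index range of a block's samples on the acquisition grid."""
        start = int(round(block.onset * self.sampling_rate))
        stop = int(round(block.end * self.sampling_rate))
        return slice(start, min(stop, self.n_samples))

    def to_events(self) -> pd.DataFrame:
        """Serialize as an (onset, duration, label) event table."""
        return pd.DataFrame(
            {
                "onset": [b.onset for b in self.blocks],
                "duration": [b.duration for b in self.blocks],
                "label": [b.label.value for b in self.blocks],
            }
        )

    @classmethod
    def from_events(
        cls, events: pd.DataFrame, sampling_rate: float = 8.0
    ) -> "ParadigmSchedule":
        blocks = tuple(
            Block(_as_label(row.label), float(row.onset), float(row.duration))
            for row in events.itertuples()
        )
        return cls(blocks=blocks, sampling_rate=sampling_rate)


def build_default_paradigm(
    levels: Sequence["Label | str"] = (Label.MWL1,),
    n_trials: int = 10,
    task_s: float = 20.0,
    rest_s: float = 20.0,
    baseline_s: float = 146.0,
    inter_level_delay_s: float = 25.0,
    sampling_rate: float = 8.0,
) -> ParadigmSchedule:
    """Build the standard block design of the study.

    A 146 s resting baseline is followed, for each workload level, by
    ``n_trials`` repetitions of ``task_s`` seconds of mental arithmetic and
    ``rest_s`` seconds of rest; consecutive levels are separated by a
    resting delay of ``inter_level_delay_s`` seconds.  With one level and
    the defaults the session lasts 146 + 10 x (20 + 20) = 546 s.

    The inter-level delay is labeled ``rest`` (it is a return to baseline).
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    for name, v in [
        ("task_s", task_s),
        ("rest_s", rest_s),
        ("baseline_s", baseline_s),
        ("inter_level_delay_s", inter_level_delay_s),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    level_labels = [_as_label(lv) for lv in levels]
    for lv in level_labels:
        if lv not in TASK_LABELS:
            raise ValueError(f"{lv} is not a workload level")

    blocks: list[Block] = []
    t = 0.0

    def push(label: Label, duration: float) -> None:
        nonlocal t
        if duration > 0:
            blocks.append(Block(label, t, duration))
            t += duration

    push(Label.REST, baseline_s)
    for i, lv in enumerate(level_labels):
        if i > 0:
            push(Label.REST, inter_level_delay_s)
        for _ in range(n_trials):
            push(lv, task_s)
            push(Label.REST, rest_s)
    if not blocks:
        raise ValueError("degenerate schedule: all durations are zero")
    return ParadigmSchedule(blocks=tuple(blocks), sampling_rate=sampling_rate)


def label_vector(schedule: ParadigmSchedule) -> np.ndarray:
    """Per-sample label sequence of a schedule (see the method of the same name)."""
    return schedule.label_vector()
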