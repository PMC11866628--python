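"""The Recording container: a labeled multichannel EEG segment.

A Recording is a channels x samples float array in microvolts with its
sampling rate, ordered channel labels, and the study metadata (subject,
condition, side, pre/post segment) needed to route it through the
pre/post x active/sham comparison.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np


class Condition(str, enum.Enum):
    ACTIVE = "active"
    SHAM = "sham"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Segment(str, enum.Enum):
    PRE = "pre"
    POST = "post"


@dataclass
class Recording:
    """channels x samples EEG data in microvolts with montage labels."""

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    subject_id: str = "s00"
    condition: Condition = Condition.SHAM
    side: Side = Side.LEFT
    segment: Segment = Segment.PRE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.labels = tuple(self.labels)
        self.condition = Condition(self.condition)
        self.side = Side(self.side)
        self.segment = Segment(self.segment)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with new samples, metadata unchanged."""
        return replace(self, data=np.asarray(data, dtype=float))

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy())

    @property
    def key(self) -> tuple[str, str, str, str]:
        """(subject, condition, side, segment) identity tuple."""
        return (
            self.subject_id,
            self.condition.value,
            self.side.value,
            self.segment.value,
        )
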