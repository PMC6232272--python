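"""Core containers shared across the pipeline.

The class order (W, N1, N2, N3, R) is fixed everywhere: hypnograms,
posterior matrices, confusion matrices and model outputs all use it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Canonical stage order used by every module.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")

STAGE_TO_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Channel roles of a four-channel PSG montage.
CHANNEL_ROLES: tuple[str, ...] = ("EEG", "EOG_L", "EOG_R", "EMG")


def stage_index(stage: str) -> int:
    """Index of ``stage`` in the canonical (W, N1, N2, N3, R) order."""
    try:
        return STAGE_TO_INDEX[stage]
    except KeyError:
        raise ValueError(f"unknown sleep stage {stage!r}; expected one of {STAGES}") from None


def stages_to_indices(stages: Sequence[str]) -> np.ndarray:
    return np.array([stage_index(s) for s in stages], dtype=np.int64)


def indices_to_stages(idx: Sequence[int]) -> list[str]:
    return [STAGES[int(i)] for i in idx]


@dataclass
class Channel:
    """One PSG channel: role, free-text label, samples in microvolt, rate."""

    role: str
    label: str
    samples: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        if self.role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {self.role!r}; expected one of {CHANNEL_ROLES}")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("channel samples must be a 1-D array")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


@dataclass
class Recording:
    """Multichannel PSG recording (EEG, EOG_L, EOG_R, EMG), units microvolt."""

    channels: list[Channel]

    def __post_init__(self) -> None:
        roles = [c.role for c in self.channels]
        if len(set(roles)) != len(roles):
            raise ValueError(f"channel roles must be unique, got {roles}")

    def channel(self, role: str) -> Channel:
        for c in self.channels:
            if c.role == role:
                return c
        raise KeyError(f"recording has no channel with role {role!r}; available: " f"{[c.role for c in self.channels]}")

    def has_channel(self, role: str) -> bool:
        return any(c.role == role for c in self.channels)

    @property
    def duration_s(self) -> float:
        return max(c.duration_s for c in self.channels)

    @property
    def roles(self) -> list[str]:
        return [c.role for c in self.channels]


@dataclass
class Hypnogram:
    """Per-epoch stage sequence with its epoch length in seconds.

    ``lights_off``/``lights_on`` are optional epoch indices marking the
    scored lights-out window (used by MSLT protocols).
    """

    stages: list[str]
    epoch_len_s: int
    lights_off: Optional[int] = None
    lights_on: Optional[int] = None

    def __post_init__(self) -> None:
        if self.epoch_len_s not in (20, 30):
            raise ValueError(f"epoch length must be 20 or 30 s, got {self.epoch_len_s}")
        if len(self.stages) < 1:
            raise ValueError("hypnogram must contain at least one epoch")
        for i, s in enumerate(self.stages):
            if s not in STAGE_TO_INDEX:
                raise ValueError(f"unknown stage {s!r} at epoch {i}")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> int:
        return len(self.stages) * self.epoch_len_s

    def as_indices(self) -> np.ndarray:
        return stages_to_indices(self.stages)

    @classmethod
    def from_indices(cls, idx: Sequence[int], epoch_len_s: int, **kw) -> "Hypnogram":
        return cls(indices_to_stages(idx), epoch_len_s, **kw)


def n_stage_transitions(stages: Sequence[str]) -> int:
    """Number of epoch boundaries where the stage changes."""
    return int(sum(a != b for a, b in zip(stages[:-1], stages[1:])))
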