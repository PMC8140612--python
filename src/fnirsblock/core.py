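"""Core containers: event schedules and multichannel recordings.

Every analysis stage transforms a :class:`Recording`.  The ``unit`` tag
tracks where the data sit in the optics chain (raw intensity -> optical
density -> molar hemoglobin), so mis-ordered pipeline calls fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from .montage import Montage

CONDITIONS = ("speech", "noise", "silence")


class Unit(str, Enum):
    RAW_INTENSITY = "raw_intensity"
    OPTICAL_DENSITY = "optical_density"
    MOLAR = "molar"  # ΔHbO / ΔHbR in μM


#: Row chroma tags after Beer-Lambert conversion.
HBO = "hbo"
HBR = "hbr"


@dataclass
class EventSchedule:
    """Condition-labelled stimulus onsets and durations (seconds)."""

    onsets: np.ndarray
    durations: np.ndarray
    conditions: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if not (len(self.onsets) == len(self.durations) == len(self.conditions)):
            raise ValueError("onsets, durations and conditions must have equal length")
        if len(self.onsets) and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        if np.any(self.durations <= 0):
            raise ValueError("event durations must be positive")

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def condition_set(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen

    def for_condition(self, condition: str) -> "EventSchedule":
        m = self.conditions == condition
        return EventSchedule(self.onsets[m], self.durations[m], self.conditions[m])

    def isi(self) -> np.ndarray:
        """Inter-stimulus intervals: offset of one event to the next onset."""
        if len(self) < 2:
            return np.empty(0)
        return self.onsets[1:] - (self.onsets[:-1] + self.durations[:-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset_s": self.onsets, "duration_s": self.durations, "condition": self.conditions}
        )

    @classmethod
    def empty(cls) -> "EventSchedule":
        return cls(np.empty(0), np.empty(0), np.empty(0, dtype=object))


@dataclass
class Recording:
    """A multichannel fNIRS time series plus montage and events.

    ``data`` has one row per (channel, chroma) pair in interleaved order:
    row ``2*ch`` is the first wavelength (or HbO), row ``2*ch + 1`` the
    second wavelength (or HbR).  ``row_chroma`` names the per-row tag
    ("760"/"850" nm before conversion, "hbo"/"hbr" after).  Molar data are
    in μM.
    """

    data: np.ndarray
    sfreq: float
    unit: Unit
    montage: Montage
    events: EventSchedule = field(default_factory=EventSchedule.empty)
    row_chroma: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        n_rows = 2 * self.montage.n_channels
        if self.data.shape[0] != n_rows:
            raise ValueError(
                f"expected {n_rows} rows (2 per channel) but data has {self.data.shape[0]}"
            )
        if not self.row_chroma:
            wl = self.montage.wavelengths
            if self.unit is Unit.MOLAR:
                tags = (HBO, HBR)
            else:
                tags = (f"{wl[0]:g}", f"{wl[1]:g}")
            self.row_chroma = list(tags) * self.montage.n_channels
        if len(self.row_chroma) != n_rows:
            raise ValueError("row_chroma length must equal number of rows")
        if self.unit is Unit.RAW_INTENSITY and np.any(self.data <= 0):
            bad = np.unique(np.where(self.data <= 0)[0] // 2)
            raise ValueError(f"raw intensity must be strictly positive (channels {bad.tolist()})")
        if len(self.events) and np.any(self.events.onsets >= self.duration):
            raise ValueError("event onsets must fall within the recording")

    # -- basic geometry ---------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.montage.n_channels

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    def rows_for_channel(self, ch: int) -> tuple[int, int]:
        return 2 * ch, 2 * ch + 1

    def row_channel(self, row: int) -> int:
        return row // 2

    def channel_rows(self, channels: list[int]) -> np.ndarray:
        return np.array([r for c in channels for r in self.rows_for_channel(c)], dtype=int)

    def rows_for_chroma(self, chroma: str) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.row_chroma) if t == chroma], dtype=int)

    # -- manipulation -----------------------------------------------------

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            row_chroma=list(self.row_chroma),
        )

    def with_data(self, data: np.ndarray, unit: Unit | None = None,
                  row_chroma: list[str] | None = None) -> "Recording":
        return Recording(
            data=data,
            sfreq=self.sfreq,
            unit=unit or self.unit,
            montage=self.montage,
            events=self.events,
            row_chroma=row_chroma if row_chroma is not None else list(self.row_chroma),
        )

    def pick_channels(self, channels: list[int]) -> "Recording":
        """Keep only the given channels (montage subset, ROI map remapped)."""
        rows = self.channel_rows(channels)
        return Recording(
            data=self.data[rows],
            sfreq=self.sfreq,
            unit=self.unit,
            montage=self.montage.subset(channels),
            events=self.events,
            row_chroma=[self.row_chroma[r] for r in rows],
        )

    def require_unit(self, unit: Unit, op: str) -> None:
        if self.unit is not unit:
            raise ValueError(
                f"{op} requires unit={unit.value!r} but recording is {self.unit.value!r}"
            )
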