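"""Sampling timeline for a multi-day drift time series.

All times-of-day are real hours on a 24-h clock in [0, 24):
11 a.m. = 11.0, 11 p.m. = 23.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Timeline:
    """Sample times of a drift expression time series.

    Parameters
    ----------
    sample_times
        Hours on a continuous axis from the first sample (0, 4, 8, ...).
        Must be strictly increasing.
    start_clock
        Local time-of-day of the first sample, hours in [0, 24).
    dawn, dusk
        Representative local dawn / dusk time-of-day (hours). The drift
        spans only a few days, over which dawn moves by minutes, so a
        single value per analysis is used.
    """

    sample_times: np.ndarray
    start_clock: float = 10.0
    dawn: float = 6.9
    dusk: float = 19.0

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        object.__setattr__(self, "sample_times", t)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("sample_times must be a non-empty 1-D array")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if not (0.0 <= self.start_clock < 24.0):
            raise ValueError(f"start_clock must be in [0, 24), got {self.start_clock}")
        if not (0.0 <= self.dawn < 24.0 and 0.0 <= self.dusk < 24.0):
            raise ValueError("dawn and dusk must be in [0, 24)")
        if not self.dawn < self.dusk:
            raise ValueError(f"dawn ({self.dawn}) must precede dusk ({self.dusk}) within a day")

    @property
    def n_samples(self) -> int:
        return int(self.sample_times.size)

    @property
    def clock_times(self) -> np.ndarray:
        """Local time-of-day of each sample, hours in [0, 24)."""
        return (self.start_clock + self.sample_times) % 24.0

    @property
    def sample_labels(self) -> list[str]:
        """Labels like ``d1_1000``: drift day and HHMM clock time."""
        days = ((self.start_clock + self.sample_times) // 24.0).astype(int) + 1
        labels = []
        for day, clock in zip(days, self.clock_times):
            hh = int(clock)
            mm = int(round((clock - hh) * 60))
            if mm == 60:  # guard against float rounding at the hour
                hh, mm = (hh + 1) % 24, 0
            labels.append(f"d{day}_{hh:02d}{mm:02d}")
        return labels

    @classmethod
    def drift_default(cls) -> "Timeline":
        """The study design: 16 samples at 4-h spacing spanning ~2.6 days,
        starting mid-morning, with late-September dawn/dusk."""
        return cls(sample_times=np.arange(16) * 4.0)

    def to_dict(self) -> dict:
        return {
            "sample_times": [float(x) for x in self.sample_times],
            "start_clock": self.start_clock,
            "dawn": self.dawn,
            "dusk": self.dusk,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Timeline":
        return cls(
            sample_times=np.asarray(d["sample_times"], dtype=float),
            start_clock=float(d.get("start_clock", 10.0)),
            dawn=float(d.get("dawn", 6.9)),
            dusk=float(d.get("dusk", 19.0)),
        )
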