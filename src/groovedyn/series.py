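"""Time-stamped scalar series (angles in degrees, lengths in Å)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = ["TimeSeries", "AngleSeries"]


@dataclass
class TimeSeries:
    """Per-frame scalar observable with times in μs."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ConfigError("times and values must be 1-D arrays of equal length")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ConfigError("series times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_us": self.times, self.label or "value": self.values})


@dataclass
class AngleSeries(TimeSeries):
    """Deviation-angle series; values constrained to [0, 180] degrees."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if len(self.values) and (
            self.values.min() < 0.0 or self.values.max() > 180.0
        ):
            raise ConfigError("angle values must lie in [0, 180] degrees")
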