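"""The GrowthSeries container: one observed or simulated time-biomass dataset."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import SeriesError

__all__ = ["GrowthSeries"]


@dataclass(frozen=True)
class GrowthSeries:
    """An ordered time-biomass series.

    Parameters
    ----------
    times : array_like
        Observation times in days, strictly increasing.
    biomass : array_like
        Dry-mass observations in grams, non-negative, same length as
        ``times``.  At least 2 points (fitting requires >= 5).
    label : str
        Free-text species / series identifier.
    """

    times: np.ndarray
    biomass: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.biomass, dtype=float)
        if t.ndim != 1 or w.ndim != 1:
            raise SeriesError("times and biomass must be one-dimensional")
        if t.size != w.size:
            raise SeriesError(
                f"length mismatch: {t.size} times vs {w.size} biomass values"
            )
        if t.size < 2:
            raise SeriesError(f"need at least 2 observations, got {t.size}")
        if not np.isfinite(t).all() or not np.isfinite(w).all():
            raise SeriesError("times and biomass must be finite")
        if np.any(np.diff(t) <= 0):
            raise SeriesError("times must be strictly increasing")
        if np.any(w < 0):
            raise SeriesError("biomass values must be non-negative")
        t.setflags(write=False)
        w.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "biomass", w)

    @property
    def n(self) -> int:
        return int(self.times.size)

    def __len__(self) -> int:
        return self.n

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_column: str = "time",
        biomass_column: str = "biomass",
        label: str = "",
    ) -> "GrowthSeries":
        for col in (time_column, biomass_column):
            if col not in df.columns:
                raise SeriesError(f"column {col!r} not found in dataframe")
        return cls(
            df[time_column].to_numpy(dtype=float),
            df[biomass_column].to_numpy(dtype=float),
            label=label,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "biomass": self.biomass})
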