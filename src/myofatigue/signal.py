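"""Uniformly sampled single-channel time series."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples
        Signal values, in mV for SEMG.
    fs
        Sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def to_csv(self, path: str | Path) -> None:
        """Write the signal as CSV with columns ``time_s, value_mV``."""
        pd.DataFrame({"time_s": self.t, "value_mV": self.samples}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Signal":
        """Read a signal written by :meth:`to_csv`."""
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ValueError("need at least two samples to infer the sampling rate")
        fs = 1.0 / float(np.median(np.diff(t)))
        return cls(df["value_mV"].to_numpy(), fs)
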