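"""Windowed SEMG fatigue features.

Time domain: integrated EMG (IEMG, the time integral of the rectified
signal, mV·s) and root-mean-square amplitude (RMS, mV).  Frequency domain:
mean power frequency (MPF, Hz), the spectral centroid of the Welch power
spectrum restricted to the analysis band.  During fatiguing contractions
IEMG and RMS rise with motor-unit recruitment while MPF stays comparatively
flat, so their windowed trajectories are the monitoring signal.

IEMG integrates the rectified signal |x(t)|: without rectification the
integral of a zero-mean signal would vanish and carry no recruitment
information.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import welch

from myofatigue.signal import Signal

DEFAULT_BAND = (20.0, 500.0)


@dataclass(frozen=True)
class Window:
    """One analysis window: samples (mV), sampling rate, start time and
    duration."""

    samples: np.ndarray
    fs: float
    t_start: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.size < 2:
            raise ValueError("window must contain at least 2 samples")

    @property
    def T(self) -> float:
        return self.samples.size / self.fs


@dataclass
class FeatureSeries:
    """Windowed feature trajectories: start times (s), IEMG (mV·s),
    RMS (mV) and MPF (Hz), all equal length."""

    t: np.ndarray
    iemg: np.ndarray
    rms: np.ndarray
    mpf: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.iemg = np.asarray(self.iemg, float)
        self.rms = np.asarray(self.rms, float)
        self.mpf = np.asarray(self.mpf, float)
        if not (len(self.t) == len(self.iemg) == len(self.rms) == len(self.mpf)):
            raise ValueError("feature arrays must have equal length")

    def __len__(self) -> int:
        return len(self.t)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"t_start_s": self.t, "iemg_mVs": self.iemg,
             "rms_mV": self.rms, "mpf_Hz": self.mpf}
        ).to_csv(path, index=False)


def segment(signal: Signal, window_s: float = 1.0,
            overlap_fraction: float = 0.5) -> list[Window]:
    """Slice a signal into fixed-length windows.

    Consecutive windows advance by ``window_s * (1 - overlap_fraction)``;
    a trailing partial window is dropped.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    wlen = int(round(window_s * signal.fs))
    if wlen < 2:
        raise ValueError("window too short: need window_s * fs >= 2")
    step = max(1, int(round(wlen * (1 - overlap_fraction))))
    out = []
    for start in range(0, len(signal) - wlen + 1, step):
        out.append(Window(signal.samples[start: start + wlen], signal.fs,
                          start / signal.fs))
    return out


def iemg(window: Window) -> float:
    """Integrated EMG: trapezoidal integral of |x(t)| over the window (mV·s)."""
    return float(np.trapezoid(np.abs(window.samples), dx=1.0 / window.fs))


def rms(window: Window) -> float:
    """RMS amplitude sqrt((1/T)·∫ x² dt), trapezoidal integration (mV)."""
    integral = np.trapezoid(window.samples**2, dx=1.0 / window.fs)
    # trapezoidal T spans N-1 intervals
    T = (window.samples.size - 1) / window.fs
    return float(np.sqrt(integral / T))


def mpf(window: Window, band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Mean power frequency: spectral centroid ∫f·PS df / ∫PS df of the
    Welch power spectrum restricted to ``band`` (Hz)."""
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError("band must satisfy 0 < min < max")
    if lo >= window.fs / 2:
        raise ValueError("band must lie inside (0, fs/2)")
    f, ps = welch(window.samples, fs=window.fs, window="hann",
                  nperseg=window.samples.size)
    sel = (f >= lo) & (f <= hi)
    total = np.sum(ps[sel])
    if total <= 0:
        raise ValueError("zero in-band power; MPF undefined")
    return float(np.sum(f[sel] * ps[sel]) / total)


def compute_feature_series(signal: Signal, window_s: float = 1.0,
                           overlap: float = 0.5,
                           band: tuple[float, float] = DEFAULT_BAND) -> FeatureSeries:
    """IEMG/RMS/MPF per window over the whole signal."""
    wins = segment(signal, window_s, overlap)
    return FeatureSeries(
        t=np.array([w.t_start for w in wins]),
        iemg=np.array([iemg(w) for w in wins]),
        rms=np.array([rms(w) for w in wins]),
        mpf=np.array([mpf(w, band) for w in wins]),
    )
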