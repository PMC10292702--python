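"""Wavelet-threshold SEMG denoising.

Detail coefficients below a threshold λ are treated as noise.  Three
shrinkage rules are provided: *hard* (keep-or-kill), *soft* (kill and shrink
survivors by λ), and an *improved* rule that interpolates between them —
continuous at |w| = λ like soft thresholding, but asymptotically unbiased
like hard thresholding, with a shape parameter k steering between the two
(k → ∞ recovers hard thresholding).

λ follows the universal-threshold rule λ = σ·sqrt(2 ln N) with the noise
scale σ estimated robustly from the median absolute finest-level detail
coefficient divided by 0.6745 (the normal-consistency constant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pywt

from myofatigue.signal import Signal

ThresholdMode = Literal["hard", "soft", "improved"]

#: median(|Z|) for a standard normal Z — makes the MAD estimator consistent.
MAD_NORMAL = 0.6745


@dataclass
class WaveletDecomposition:
    """Multi-level DWT of a signal.

    ``details`` is ordered finest → coarsest; ``N`` is the original signal
    length so reconstruction can be truncated back to it.
    """

    wavelet_name: str
    levels: int
    approx: np.ndarray
    details: list[np.ndarray]
    N: int

    @classmethod
    def decompose(cls, signal: Signal, wavelet_name: str = "db4",
                  levels: int = 4) -> "WaveletDecomposition":
        if levels < 1:
            raise ValueError("levels must be >= 1")
        if len(signal) < 2**levels:
            raise ValueError(
                f"signal of length {len(signal)} too short for {levels} levels"
            )
        coeffs = pywt.wavedec(signal.samples, wavelet_name, level=levels,
                              mode="symmetric")
        approx, details_coarse_first = coeffs[0], coeffs[1:]
        return cls(wavelet_name, levels, approx,
                   details_coarse_first[::-1], len(signal))

    def reconstruct(self, fs: float) -> Signal:
        coeffs = [self.approx] + list(self.details[::-1])
        rec = pywt.waverec(coeffs, self.wavelet_name, mode="symmetric")
        return Signal(rec[: self.N], fs)

    @property
    def finest_details(self) -> np.ndarray:
        return self.details[0]


@dataclass(frozen=True)
class ThresholdParams:
    """Shrinkage rule: threshold ``lam``, shape ``k`` (improved rule only),
    and mode in {hard, soft, improved}."""

    lam: float
    k: float = 2.0
    mode: ThresholdMode = "improved"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.mode not in ("hard", "soft", "improved"):
            raise ValueError(f"unknown mode {self.mode!r}")


def estimate_noise_sigma(finest_details: np.ndarray) -> float:
    """Robust noise scale: median(|w|) / 0.6745 over the finest-level
    detail coefficients."""
    w = np.asarray(finest_details, dtype=float)
    if w.size == 0:
        raise ValueError("empty coefficient vector")
    return float(np.median(np.abs(w)) / MAD_NORMAL)


def universal_threshold(sigma: float, N: int) -> float:
    """Universal threshold λ = σ·sqrt(2 ln N)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if N < 2:
        raise ValueError("N must be >= 2")
    return float(sigma * np.sqrt(2.0 * np.log(N)))


def apply_threshold(w: np.ndarray | float, params: ThresholdParams) -> np.ndarray | float:
    """Apply the selected shrinkage rule elementwise.

    Improved rule (continuous at |w| = λ, odd, and squeezed between soft and
    hard)::

        |w| >= λ:  W = w - sign(w) * k * λ**(k+1) / ((k+1) * |w|**k)
        |w| <  λ:  W = sign(w) * |w|**(k+1) / ((k+1) * λ**k)
    """
    scalar = np.isscalar(w)
    w = np.asarray(w, dtype=float)
    lam, k = params.lam, params.k
    aw = np.abs(w)
    sw = np.sign(w)
    if params.mode == "hard":
        out = np.where(aw >= lam, w, 0.0)
    elif params.mode == "soft":
        out = np.where(aw >= lam, sw * (aw - lam), 0.0)
    else:
        if lam == 0:
            out = w.copy()
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                big = w - sw * k * lam ** (k + 1) / ((k + 1) * aw**k)
                small = sw * aw ** (k + 1) / ((k + 1) * lam**k)
            out = np.where(aw >= lam, big, small)
    return float(out) if scalar else out


def denoise(signal: Signal, wavelet_name: str = "db4", levels: int = 4,
            params: ThresholdParams | None = None,
            mode: ThresholdMode = "improved", k: float = 2.0) -> Signal:
    """Wavelet-threshold denoising.

    Decomposes the signal, estimates σ from the finest-level details,
    computes λ = σ·sqrt(2 ln N) with N the signal length, shrinks every
    detail level with the selected rule (the approximation is untouched),
    and reconstructs.  If ``params`` is given its λ is used verbatim.
    """
    dec = WaveletDecomposition.decompose(signal, wavelet_name, levels)
    if params is None:
        sigma = estimate_noise_sigma(dec.finest_details)
        lam = universal_threshold(sigma, len(signal))
        params = ThresholdParams(lam=lam, k=k, mode=mode)
    dec.details = [np.asarray(apply_threshold(d, params)) for d in dec.details]
    return dec.reconstruct(signal.fs)


def snr(clean: Signal | np.ndarray, estimate: Signal | np.ndarray) -> float:
    """Signal-to-noise ratio 10·log10(Σ clean² / Σ (clean − estimate)²) in dB;
    +inf when the estimate equals the clean signal exactly."""
    c = clean.samples if isinstance(clean, Signal) else np.asarray(clean, float)
    e = estimate.samples if isinstance(estimate, Signal) else np.asarray(estimate, float)
    if c.shape != e.shape:
        raise ValueError("length mismatch")
    if not np.any(c):
        raise ValueError("clean signal is identically zero")
    err = np.sum((c - e) ** 2)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(np.sum(c**2) / err))


def rmse(clean: Signal | np.ndarray, estimate: Signal | np.ndarray) -> float:
    """Root-mean-square error between clean and estimate."""
    c = clean.samples if isinstance(clean, Signal) else np.asarray(clean, float)
    e = estimate.samples if isinstance(estimate, Signal) else np.asarray(estimate, float)
    if c.shape != e.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((c - e) ** 2)))


# ---------------------------------------------------------------------------
# benchmark
# ---------------------------------------------------------------------------


def benchmark(seed: int = 0, replicates: int = 20, k: float = 2.0,
              duration_s: float = 5.0,
              modes: tuple[ThresholdMode, ...] = ("hard", "soft", "improved")):
    """Seeded denoising benchmark on the standard synthetic SEMG mixture.

    Each replicate: a clean surrogate SEMG (≈1 mV RMS) contaminated with
    heavy white noise (σ = 2.0 mV), 50 Hz power line (0.3 mV) and 0.5 Hz
    baseline wander (0.3 mV) is denoised with each threshold mode; returns
    a DataFrame with columns ``mode, SNR_dB, RMSE`` of per-mode means.

    The benchmark operates in the noise-dominated regime: the surrogate SEMG
    is itself a band-limited Gaussian process, so its wavelet representation
    is not sparse and threshold denoising pays off only when the noise
    dominates the detail scales — which is also the regime the universal
    threshold rule assumes.
    """
    from myofatigue.synthetic import FatigueProfile, NoiseSpec, add_noise, \
        generate_clean_semg

    import pandas as pd

    rng = np.random.default_rng(seed)
    rows: dict[str, dict[str, list[float]]] = {
        m: {"snr": [], "rmse": []} for m in modes
    }
    for _ in range(replicates):
        s1, s2 = int(rng.integers(2**31)), int(rng.integers(2**31))
        profile = FatigueProfile(duration_s=duration_s, rms_start=1.0, rms_end=1.0)
        clean = generate_clean_semg(profile, seed=s1)
        noisy, _ = add_noise(clean, NoiseSpec(white_sigma=2.0, powerline_amp=0.3,
                                              baseline_amp=0.3, seed=s2))
        for m in modes:
            den = denoise(noisy, mode=m, k=k)
            rows[m]["snr"].append(snr(clean, den))
            rows[m]["rmse"].append(rmse(clean, den))
    return pd.DataFrame(
        {
            "mode": list(modes),
            "SNR_dB": [float(np.mean(rows[m]["snr"])) for m in modes],
            "RMSE": [float(np.mean(rows[m]["rmse"])) for m in modes],
        }
    )
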