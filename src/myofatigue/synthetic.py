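"""Ground-truthed synthetic SEMG signals and layered speckle phantoms.

The SEMG surrogate is band-limited Gaussian noise (20–450 Hz at fs = 1000 Hz,
leaving a guard band below Nyquist) whose windowed RMS ramps linearly over
the recording and whose spectral centre can drift, mimicking the amplitude
rise with near-constant mean power frequency seen during fatiguing
contractions.  Contamination (white noise, 50 Hz power line, slow baseline
wander) is added separately so the clean reference stays available for
SNR/RMSE benchmarking.

The ultrasound surrogate is a two-muscle-layer B-mode phantom: piecewise
constant echogenicity by depth multiplied by a unit-mean Rayleigh speckle
field, with known layer-boundary depths and a constant per-frame axial
shift, so tracking and thickness estimates can be checked against ground
truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import signal as sps

from myofatigue.signal import Signal

#: Synthesis band (Hz).  The upper edge is kept at 450 Hz rather than the
#: 500 Hz acquisition band edge so a 4th-order band-pass at fs = 1000 Hz has
#: a guard band below Nyquist and no aliased edge effects.
SYNTH_BAND = (20.0, 450.0)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FatigueProfile:
    """Target trajectory of the surrogate SEMG over a recording.

    RMS ramps linearly from ``rms_start`` to ``rms_end`` (mV); the spectral
    centre drifts linearly from ``mpf_start`` to ``mpf_end`` (Hz).
    """

    duration_s: float
    rms_start: float = 0.5
    rms_end: float = 1.5
    mpf_start: float = 120.0
    mpf_end: float = 120.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.rms_start <= 0 or self.rms_end <= 0:
            raise ValueError("rms values must be positive")
        for f in (self.mpf_start, self.mpf_end):
            if not 20.0 <= f <= 500.0:
                raise ValueError("mpf values must lie in [20, 500] Hz")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive contamination: white Gaussian noise, 50 Hz power-line
    interference, and slow (0.5 Hz) baseline wander.  Amplitudes in mV."""

    white_sigma: float = 0.0
    powerline_amp: float = 0.0
    baseline_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.white_sigma, self.powerline_amp, self.baseline_amp) < 0:
            raise ValueError("noise amplitudes must be non-negative")


POWERLINE_HZ = 50.0
BASELINE_HZ = 0.5


@dataclass(frozen=True)
class PhantomSpec:
    """Two-muscle-layer speckle phantom.

    Depth increases with row index.  Three boundary depths (mm) delimit the
    surface muscle (surface → deep boundary) and the deep muscle (deep →
    bottom boundary); tissue above the surface boundary and below the bottom
    boundary gets the outer echogenicity levels.  ``layer_mean_echogenicity``
    gives the mean 8-bit gray level of the four depth bands, top to bottom.
    ``frame_displacement_mm`` shifts all boundaries deeper by that amount per
    frame.  ``speckle_grain_px`` sets the speckle cell size in pixels
    (coarser grain → smoother texture).
    """

    height_px: int = 200
    width_px: int = 200
    pixel_spacing_mm: float = 0.1
    surface_boundary_mm: float = 2.0
    deep_boundary_mm: float = 8.0
    bottom_boundary_mm: float = 16.0
    layer_mean_echogenicity: tuple[float, float, float, float] = (40.0, 120.0, 80.0, 160.0)
    speckle_scale: float = 0.3
    speckle_grain_px: int = 1
    frame_displacement_mm: float = 0.0
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        depth_mm = self.height_px * self.pixel_spacing_mm
        if not (0 < self.surface_boundary_mm < self.deep_boundary_mm
                < self.bottom_boundary_mm <= depth_mm):
            raise ValueError(
                "boundaries must satisfy 0 < surface < deep < bottom <= image depth"
            )
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if len(self.layer_mean_echogenicity) != 4:
            raise ValueError("layer_mean_echogenicity needs 4 levels (top to bottom)")
        if self.speckle_scale < 0:
            raise ValueError("speckle_scale must be non-negative")
        if self.speckle_grain_px < 1:
            raise ValueError("speckle_grain_px must be >= 1")
        # every boundary must stay inside the image for the whole sequence
        final_bottom = (self.bottom_boundary_mm
                        + (self.n_frames - 1) * self.frame_displacement_mm)
        if final_bottom > depth_mm or (
            self.surface_boundary_mm
            + (self.n_frames - 1) * min(self.frame_displacement_mm, 0.0) <= 0
        ):
            raise ValueError("boundaries leave the image during the sequence")


@dataclass
class FrameSequence:
    """Ordered grayscale frames with pixel spacing and optional per-frame
    ground-truth boundary depths (mm), shape (n_frames, 3)."""

    frames: np.ndarray  # (n, H, W) uint8
    pixel_spacing_mm: float
    boundaries_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (n, height, width)")
        if self.boundaries_mm is not None:
            self.boundaries_mm = np.asarray(self.boundaries_mm, dtype=float)
            if self.boundaries_mm.shape != (len(self.frames), 3):
                raise ValueError("boundaries_mm must have shape (n_frames, 3)")

    def __len__(self) -> int:
        return len(self.frames)

    def to_tiff(self, path: str | Path) -> None:
        """Write a multi-page TIFF plus a JSON sidecar (``<path>.json``)
        carrying pixel spacing and ground-truth boundaries."""
        path = Path(path)
        tifffile.imwrite(path, self.frames, photometric="minisblack")
        sidecar = {"pixel_spacing_mm": self.pixel_spacing_mm}
        if self.boundaries_mm is not None:
            sidecar["boundaries_mm"] = self.boundaries_mm.tolist()
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "FrameSequence":
        path = Path(path)
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        sidecar_path = Path(str(path) + ".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar_path}")
        sidecar = json.loads(sidecar_path.read_text())
        if "pixel_spacing_mm" not in sidecar:
            raise KeyError("sidecar is missing required field 'pixel_spacing_mm'")
        boundaries = sidecar.get("boundaries_mm")
        return cls(
            frames,
            float(sidecar["pixel_spacing_mm"]),
            None if boundaries is None else np.asarray(boundaries),
        )


@dataclass
class LabeledWindowSet:
    """Fixed-length SEMG windows with binary fatigue labels
    (0 = non-fatigued, 1 = fatigued)."""

    windows: np.ndarray  # (n, window_len)
    labels: np.ndarray  # (n,) in {0, 1}
    fs: float

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.windows.ndim != 2:
            raise ValueError("windows must be a 2-D array (n, window_len)")
        if len(self.windows) != len(self.labels):
            raise ValueError("windows and labels must have equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.labels)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.windows)
        df.insert(0, "label", self.labels)
        df.insert(0, "fs", self.fs)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledWindowSet":
        import pandas as pd

        df = pd.read_csv(path)
        fs = float(df.pop("fs").iloc[0])
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(), labels, fs)


# ---------------------------------------------------------------------------
# SEMG generation
# ---------------------------------------------------------------------------


def _bandpass_sos(low: float, high: float, fs: float) -> np.ndarray:
    return sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def _band_for_centre(centre: float, fs: float) -> tuple[float, float]:
    """Symmetric pass band around ``centre`` clipped to the synthesis band."""
    half = 100.0
    low = max(SYNTH_BAND[0], centre - half)
    high = min(SYNTH_BAND[1], centre + half, fs / 2 * 0.98)
    if high <= low:
        raise ValueError("requested spectral centre leaves no usable band")
    return low, high


def generate_clean_semg(profile: FatigueProfile, fs: float = 1000.0,
                        seed: int = 0) -> Signal:
    """Generate a clean surrogate SEMG signal.

    Zero-mean Gaussian noise is band-pass filtered (4th-order Butterworth,
    zero phase) around a spectral centre that ramps ``mpf_start → mpf_end``,
    then amplitude-modulated so the windowed RMS ramps linearly
    ``rms_start → rms_end``.  Deterministic given ``seed``.
    """
    if fs < 2 * SYNTH_BAND[1]:
        raise ValueError(f"fs must be at least {2 * SYNTH_BAND[1]} Hz")
    n = int(round(profile.duration_s * fs))
    if n < 8:
        raise ValueError("duration too short for synthesis")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)

    if profile.mpf_start == profile.mpf_end:
        low, high = _band_for_centre(profile.mpf_start, fs)
        x = sps.sosfiltfilt(_bandpass_sos(low, high, fs), white)
    else:
        # time-varying spectrum: filter the same noise through per-block
        # band-passes and cross-fade with a 50%-overlap Hann window
        block = max(int(fs), 256)
        hop = block // 2
        starts = range(0, max(n - hop, 1), hop)
        x = np.zeros(n)
        norm = np.zeros(n)
        for s in starts:
            e = min(s + block, n)
            mid = (s + e) / 2 / n
            centre = profile.mpf_start + (profile.mpf_end - profile.mpf_start) * mid
            low, high = _band_for_centre(centre, fs)
            filt = sps.sosfiltfilt(_bandpass_sos(low, high, fs), white)
            w = np.hanning(e - s) + 1e-12
            x[s:e] += filt[s:e] * w
            norm[s:e] += w
        x /= norm

    x -= x.mean()
    x /= x.std()
    ramp = np.linspace(profile.rms_start, profile.rms_end, n)
    return Signal(x * ramp, fs)


def add_noise(clean: Signal, spec: NoiseSpec) -> tuple[Signal, Signal]:
    """Contaminate ``clean`` with white noise, 50 Hz interference and 0.5 Hz
    baseline wander; returns ``(noisy, clean_ref)`` with the clean reference
    unmodified so denoising can be scored against known truth."""
    if len(clean) == 0:
        raise ValueError("clean signal must be non-empty")
    rng = np.random.default_rng(spec.seed)
    t = clean.t
    noise = spec.white_sigma * rng.standard_normal(len(clean))
    phi = rng.uniform(0, 2 * np.pi)
    noise += spec.powerline_amp * np.sin(2 * np.pi * POWERLINE_HZ * t + phi)
    phi_b = rng.uniform(0, 2 * np.pi)
    noise += spec.baseline_amp * np.sin(2 * np.pi * BASELINE_HZ * t + phi_b)
    return Signal(clean.samples + noise, clean.fs), clean


def generate_labeled_windows(
    n_per_class: int,
    window_len: int,
    class_profiles: tuple[FatigueProfile, FatigueProfile],
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    fs: float = 1000.0,
) -> LabeledWindowSet:
    """Generate ``2 * n_per_class`` labeled SEMG windows.

    Class 0 windows are drawn from the first (non-fatigued) profile, class 1
    from the second (fatigued) profile; the combined set is shuffled
    deterministically by ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    rng = np.random.default_rng(seed)
    windows, labels = [], []
    for label, profile in enumerate(class_profiles):
        dur = n_per_class * window_len / fs
        prof = FatigueProfile(
            duration_s=dur,
            rms_start=profile.rms_start,
            rms_end=profile.rms_end,
            mpf_start=profile.mpf_start,
            mpf_end=profile.mpf_end,
        )
        clean = generate_clean_semg(prof, fs=fs,
                                    seed=int(rng.integers(2**31)))
        nspec = NoiseSpec(noise.white_sigma, noise.powerline_amp,
                          noise.baseline_amp, seed=int(rng.integers(2**31)))
        noisy, _ = add_noise(clean, nspec)
        w = noisy.samples[: n_per_class * window_len].reshape(n_per_class, window_len)
        windows.append(w)
        labels.append(np.full(n_per_class, label))
    windows = np.concatenate(windows)
    labels = np.concatenate(labels)
    order = rng.permutation(len(labels))
    return LabeledWindowSet(windows[order], labels[order], fs)


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------


def _speckle_field(shape: tuple[int, int], scale: float, grain_px: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-mean multiplicative speckle: a Rayleigh field rescaled to mean 1
    and blended as ``1 + scale * (R - 1)``; grain_px sets the cell size."""
    if scale == 0:
        return np.ones(shape)
    h = -(-shape[0] // grain_px)
    w = -(-shape[1] // grain_px)
    raw = rng.rayleigh(scale=1.0, size=(h, w))
    raw /= np.sqrt(np.pi / 2)  # Rayleigh(1) mean
    if grain_px > 1:
        raw = np.kron(raw, np.ones((grain_px, grain_px)))
    raw = raw[: shape[0], : shape[1]]
    return 1.0 + scale * (raw - 1.0)


def generate_phantom_sequence(spec: PhantomSpec) -> FrameSequence:
    """Generate a layered speckle phantom sequence with ground truth.

    Each frame is the piecewise-constant depth profile of layer
    echogenicities multiplied by a frozen unit-mean speckle field; the whole
    tissue (profile and speckle alike) shifts axially by
    ``frame_displacement_mm`` per frame, so block-matching trackers see a
    consistent moving texture.  Ground-truth boundary depths are attached
    per frame.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height_px, spec.width_px
    disp_px_f = spec.frame_displacement_mm / spec.pixel_spacing_mm
    max_shift = int(np.ceil(abs(disp_px_f) * (spec.n_frames - 1)))
    pad = max_shift + 1

    # static tissue in extended depth coordinates; frame k samples it at an
    # offset so structures move deeper by disp_px per frame
    ext_rows = np.arange(-pad, H + pad)
    depth_mm = (ext_rows + 0.5) * spec.pixel_spacing_mm
    levels = np.asarray(spec.layer_mean_echogenicity, dtype=float)
    idx = np.searchsorted(
        [spec.surface_boundary_mm, spec.deep_boundary_mm, spec.bottom_boundary_mm],
        depth_mm, side="left",
    )
    profile = levels[idx][:, None] * np.ones((1, W))
    speckle = _speckle_field(profile.shape, spec.speckle_scale,
                             spec.speckle_grain_px, rng)
    tissue = profile * speckle

    frames = np.empty((spec.n_frames, H, W), dtype=np.uint8)
    boundaries = np.empty((spec.n_frames, 3))
    for k in range(spec.n_frames):
        shift = int(round(k * disp_px_f))
        # tissue moved deeper by `shift` rows: frame row r shows tissue row r-shift
        top = pad - shift
        frames[k] = np.clip(np.round(tissue[top: top + H]), 0, 255).astype(np.uint8)
        boundaries[k] = (
            np.array([spec.surface_boundary_mm, spec.deep_boundary_mm,
                      spec.bottom_boundary_mm])
            + k * spec.frame_displacement_mm
        )
    return FrameSequence(frames, spec.pixel_spacing_mm, boundaries)
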