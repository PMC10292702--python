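"""Ultrasound muscle-image analysis.

Block matching by normalized cross-correlation (NCC) tracks a manually
selected region of interest (ROI) — e.g. a patch straddling a fascial
boundary — through a B-mode frame sequence.  Layer-boundary rows converted
by the pixel spacing give surface, deep and total muscle thickness.  Texture
is summarised by gray-level co-occurrence matrix (GLCM) features: angular
second moment (ASM, energy/uniformity), contrast (local variation) and
homogeneity (HOM, inverse difference moment).

Conventions: row-major, 0-based pixel coordinates with the origin at the
top-left; depth increases with row index; ROIs are half-open
``[row, row+height) x [col, col+width)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from myofatigue.synthetic import FrameSequence

#: default GLCM setup: 32 gray levels, unit offsets in the four standard
#: directions (0, 45, 90, 135 degrees), symmetrized.
DEFAULT_LEVELS = 32
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest (top-left corner, size in pixels)."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError("ROI must be at least 2x2 pixels")
        if self.row < 0 or self.col < 0:
            raise ValueError("ROI corner must be non-negative")

    def fits(self, frame: np.ndarray) -> bool:
        return (self.row + self.height <= frame.shape[0]
                and self.col + self.width <= frame.shape[1])

    def extract(self, frame: np.ndarray) -> np.ndarray:
        if not self.fits(frame):
            raise ValueError("ROI does not fit inside the frame")
        return frame[self.row: self.row + self.height,
                     self.col: self.col + self.width]

    def shifted(self, drow: int, dcol: int) -> "ROI":
        return ROI(self.row + drow, self.col + dcol, self.height, self.width)


def normalized_cross_correlation(x_patch: np.ndarray,
                                 y_patch: np.ndarray) -> float:
    """Zero-mean, variance-normalized correlation of two equal-shape pixel
    blocks, in [-1, 1]; raises on constant blocks (zero variance)."""
    x = np.asarray(x_patch, dtype=float)
    y = np.asarray(y_patch, dtype=float)
    if x.shape != y.shape:
        raise ValueError("patch shapes differ")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        raise ValueError("constant patch: correlation undefined")
    return float(np.clip(np.sum(xc * yc) / denom, -1.0, 1.0))


@dataclass
class Trajectory:
    """ROI positions per frame with the peak correlation at each frame.

    ``truncated`` is set when tracking halted because the ROI reached the
    frame border at the maximal allowed offset.
    """

    rois: list[ROI]
    rd: np.ndarray
    truncated: bool = False

    def displacements(self) -> np.ndarray:
        """Per-frame (drow, dcol) relative to the initial ROI."""
        r0 = self.rois[0]
        return np.array([[r.row - r0.row, r.col - r0.col] for r in self.rois])


def track_roi(sequence: FrameSequence, roi0: ROI,
              search_margin: int = 5) -> Trajectory:
    """Track an ROI through a frame sequence by exhaustive integer-pixel NCC
    search within ``±search_margin`` of the previous position, always
    matching against the frame-0 template (no template update, so no drift).

    Ties in peak correlation are broken by the smallest displacement, then
    lexicographically by (row, col) offset.
    """
    if search_margin < 1:
        raise ValueError("search_margin must be >= 1")
    frames = sequence.frames
    template = roi0.extract(frames[0]).astype(float)
    if np.all(template == template.flat[0]):
        raise ValueError("template ROI is constant; pick a textured region")
    rois = [roi0]
    rd = [1.0]
    truncated = False
    H, W = frames[0].shape
    current = roi0
    for k in range(1, len(frames)):
        frame = frames[k]
        best = None
        clipped = False
        for drow in range(-search_margin, search_margin + 1):
            for dcol in range(-search_margin, search_margin + 1):
                cand = current.shifted(drow, dcol)
                if cand.row < 0 or cand.col < 0 or not cand.fits(frame):
                    clipped = True
                    continue
                patch = cand.extract(frame).astype(float)
                try:
                    score = normalized_cross_correlation(template, patch)
                except ValueError:
                    continue
                key = (-score, drow * drow + dcol * dcol, drow, dcol)
                if best is None or key < best[0]:
                    best = (key, cand, score)
        if best is None:
            truncated = True
            break
        _, current, score = best
        rois.append(current)
        rd.append(score)
        at_border = (current.row == 0 or current.col == 0
                     or current.row + current.height == H
                     or current.col + current.width == W)
        if clipped and at_border:
            truncated = True
            break
    return Trajectory(rois, np.asarray(rd), truncated)


@dataclass(frozen=True)
class ThicknessResult:
    """Surface, deep and total muscle thickness in millimetres."""

    surface_mm: float
    deep_mm: float
    total_mm: float

    def __post_init__(self) -> None:
        if min(self.surface_mm, self.deep_mm, self.total_mm) <= 0:
            raise ValueError("thicknesses must be positive")
        if abs(self.total_mm - (self.surface_mm + self.deep_mm)) > 1e-6:
            raise ValueError("total must equal surface + deep")


def thickness_from_boundaries(surface_row: float, deep_row: float,
                              bottom_row: float,
                              pixel_spacing_mm: float) -> ThicknessResult:
    """Convert three boundary rows (surface fascia, surface/deep interface,
    deep muscle bottom) to layer thicknesses."""
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel_spacing_mm must be positive")
    if not surface_row < deep_row < bottom_row:
        raise ValueError("rows must satisfy surface < deep < bottom")
    surface = (deep_row - surface_row) * pixel_spacing_mm
    deep = (bottom_row - deep_row) * pixel_spacing_mm
    return ThicknessResult(surface, deep, surface + deep)


def mean_response_amplitude(frame: np.ndarray, roi: ROI) -> float:
    """Mean pixel magnitude in the ROI after rescaling gray levels to
    [0, 1] (8-bit range)."""
    patch = roi.extract(np.asarray(frame))
    return float(np.mean(np.abs(patch.astype(float))) / 255.0)


# ---------------------------------------------------------------------------
# GLCM texture
# ---------------------------------------------------------------------------


def gray_quantize(image: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Uniformly bin the full 8-bit representable range [0, 255] into
    ``levels`` equal bins, mapping to {0, ..., levels-1}."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if levels > 256:
        raise ValueError("levels exceeds the 8-bit representable range")
    img = np.asarray(image)
    if img.min() < 0 or img.max() > 255:
        raise ValueError("expected 8-bit gray levels in [0, 255]")
    return np.minimum((img.astype(int) * levels) // 256, levels - 1)


@dataclass
class GLCMMatrix:
    """Normalized gray-level co-occurrence matrix (sums to 1)."""

    U: np.ndarray
    levels: int
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.U.shape != (self.levels, self.levels):
            raise ValueError("U must be levels x levels")


def compute_glcm(quantized: np.ndarray,
                 offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS,
                 levels: int | None = None,
                 symmetric: bool = True) -> GLCMMatrix:
    """Co-occurrence counts of (value at p, value at p + offset) over all
    valid pixels p, accumulated over ``offsets``, optionally symmetrized
    (transpose added), normalized to sum 1."""
    q = np.asarray(quantized)
    if len(offsets) == 0:
        raise ValueError("offsets must be non-empty")
    L = int(levels) if levels is not None else int(q.max()) + 1
    if q.max() >= L:
        raise ValueError("image values must be < levels")
    counts = np.zeros((L, L))
    H, W = q.shape
    for drow, dcol in offsets:
        if abs(drow) >= H or abs(dcol) >= W:
            raise ValueError(f"offset {(drow, dcol)} larger than the image")
        r0, r1 = max(0, -drow), min(H, H - drow)
        c0, c1 = max(0, -dcol), min(W, W - dcol)
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + drow: r1 + drow, c0 + dcol: c1 + dcol].ravel()
        np.add.at(counts, (a, b), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs for the given offsets")
    return GLCMMatrix(counts / total, L, tuple(tuple(o) for o in offsets),
                      symmetric)


@dataclass(frozen=True)
class TextureFeatures:
    """GLCM texture summary: ASM (energy), contrast, HOM (inverse
    difference moment)."""

    asm: float
    contrast: float
    hom: float


def texture_features(glcm: GLCMMatrix) -> TextureFeatures:
    """ASM = ΣΣ U², contrast = ΣΣ (i-j)²·U, HOM = ΣΣ U / (1 + (i-j)²)."""
    U = glcm.U
    if abs(U.sum() - 1.0) > 1e-6:
        raise ValueError("GLCM must be normalized to sum 1")
    i, j = np.indices(U.shape)
    d2 = (i - j) ** 2
    return TextureFeatures(
        asm=float(np.sum(U**2)),
        contrast=float(np.sum(d2 * U)),
        hom=float(np.sum(U / (1.0 + d2))),
    )


def roi_texture(frame: np.ndarray, roi: ROI,
                levels: int = DEFAULT_LEVELS,
                offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS) -> TextureFeatures:
    """Quantize an ROI and compute its GLCM texture features (offsets
    accumulated and symmetrized — standard rotation-averaged setup)."""
    q = gray_quantize(roi.extract(frame), levels)
    return texture_features(compute_glcm(q, offsets, levels=levels))
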