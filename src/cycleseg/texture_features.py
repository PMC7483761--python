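"""GLCM/Haralick and LBP texture descriptors for the per-pixel baselines.

Features are computed per 2D z-slice. For every pixel, an odd-sided window
(default 11x11) is quantized to a fixed number of gray levels and a
symmetric, normalized gray-level co-occurrence matrix (GLCM) is built for
each displacement offset; nine Haralick statistics summarize each GLCM and
are averaged over the offsets. The per-pixel map is numba-compiled; the
plain-NumPy single-window routines below double as its oracle.

Local binary patterns compare each pixel's circular neighborhood (radius R,
N samples, bilinear interpolation, starting at the east neighbor and
proceeding clockwise in image orientation) against the center:

    LBP_{N,R}(x, y) = sum_{n=0}^{N-1} s(i_n - i_c) * 2^n,   s(d) = 1 if d >= 0 else 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage

from .core_io import VoxelVolume

__all__ = [
    "GLCM",
    "HaralickVector",
    "LBPConfig",
    "DEFAULT_OFFSETS",
    "compute_glcm",
    "haralick_vector",
    "haralick_map",
    "lbp_map",
    "lbp_volume",
]

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "sum_variance",
    "idm",
    "sum_average",
    "entropy",
    "sum_entropy",
)

#: Haralick-standard displacement set: distance 1 at 0, 45, 90, 135 degrees,
#: expressed as (dy, dx) in image coordinates.
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

DEFAULT_LEVELS = 32


@dataclass
class GLCM:
    """Symmetric pair-frequency matrix over quantized gray levels."""

    matrix: np.ndarray
    levels: int
    offset: tuple[int, int]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (self.levels, self.levels):
            raise ValueError(f"GLCM must be {self.levels}x{self.levels}; got {m.shape}")
        if m.min() < 0:
            raise ValueError("GLCM entries must be >= 0")
        total = m.sum()
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"GLCM must sum to 1; got {total}")
        self.matrix = m


@dataclass
class HaralickVector:
    asm: float
    contrast: float
    correlation: float
    variance: float
    sum_variance: float
    idm: float
    sum_average: float
    entropy: float
    sum_entropy: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in HARALICK_NAMES])


@dataclass
class LBPConfig:
    """Circular-neighborhood parameters: N samples on radius R."""

    N: int = 8
    R: float = 1.0

    def __post_init__(self) -> None:
        if self.N < 4:
            raise ValueError("N must be >= 4")
        if self.R < 1:
            raise ValueError("R must be >= 1")


def quantize(patch: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization to integer levels 0..levels-1.

    Integer inputs already within range are used as-is; otherwise the
    window's own min-max range is divided into equal bins (a constant
    window maps to level 0).
    """
    patch = np.asarray(patch)
    if np.issubdtype(patch.dtype, np.integer) and patch.min() >= 0 and patch.max() < levels:
        return patch.astype(np.int64)
    lo, hi = float(patch.min()), float(patch.max())
    if hi <= lo:
        return np.zeros(patch.shape, dtype=np.int64)
    q = np.floor((patch - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def compute_glcm(patch: np.ndarray, levels: int = DEFAULT_LEVELS, offset: tuple[int, int] = (0, 1)) -> GLCM:
    """Symmetric normalized co-occurrence matrix of a 2D patch.

    Pairs (p, p + offset) with both pixels inside the patch are counted in
    both directions, then frequencies are normalized to sum 1.
    """
    patch = np.asarray(patch)
    if patch.ndim != 2:
        raise ValueError("patch must be 2D")
    dy, dx = offset
    if (dy, dx) == (0, 0):
        raise ValueError("offset must be nonzero")
    if abs(dy) >= patch.shape[0] or abs(dx) >= patch.shape[1]:
        raise ValueError(f"offset {offset} does not fit patch of shape {patch.shape}")
    q = quantize(patch, levels)
    ys = slice(max(0, -dy), q.shape[0] - max(0, dy))
    xs = slice(max(0, -dx), q.shape[1] - max(0, dx))
    a = q[ys, xs]
    b = q[max(0, dy) : q.shape[0] + min(0, dy), max(0, dx) : q.shape[1] + min(0, dx)]
    m = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(m, (a.ravel(), b.ravel()), 1.0)
    m += m.T.copy()  # symmetric accumulation: count each pair both ways
    total = m.sum()
    if total > 0:
        m /= total
    return GLCM(m, levels, (dy, dx))


def haralick_vector(glcm: GLCM) -> HaralickVector:
    """Nine Haralick statistics of a normalized symmetric GLCM.

    ``variance`` is the second moment of the GLCM about its mean gray
    level; ``sum_variance`` the second moment of the gray-sum
    distribution p_{x+y} about the sum average; logs are natural.
    A zero-variance (single-level) GLCM reports correlation 1 by
    convention, with a warning.
    """
    p = glcm.matrix
    L = glcm.levels
    i = np.arange(L)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    asm = float((p**2).sum())
    contrast = float((((ii - jj) ** 2) * p).sum())
    px = p.sum(axis=1)  # marginal; equals p.sum(axis=0) by symmetry
    mu = float((i * px).sum())
    var_marg = float((((i - mu) ** 2) * px).sum())
    if var_marg <= 0:
        warnings.warn("zero-variance GLCM: correlation set to 1 by convention")
        correlation = 1.0
    else:
        correlation = float(((ii - mu) * (jj - mu) * p).sum() / var_marg)
    variance = float((((ii - mu) ** 2) * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())

    # gray-sum distribution p_{x+y}(k), k = i + j in 0..2L-2
    k = np.arange(2 * L - 1)
    pxy = np.zeros(2 * L - 1)
    np.add.at(pxy, (ii + jj).ravel(), p.ravel())
    sum_average = float((k * pxy).sum())
    sum_variance = float((((k - sum_average) ** 2) * pxy).sum())
    nzs = pxy[pxy > 0]
    sum_entropy = float(-(nzs * np.log(nzs)).sum())

    return HaralickVector(
        asm=asm,
        contrast=contrast,
        correlation=correlation,
        variance=variance,
        sum_variance=sum_variance,
        idm=idm,
        sum_average=sum_average,
        entropy=entropy,
        sum_entropy=sum_entropy,
    )


@njit(cache=True)
def _haralick_slice(q, offsets, levels, half):  # pragma: no cover - compiled
    ny, nx = q.shape
    out = np.zeros((9, ny, nx))
    win = 2 * half + 1
    glcm = np.zeros((levels, levels))
    px = np.zeros(levels)
    pxy = np.zeros(2 * levels - 1)
    for yy in range(half, ny - half):
        for xx in range(half, nx - half):
            acc = np.zeros(9)
            for o in range(offsets.shape[0]):
                dy, dx = offsets[o, 0], offsets[o, 1]
                glcm[:, :] = 0.0
                total = 0.0
                for wy in range(yy - half, yy + half + 1):
                    for wx in range(xx - half, xx + half + 1):
                        y2, x2 = wy + dy, wx + dx
                        if (y2 >= yy - half) and (y2 <= yy + half) and (x2 >= xx - half) and (x2 <= xx + half):
                            a, b = q[wy, wx], q[y2, x2]
                            glcm[a, b] += 1.0
                            glcm[b, a] += 1.0
                            total += 2.0
                if total > 0:
                    inv = 1.0 / total
                    for a in range(levels):
                        for b in range(levels):
                            glcm[a, b] *= inv
                asm = 0.0
                contrast = 0.0
                idm = 0.0
                entropy = 0.0
                px[:] = 0.0
                pxy[:] = 0.0
                for a in range(levels):
                    for b in range(levels):
                        v = glcm[a, b]
                        if v > 0.0:
                            asm += v * v
                            d = a - b
                            contrast += d * d * v
                            idm += v / (1.0 + d * d)
                            entropy -= v * np.log(v)
                            px[a] += v
                            pxy[a + b] += v
                mu = 0.0
                for a in range(levels):
                    mu += a * px[a]
                var_marg = 0.0
                for a in range(levels):
                    var_marg += (a - mu) ** 2 * px[a]
                corr_num = 0.0
                variance = 0.0
                for a in range(levels):
                    for b in range(levels):
                        v = glcm[a, b]
                        if v > 0.0:
                            corr_num += (a - mu) * (b - mu) * v
                            variance += (a - mu) ** 2 * v
                correlation = corr_num / var_marg if var_marg > 0.0 else 1.0
                sum_average = 0.0
                for kk in range(2 * levels - 1):
                    sum_average += kk * pxy[kk]
                sum_variance = 0.0
                sum_entropy = 0.0
                for kk in range(2 * levels - 1):
                    v = pxy[kk]
                    if v > 0.0:
                        sum_variance += (kk - sum_average) ** 2 * v
                        sum_entropy -= v * np.log(v)
                acc[0] += asm
                acc[1] += contrast
                acc[2] += correlation
                acc[3] += variance
                acc[4] += sum_variance
                acc[5] += idm
                acc[6] += sum_average
                acc[7] += entropy
                acc[8] += sum_entropy
            out[:, yy, xx] = acc / offsets.shape[0]
    return out


def haralick_map(
    volume: VoxelVolume | np.ndarray,
    patch_size: int = 11,
    levels: int = DEFAULT_LEVELS,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
) -> np.ndarray:
    """Per-pixel 9-channel Haralick feature volume, shape (9, z, y, x).

    For every pixel of every z-slice, the nine statistics of the centered
    ``patch_size``-square window, averaged over the offsets. Quantization
    is per volume (equal-width over the volume's range) so features are
    comparable across slices; borders use reflect padding so the output
    matches the input shape.
    """
    data = volume.data if isinstance(volume, VoxelVolume) else np.asarray(volume)
    if data.ndim == 2:
        data = data[np.newaxis]
    if patch_size % 2 == 0:
        raise ValueError("patch_size must be odd")
    half = patch_size // 2
    q = quantize(data, levels)
    offs = np.asarray(offsets, dtype=np.int64)
    pad = half + int(np.abs(offs).max())
    out = np.empty((9, *data.shape), dtype=np.float64)
    for z in range(data.shape[0]):
        qs = np.pad(q[z], pad, mode="reflect")
        full = _haralick_slice(qs, offs, levels, half)
        out[:, z] = full[:, pad:-pad, pad:-pad]
    return out


def haralick_window_oracle(
    window: np.ndarray,
    levels: int = DEFAULT_LEVELS,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
) -> np.ndarray:
    """Brute-force single-window feature vector (already-quantized input)."""
    vecs = [haralick_vector(compute_glcm(window, levels, o)).as_array() for o in offsets]
    return np.mean(vecs, axis=0)


def lbp_map(image: np.ndarray, config: LBPConfig | None = None) -> np.ndarray:
    """LBP code map of a 2D image; borders use reflect padding.

    Neighbor n sits at angle 2*pi*n/N from the east direction, proceeding
    clockwise in image orientation (y down), sampled with bilinear
    interpolation. Comparisons use a tiny relative tolerance so exact
    ties (e.g. constant regions) count as >=.
    """
    config = config or LBPConfig()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("lbp_map expects a 2D slice")
    ny, nx = image.shape
    yy, xx = np.meshgrid(np.arange(ny, dtype=np.float64), np.arange(nx, dtype=np.float64), indexing="ij")
    codes = np.zeros((ny, nx), dtype=np.int64)
    for n in range(config.N):
        theta = 2.0 * np.pi * n / config.N
        dy = config.R * np.sin(theta)  # y grows downward: clockwise on screen
        dx = config.R * np.cos(theta)
        sampled = ndimage.map_coordinates(image, [yy + dy, xx + dx], order=1, mode="reflect")
        bit = (sampled - image) >= -1e-9 * (1.0 + np.abs(image))
        codes += bit.astype(np.int64) << n
    return codes


def lbp_volume(volume: VoxelVolume | np.ndarray, config: LBPConfig | None = None) -> np.ndarray:
    """Per-slice LBP codes as a 1-channel feature volume (1, z, y, x)."""
    data = volume.data if isinstance(volume, VoxelVolume) else np.asarray(volume)
    out = np.stack([lbp_map(data[z], config) for z in range(data.shape[0])])
    return out[np.newaxis].astype(np.float64)
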