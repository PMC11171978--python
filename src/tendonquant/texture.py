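"""Texture descriptors for rectangular ROIs.

Three families feed the 13 texture variables computed per texture ROI:

* six gray-level co-occurrence (GLCM) features from a symmetric,
  angle-averaged co-occurrence matrix at unit distance;
* five gray-level difference statistics (GLDS) from the pooled histogram of
  absolute quantized differences over four unit displacements;
* two statistics of the pooled detail coefficients of a one-level 2D Haar
  decomposition of the raw (unquantized) region.

The quantized alphabet feeds GLCM/GLDS; the Haar transform operates on the
raw 8-bit region. An undefined GLCM correlation (constant region) is
reported as NaN, never coerced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

DEFAULT_ANGLES = (0, 45, 90, 135)
DEFAULT_DISPLACEMENTS = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass(frozen=True)
class GlcmMatrix:
    """Symmetric, normalized co-occurrence matrix averaged over orientations."""

    p: np.ndarray
    levels: int
    distance: int
    angles: tuple[int, ...]


@dataclass(frozen=True)
class GldsHistogram:
    """Probability histogram of absolute gray-level differences k = 0..Ng-1."""

    q: np.ndarray
    levels: int
    displacements: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class TextureFeatures:
    glcm_contrast: float
    glcm_sum_average: float
    glcm_ssq_variance: float
    glcm_difference_variance: float
    glcm_correlation: float  # NaN when undefined (constant region)
    glcm_idm: float
    glds_homogeneity: float
    glds_contrast: float
    glds_asm: float
    glds_entropy: float
    glds_mean: float
    haar_mean: float
    haar_variance: float

    def as_dict(self) -> dict[str, float]:
        return {
            "glcm_contrast": self.glcm_contrast,
            "glcm_sum_average": self.glcm_sum_average,
            "glcm_ssq_variance": self.glcm_ssq_variance,
            "glcm_difference_variance": self.glcm_difference_variance,
            "glcm_correlation": self.glcm_correlation,
            "glcm_idm": self.glcm_idm,
            "glds_homogeneity": self.glds_homogeneity,
            "glds_contrast": self.glds_contrast,
            "glds_asm": self.glds_asm,
            "glds_entropy": self.glds_entropy,
            "glds_mean": self.glds_mean,
            "haar_mean": self.haar_mean,
            "haar_variance": self.haar_variance,
        }


def quantize(region: np.ndarray, levels: int = 32) -> np.ndarray:
    """Map 8-bit values to ``floor(v * levels / 256)``, i.e. [0, levels-1]."""
    if not 2 <= levels <= 256:
        raise ValueError(f"levels must be in [2, 256], got {levels}")
    region = np.asarray(region)
    if region.min() < 0 or region.max() > 255:
        raise ValueError("region values must be 8-bit, in [0, 255]")
    return (region.astype(np.int64) * levels) // 256


def glcm(
    region: np.ndarray,
    levels: int,
    distance: int = 1,
    angles: tuple[int, ...] = DEFAULT_ANGLES,
) -> GlcmMatrix:
    """Co-occurrence matrix of a quantized region.

    For each angle, ordered pixel pairs at the offset are counted,
    symmetrized by adding the transpose and normalized; the result is the
    mean over the requested angles.
    """
    region = np.asarray(region, dtype=np.int64)
    if region.ndim != 2 or min(region.shape) < 1:
        raise ValueError("region must be a 2D matrix")
    if region.max() >= levels:
        raise ValueError("region is not quantized to the stated number of levels")
    mats = []
    for ang in angles:
        if ang not in _ANGLE_OFFSETS:
            raise ValueError(f"unsupported angle {ang}; choose from {sorted(_ANGLE_OFFSETS)}")
        dr, dc = (d * distance for d in _ANGLE_OFFSETS[ang])
        counts = _pair_counts(region, dr, dc, levels)
        total = counts.sum()
        if total == 0:
            continue
        sym = counts + counts.T
        mats.append(sym / sym.sum())
    if not mats:
        raise ValueError("region has no pixel pairs at the requested offsets")
    p = np.mean(mats, axis=0)
    return GlcmMatrix(p=p, levels=levels, distance=distance, angles=tuple(angles))


def _pair_counts(region: np.ndarray, dr: int, dc: int, levels: int) -> np.ndarray:
    rows, cols = region.shape
    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    if r0 >= r1 or c0 >= c1:
        return np.zeros((levels, levels), dtype=np.int64)
    a = region[r0:r1, c0:c1].ravel()
    b = region[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.zeros((levels, levels), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    return counts


def glcm_features(m: GlcmMatrix) -> dict[str, float]:
    """Haralick-style features of one co-occurrence matrix.

    contrast, sum average, sum-of-squares variance, difference variance,
    correlation (NaN when a marginal is degenerate) and inverse difference
    moment.
    """
    p = m.p
    ng = m.levels
    i = np.arange(ng)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    contrast = float(((ii - jj) ** 2 * p).sum())
    # sum distribution p_{x+y}(k), k = 0..2(Ng-1)
    psum = np.zeros(2 * ng - 1)
    np.add.at(psum, (ii + jj).ravel(), p.ravel())
    sum_average = float((np.arange(2 * ng - 1) * psum).sum())
    # marginal p_x (= p_y by symmetry)
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    ssq_variance = float(((ii - mu) ** 2 * p).sum())
    # difference distribution p_{x-y}(k), k = 0..Ng-1
    pdiff = np.zeros(ng)
    np.add.at(pdiff, np.abs(ii - jj).ravel(), p.ravel())
    dmean = float((i * pdiff).sum())
    difference_variance = float(((i - dmean) ** 2 * pdiff).sum())
    # correlation
    sigma2 = float((i**2 * px).sum()) - mu**2
    if sigma2 <= 1e-15:
        correlation = math.nan
    else:
        correlation = (float((ii * jj * p).sum()) - mu * mu) / sigma2
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    return {
        "glcm_contrast": contrast,
        "glcm_sum_average": sum_average,
        "glcm_ssq_variance": ssq_variance,
        "glcm_difference_variance": difference_variance,
        "glcm_correlation": correlation,
        "glcm_idm": idm,
    }


def glcm_homogeneity(m: GlcmMatrix) -> float:
    """Bone-variant homogeneity ``sum p(i,j) / (1 + |i - j|)``.

    Deliberately distinct from the inverse difference moment, which divides
    by ``1 + (i - j)^2``.
    """
    ii, jj = np.meshgrid(np.arange(m.levels), np.arange(m.levels), indexing="ij")
    return float((m.p / (1.0 + np.abs(ii - jj))).sum())


def glds(
    region: np.ndarray,
    levels: int,
    displacements: tuple[tuple[int, int], ...] = DEFAULT_DISPLACEMENTS,
) -> GldsHistogram:
    """Pooled histogram of absolute quantized differences over displacements."""
    region = np.asarray(region, dtype=np.int64)
    if region.max() >= levels:
        raise ValueError("region is not quantized to the stated number of levels")
    counts = np.zeros(levels, dtype=np.int64)
    rows, cols = region.shape
    for dr, dc in displacements:
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        diff = np.abs(region[r0:r1, c0:c1] - region[r0 + dr : r1 + dr, c0 + dc : c1 + dc])
        np.add.at(counts, diff.ravel(), 1)
    total = counts.sum()
    if total == 0:
        raise ValueError("region has no pixel pairs at the requested displacements")
    return GldsHistogram(q=counts / total, levels=levels, displacements=tuple(displacements))


def glds_features(h: GldsHistogram) -> dict[str, float]:
    q = h.q
    k = np.arange(h.levels)
    pos = q > 0
    return {
        "glds_homogeneity": float((q / (1.0 + k**2)).sum()),
        "glds_contrast": float((k**2 * q).sum()),
        "glds_asm": float((q**2).sum()),
        "glds_entropy": float(-(q[pos] * np.log(q[pos])).sum()),
        "glds_mean": float((k * q).sum()),
    }


def haar_detail_coefficients(region: np.ndarray) -> np.ndarray:
    """Pooled detail coefficients of a one-level 2D Haar decomposition.

    Each non-overlapping 2x2 block ``[[a, b], [c, d]]`` yields horizontal
    ``(a + b - c - d)/2``, vertical ``(a - b + c - d)/2`` and diagonal
    ``(a - b - c + d)/2`` detail coefficients (orthonormal scaling). Odd
    trailing rows/columns are truncated; padding would invent gradients.
    """
    region = np.asarray(region, dtype=float)
    rows, cols = region.shape
    if rows < 2 or cols < 2:
        raise ValueError("Haar transform needs a region of at least 2x2")
    region = region[: rows - rows % 2, : cols - cols % 2]
    a = region[0::2, 0::2]
    b = region[0::2, 1::2]
    c = region[1::2, 0::2]
    d = region[1::2, 1::2]
    horizontal = (a + b - c - d) / 2.0
    vertical = (a - b + c - d) / 2.0
    diagonal = (a - b - c + d) / 2.0
    return np.concatenate([horizontal.ravel(), vertical.ravel(), diagonal.ravel()])


def haar_features(region: np.ndarray) -> tuple[float, float]:
    """Mean and population variance of |detail coefficient| pooled over bands."""
    mags = np.abs(haar_detail_coefficients(region))
    return float(mags.mean()), float(mags.var())


def texture_vector(
    region: np.ndarray,
    levels: int = 32,
    distance: int = 1,
    angles: tuple[int, ...] = DEFAULT_ANGLES,
    displacements: tuple[tuple[int, int], ...] = DEFAULT_DISPLACEMENTS,
) -> TextureFeatures:
    """All 13 texture variables of one rectangular 8-bit region."""
    quant = quantize(region, levels)
    gf = glcm_features(glcm(quant, levels, distance, angles))
    df = glds_features(glds(quant, levels, displacements))
    hm, hv = haar_features(region)
    return TextureFeatures(**gf, **df, haar_mean=hm, haar_variance=hv)
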