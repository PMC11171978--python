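"""Bone-interface segmentation and the seven bone variables.

The bright bone reflection inside the bone ROI is segmented by thresholding
(Otsu by default, fixed threshold optionally), cleaned of sub-minimum
speckle components, and summarized by fragment count, total area, total
outer-contour perimeter (unit steps, diagonals weighted sqrt(2)), convexity
of the foreground union, and a three-variable GLCM triple computed on the
raw ROI echotexture (not the binary mask).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from tendonquant.config import _parse_fixed_threshold
from tendonquant.geometry import shoelace_area
from tendonquant.texture import DEFAULT_ANGLES, glcm, glcm_features, glcm_homogeneity, quantize

_EIGHT_CONN = np.ones((3, 3), dtype=bool)

# Moore neighborhood in clockwise order starting west
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))
_MOORE_INDEX = {off: k for k, off in enumerate(_MOORE)}


@dataclass(frozen=True)
class BoneSegmentation:
    mask: np.ndarray  # binary, congruent with the ROI
    labels: np.ndarray  # 0 = background, 1..n = fragments
    n_fragments: int
    threshold_used: float
    threshold_degenerate: bool  # True when the region had a single gray level
    min_fragment_px: int


@dataclass(frozen=True)
class BoneFeatures:
    n_fragments: int
    area: float
    perimeter: float
    convexity: float  # NaN when no fragments
    glcm_homogeneity: float
    glcm_contrast: float
    glcm_correlation: float

    def as_dict(self) -> dict[str, float]:
        return {
            "bone_n_fragments": float(self.n_fragments),
            "bone_area": self.area,
            "bone_perimeter": self.perimeter,
            "bone_convexity": self.convexity,
            "bone_glcm_homogeneity": self.glcm_homogeneity,
            "bone_glcm_contrast": self.glcm_contrast,
            "bone_glcm_correlation": self.glcm_correlation,
        }


def otsu_threshold(region: np.ndarray) -> float:
    """Otsu's threshold: maximize between-class variance over cut points.

    Foreground is ``value >= t``. With well-separated modes the criterion is
    flat across the empty gap between them; the midpoint of the maximizer
    plateau is returned so the cut lands mid-gap instead of hugging the
    lower mode.
    """
    hist = np.bincount(np.asarray(region, dtype=np.int64).ravel(), minlength=256).astype(float)
    total = hist.sum()
    w0 = np.cumsum(hist)[:-1]  # pixels below threshold t = 1..255
    w1 = total - w0
    cum_mean = np.cumsum(hist * np.arange(256))[:-1]
    grand = cum_mean[-1] + hist[255] * 255
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = cum_mean / w0
        mu1 = (grand - cum_mean) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[~np.isfinite(var_between)] = -1.0
    vmax = var_between.max()
    plateau = np.flatnonzero(var_between >= vmax * (1 - 1e-12))
    return float(plateau[(len(plateau) - 1) // 2] + 1)  # +1: index i is threshold t = i + 1


def segment_bone(
    region: np.ndarray,
    threshold_method: str = "otsu",
    min_fragment_px: int = 5,
) -> BoneSegmentation:
    """Threshold the ROI (foreground = pixels >= threshold) and label fragments.

    Components are 8-connected; components below ``min_fragment_px`` are
    removed as speckle. A single-gray-level region makes Otsu degenerate and
    yields zero fragments with the threshold flagged.
    """
    region = np.asarray(region)
    if region.ndim != 2:
        raise ValueError("bone ROI must be a 2D matrix")
    if min_fragment_px < 1:
        raise ValueError("min_fragment_px must be >= 1")
    degenerate = False
    if threshold_method == "otsu":
        if region.min() == region.max():
            degenerate = True
            thr = float(region.max()) + 1.0  # nothing passes
        else:
            thr = otsu_threshold(region)
    else:
        thr = float(_parse_fixed_threshold(threshold_method))
    mask = region >= thr
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_fragment_px) + 1
        relabel = np.zeros(n + 1, dtype=np.int32)
        relabel[keep] = np.arange(1, len(keep) + 1)
        labels = relabel[labels]
        n = len(keep)
    mask = labels > 0
    return BoneSegmentation(
        mask=mask,
        labels=labels,
        n_fragments=int(n),
        threshold_used=thr,
        threshold_degenerate=degenerate,
        min_fragment_px=min_fragment_px,
    )


def trace_outer_contour(mask: np.ndarray) -> list[tuple[int, int]]:
    """Outer boundary pixels of a single connected component (Moore tracing).

    Returns the closed clockwise tour of boundary pixel centers, starting at
    the uppermost-leftmost foreground pixel. A single isolated pixel yields a
    one-element tour.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    flat = np.flatnonzero(mask)
    if flat.size == 0:
        return []
    start = (int(flat[0] // cols), int(flat[0] % cols))

    def fg(r: int, c: int) -> bool:
        return 0 <= r < rows and 0 <= c < cols and mask[r, c]

    cur = start
    back = (start[0], start[1] - 1)  # west neighbor is background by raster order
    tour = [start]
    first_state: tuple | None = None
    for _ in range(8 * int(mask.sum()) + 8):
        b_idx = _MOORE_INDEX[(back[0] - cur[0], back[1] - cur[1])]
        nxt = None
        prev = back
        for k in range(1, 9):
            dr, dc = _MOORE[(b_idx + k) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if fg(*cand):
                nxt = cand
                break
            prev = cand
        if nxt is None:  # isolated pixel
            return tour
        state = (cur, nxt)
        if first_state is None:
            first_state = state
        elif state == first_state:
            break
        back = prev
        cur = nxt
        tour.append(cur)
    # the loop re-enters the starting position before the state repeats
    return tour[:-1] if len(tour) > 1 and tour[-1] == tour[0] else tour


def contour_perimeter(mask: np.ndarray) -> float:
    """Arc length of the closed outer contour: 1 per axial, sqrt(2) per diagonal step."""
    tour = trace_outer_contour(mask)
    if len(tour) < 2:
        return 0.0
    pts = np.asarray(tour + [tour[0]], dtype=float)
    steps = np.diff(pts, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def _foreground_hull_area(mask: np.ndarray) -> float:
    """Convex-hull area of the foreground pixel centers.

    Degenerate masks (a point or a line of centers) count as convex. Using
    centers instead of pixel-square corners avoids the staircase bias that
    would keep convexity of a smooth convex fragment visibly below 1.
    """
    rr, cc = np.nonzero(mask)
    pts = np.column_stack([cc, rr]).astype(float)
    try:
        hull = ConvexHull(pts)
    except (QhullError, ValueError):
        return 0.0
    hx, hy = pts[hull.vertices, 0], pts[hull.vertices, 1]
    return shoelace_area(hx, hy)


def bone_features(
    seg: BoneSegmentation,
    region: np.ndarray,
    levels: int = 32,
    distance: int = 1,
    angles: tuple[int, ...] = DEFAULT_ANGLES,
    pixel_spacing_mm: tuple[float, float] | None = None,
) -> BoneFeatures:
    """The seven bone variables from a segmentation and its source region.

    Area and perimeter aggregate over all fragments; convexity compares the
    union's pixel area with the convex hull of the foreground pixel squares.
    The texture triple describes the raw ROI echotexture.
    """
    n = seg.n_fragments
    if n == 0:
        area = perimeter = 0.0
        convexity = math.nan
    else:
        area = float(seg.mask.sum())
        perimeter = 0.0
        for lab in range(1, n + 1):
            perimeter += contour_perimeter(seg.labels == lab)
        hull_area = _foreground_hull_area(seg.mask)
        convexity = 1.0 if hull_area <= 0 else min(1.0, area / hull_area)
    if pixel_spacing_mm is not None:
        sy, sx = pixel_spacing_mm
        area *= sy * sx
        perimeter *= math.sqrt(sy * sx)  # isotropic spacing assumed for arc length
    m = glcm(quantize(region, levels), levels, distance, angles)
    gf = glcm_features(m)
    return BoneFeatures(
        n_fragments=n,
        area=area,
        perimeter=perimeter,
        convexity=convexity,
        glcm_homogeneity=glcm_homogeneity(m),
        glcm_contrast=gf["glcm_contrast"],
        glcm_correlation=gf["glcm_correlation"],
    )
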