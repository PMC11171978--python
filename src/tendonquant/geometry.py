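"""Tendon morphology from the polygonal ROI.

The polygon outlining the tendon body is split at its leftmost and rightmost
vertices into an upper and a lower border chain. Widths are the vertical
distances between the chains sampled at equally spaced stations along x;
the five morphology variables are summary statistics of that width profile.
Convexity (polygon area / convex-hull area, both by the shoelace formula) is
computed as an auxiliary value but kept out of the canonical 51-vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from tendonquant.io import PolyROI, ValidationError


@dataclass(frozen=True)
class WidthProfile:
    stations: np.ndarray  # x positions, pixels
    widths: np.ndarray  # same length; pixels, or mm when spacing applied
    units: str = "px"


@dataclass(frozen=True)
class MorphologyFeatures:
    max_width: float
    min_width: float
    mean_width: float
    parallelism_sd: float
    width_ratio: float  # NaN when min width is 0 (degenerate pinch)
    convexity: float  # auxiliary, not part of the 51-vector
    units: str = "px"

    def as_dict(self) -> dict[str, float]:
        return {
            "morph_max_width": self.max_width,
            "morph_min_width": self.min_width,
            "morph_mean_width": self.mean_width,
            "morph_parallelism_sd": self.parallelism_sd,
            "morph_width_ratio": self.width_ratio,
        }


def shoelace_area(xs: np.ndarray, ys: np.ndarray) -> float:
    """Unsigned polygon area by the shoelace formula."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    return 0.5 * abs(float(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1))))


def convex_hull_area(xs: np.ndarray, ys: np.ndarray) -> float:
    pts = np.column_stack([xs, ys])
    hull = ConvexHull(pts)
    hx, hy = pts[hull.vertices, 0], pts[hull.vertices, 1]
    return shoelace_area(hx, hy)


def convexity_ratio(xs: np.ndarray, ys: np.ndarray) -> float:
    """Polygon area / convex hull area, clamped into (0, 1].

    Clamping absorbs float rounding of order 1e-15 for convex inputs; a
    genuinely concave polygon sits well below the clamp.
    """
    ratio = shoelace_area(xs, ys) / convex_hull_area(xs, ys)
    return 1.0 if ratio > 1.0 - 1e-12 else ratio


def split_chains(poly: PolyROI) -> tuple[np.ndarray, np.ndarray]:
    """Split the polygon into upper and lower border chains.

    The vertex cycle is cut at the leftmost and the rightmost vertices (ties
    broken by smaller y). Each chain must be x-monotone; the chain with the
    smaller mean y is the upper border. Returns (upper, lower) as (n, 2)
    arrays of (x, y) with x non-decreasing left to right.
    """
    verts = np.asarray(poly.vertices, dtype=float)
    n = len(verts)
    if verts[:, 0].max() - verts[:, 0].min() < 2:
        raise ValidationError("polygon x-extent must span at least 2 pixels")
    keys = np.lexsort((verts[:, 1], verts[:, 0]))  # by x, then smaller y
    i_left = int(keys[0])
    right_x = verts[:, 0].max()
    right_candidates = np.flatnonzero(verts[:, 0] == right_x)
    i_right = int(right_candidates[np.argmin(verts[right_candidates, 1])])

    def walk(src: int, dst: int) -> np.ndarray:
        idx = [src]
        k = src
        while k != dst:
            k = (k + 1) % n
            idx.append(k)
        return verts[idx]

    chain_a = walk(i_left, i_right)
    chain_b = walk(i_right, i_left)[::-1]  # reorient left-to-right
    for chain in (chain_a, chain_b):
        if np.any(np.diff(chain[:, 0]) < 0):
            raise ValidationError("polygon border chain doubles back in x; not x-monotone")
    if chain_a[:, 1].mean() <= chain_b[:, 1].mean():
        upper, lower = chain_a, chain_b
    else:
        upper, lower = chain_b, chain_a
    # Vertical edges (runs of equal x, e.g. the polygon's end edges) make a
    # chain multi-valued in x; keep the vertex nearest the chain's own side.
    return _collapse_equal_x(upper, keep="min"), _collapse_equal_x(lower, keep="max")


def _collapse_equal_x(chain: np.ndarray, keep: str) -> np.ndarray:
    pick = np.argmin if keep == "min" else np.argmax
    out: list[np.ndarray] = []
    i = 0
    while i < len(chain):
        j = i
        while j + 1 < len(chain) and chain[j + 1, 0] == chain[i, 0]:
            j += 1
        run = chain[i : j + 1]
        out.append(run[pick(run[:, 1])])
        i = j + 1
    return np.asarray(out)


def width_profile(
    upper: np.ndarray,
    lower: np.ndarray,
    n_stations: int = 100,
    pixel_spacing_mm: tuple[float, float] | None = None,
) -> WidthProfile:
    """Vertical widths between the interpolated chains at equally spaced x."""
    if n_stations < 2:
        raise ValueError("n_stations must be >= 2")
    x_lo = max(upper[0, 0], lower[0, 0])
    x_hi = min(upper[-1, 0], lower[-1, 0])
    if x_hi <= x_lo:
        raise ValidationError("chains share no x-range")
    xs = np.linspace(x_lo, x_hi, n_stations)
    y_up = np.interp(xs, upper[:, 0], upper[:, 1])
    y_lo = np.interp(xs, lower[:, 0], lower[:, 1])
    widths = np.abs(y_lo - y_up)
    units = "px"
    if pixel_spacing_mm is not None:
        widths = widths * pixel_spacing_mm[0]  # widths run along rows
        units = "mm"
    return WidthProfile(stations=xs, widths=widths, units=units)


def morphology_features(
    poly: PolyROI,
    n_stations: int = 100,
    pixel_spacing_mm: tuple[float, float] | None = None,
) -> MorphologyFeatures:
    """The five width variables plus auxiliary convexity of the tendon polygon.

    parallelism_sd is the population standard deviation of the sampled
    widths (the stations form a deterministic grid, not a random sample).
    """
    upper, lower = split_chains(poly)
    profile = width_profile(upper, lower, n_stations, pixel_spacing_mm)
    w = profile.widths
    w_max, w_min, w_mean = float(w.max()), float(w.min()), float(w.mean())
    ratio = w_max / w_min if w_min > 0 else math.nan
    xs, ys = poly.as_arrays()
    return MorphologyFeatures(
        max_width=w_max,
        min_width=w_min,
        mean_width=w_mean,
        parallelism_sd=float(w.std()),
        width_ratio=ratio,
        convexity=convexity_ratio(xs, ys),
        units=profile.units,
    )
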