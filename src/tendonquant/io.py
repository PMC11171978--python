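"""Data model and file readers/writers shared by all pipeline stages.

Conventions fixed here and relied on everywhere else:

* coordinates are 0-based with ``x`` = column and ``y`` = row;
* rectangles are half-open, covering ``[x0, x0+w) x [y0, y0+h)``;
* the canonical order of the 51 quantitative variables is
  :data:`FEATURE_NAMES` (13 quality + 13 upper edge + 13 lower edge +
  5 morphology + 7 bone);
* undefined values (e.g. texture correlation of a constant region) are
  carried as NaN, never coerced to a number.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from shapely.geometry import Polygon as _ShapelyPolygon

RECT_ROI_NAMES = ("quality", "upper_edge", "lower_edge", "bone")
POLY_ROI_NAME = "morphology"

#: rating ROIs of the ordinal 0-3 clinical scale
RATING_ROI_NAMES = ("bone", "quality", "thickness", "upper_edge", "lower_edge")

TEXTURE_FEATURE_NAMES = (
    "glcm_contrast",
    "glcm_sum_average",
    "glcm_ssq_variance",
    "glcm_difference_variance",
    "glcm_correlation",
    "glcm_idm",
    "glds_homogeneity",
    "glds_contrast",
    "glds_asm",
    "glds_entropy",
    "glds_mean",
    "haar_mean",
    "haar_variance",
)

MORPH_FEATURE_NAMES = (
    "morph_max_width",
    "morph_min_width",
    "morph_mean_width",
    "morph_parallelism_sd",
    "morph_width_ratio",
)

BONE_FEATURE_NAMES = (
    "bone_n_fragments",
    "bone_area",
    "bone_perimeter",
    "bone_convexity",
    "bone_glcm_homogeneity",
    "bone_glcm_contrast",
    "bone_glcm_correlation",
)

#: canonical order of the full 51-variable quantitative vector
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"quality_{n}" for n in TEXTURE_FEATURE_NAMES)
    + tuple(f"upper_edge_{n}" for n in TEXTURE_FEATURE_NAMES)
    + tuple(f"lower_edge_{n}" for n in TEXTURE_FEATURE_NAMES)
    + MORPH_FEATURE_NAMES
    + BONE_FEATURE_NAMES
)

#: mapping from rating ROI to the feature-name prefix it judges
RATING_ROI_TO_PREFIX = {
    "quality": "quality_",
    "upper_edge": "upper_edge_",
    "lower_edge": "lower_edge_",
    "thickness": "morph_",
    "bone": "bone_",
}


class ValidationError(ValueError):
    """Raised when an input file or domain object violates its contract."""


@dataclass(frozen=True)
class UltrasoundImage:
    """An 8-bit grayscale B-mode image with optional physical pixel spacing."""

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float] | None = None  # (row, col) spacing

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValidationError(f"image must be a 2D matrix of at least 2x2, got shape {px.shape}")
        if px.size and (px.min() < 0 or px.max() > 255):
            raise ValidationError("image intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))
        if self.pixel_spacing_mm is not None:
            sp = tuple(float(s) for s in self.pixel_spacing_mm)
            if len(sp) != 2 or any(s <= 0 for s in sp):
                raise ValidationError("pixel_spacing_mm must be two positive reals (row, col)")
            object.__setattr__(self, "pixel_spacing_mm", sp)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangle, half-open ``[x0, x0+width) x [y0, y0+height)``."""

    name: str
    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.name not in RECT_ROI_NAMES:
            raise ValidationError(f"unknown rectangular ROI name {self.name!r}; expected one of {RECT_ROI_NAMES}")
        if self.width < 4 or self.height < 4:
            raise ValidationError(f"ROI {self.name!r}: width and height must be >= 4 (texture matrices need pixel pairs)")
        if self.x0 < 0 or self.y0 < 0:
            raise ValidationError(f"ROI {self.name!r}: negative corner ({self.x0}, {self.y0})")

    def check_bounds(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        if self.x0 + self.width > cols or self.y0 + self.height > rows:
            raise ValidationError(
                f"ROI {self.name!r} [{self.x0}:{self.x0 + self.width}) x [{self.y0}:{self.y0 + self.height}) "
                f"escapes image bounds {cols} x {rows}"
            )

    def extract(self, image: UltrasoundImage | np.ndarray) -> np.ndarray:
        px = image.pixels if isinstance(image, UltrasoundImage) else np.asarray(image)
        self.check_bounds(px.shape)
        return px[self.y0 : self.y0 + self.height, self.x0 : self.x0 + self.width]


@dataclass(frozen=True)
class PolyROI:
    """Simple closed polygon in pixel coordinates (x, y), >= 4 vertices."""

    vertices: tuple[tuple[float, float], ...]
    name: str = POLY_ROI_NAME

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 4:
            raise ValidationError(f"polygon needs >= 4 vertices, got {len(verts)}")
        poly = _ShapelyPolygon(verts)
        if not poly.is_simple or not poly.is_valid:
            raise ValidationError("polygon is self-intersecting or otherwise invalid")
        if poly.area <= 0:
            raise ValidationError("polygon has zero area")

    def check_bounds(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        xs = [v[0] for v in self.vertices]
        ys = [v[1] for v in self.vertices]
        if min(xs) < 0 or min(ys) < 0 or max(xs) > cols or max(ys) > rows:
            raise ValidationError(f"polygon escapes image bounds {cols} x {rows}")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.vertices, dtype=float)
        return arr[:, 0], arr[:, 1]


@dataclass(frozen=True)
class RoiSet:
    """Named regions of interest tied to one image: up to 4 rectangles + 1 polygon."""

    image_id: str
    rects: tuple[RectROI, ...] = ()
    poly: PolyROI | None = None

    def __post_init__(self) -> None:
        names = [r.name for r in self.rects]
        if len(names) != len(set(names)):
            raise ValidationError(f"duplicate ROI names: {names}")

    def rect(self, name: str) -> RectROI | None:
        for r in self.rects:
            if r.name == name:
                return r
        return None

    def validate_against(self, image: UltrasoundImage) -> None:
        for r in self.rects:
            r.check_bounds(image.shape)
        if self.poly is not None:
            self.poly.check_bounds(image.shape)

    @property
    def is_complete(self) -> bool:
        return self.poly is not None and all(self.rect(n) is not None for n in RECT_ROI_NAMES)


@dataclass(frozen=True)
class FeatureVector:
    """The ordered 51-variable quantitative description of one image.

    Values are keyed by the canonical names in :data:`FEATURE_NAMES`;
    NaN marks a flagged-undefined or flagged-missing value.
    """

    image_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(FEATURE_NAMES)
        if unknown:
            raise ValidationError(f"unknown feature names: {sorted(unknown)}")
        ordered = {name: float(self.values.get(name, math.nan)) for name in FEATURE_NAMES}
        object.__setattr__(self, "values", ordered)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.image_id)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_image(path: str | Path, pixel_spacing_mm: tuple[float, float] | None = None) -> UltrasoundImage:
    """Read a PNG as an 8-bit grayscale image.

    Multi-channel inputs are converted deterministically with ITU-R 601 luma
    weights; 16-bit inputs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        if im.mode == "I;16" or im.mode.startswith("I"):
            raise ValidationError(f"{path}: only 8-bit images are supported, got mode {im.mode!r}")
        if im.mode != "L":
            im = im.convert("L")
        arr = np.asarray(im, dtype=np.uint8)
    if arr.size == 0:
        raise ValidationError(f"{path}: zero-size image")
    return UltrasoundImage(pixels=arr, pixel_spacing_mm=pixel_spacing_mm)


def write_image(image: UltrasoundImage | np.ndarray, path: str | Path) -> None:
    px = image.pixels if isinstance(image, UltrasoundImage) else np.asarray(image, dtype=np.uint8)
    Image.fromarray(px, mode="L").save(Path(path), format="PNG")


def read_roiset(path: str | Path, image_shape: tuple[int, int] | None = None) -> RoiSet:
    """Read a ROI set from JSON.

    Two layouts are accepted: a flat object mapping ROI names to
    ``[x0, y0, width, height]`` (and ``"morphology"`` to a vertex list), or a
    structured object ``{"image_id": ..., "rects": {...}, "morphology": [...]}``.
    Out-of-bounds or degenerate ROIs are rejected, never repaired.
    """
    path = Path(path)
    raw = json.loads(path.read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: ROI file must contain a JSON object")
    image_id = str(raw.get("image_id", path.stem))
    rect_specs: dict[str, object] = {}
    source = raw.get("rects", raw)
    if not isinstance(source, dict):
        raise ValidationError(f"{path}: 'rects' must be an object")
    poly_spec = raw.get(POLY_ROI_NAME, None)
    for key, val in source.items():
        if key in ("image_id", "rects"):
            continue
        if key == POLY_ROI_NAME:
            poly_spec = val
            continue
        if key not in RECT_ROI_NAMES:
            raise ValidationError(f"{path}: unknown ROI name {key!r}")
        rect_specs[key] = val

    rects = []
    for name, spec in rect_specs.items():
        if not (isinstance(spec, (list, tuple)) and len(spec) == 4):
            raise ValidationError(f"{path}: ROI {name!r} must be [x0, y0, width, height]")
        rects.append(RectROI(name=name, x0=int(spec[0]), y0=int(spec[1]), width=int(spec[2]), height=int(spec[3])))

    poly = None
    if poly_spec is not None:
        if not (isinstance(poly_spec, (list, tuple)) and len(poly_spec) >= 4):
            raise ValidationError(f"{path}: polygon must be a list of >= 4 [x, y] vertices")
        poly = PolyROI(vertices=tuple((float(p[0]), float(p[1])) for p in poly_spec))

    roiset = RoiSet(image_id=image_id, rects=tuple(rects), poly=poly)
    if image_shape is not None:
        for r in roiset.rects:
            r.check_bounds(image_shape)
        if roiset.poly is not None:
            roiset.poly.check_bounds(image_shape)
    return roiset


def write_roiset(roiset: RoiSet, path: str | Path) -> None:
    out: dict[str, object] = {"image_id": roiset.image_id}
    out["rects"] = {r.name: [r.x0, r.y0, r.width, r.height] for r in roiset.rects}
    if roiset.poly is not None:
        out[POLY_ROI_NAME] = [[x, y] for x, y in roiset.poly.vertices]
    Path(path).write_text(json.dumps(out, indent=2))


def features_to_frame(vectors: Iterable[FeatureVector]) -> pd.DataFrame:
    rows = [dict(image_id=v.image_id, **v.values) for v in vectors]
    return pd.DataFrame(rows, columns=["image_id", *FEATURE_NAMES])


def write_features(vectors: Sequence[FeatureVector], path: str | Path) -> None:
    """Write feature vectors to CSV: one row per image, canonical column order."""
    features_to_frame(vectors).to_csv(Path(path), index=False, float_format="%.17g")


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = [c for c in ("image_id", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing feature columns {missing[:5]}{'...' if len(missing) > 5 else ''}")
    return df


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Read the ordinal rating table (subject_id, session, roi_name, grade)."""
    df = pd.read_csv(Path(path))
    required = {"subject_id", "session", "roi_name", "grade"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: rating CSV must have columns {sorted(required)}")
    if not df["grade"].isin([0, 1, 2, 3]).all():
        raise ValidationError(f"{path}: grades must be integers in 0..3")
    bad = ~df["roi_name"].isin(RATING_ROI_NAMES)
    if bad.any():
        raise ValidationError(f"{path}: unknown rating ROI names {sorted(df.loc[bad, 'roi_name'].unique())}")
    if df.duplicated(["subject_id", "session", "roi_name"]).any():
        raise ValidationError(f"{path}: duplicate (subject, session, roi) rows")
    return df
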