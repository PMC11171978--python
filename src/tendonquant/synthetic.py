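"""Deterministic synthetic fixtures: phantom images and simulated datasets.

Every generator is a pure function of its spec (seed included), so repeated
calls are bit-identical. The phantom emulates a longitudinal tendon view:
multiplicative Rayleigh speckle over horizontal fibrillar banding, optional
hypoechoic lesions, and a bright bone band that can be interrupted by gaps
(ground truth for the fragment count). Statistical generators draw from the
random-intercept logistic model and from a tunable-agreement rating mixture.

No claim of acoustic fidelity is made; the point is controllable ground
truth for every pipeline stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from tendonquant.io import (
    FEATURE_NAMES,
    PolyROI,
    RATING_ROI_NAMES,
    RectROI,
    RoiSet,
    UltrasoundImage,
)

#: fixed threshold guaranteed to separate the phantom bone band from speckle
PHANTOM_BONE_THRESHOLD = 160


@dataclass(frozen=True)
class PhantomSpec:
    size: tuple[int, int] = (256, 384)  # rows, cols
    background_mean: float = 60.0
    tendon_mean: float = 110.0
    speckle_scale: float = 1.0  # Rayleigh scale of the (normalized) envelope
    psf_sigma: float = 1.2  # Gaussian point-spread smoothing of the envelope, px
    band_period: float = 12.0  # fibrillar stripe period, rows
    band_contrast: float = 0.25
    lesion_count: int = 0
    lesion_radius: float = 9.0
    lesion_darkening: float = 0.5  # fraction of intensity removed inside a lesion
    #: speckle-fluctuation multiplier inside lesions; > 1/(1 - darkening) makes a
    #: lesion both darker and more contrasty, like disorganized tendon matrix
    lesion_heterogeneity: float = 3.0
    bone_y: int = 190
    bone_thickness: int = 10
    bone_brightness: float = 230.0
    bone_n_gaps: int = 0
    bone_gap_width: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.size
        if self.bone_y + self.bone_thickness > rows:
            raise ValueError("bone band outside image")
        if self.bone_n_gaps < 0 or self.bone_gap_width < 2:
            raise ValueError("invalid bone gap parameters")
        if not 0.0 <= self.lesion_darkening < 1.0:
            raise ValueError("lesion_darkening must be in [0, 1)")


@dataclass(frozen=True)
class SimSpec:
    n_subjects: int = 50
    obs_per_subject: int = 4
    beta0: float = -1.0
    beta1: float = 1.5
    sigma: float = 1.0
    x_mean: float = 0.0
    x_sd: float = 1.0
    #: rater-noise SD added to the linear predictor before grade binning; a
    #: strictly deterministic grade would make grade-based fits separable
    grade_noise_sd: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.obs_per_subject < 1:
            raise ValueError("need >= 2 subjects with >= 1 observation each")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def generate_phantom(spec: PhantomSpec) -> tuple[UltrasoundImage, RoiSet, dict]:
    """Phantom image plus ground-truth ROI set.

    Returns (image, roiset, truth) where truth records the expected bone
    fragment count at :data:`PHANTOM_BONE_THRESHOLD`, lesion centers, and the
    tendon polygon.
    """
    rows, cols = spec.size
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)

    tendon_top, tendon_bottom = int(rows * 0.25), int(rows * 0.60)
    base = np.full((rows, cols), spec.background_mean)
    in_tendon = (yy >= tendon_top) & (yy < tendon_bottom)
    stripes = 1.0 + spec.band_contrast * np.sin(2 * math.pi * yy / spec.band_period)
    base[in_tendon] = spec.tendon_mean * stripes[in_tendon]

    lesions = []
    het = np.ones((rows, cols))
    margin = spec.lesion_radius + 2
    for _ in range(spec.lesion_count):
        cy = rng.uniform(tendon_top + margin, tendon_bottom - margin)
        cx = rng.uniform(margin, cols - margin)
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.lesion_radius**2
        base[inside] *= 1.0 - spec.lesion_darkening
        het[inside] = spec.lesion_heterogeneity
        lesions.append((cy, cx))

    envelope = rng.rayleigh(scale=spec.speckle_scale, size=(rows, cols))
    envelope /= spec.speckle_scale * math.sqrt(math.pi / 2.0)
    if spec.psf_sigma > 0:
        envelope = gaussian_filter(envelope, spec.psf_sigma)  # correlated speckle
    # amplified fluctuations inside lesions; clipping at 0 leaves anechoic foci
    img = np.maximum(base * (1.0 + het * (envelope - 1.0)), 0.0)

    # bright specular bone band: additive Gaussian noise, not full speckle,
    # so the band stays safely above PHANTOM_BONE_THRESHOLD
    band = (yy >= spec.bone_y) & (yy < spec.bone_y + spec.bone_thickness)
    img[band] = spec.bone_brightness + rng.normal(0.0, 5.0, size=int(band.sum()))
    if spec.bone_n_gaps:
        centers = np.linspace(0, cols, spec.bone_n_gaps + 2)[1:-1]
        for cx in centers:
            gap = band & (np.abs(xx - cx) <= spec.bone_gap_width / 2.0)
            img[gap] = spec.background_mean * envelope[gap]

    image = UltrasoundImage(pixels=np.clip(np.rint(img), 0, 255).astype(np.uint8))

    x_l, x_r = int(cols * 0.1), int(cols * 0.9)
    body_h = tendon_bottom - tendon_top
    quality = RectROI("quality", x0=x_l, y0=tendon_top + body_h // 4, width=x_r - x_l, height=body_h // 2)
    upper = RectROI("upper_edge", x0=x_l, y0=max(0, tendon_top - 8), width=x_r - x_l, height=16)
    lower = RectROI("lower_edge", x0=x_l, y0=tendon_bottom - 8, width=x_r - x_l, height=16)
    bone = RectROI(
        "bone",
        x0=x_l,
        y0=max(0, spec.bone_y - 10),
        width=x_r - x_l,
        height=min(rows - max(0, spec.bone_y - 10), spec.bone_thickness + 20),
    )
    poly = PolyROI(
        vertices=(
            (float(x_l), float(tendon_top)),
            (float(x_r), float(tendon_top)),
            (float(x_r), float(tendon_bottom)),
            (float(x_l), float(tendon_bottom)),
        )
    )
    roiset = RoiSet(image_id=f"phantom-{spec.seed}", rects=(quality, upper, lower, bone), poly=poly)
    roiset.validate_against(image)
    truth = {
        "n_bone_fragments": spec.bone_n_gaps + 1,
        "bone_threshold": PHANTOM_BONE_THRESHOLD,
        "lesions": lesions,
        "tendon_polygon": poly.vertices,
        "tendon_width_px": float(body_h),
    }
    return image, roiset, truth


def generate_glmm_dataset(spec: SimSpec) -> pd.DataFrame:
    """Longitudinal dataset from the random-intercept logistic model.

    Columns: subject_id, obs, x, y (binary draw), grade (ordinal 0-3 from
    empirical quartiles of the linear predictor, so all grades occur with
    non-trivial frequency).
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_subjects, spec.obs_per_subject
    u = rng.normal(0.0, spec.sigma, size=n)
    x = rng.normal(spec.x_mean, spec.x_sd, size=(n, m))
    eta = spec.beta0 + spec.beta1 * x + u[:, None]
    y = rng.uniform(size=(n, m)) < expit(eta)
    rated = eta + rng.normal(0.0, spec.grade_noise_sd, size=(n, m))
    cuts = np.quantile(rated, [0.25, 0.5, 0.75])
    grade = np.digitize(rated, cuts)
    return pd.DataFrame(
        {
            "subject_id": np.repeat([f"S{i:04d}" for i in range(n)], m),
            "obs": np.tile(np.arange(1, m + 1), n),
            "x": x.ravel(),
            "y": y.astype(int).ravel(),
            "grade": grade.astype(int).ravel(),
        }
    )


def generate_rating_pairs(n: int, agreement_level: float, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Paired ordinal 0-3 ratings with tunable session-2 agreement.

    Session 1 is uniform over {0..3}; session 2 copies it with probability
    ``agreement_level`` and is resampled uniformly otherwise, which makes the
    expected kappa a simple function of the agreement level.
    """
    if not 0.0 <= agreement_level <= 1.0:
        raise ValueError("agreement_level must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    s1 = rng.integers(0, 4, size=n)
    resample = rng.uniform(size=n) >= agreement_level
    s2 = np.where(resample, rng.integers(0, 4, size=n), s1)
    return s1, s2


def generate_study_tables(
    n_subjects: int = 40,
    seed: int = 0,
    signal_features: tuple[str, ...] = (
        "quality_glds_homogeneity",
        "bone_glcm_contrast",
        "morph_mean_width",
        "upper_edge_glcm_idm",
        "lower_edge_glds_contrast",
    ),
    noise_sd: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired-session feature and rating tables for end-to-end pipeline tests.

    A latent per-subject severity drives both the ordinal grades of every
    rating ROI and a handful of designated signal features; the remaining
    features are session noise. Returns (features, ratings): features has
    one row per (subject, session) with the 51 canonical columns; ratings is
    long-form (subject_id, session, roi_name, grade).
    """
    rng = np.random.default_rng(seed)
    severity = rng.uniform(-2.0, 2.0, size=n_subjects)
    subjects = [f"S{i:04d}" for i in range(n_subjects)]

    feat_rows = []
    rating_rows = []
    cuts = np.quantile(severity, [0.25, 0.5, 0.75])
    for i, subj in enumerate(subjects):
        for session in (1, 2):
            row: dict[str, object] = {"image_id": f"{subj}-s{session}", "subject_id": subj, "session": session}
            for name in FEATURE_NAMES:
                signal = severity[i] if name in signal_features else 0.0
                row[name] = signal + rng.normal(0.0, noise_sd)
            feat_rows.append(row)
            for roi in RATING_ROI_NAMES:
                wobble = severity[i] + rng.normal(0.0, 0.3)
                grade = int(np.digitize(wobble, cuts))
                rating_rows.append({"subject_id": subj, "session": session, "roi_name": roi, "grade": grade})
    features = pd.DataFrame(feat_rows, columns=["image_id", "subject_id", "session", *FEATURE_NAMES])
    ratings = pd.DataFrame(rating_rows)
    return features, ratings
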