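"""End-to-end orchestration: image -> 51-variable vector -> reliability -> prediction."""

from __future__ import annotations

import json

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tendonquant.bone import bone_features, segment_bone
from tendonquant.config import RunConfig
from tendonquant.geometry import morphology_features
from tendonquant.io import (
    FEATURE_NAMES,
    RATING_ROI_NAMES,
    RATING_ROI_TO_PREFIX,
    RECT_ROI_NAMES,
    FeatureVector,
    RoiSet,
    UltrasoundImage,
    ValidationError,
)
from tendonquant.prediction import (
    STATUS_NOT_CREATED,
    STATUS_OK,
    dichotomize,
    fit_glmm,
    lolo_cv,
    roc_auc,
    select_best,
)
from tendonquant.reliability import reliability_table
from tendonquant.texture import texture_vector

TEXTURE_ROI_NAMES = ("quality", "upper_edge", "lower_edge")
RESPONSES = ("Y1", "Y3")


def extract_all(image: UltrasoundImage, rois: RoiSet, config: RunConfig | None = None) -> FeatureVector:
    """Compute the full 51-variable quantitative vector for one image.

    Missing ROIs produce NaN-flagged blocks rather than silent omission, so
    the output always has the canonical 51 names in canonical order.
    """
    config = config or RunConfig()
    rois.validate_against(image)
    values: dict[str, float] = {}

    for roi_name in TEXTURE_ROI_NAMES:
        rect = rois.rect(roi_name)
        if rect is None:
            continue
        tf = texture_vector(
            rect.extract(image),
            levels=config.quant_levels,
            distance=config.glcm_distance,
            angles=config.glcm_angles,
            displacements=config.glds_displacements,
        )
        values.update({f"{roi_name}_{k}": v for k, v in tf.as_dict().items()})

    if rois.poly is not None:
        mf = morphology_features(rois.poly, config.morph_stations, image.pixel_spacing_mm)
        values.update(mf.as_dict())

    bone_rect = rois.rect("bone")
    if bone_rect is not None:
        region = bone_rect.extract(image)
        seg = segment_bone(region, config.bone_threshold, config.bone_min_fragment_px)
        bf = bone_features(
            seg,
            region,
            levels=config.quant_levels,
            distance=config.glcm_distance,
            angles=config.glcm_angles,
            pixel_spacing_mm=image.pixel_spacing_mm,
        )
        values.update(bf.as_dict())

    return FeatureVector(image_id=rois.image_id, values=values)


@dataclass
class ValidationReport:
    """Bundle produced by :func:`run_validation`.

    ``quantitative_reliability``: per-variable kappa-free reliability table;
    ``clinical_reliability``: per-rating-ROI ordinal-grade coefficients;
    ``models``: per (roi, response) ranked model tables;
    ``statuses``: per (roi, response) overall status string.
    """

    config: RunConfig
    quantitative_reliability: pd.DataFrame
    clinical_reliability: pd.DataFrame
    retained: list[str]
    models: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    statuses: dict[tuple[str, str], str] = field(default_factory=dict)
    degenerate_folds: dict[tuple[str, str, str], tuple] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(self.config.to_json())
        self.quantitative_reliability.to_csv(outdir / "reliability_quantitative.csv", index=False)
        self.clinical_reliability.to_csv(outdir / "reliability_clinical.csv", index=False)
        for (roi, resp), table in self.models.items():
            table.to_csv(outdir / f"models_{roi}_{resp}.csv", index=False)
        summary = {
            "retained": self.retained,
            "statuses": {f"{roi}/{resp}": s for (roi, resp), s in self.statuses.items()},
            "selected": {
                f"{roi}/{resp}": (
                    table.iloc[0]["variable"] if len(table) and bool(table.iloc[0]["selected"]) else None
                )
                for (roi, resp), table in self.models.items()
            },
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


def _paired_wide(features: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """One row per subject with <col>_s1/<col>_s2 columns from a two-session table."""
    sessions = sorted(features["session"].unique())
    if sessions != [1, 2]:
        raise ValidationError(f"expected exactly sessions [1, 2], got {sessions}")
    s1 = features[features["session"] == 1].set_index("subject_id")[columns]
    s2 = features[features["session"] == 2].set_index("subject_id")[columns]
    common = s1.index.intersection(s2.index)
    wide = s1.loc[common].add_suffix("_s1").join(s2.loc[common].add_suffix("_s2"))
    return wide.reset_index()


def run_validation(
    features: pd.DataFrame,
    ratings: pd.DataFrame,
    config: RunConfig | None = None,
) -> ValidationReport:
    """The full reliability-and-validity pipeline.

    ``features``: one row per (subject_id, session in {1, 2}) with the 51
    canonical feature columns. ``ratings``: long-form ordinal grades
    (subject_id, session, roi_name, grade).

    Stages: per-variable reliability -> ICC screening -> per rating-ROI and
    response (Y1/Y3) single-covariate random-intercept logistic models on the
    retained variables of that ROI -> leave-one-subject-out CV -> ROC/AUC ->
    highest-AUC selection. Degenerate responses yield a "not created" status.
    """
    config = config or RunConfig()
    for col in ("subject_id", "session"):
        if col not in features.columns:
            raise ValidationError(f"features table lacks column {col!r}")
    feat_cols = [c for c in FEATURE_NAMES if c in features.columns]
    if len(feat_cols) != len(FEATURE_NAMES):
        missing = sorted(set(FEATURE_NAMES) - set(feat_cols))
        raise ValidationError(f"features table lacks {len(missing)} canonical columns, e.g. {missing[:3]}")

    wide_feat = _paired_wide(features, list(FEATURE_NAMES))
    quant_rel = reliability_table(
        wide_feat,
        list(FEATURE_NAMES),
        kind="quantitative",
        icc_form=config.icc_form,
        threshold=config.icc_threshold,
    )
    retained = quant_rel.loc[quant_rel["retained"], "variable"].tolist()

    grades = ratings.pivot_table(
        index="subject_id", columns=["roi_name", "session"], values="grade", aggfunc="first"
    )
    clin_rows = []
    for roi in RATING_ROI_NAMES:
        try:
            a = grades[(roi, 1)].dropna().astype(int)
            b = grades[(roi, 2)].dropna().astype(int)
        except KeyError:
            continue
        common = a.index.intersection(b.index)
        wide = pd.DataFrame({f"{roi}_s1": a.loc[common], f"{roi}_s2": b.loc[common]}).reset_index()
        table = reliability_table(wide, [roi], kind="clinical", icc_form=config.icc_form, threshold=config.icc_threshold)
        clin_rows.append(table)
    clinical_rel = pd.concat(clin_rows, ignore_index=True) if clin_rows else pd.DataFrame()

    report = ValidationReport(
        config=config,
        quantitative_reliability=quant_rel,
        clinical_reliability=clinical_rel,
        retained=retained,
    )

    merged = features.merge(ratings, on=["subject_id", "session"], how="inner")
    for roi in RATING_ROI_NAMES:
        prefix = RATING_ROI_TO_PREFIX[roi]
        roi_vars = [v for v in retained if v.startswith(prefix)]
        roi_data = merged[merged["roi_name"] == roi]
        for resp in RESPONSES:
            key = (roi, resp)
            if roi_data.empty:
                report.statuses[key] = STATUS_NOT_CREATED
                report.models[key] = select_best({})
                continue
            y = dichotomize(roi_data["grade"].to_numpy(), resp)
            if len(np.unique(y)) < 2 or len(roi_data["subject_id"].unique()) < 3 or not roi_vars:
                report.statuses[key] = STATUS_NOT_CREATED if len(np.unique(y)) < 2 else STATUS_OK
                report.models[key] = select_best(
                    {v: {"status": STATUS_NOT_CREATED} for v in roi_vars}
                    if len(np.unique(y)) < 2
                    else {}
                )
                continue
            results: dict[str, dict] = {}
            for var in roi_vars:
                x = roi_data[var].to_numpy(dtype=float)
                subj = roi_data["subject_id"].to_numpy()
                ok = np.isfinite(x)
                if len(np.unique(y[ok])) < 2 or len(np.unique(subj[ok])) < 3:
                    results[var] = {"status": STATUS_NOT_CREATED}
                    continue
                xv = x[ok]
                if config.standardize:
                    sd = xv.std()
                    xv = (xv - xv.mean()) / (sd if sd > 0 else 1.0)
                fit = fit_glmm(xv, y[ok], subj[ok], method=config.glmm_method, n_nodes=config.glmm_nodes)
                if fit.status == STATUS_NOT_CREATED:
                    results[var] = {"status": fit.status}
                    continue
                cv = lolo_cv(xv, y[ok], subj[ok], method=config.glmm_method, n_nodes=config.glmm_nodes)
                roc = roc_auc(cv.prob, cv.y)
                if cv.degenerate_folds:
                    report.degenerate_folds[(roi, resp, var)] = cv.degenerate_folds
                results[var] = {
                    "status": fit.status,
                    "auc": roc.auc,
                    "beta0": fit.beta0,
                    "beta1": fit.beta1,
                    "se_beta1": fit.se_beta1,
                    "sigma2": fit.sigma2,
                }
            report.statuses[key] = STATUS_OK
            report.models[key] = select_best(results)
    return report
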