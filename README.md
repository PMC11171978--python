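# tendonquant

Quantitative assessment of tendon B-mode ultrasound images, plus the
statistical pipeline needed to validate such measurements against an
expert's ordinal grading.

Given an 8-bit grayscale PNG and a set of user-supplied regions of interest
(three texture rectangles — tissue quality, upper edge, lower edge — a
tendon-shaped polygon, and a bone rectangle), the package computes a
canonical **51-variable feature vector**:

| block | variables |
| --- | --- |
| quality / upper edge / lower edge | 13 each: 6 GLCM (contrast, sum average, sum-of-squares variance, difference variance, correlation, inverse difference moment), 5 GLDS (homogeneity, contrast, angular second moment, entropy, mean), 2 Haar-detail statistics (mean, variance) |
| morphology (polygon) | max / min / mean width, parallelism (width SD), max/min width ratio |
| bone (thresholded) | fragment count, area, perimeter, convexity, GLCM homogeneity / contrast / correlation |

The statistics side covers test–retest reliability and validity:

* **Reliability** — quadratic-weighted kappa for ordinal grades; single-measure
  intraclass correlations (one-way, two-way agreement, two-way consistency —
  verified against `pingouin`); tie-corrected Kendall's W; and an ICC
  screening rule (variables with ICC < 0.75 are rejected as predictors).
* **Validity** — per variable, a random-intercept logistic mixed model
  (marginal likelihood by vectorized Gauss–Hermite quadrature, or a Laplace
  approximation; both match R `lme4` to ~6 decimals), leave-one-subject-out
  cross-validation with new-subject prediction at the fixed effects,
  midrank ROC/AUC on the pooled cross-validated probabilities, and
  highest-AUC model selection per ROI and response (Y1 = any change,
  Y3 = severe change). Single-class responses are reported as
  "model not created" instead of producing a degenerate fit.

A synthetic module generates deterministic phantoms (correlated Rayleigh
speckle, fibrillar banding, hypoechoic lesions, a fragmentable bright bone
band with ground-truth fragment counts) and simulated longitudinal datasets,
so the whole pipeline is testable without clinical data.

## CLI

```sh
tendonquant synth --out fixtures --n-images 3 --n-subjects 20 --seed 0
tendonquant features --image fixtures/phantom_000.png \
    --rois fixtures/phantom_000.rois.json --out features.csv
tendonquant reliability --features fixtures/features.csv \
    --ratings fixtures/ratings.csv --out reliability_out
tendonquant predict --merged fixtures/features.csv \
    --ratings fixtures/ratings.csv --out predict_out
tendonquant all --features fixtures/features.csv \
    --ratings fixtures/ratings.csv --out report_out
```

ROI files are JSON (`{"quality": [x0, y0, width, height], ...,
"morphology": [[x, y], ...]}`, 0-based, half-open rectangles). Feature and
rating tables are CSV; reports are CSV/JSON bundles that embed the resolved
configuration. Exit codes: 0 success, 2 validation error, 3 completed with
degenerate ("model not created") sections.

## Notes

* All estimators are deterministic; every stochastic generator takes a seed.
* Undefined values (GLCM correlation of a constant region, convexity of an
  empty segmentation, width ratio of a pinched polygon) are carried as NaN
  and excluded pairwise downstream, never coerced.
* The pooled leave-one-subject-out AUC is pessimistically biased at chance
  level (fold intercepts anti-correlate with the held-out subject's
  prevalence). This is intrinsic to pooled cross-validated probabilities —
  R `lme4` predictions reproduce it exactly — and is documented in the test
  suite rather than hidden.
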