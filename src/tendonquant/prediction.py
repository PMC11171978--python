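"""Validity analysis: random-intercept logistic mixed models and cross-validated ROC/AUC.

For one quantitative covariate x and a dichotomized ordinal response, the
model is

    logit P(Y_ij = 1 | x_ij, u_j) = beta0 + beta1 * x_ij + u_j,
    u_j ~ N(0, sigma^2) per subject j,

fitted by maximizing the marginal likelihood with the per-subject random
intercept integrated out by Gauss-Hermite quadrature (default) or a Laplace
approximation. Validity is assessed by leave-one-subject-out
cross-validation: each subject's observations are predicted by a model fitted
on everyone else, with the new subject's random effect at its prior mean 0,
and the pooled cross-validated probabilities are scored by ROC/AUC.

A response with a single observed class yields a "not created" status rather
than a degenerate fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import approx_fprime, minimize
from scipy.special import expit
from scipy.stats import rankdata

STATUS_OK = "ok"
STATUS_NOT_CREATED = "not_created"
STATUS_NON_CONVERGED = "non_converged"

_BETA_BOUND = 60.0
_SIGMA_BOUND = 30.0


@dataclass(frozen=True)
class GlmmFit:
    beta0: float
    beta1: float
    sigma2: float
    loglik: float
    converged: bool
    status: str
    method: str
    se_beta0: float = math.nan
    se_beta1: float = math.nan
    n_obs: int = 0
    n_subjects: int = 0

    def predict_fixed(self, x) -> np.ndarray:
        """Probability for a new subject (random effect at its prior mean 0)."""
        return expit(self.beta0 + self.beta1 * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class CvPrediction:
    subjects: np.ndarray
    x: np.ndarray
    y: np.ndarray
    prob: np.ndarray
    degenerate_folds: tuple = ()  # subjects whose training fold lost a class


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float


def dichotomize(grades, rule: str) -> np.ndarray:
    """Binary response from ordinal 0-3 grades: Y1 = grade > 0, Y3 = grade == 3."""
    g = np.asarray(grades, dtype=int)
    if g.min() < 0 or g.max() > 3:
        raise ValueError("grades must lie in 0..3")
    if rule == "Y1":
        return (g > 0).astype(int)
    if rule == "Y3":
        return (g == 3).astype(int)
    raise ValueError(f"unknown dichotomization rule {rule!r}; use 'Y1' or 'Y3'")


def _group_layout(subjects) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort observations by subject; return (order, group start offsets, unique subjects)."""
    codes, uniq = pd.factorize(np.asarray(subjects))
    order = np.argsort(codes, kind="stable")
    starts = np.searchsorted(codes[order], np.arange(len(uniq)))
    return order, starts, np.asarray(uniq)


def _nll_ghq(params: np.ndarray, x, y, starts, z, w) -> tuple[float, np.ndarray]:
    """Negative marginal log-likelihood and its gradient, Gauss-Hermite nodes.

    ``x``/``y`` must already be sorted by subject with group boundaries at
    ``starts``. Shapes: nodes K, observations N, subjects J.
    """
    b0, b1, sigma = params
    eta = b0 + b1 * x  # (N,)
    u = math.sqrt(2.0) * sigma * z  # (K,)
    eta_ku = eta[None, :] + u[:, None]  # (K, N)
    ll_obs = y[None, :] * eta_ku - np.logaddexp(0.0, eta_ku)
    s = np.add.reduceat(ll_obs, starts, axis=1)  # (K, J)
    log_a = np.log(w / math.sqrt(math.pi))  # (K,)
    t = s + log_a[:, None]
    m = t.max(axis=0)
    et = np.exp(t - m[None, :])
    lse = et.sum(axis=0)
    loglik = float((m + np.log(lse)).sum())
    # softmax node weights per subject
    omega = et / lse[None, :]  # (K, J)
    resid = y[None, :] - expit(eta_ku)  # (K, N)
    g0 = np.add.reduceat(resid, starts, axis=1)  # (K, J)
    g1 = np.add.reduceat(resid * x[None, :], starts, axis=1)
    d_b0 = float((omega * g0).sum())
    d_b1 = float((omega * g1).sum())
    d_sigma = float((omega * g0 * (math.sqrt(2.0) * z)[:, None]).sum())
    return -loglik, -np.array([d_b0, d_b1, d_sigma])


def _nll_laplace(params: np.ndarray, x, y, starts) -> float:
    """Negative marginal log-likelihood, Laplace approximation at the per-subject mode."""
    b0, b1, sigma = params
    n_subj = len(starts)
    eta_fixed = b0 + b1 * x
    if sigma < 1e-6:
        ll = y * eta_fixed - np.logaddexp(0.0, eta_fixed)
        return -float(ll.sum())
    inv_s2 = 1.0 / sigma**2
    u = np.zeros(n_subj)
    counts = np.diff(np.append(starts, len(x)))
    subj_of = np.repeat(np.arange(n_subj), counts)
    for _ in range(50):  # damped Newton on each subject's mode, vectorized
        eta = eta_fixed + u[subj_of]
        p = expit(eta)
        grad = np.add.reduceat(y - p, starts) - u * inv_s2
        hess = -np.add.reduceat(p * (1.0 - p), starts) - inv_s2
        step = grad / hess
        u_new = u - step
        u = u_new
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta_fixed + u[subj_of]
    p = expit(eta)
    f = np.add.reduceat(y * eta - np.logaddexp(0.0, eta), starts) - 0.5 * u**2 * inv_s2
    h = np.add.reduceat(p * (1.0 - p), starts) + inv_s2
    loglik = float((f - 0.5 * np.log(h) - math.log(sigma)).sum())
    return -loglik


def fit_glmm(
    x,
    y,
    subjects,
    method: str = "ghq",
    n_nodes: int = 25,
    compute_se: bool = True,
    start: tuple[float, float, float] | None = None,
) -> GlmmFit:
    """Maximum-likelihood fit of the random-intercept logistic model.

    Refuses (status ``not_created``) when the response has a single class,
    mirroring the degenerate-response guard of the analysis pipeline.
    Complete separation shows up as estimates pinned at the box bounds and is
    reported as non-converged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if not np.isfinite(x).all():
        raise ValueError("covariate must be finite (filter flagged-missing values first)")
    order, starts, uniq = _group_layout(subjects)
    if len(uniq) < 2:
        raise ValueError("need >= 2 subjects")
    n_classes = len(np.unique(y))
    if n_classes < 2:
        return GlmmFit(
            beta0=math.nan, beta1=math.nan, sigma2=math.nan, loglik=math.nan,
            converged=False, status=STATUS_NOT_CREATED, method=method,
            n_obs=len(x), n_subjects=len(uniq),
        )
    xs, ys = x[order], y[order]

    if method == "ghq":
        z, w = hermgauss(n_nodes)
        fun = lambda p: _nll_ghq(p, xs, ys, starts, z, w)
        jac = True
    elif method == "laplace":
        fun = lambda p: _nll_laplace(p, xs, ys, starts)
        jac = None
    else:
        raise ValueError(f"unknown method {method!r}")

    if start is None:
        p_bar = min(max(ys.mean(), 1e-3), 1 - 1e-3)
        start = (math.log(p_bar / (1 - p_bar)), 0.0, 1.0)
    bounds = [(-_BETA_BOUND, _BETA_BOUND), (-_BETA_BOUND, _BETA_BOUND), (0.0, _SIGMA_BOUND)]
    res = minimize(fun, np.asarray(start, dtype=float), jac=jac, method="L-BFGS-B", bounds=bounds)
    b0, b1, sigma = res.x
    on_bound = abs(b0) >= 0.99 * _BETA_BOUND or abs(b1) >= 0.99 * _BETA_BOUND or sigma >= 0.99 * _SIGMA_BOUND
    converged = bool(res.success) and not on_bound
    se0 = se1 = math.nan
    if compute_se and converged:
        se0, se1 = _wald_se(fun, res.x, jac)
    return GlmmFit(
        beta0=float(b0), beta1=float(b1), sigma2=float(sigma**2),
        loglik=float(-res.fun), converged=converged,
        status=STATUS_OK if converged else STATUS_NON_CONVERGED,
        method=method, se_beta0=se0, se_beta1=se1,
        n_obs=len(x), n_subjects=len(uniq),
    )


def _wald_se(fun, opt: np.ndarray, jac) -> tuple[float, float]:
    """Standard errors of (beta0, beta1) from a finite-difference Hessian of the nll."""
    eps = 1e-5
    if jac:
        grad = lambda p: fun(p)[1]
    else:
        nll = lambda p: fun(p)
        grad = lambda p: approx_fprime(p, nll, 1.49e-8)
    k = len(opt)
    hess = np.zeros((k, k))
    for i in range(k):
        step = np.zeros(k)
        step[i] = eps
        hi = max(opt[i] - eps, 0.0) if i == 2 else opt[i] - eps  # sigma stays >= 0
        lo_pt = opt.copy()
        lo_pt[i] = hi
        hess[i] = (grad(opt + step) - grad(lo_pt)) / (opt[i] + eps - hi)
    hess = 0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(hess)
        if cov[0, 0] <= 0 or cov[1, 1] <= 0:
            raise np.linalg.LinAlgError
        return float(math.sqrt(cov[0, 0])), float(math.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        # fall back to the fixed-effects block with sigma held fixed
        sub = hess[:2, :2]
        try:
            cov = np.linalg.inv(sub)
            return float(math.sqrt(max(cov[0, 0], 0.0))), float(math.sqrt(max(cov[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            return math.nan, math.nan


def lolo_cv(
    x,
    y,
    subjects,
    method: str = "ghq",
    n_nodes: int = 25,
) -> CvPrediction:
    """Leave-one-subject-out cross-validated probabilities.

    Each held-out subject is predicted by the fixed-effects part of a model
    fitted on all remaining subjects (new random-effect level at 0), so the
    held-out labels can never influence the held-out predictions. Folds whose
    training data lose one response class fall back to the training
    prevalence, and those subjects are reported as degenerate folds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    subjects = np.asarray(subjects)
    if len(np.unique(subjects)) < 3:
        raise ValueError("leave-one-subject-out needs >= 3 subjects")
    if len(np.unique(y)) < 2:
        raise ValueError("response has a single class; model not created")
    prob = np.empty(len(x), dtype=float)
    degenerate = []
    for subj in np.unique(subjects):
        test = subjects == subj
        train = ~test
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            prev = y_tr.mean()
            n_tr = len(y_tr)
            prob[test] = min(max(prev, 0.5 / n_tr), 1 - 0.5 / n_tr)
            degenerate.append(subj)
            continue
        # deterministic cold start: fold fits depend only on their training data,
        # so held-out labels cannot influence held-out predictions even via the
        # optimizer's path
        fit = fit_glmm(
            x[train], y_tr, subjects[train],
            method=method, n_nodes=n_nodes, compute_se=False,
        )
        prob[test] = np.clip(fit.predict_fixed(x[test]), 1e-12, 1 - 1e-12)
    return CvPrediction(subjects=subjects, x=x, y=y, prob=prob, degenerate_folds=tuple(degenerate))


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC of probability scores against binary labels.

    The AUC is the midrank Mann-Whitney concordance: the probability that a
    random positive scores above a random negative, ties counted half.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(labels, dtype=int)
    n_pos = int(t.sum())
    n_neg = len(t) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute ROC/AUC")
    ranks = rankdata(s)
    auc = (ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        pred = s >= thr
        sens[i] = (pred & (t == 1)).sum() / n_pos
        spec[i] = (~pred & (t == 0)).sum() / n_neg
    return RocResult(thresholds=thresholds, sensitivities=sens, specificities=spec, auc=float(auc))


def select_best(results: dict[str, dict]) -> pd.DataFrame:
    """Rank per-variable model results by cross-validated AUC.

    ``results`` maps variable name to a dict with at least ``status`` and,
    for successful models, ``auc``, ``beta1`` and ``se_beta1``. Ties are
    broken by larger |beta1| / se, then variable name, so ranking is
    deterministic. "Not created" models are listed last with their reasons.
    """
    rows = []
    for name, r in results.items():
        ok = r.get("status") == STATUS_OK and np.isfinite(r.get("auc", math.nan))
        se = r.get("se_beta1", math.nan)
        b1 = r.get("beta1", math.nan)
        zstat = abs(b1) / se if (np.isfinite(se) and se > 0 and np.isfinite(b1)) else 0.0
        rows.append(
            {
                "variable": name,
                "status": r.get("status", STATUS_NOT_CREATED),
                "auc": r.get("auc", math.nan) if ok else math.nan,
                "beta0": r.get("beta0", math.nan),
                "beta1": b1,
                "se_beta1": se,
                "sigma2": r.get("sigma2", math.nan),
                "_z": zstat,
                "_ok": ok,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["_ok", "auc", "_z", "variable"],
        ascending=[False, False, False, True],
        na_position="last",
        kind="stable",
    ).drop(columns=["_z", "_ok"])
    df.insert(0, "rank", range(1, len(df) + 1))
    df["selected"] = False
    if len(df) and df.iloc[0]["status"] == STATUS_OK:
        df.iloc[0, df.columns.get_loc("selected")] = True
    return df.reset_index(drop=True)
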