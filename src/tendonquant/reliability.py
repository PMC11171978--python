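"""Intra-rater reliability: weighted kappa, ICC, Kendall's W, screening.

Session-1 vs session-2 agreement of the ordinal clinical grades is measured
with the quadratic- ("squared-") weighted kappa; agreement of each
quantitative variable with the single-measure intraclass correlation
coefficients (one-way, two-way absolute agreement, two-way consistency) and
the tie-corrected Kendall coefficient of concordance. Quantitative
variables whose screening ICC falls below a threshold (default 0.75) are
rejected as candidate predictors.

Undefined coefficients (zero expected disagreement, zero total variance,
all-tied data) are returned as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass(frozen=True)
class IccResult:
    oneway: float
    agreement: float
    consistency: float
    n_used: int

    def by_form(self, form: str) -> float:
        return {"oneway": self.oneway, "agreement": self.agreement, "consistency": self.consistency}[form]


def weighted_kappa(session1, session2, n_categories: int = 4) -> float:
    """Quadratic-weighted Cohen's kappa for paired ordinal ratings.

    Disagreement weights are ``w_ij = ((i - j) / (k - 1))**2``; kappa is
    ``1 - sum(w * observed) / sum(w * expected)`` with expected the product
    of the marginals. Returns NaN when the expected disagreement is zero
    (both sessions constant).
    """
    a = np.asarray(session1, dtype=int)
    b = np.asarray(session2, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("sessions must be equal-length 1D arrays")
    if a.size < 2:
        raise ValueError("need at least 2 paired ratings")
    k = n_categories
    if a.min() < 0 or b.min() < 0 or a.max() >= k or b.max() >= k:
        raise ValueError(f"grades must lie in 0..{k - 1}")
    obs = np.zeros((k, k))
    np.add.at(obs, (a, b), 1.0)
    obs /= a.size
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = ((i - j) / (k - 1)) ** 2
    denom = float((w * exp).sum())
    if denom <= 1e-15:
        return math.nan
    return 1.0 - float((w * obs).sum()) / denom


def icc(session1, session2) -> IccResult:
    """Single-measure intraclass correlations of two paired sessions.

    Computes all three classical single-rater forms from the two-way
    mean-squares decomposition: one-way random, two-way absolute agreement
    and two-way consistency. Pairs with a non-finite value in either session
    are excluded; at least 3 complete pairs are required.
    """
    a = np.asarray(session1, dtype=float)
    b = np.asarray(session2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("sessions must be equal-length 1D arrays")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = a.size
    if n < 3:
        raise ValueError("ICC needs >= 3 complete pairs")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ss_within = ss_total - ss_rows
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = ss_within / (n * (k - 1))
    if ss_total <= 1e-15:
        return IccResult(math.nan, math.nan, math.nan, n)
    icc1 = _safe_ratio(msr - msw, msr + (k - 1) * msw)
    icc_c = _safe_ratio(msr - mse, msr + (k - 1) * mse)
    icc_a = _safe_ratio(msr - mse, msr + (k - 1) * mse + (k / n) * (msc - mse))
    return IccResult(oneway=icc1, agreement=icc_a, consistency=icc_c, n_used=n)


def _safe_ratio(num: float, den: float) -> float:
    return math.nan if abs(den) <= 1e-15 else float(num / den)


def kendall_w(matrix) -> float:
    """Tie-corrected Kendall coefficient of concordance.

    ``matrix`` is (n subjects) x (m sessions); sessions rank the subjects
    with midranks for ties. Returns NaN when every session is fully tied.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n x m matrix with n >= 2 subjects and m >= 2 sessions")
    if not np.isfinite(x).all():
        raise ValueError("matrix must be complete (pairwise-filter before calling)")
    n, m = x.shape
    ranks = np.column_stack([rankdata(x[:, j]) for j in range(m)])
    r_sums = ranks.sum(axis=1)
    s = 12.0 * (r_sums**2).sum() - 3.0 * m**2 * n * (n + 1) ** 2
    tie_term = 0.0
    for j in range(m):
        _, counts = np.unique(x[:, j], return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    denom = m**2 * n * (n**2 - 1) - m * tie_term
    if denom <= 1e-15:
        return math.nan
    return float(s / denom)


def screen_variables(icc_values: dict[str, float], threshold: float = 0.75) -> tuple[list[str], dict[str, str]]:
    """Apply the ICC screening rule: keep ICC >= threshold.

    Returns (retained names in input order, rejection reasons by name).
    Undefined (NaN) ICCs are rejected with reason "undefined".
    """
    retained: list[str] = []
    rejected: dict[str, str] = {}
    for name, value in icc_values.items():
        if not np.isfinite(value):
            rejected[name] = "undefined"
        elif value < threshold:
            rejected[name] = f"icc {value:.4f} < {threshold}"
        else:
            retained.append(name)
    return retained, rejected


def reliability_table(
    paired: pd.DataFrame,
    value_columns: list[str],
    kind: str = "quantitative",
    icc_form: str = "agreement",
    threshold: float = 0.75,
    n_categories: int = 4,
) -> pd.DataFrame:
    """Per-variable reliability coefficients from a wide paired table.

    ``paired`` must hold one row per subject with ``<col>_s1`` / ``<col>_s2``
    columns for each entry of ``value_columns``. For ``kind="clinical"`` a
    quadratic-weighted kappa is added. Output columns: variable, kappa,
    icc_1, icc_a, icc_c, kcc, n_used, retained.
    """
    rows = []
    for col in value_columns:
        a = paired[f"{col}_s1"].to_numpy(dtype=float)
        b = paired[f"{col}_s2"].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        kappa = math.nan
        if kind == "clinical" and ok.sum() >= 2:
            kappa = weighted_kappa(a[ok].astype(int), b[ok].astype(int), n_categories)
        try:
            r = icc(a, b)
            icc_vals = (r.oneway, r.agreement, r.consistency)
            n_used = r.n_used
            screen = r.by_form(icc_form)
        except ValueError:
            icc_vals = (math.nan, math.nan, math.nan)
            n_used = int(ok.sum())
            screen = math.nan
        kcc = kendall_w(np.column_stack([a[ok], b[ok]])) if ok.sum() >= 2 else math.nan
        rows.append(
            {
                "variable": col,
                "kappa": kappa,
                "icc_1": icc_vals[0],
                "icc_a": icc_vals[1],
                "icc_c": icc_vals[2],
                "kcc": kcc,
                "n_used": n_used,
                "retained": bool(np.isfinite(screen) and screen >= threshold),
            }
        )
    return pd.DataFrame(rows)
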