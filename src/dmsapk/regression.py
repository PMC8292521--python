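"""Median (50th-percentile quantile) regression of kidney uptake fraction on
age, weight, and sex.

The coefficient vector minimizes the absolute-deviation loss
``sum_i |y_i - x_i' beta|`` (the tau = 0.5 check function), solved exactly as
a linear program (HiGHS): minimize ``sum(u + v)`` subject to
``X beta + u - v = y`` with ``u, v >= 0``.  Median regression is robust to
non-normal outcomes, which is why it is the estimator of choice for the
uptake-fraction cohort analysis.

Confidence intervals and P values come from a nonparametric bootstrap
(resampling patients with replacement, percentile CIs, normal-approximation
P from the bootstrap SE) with a fixed seed, so results are reproducible
bit-for-bit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linprog

__all__ = [
    "l1_fit",
    "median_regression",
    "run_cohort_regressions",
    "AGE_CATEGORY_EDGES",
    "age_category",
]

#: Age-category edges in years: 0-<3 (reference), 3-<7, 7-<13, >=13.
AGE_CATEGORY_EDGES = (3.0, 7.0, 13.0)
_AGE_LABELS = ("0 to <3 years", "3 to <7 years", "7 to <13 years", ">=13 years")


def age_category(age_y) -> np.ndarray:
    """Categorise ages into the four pediatric bands."""
    return np.array(
        [_AGE_LABELS[int(np.searchsorted(AGE_CATEGORY_EDGES, a, side="right"))]
         for a in np.atleast_1d(np.asarray(age_y, dtype=float))]
    )


def l1_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact L1 (median) regression coefficients via linear programming."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than coefficients ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the offending columns for the caller
        bad = []
        for j in range(p):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(j)
        raise ValueError(f"rank-deficient design: collinear columns {bad}")
    c = np.concatenate([np.zeros(p), np.ones(2 * n)])
    A_eq = np.hstack([X, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"L1 linear program failed: {res.message}")
    return res.x[:p]


def _bootstrap(X, y, beta_hat, n_boot, seed):
    rng = np.random.default_rng(seed)
    n = len(y)
    betas = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            betas[b] = l1_fit(X[idx], y[idx])
        except (ValueError, RuntimeError):
            betas[b] = beta_hat  # degenerate resample: fall back to the point fit
    return betas


def median_regression(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Median regression with bootstrap CIs and P values.

    ``X`` must already contain an intercept column if one is wanted.
    Returns a DataFrame with one row per coefficient: ``term, coefficient,
    ci_low, ci_high, p_value``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[1] != len(names):
        raise ValueError("one name per design column is required")
    beta = l1_fit(X, y)
    betas = _bootstrap(X, y, beta, n_boot, seed)
    alpha = (1.0 - ci_level) / 2.0
    lo = np.quantile(betas, alpha, axis=0)
    hi = np.quantile(betas, 1.0 - alpha, axis=0)
    se = betas.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, np.abs(beta) / se, np.inf)
    p = 2.0 * stats.norm.sf(z)
    # a percentile CI need not contain the point estimate in pathological
    # resamples; widen so the reported interval always brackets it
    lo = np.minimum(lo, beta)
    hi = np.maximum(hi, beta)
    return pd.DataFrame(
        {
            "term": names,
            "coefficient": beta,
            "ci_low": lo,
            "ci_high": hi,
            "p_value": p,
        }
    )


def _clinical_frame(records) -> pd.DataFrame:
    from .kinetics import records_to_frame

    df = records_to_frame(records)
    df = df[df["modality"] == "SPECT"].copy()
    if df["patient_id"].duplicated().any():
        raise ValueError("expected one clinical-time (SPECT) record per patient")
    df["female"] = (df["sex"] == "female").astype(float)
    df["weight_per_5kg"] = df["weight_kg"] / 5.0
    df["age_cat"] = age_category(df["age_y"].to_numpy())
    return df


def run_cohort_regressions(
    records, n_boot: int = 2000, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariate and multivariable median regressions of the clinical-time
    kidney fraction on age, age category, weight (per 5 kg), and sex.

    Mirrors the published analysis layout: univariate fits per covariate and
    a multivariable fit with age + weight + sex; significance flagged at
    P < 0.05.  Returns ``(univariate, multivariable)`` DataFrames.
    """
    df = _clinical_frame(records)
    y = df["fraction"].to_numpy()
    n = len(df)
    ones = np.ones(n)

    uni_rows = []

    def _fit(X, names, label_rows, boot_seed):
        res = median_regression(X, y, names, n_boot=n_boot, seed=boot_seed)
        for i in label_rows:
            row = res.iloc[i].to_dict()
            row["significant"] = row["p_value"] < 0.05
            uni_rows.append(row)

    _fit(np.column_stack([ones, df["age_y"]]), ["intercept", "age_per_year"], [1], seed)
    # age categories: reference 0-<3; drop empty levels with a warning
    cats_present = [c for c in _AGE_LABELS if (df["age_cat"] == c).any()]
    dropped = set(_AGE_LABELS) - set(cats_present)
    if dropped:
        warnings.warn(f"empty age categories dropped: {sorted(dropped)}")
    dummy_labels = [c for c in cats_present if c != _AGE_LABELS[0]]
    if dummy_labels:
        dummies = np.column_stack(
            [(df["age_cat"] == c).astype(float) for c in dummy_labels]
        )
        _fit(
            np.column_stack([ones, dummies]),
            ["intercept"] + dummy_labels,
            list(range(1, 1 + len(dummy_labels))),
            seed + 1,
        )
    _fit(
        np.column_stack([ones, df["weight_per_5kg"]]),
        ["intercept", "weight_per_5kg"],
        [1],
        seed + 2,
    )
    _fit(np.column_stack([ones, df["female"]]), ["intercept", "female"], [1], seed + 3)
    univariate = pd.DataFrame(uni_rows)

    X_multi = np.column_stack([ones, df["age_y"], df["weight_per_5kg"], df["female"]])
    multi = median_regression(
        X_multi,
        y,
        ["intercept", "age_per_year", "weight_per_5kg", "female"],
        n_boot=n_boot,
        seed=seed + 4,
    )
    multi["significant"] = multi["p_value"] < 0.05
    return univariate, multi
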