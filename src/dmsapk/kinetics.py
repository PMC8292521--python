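"""Kidney biokinetic modelling for Tc-99m DMSA.

The organ time-activity model is the ICRP sum-of-exponentials form

    A_s(t) / A_0 = F_S * sum_i a_i * exp(-ln2 / T_i * t)

where ``F_S`` is the fractional distribution to the kidneys (fraction of the
administered activity that would reach the organ absent radioactive decay),
each ``(a_i, T_i)`` pair is a kinetic component with biological half-time
``T_i`` (hours; ``inf`` means no biological clearance), and a negative
``a_i`` encodes the uptake (build-up) phase.  For DMSA the data support a
two-component model with ``a_1`` fixed at -1 (uptake) and ``T_2`` fixed at
infinity (plateau: trapped tracer).

The decay-weighted time-integrated activity coefficient (TIAC, formerly
"residence time") follows in closed form:

    TIAC = F_S * sum_i a_i / (lambda_i + lambda_p),   lambda = ln2 / T

with ``lambda_p = ln2 / T_phys`` the physical decay constant.  The TIAC is
the kinetic input to absorbed-dose calculation.

Fitting is weighted nonlinear least squares on time-binned cohort data.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares

from .projector import LN2, TC99M_HALF_LIFE_H

__all__ = [
    "KidneyUptakeRecord",
    "BiokineticModel",
    "FitResult",
    "TIACResult",
    "model_fraction",
    "bin_records",
    "fit_biokinetic",
    "tiac",
    "tiac_uncertainty",
    "compare_models",
    "load_model",
    "load_binned_table",
    "records_to_frame",
    "frame_to_records",
    "DEFAULT_BIN_WIDTH_H",
]

#: 10-minute binning used for cohort time-activity data (hours).
DEFAULT_BIN_WIDTH_H = 1.0 / 6.0


@dataclass
class KidneyUptakeRecord:
    """One patient x time measurement of fractional kidney uptake.

    ``fraction`` is A_s(t)/A_0 decay-corrected to injection time (i.e. the
    biological fraction).  ``fraction_true`` carries the generating truth for
    synthetic cohorts and is None for measured data.
    """

    patient_id: str
    age_y: float
    weight_kg: float
    sex: str  # "male" | "female"
    group: str  # "retrospective" | "prospective_early" | "prospective_delayed"
    time_h: float
    fraction: float
    modality: str = "SPECT"  # "SPECT" | "planar"
    fraction_true: float | None = None

    def __post_init__(self):
        if self.time_h < 0:
            raise ValueError("time_h must be non-negative")
        if not 0 <= self.fraction <= 1:
            raise ValueError(f"fraction must lie in [0, 1], got {self.fraction}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


_RECORD_COLUMNS = [
    "patient_id",
    "age_y",
    "weight_kg",
    "sex",
    "group",
    "time_h",
    "fraction",
    "modality",
    "fraction_true",
]


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in _RECORD_COLUMNS} for r in records])


def frame_to_records(df: pd.DataFrame) -> list[KidneyUptakeRecord]:
    out = []
    for row in df.itertuples(index=False):
        d = {c: getattr(row, c) for c in _RECORD_COLUMNS if hasattr(row, c)}
        ft = d.get("fraction_true")
        if ft is not None and (isinstance(ft, float) and math.isnan(ft)):
            d["fraction_true"] = None
        out.append(KidneyUptakeRecord(**d))
    return out


@dataclass(frozen=True)
class BiokineticModel:
    """F_S plus exponential components ``(a_i, T_i)``; T_i may be ``inf``."""

    F_S: float
    components: tuple[tuple[float, float], ...]
    name: str = ""

    def __post_init__(self):
        comps = tuple((float(a), float(T)) for a, T in self.components)
        object.__setattr__(self, "components", comps)
        if self.F_S < 0:
            raise ValueError("F_S must be non-negative")
        if sum(a for a, _ in comps) < -1e-12:
            raise ValueError("sum of a_i must be non-negative (fraction at t=0)")
        for a, T in comps:
            if T <= 0:
                raise ValueError("component half-times must be positive")

    @property
    def plateau(self) -> float:
        """Limit of the fraction as t -> infinity (components with finite T
        decay away)."""
        return self.F_S * sum(a for a, T in self.components if math.isinf(T))


def model_fraction(model: BiokineticModel, t_h) -> np.ndarray | float:
    """Evaluate A_s(t)/A_0 for the model; ``T_i = inf`` contributes a
    constant (rate-0) term."""
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = np.zeros_like(t)
    for a, T in model.components:
        lam = 0.0 if math.isinf(T) else LN2 / T
        out = out + a * np.exp(-lam * t)
    out = model.F_S * out
    return float(out) if out.ndim == 0 else out


def load_model(name: str) -> BiokineticModel:
    """Load a named published parameter set ('icrp53', 'evans',
    'current_study') shipped with the package."""
    text = (
        importlib.resources.files("dmsapk").joinpath("data/models.yaml").read_text()
    )
    sets = yaml.safe_load(text)
    if name not in sets:
        raise KeyError(f"unknown model {name!r}; available: {sorted(sets)}")
    entry = sets[name]
    comps = tuple((c["a"], float(c["T_h"])) for c in entry["components"])
    return BiokineticModel(F_S=entry["F_S"], components=comps, name=name)


def load_binned_table() -> pd.DataFrame:
    """The published 10-minute-binned pediatric kidney uptake fractions
    (retrospective cohort) shipped with the package."""
    path = importlib.resources.files("dmsapk").joinpath("data/binned_uptake.csv")
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p)


def bin_records(records, bin_width_h: float = DEFAULT_BIN_WIDTH_H) -> pd.DataFrame:
    """Bin uptake records into half-open time bins aligned at t=0.

    Returns a DataFrame with columns ``t_start_h, t_end_h, t_mid_h, n,
    mean_fraction, sd_fraction, cv_pct``; SD/CV are NaN for single-record
    bins and empty bins are omitted.  Bin representative time is the
    midpoint of the true (unrounded) bin edges.
    """
    if bin_width_h <= 0:
        raise ValueError("bin_width_h must be positive")
    t = np.array([r.time_h for r in records], dtype=float)
    y = np.array([r.fraction for r in records], dtype=float)
    idx = np.floor(t / bin_width_h).astype(int)
    rows = []
    for k in sorted(set(idx)):
        sel = idx == k
        n = int(sel.sum())
        mean = float(y[sel].mean())
        sd = float(y[sel].std(ddof=1)) if n >= 2 else np.nan
        cv = 100.0 * sd / mean if (n >= 2 and mean > 0) else np.nan
        rows.append(
            {
                "t_start_h": k * bin_width_h,
                "t_end_h": (k + 1) * bin_width_h,
                "t_mid_h": (k + 0.5) * bin_width_h,
                "n": n,
                "mean_fraction": mean,
                "sd_fraction": sd,
                "cv_pct": cv,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FitResult:
    """Constrained weighted least-squares fit of the two-component model."""

    model: BiokineticModel
    se: dict[str, float]
    covariance: np.ndarray  # order (F_S, T1, a2)
    wrss: float
    weights: np.ndarray
    free_names: tuple[str, ...] = ("F_S", "T1", "a2")

    @property
    def params(self) -> dict[str, float]:
        (a1, T1), (a2, _) = self.model.components
        return {"F_S": self.model.F_S, "a1": a1, "T1": T1, "a2": a2}


def _resolve_weights(table: pd.DataFrame, weights) -> np.ndarray:
    n = table["n"].to_numpy(dtype=float)
    if isinstance(weights, str):
        if weights == "equal":
            return np.ones_like(n)
        if weights == "n":
            return n
        if weights == "inverse_variance":
            sd = table["sd_fraction"].to_numpy(dtype=float)
            pooled = np.nanmean(sd)
            sd = np.where(np.isfinite(sd) & (sd > 0), sd, pooled)
            return 1.0 / sd**2
        raise ValueError(f"unknown weighting scheme {weights!r}")
    w = np.asarray(weights, dtype=float)
    if w.shape != n.shape or np.any(w < 0):
        raise ValueError("weights must be a non-negative vector, one per bin")
    return w


def fit_biokinetic(
    table: pd.DataFrame,
    weights: str | np.ndarray = "equal",
    x0: tuple[float, float, float] | None = None,
) -> FitResult:
    """Fit F_S, T1, a2 of ``F_S*(a2 - exp(-ln2 t/T1))`` to binned data.

    ``a1`` is fixed at -1 (uptake phase) and ``T2`` at infinity (rate 0), the
    constraint under which the two-component DMSA fit is identifiable.
    ``weights``: 'equal' (default), 'n' (per-bin patient count),
    'inverse_variance', or an explicit per-bin vector.  Standard errors are
    asymptotic WLS (inverse weighted normal equations scaled by residual
    variance).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 bins to fit 3 free parameters")
    t = table["t_mid_h"].to_numpy(dtype=float)
    y = table["mean_fraction"].to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("degenerate design: all bin times equal")
    w = _resolve_weights(table, weights)
    sw = np.sqrt(w)

    def f(p, tt):
        F, T1, a2 = p
        return F * (a2 - np.exp(-LN2 / T1 * tt))

    if x0 is None:
        plateau = max(float(np.mean(y[t >= np.median(t)])), 1e-3)
        x0 = (min(plateau / 1.2, 0.99), 1.0, 1.2)
    # a2 >= 1 keeps the modelled fraction non-negative at t = 0 (a1 = -1)
    res = least_squares(
        lambda p: sw * (y - f(p, t)),
        (x0[0], x0[1], max(x0[2], 1.0)),
        bounds=([1e-9, 1e-9, 1.0], [1.0, 1e3, 1e2]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not res.success:
        raise RuntimeError(
            f"biokinetic fit did not converge: {res.message}; last iterate {res.x}, "
            f"objective {2 * res.cost}"
        )
    F, T1, a2 = res.x
    dof = max(len(t) - 3, 1)
    wrss = float(2 * res.cost)
    s2 = wrss / dof
    J = res.jac
    JTJ = J.T @ J
    try:
        cov = np.linalg.inv(JTJ) * s2
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(JTJ) * s2
    cov = 0.5 * (cov + cov.T)
    se = {k: float(np.sqrt(max(v, 0.0))) for k, v in zip(("F_S", "T1", "a2"), np.diag(cov))}
    model = BiokineticModel(F_S=float(F), components=((-1.0, float(T1)), (float(a2), math.inf)))
    return FitResult(model=model, se=se, covariance=cov, wrss=wrss, weights=w)


@dataclass
class TIACResult:
    """Decay-weighted time-integrated activity coefficient (hours)."""

    value_h: float
    se_h: float | None
    half_life_h: float

    def __post_init__(self):
        if self.value_h < 0:
            raise ValueError("TIAC must be non-negative")


def tiac(model: BiokineticModel, half_life_h: float = TC99M_HALF_LIFE_H) -> TIACResult:
    """Closed-form TIAC = F_S * sum_i a_i / (lambda_i + lambda_p) in hours.

    ``lambda_i = ln2/T_i`` (0 for T_i = inf), ``lambda_p = ln2/half_life_h``.
    """
    if half_life_h <= 0:
        raise ValueError("half_life_h must be positive")
    lam_p = LN2 / half_life_h
    total = 0.0
    for a, T in model.components:
        lam = 0.0 if math.isinf(T) else LN2 / T
        if a != 0 and lam + lam_p <= 0:
            raise ValueError("divergent component: a_i > 0 with lambda_i + lambda_p <= 0")
        total += a / (lam + lam_p)
    return TIACResult(value_h=model.F_S * total, se_h=None, half_life_h=half_life_h)


def tiac_uncertainty(
    fit: FitResult,
    half_life_h: float = TC99M_HALF_LIFE_H,
    n_draws: int = 5000,
    seed: int = 0,
) -> float:
    """Monte-Carlo SE of the TIAC: draw (F_S, T1, a2) from the fit's
    multivariate normal, truncate to the parameter bounds, evaluate the
    closed-form TIAC per draw, return the sample SD (hours)."""
    cov = np.asarray(fit.covariance, dtype=float)
    eig = np.linalg.eigvalsh(cov)
    if np.min(eig) < -1e-10 * max(np.max(eig), 1.0):
        raise ValueError("fit covariance is not positive semi-definite")
    mean = np.array([fit.params["F_S"], fit.params["T1"], fit.params["a2"]])
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mean, cov, size=n_draws, method="svd")
    lo = np.array([1e-9, 1e-9, 1e-9])
    draws = np.maximum(draws, lo)
    draws[:, 0] = np.minimum(draws[:, 0], 1.0)
    lam_p = LN2 / half_life_h
    vals = draws[:, 0] * (-1.0 / (LN2 / draws[:, 1] + lam_p) + draws[:, 2] / lam_p)
    return float(np.std(vals, ddof=1))


def compare_models(
    models: dict[str, BiokineticModel],
    reference: str = "icrp53",
    half_life_h: float = TC99M_HALF_LIFE_H,
) -> pd.DataFrame:
    """Tabulate parameters + TIAC per model and the percent difference of
    each TIAC relative to ``reference``, rounded to the nearest whole
    percent."""
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    if reference not in models:
        raise ValueError(f"reference model {reference!r} not among {sorted(models)}")
    ref_tiac = tiac(models[reference], half_life_h).value_h
    rows = []
    for name, m in models.items():
        comps = list(m.components)
        val = tiac(m, half_life_h).value_h
        rows.append(
            {
                "model": name,
                "F_S": m.F_S,
                "T1_h": comps[0][1] if comps else np.nan,
                "T2_h": comps[1][1] if len(comps) > 1 else np.nan,
                "a1": comps[0][0] if comps else np.nan,
                "a2": comps[1][0] if len(comps) > 1 else np.nan,
                "tiac_h": val,
                "pct_diff_vs_ref": int(round(100.0 * (val - ref_tiac) / ref_tiac)),
            }
        )
    return pd.DataFrame(rows)
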