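"""Pooled-QC quantile-spline drift correction.

Instrument sensitivity drifts slowly over a run; because every pooled QC is
the same sample, the trajectory of a feature's QC intensities along injection
order traces that drift.  Per feature, the conditional median of the QC
intensities is estimated by nonparametric quantile regression on a cubic
B-spline basis of the injection order,

    minimize  sum_j rho_tau(y_j - B(x_j) . beta),
    rho_tau(u) = u * (tau - 1[u < 0]),

with tau = 0.5 and 16 degrees of freedom by default (a cubic basis with 12
internal knots at equally spaced quantiles of the QC orders; boundary knots
at the ends of the full run).  The check loss is minimized exactly as a
linear program (HiGHS).  Every injection is then re-anchored multiplicatively
to the median of the feature's original QC intensities:

    corrected(i) = raw(i) * qc_median / curve(order_i)

so QCs lying exactly on the fitted curve become constant at ``qc_median``.
Outside the QC bracket the curve is clamped to its boundary value rather
than extrapolated (spline extrapolation is wild, and all serum samples are
bracketed by design anyway).  Features whose fitted curve is not strictly
positive anywhere it is needed are passed through uncorrected and reported
as failures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.interpolate import BSpline
from scipy.optimize import linprog

from .feature_table import FeatureTable, StudyDesign, FeatureTableError
from .qc_filtering import qc_cv_table

__all__ = [
    "DriftModel",
    "DriftCorrectionError",
    "bspline_basis",
    "fit_quantile_spline",
    "evaluate_drift",
    "correct_feature",
    "correct_table",
    "DriftReport",
]

SPLINE_DEGREE = 3
MIN_DF = SPLINE_DEGREE + 1  # plain cubic, no internal knots


class DriftCorrectionError(FeatureTableError):
    pass


@dataclass
class DriftModel:
    """A fitted per-feature median drift curve."""

    feature_id: str
    knots: np.ndarray  # full knot vector (with repeated boundary knots)
    coefficients: np.ndarray
    tau: float
    df: int  # effective basis dimension actually used
    qc_median: float  # median of the original QC intensities (the anchor)
    fit_orders: np.ndarray  # injection orders of the QCs used in the fit
    objective: float  # minimized check loss

    @property
    def clamp_range(self) -> tuple[float, float]:
        return float(self.fit_orders.min()), float(self.fit_orders.max())


def bspline_basis(
    x: np.ndarray, df: int, boundary: tuple[float, float], degree: int = SPLINE_DEGREE
) -> tuple[np.ndarray, np.ndarray]:
    """Full-rank cubic B-spline design matrix of dimension ``df``.

    Internal knots sit at equally spaced quantiles of ``x``; boundary knots at
    the given range (normally the full run, so the basis covers every
    injection order).  Returns (design matrix, full knot vector).
    """
    if df < MIN_DF:
        raise DriftCorrectionError(f"df must be >= {MIN_DF}")
    lo, hi = boundary
    n_internal = df - degree - 1
    quantiles = np.linspace(0.0, 1.0, n_internal + 2)[1:-1]
    internal = np.quantile(np.asarray(x, float), quantiles) if n_internal else np.array([])
    internal = np.clip(internal, lo, hi)
    knots = np.concatenate([[lo] * (degree + 1), internal, [hi] * (degree + 1)])
    xc = np.clip(np.asarray(x, float), lo, hi)
    design = BSpline.design_matrix(xc, knots, degree, extrapolate=False).toarray()
    return design, knots


def _solve_check_loss(design: np.ndarray, y: np.ndarray, tau: float) -> tuple[np.ndarray, float]:
    """Exact LP solution of min_beta sum rho_tau(y - design . beta)."""
    n, p = design.shape
    # variables: beta+ (p), beta- (p), u (n), v (n); residual = u - v
    c = np.concatenate([np.zeros(2 * p), tau * np.ones(n), (1 - tau) * np.ones(n)])
    a_eq = sparse.hstack(
        [sparse.csr_matrix(design), -sparse.csr_matrix(design), sparse.eye(n), -sparse.eye(n)],
        format="csr",
    )
    res = linprog(c, A_eq=a_eq, b_eq=y, method="highs")
    if not res.success:  # pragma: no cover - HiGHS is reliable on feasible LPs
        raise DriftCorrectionError(f"quantile LP failed: {res.message}")
    beta = res.x[:p] - res.x[p : 2 * p]
    return beta, float(res.fun)


def fit_quantile_spline(
    x,
    y,
    tau: float = 0.5,
    df: int = 16,
    run_range: tuple[float, float] | None = None,
    feature_id: str = "",
) -> DriftModel:
    """Fit the tau-quantile spline of QC intensities y over injection orders x.

    Missing (NaN) pairs are dropped.  When fewer than df+1 points remain the
    basis dimension falls back to ``max(4, floor(n/3))`` with a warning; an
    all-missing y is an error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size == 0:
        raise DriftCorrectionError(f"no QC intensities to fit for {feature_id or 'feature'}")
    if run_range is None:
        run_range = (float(x.min()), float(x.max()))
    eff_df = df
    if x.size < df + 1:
        eff_df = max(MIN_DF, int(x.size // 3))
        warnings.warn(
            f"{feature_id or 'feature'}: only {x.size} QC points for df={df}; "
            f"falling back to df={eff_df}",
            stacklevel=2,
        )
    design, knots = bspline_basis(x, eff_df, run_range)
    beta, objective = _solve_check_loss(design, y, tau)
    return DriftModel(
        feature_id=feature_id,
        knots=knots,
        coefficients=beta,
        tau=tau,
        df=eff_df,
        qc_median=float(np.median(y)),
        fit_orders=x,
        objective=objective,
    )


def evaluate_drift(model: DriftModel, orders) -> np.ndarray:
    """Fitted curve values at the given injection orders.

    Orders outside the QC bracket are clamped to the nearest fitted boundary,
    so the curve is constant beyond the first/last QC.
    """
    orders = np.atleast_1d(np.asarray(orders, float))
    lo, hi = model.clamp_range
    clamped = np.clip(orders, lo, hi)
    design = BSpline.design_matrix(
        clamped, model.knots, SPLINE_DEGREE, extrapolate=False
    ).toarray()
    return design @ model.coefficients


def correct_feature(
    feature_id: str, table: FeatureTable, design: StudyDesign, model: DriftModel
) -> pd.Series:
    """Multiplicative median-anchored correction of one feature's row.

    corrected(i) = raw(i) * qc_median / curve(order_i); missing stays missing.
    Raises if the curve is non-positive at any order where a value exists.
    """
    raw = table.intensities.loc[feature_id]
    orders = design.orders(raw.index)
    curve = evaluate_drift(model, orders)
    needed = ~raw.isna().to_numpy()
    if np.any(curve[needed] <= 0):
        raise DriftCorrectionError(
            f"{feature_id}: fitted drift curve non-positive within corrected range"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = raw.to_numpy(float) * model.qc_median / curve
    return pd.Series(corrected, index=raw.index, name=feature_id)


@dataclass
class DriftReport:
    """Per-feature QC CV before/after correction plus the failure list."""

    cv: pd.DataFrame  # columns: cv_before, cv_after
    failed: list[str]
    tau: float
    df: int

    @property
    def median_cv_before(self) -> float:
        return float(np.nanmedian(self.cv["cv_before"]))

    @property
    def median_cv_after(self) -> float:
        return float(np.nanmedian(self.cv["cv_after"]))

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "df": self.df,
            "median_cv_before": self.median_cv_before,
            "median_cv_after": self.median_cv_after,
            "n_failed": len(self.failed),
            "failed": self.failed,
        }


def correct_table(
    table: FeatureTable,
    design: StudyDesign,
    tau: float = 0.5,
    df: int = 16,
) -> tuple[FeatureTable, DriftReport, dict[str, DriftModel]]:
    """Fit + correct every feature; failures pass through uncorrected.

    Returns the corrected table, a before/after CV report and the fitted
    models.  Expects the blank/detection filters to have run already.
    """
    qc_ids = design.qc_ids
    if not qc_ids:
        raise DriftCorrectionError("drift correction requires QC injections")
    qc_orders = design.orders(qc_ids)
    run_range = design.run_range
    all_orders = design.orders(table.injections)

    cv_before = qc_cv_table(table, design)
    corrected = table.intensities.copy()
    failed: list[str] = []
    models: dict[str, DriftModel] = {}

    # design matrices depend only on which QCs are non-missing: cache them
    basis_cache: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    qc_matrix = table.intensities[qc_ids].to_numpy(float)
    full_matrix = table.intensities.to_numpy(float)

    for row, feature_id in enumerate(table.feature_ids):
        y = qc_matrix[row]
        keep = ~np.isnan(y)
        if keep.sum() == 0:
            failed.append(feature_id)
            continue
        x = qc_orders[keep]
        key = tuple(np.flatnonzero(keep))
        eff_df = df
        if x.size < df + 1:
            eff_df = max(MIN_DF, int(x.size // 3))
            warnings.warn(
                f"{feature_id}: only {x.size} QC points for df={df}; "
                f"falling back to df={eff_df}",
                stacklevel=2,
            )
        if key not in basis_cache:
            fit_design, knots = bspline_basis(x, eff_df, run_range)
            lo, hi = float(x.min()), float(x.max())
            eval_design = BSpline.design_matrix(
                np.clip(all_orders, lo, hi), knots, SPLINE_DEGREE, extrapolate=False
            ).toarray()
            basis_cache[key] = (fit_design, knots, eval_design)
        fit_design, knots, eval_design = basis_cache[key]
        beta, objective = _solve_check_loss(fit_design, y[keep], tau)
        model = DriftModel(
            feature_id=feature_id,
            knots=knots,
            coefficients=beta,
            tau=tau,
            df=eff_df,
            qc_median=float(np.median(y[keep])),
            fit_orders=x,
            objective=objective,
        )
        models[feature_id] = model
        curve = eval_design @ beta
        raw_row = full_matrix[row]
        needed = ~np.isnan(raw_row)
        if np.any(curve[needed] <= 0):
            failed.append(feature_id)
            continue
        corrected.iloc[row] = raw_row * model.qc_median / curve

    out = FeatureTable(table.features.copy(), corrected)
    cv_after = qc_cv_table(out, design)
    report = DriftReport(
        cv=pd.DataFrame({"cv_before": cv_before, "cv_after": cv_after}),
        failed=failed,
        tau=tau,
        df=df,
    )
    return out, report, models
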