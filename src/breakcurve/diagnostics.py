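"""Model-validation statistics and leverage-based applicability-domain analysis.

The statistic suite reports R², MAE, RMSE, MSE, %AAD (= 100·MAE for C/C0 on
its natural [0, 1] scale) and the standard deviation of the residuals.

The applicability domain follows the leverage (Williams-plot) method: with
design matrix X of n points and k input parameters, the hat matrix
H = X (XᵀX)⁻¹ Xᵀ has diagonals h_ii measuring each point's structural
influence; the warning leverage is H* = 3(f+1)/p for f model parameters and
p points.  A point is inside the domain iff its standardized residual lies
in [−3, 3] and 0 < h_ii < H*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StatReport:
    """Goodness-of-fit summary for one partition (train/test/total)."""

    label: str
    n: int
    r2: float
    mae: float
    rmse: float
    mse: float
    aad_percent: float
    std_resid: float

    def as_row(self) -> dict:
        return {
            "partition": self.label, "n": self.n, "MSE": self.mse,
            "AAD": self.aad_percent, "R2": self.r2, "STD": self.std_resid,
            "MAE": self.mae, "RMSE": self.rmse,
        }


def compute_stats(
    predicted: np.ndarray,
    observed: np.ndarray,
    label: str = "",
    std_as_printed: bool = False,
) -> StatReport:
    """R², MAE, RMSE, MSE, %AAD and residual STD of predictions vs observations.

    R² = 1 − SS_res/SS_tot with SS_tot taken about the observed mean (the
    standard definition).  %AAD = 100·MAE.  STD is the standard deviation of
    the residuals about their own mean; ``std_as_printed=True`` instead
    returns the RMS deviation of the predictions about the observed mean, a
    variant that measures prediction spread rather than error spread.
    """
    predicted = np.asarray(predicted, float).ravel()
    observed = np.asarray(observed, float).ravel()
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed lengths differ")
    n = predicted.size
    if n < 2:
        raise ValueError("need at least two points")

    resid = observed - predicted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("degenerate observed vector (all values identical)")

    mae = float(np.mean(np.abs(resid)))
    mse = ss_res / n
    if std_as_printed:
        std = float(np.sqrt(np.mean((predicted - observed.mean()) ** 2)))
    else:
        std = float(np.std(resid))
    return StatReport(
        label=label, n=n, r2=1.0 - ss_res / ss_tot, mae=mae,
        rmse=float(np.sqrt(mse)), mse=mse, aad_percent=100.0 * mae, std_resid=std,
    )


def hat_matrix(X: np.ndarray) -> np.ndarray:
    """Projection matrix X (XᵀX)⁻¹ Xᵀ, via pseudo-inverse on rank deficiency."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.ndim == 2 and X.shape[1] > X.shape[0]:
        logger.warning("more columns than rows; hat matrix is the identity projector")
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning("design matrix rank-deficient (rank %d < %d columns); using pseudo-inverse",
                       rank, X.shape[1])
        return X @ np.linalg.pinv(XtX) @ X.T
    return X @ np.linalg.solve(XtX, X.T)


def hat_diagonals(X: np.ndarray) -> np.ndarray:
    return np.diag(hat_matrix(X)).copy()


def warning_leverage(f: int, p: int) -> float:
    """H* = 3(f+1)/p for f model input parameters and p data points."""
    if f < 0 or p < 1:
        raise ValueError("need f >= 0 and p >= 1")
    return 3.0 * (f + 1) / p


def standardized_residuals(
    predicted: np.ndarray, observed: np.ndarray, hat_diag: np.ndarray
) -> np.ndarray:
    """R_i = e_i / (s √(1 − h_ii)) with e_i = obs − pred and s the residual RMS."""
    predicted = np.asarray(predicted, float).ravel()
    observed = np.asarray(observed, float).ravel()
    hat_diag = np.asarray(hat_diag, float).ravel()
    if not (predicted.shape == observed.shape == hat_diag.shape):
        raise ValueError("vector lengths differ")
    if np.any(hat_diag >= 1.0):
        raise ValueError("exact leverage point (h_ii >= 1); residual undefined")
    resid = observed - predicted
    s = float(np.sqrt(np.mean(resid**2)))
    if s == 0.0:
        return np.zeros_like(resid)
    return resid / (s * np.sqrt(1.0 - hat_diag))


@dataclass
class LeverageReport:
    """Williams-plot data: leverages, standardized residuals, domain flags."""

    hat_diag: np.ndarray
    std_resid: np.ndarray
    warning_leverage: float
    flags: np.ndarray  # one of {"in_domain","high_leverage","outlier_residual","both"}

    @property
    def n_outside(self) -> int:
        return int(np.sum(self.flags != "in_domain"))

    def counts(self) -> dict[str, int]:
        labels = ("in_domain", "high_leverage", "outlier_residual", "both")
        return {lab: int(np.sum(self.flags == lab)) for lab in labels}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "hat_diagonal": self.hat_diag,
            "standardized_residual": self.std_resid,
            "flag": self.flags,
        })


def classify_domain(
    predicted: np.ndarray,
    observed: np.ndarray,
    X_design: np.ndarray,
    f: int | None = None,
    residual_bound: float = 3.0,
) -> LeverageReport:
    """Leverage applicability-domain classification of every point.

    ``X_design`` is the normalized input matrix over all evaluated points
    (no intercept column by default, so f defaults to its column count).
    Each point receives exactly one flag.
    """
    X_design = np.atleast_2d(np.asarray(X_design, float))
    h = hat_diagonals(X_design)
    r = standardized_residuals(predicted, observed, h)
    p = X_design.shape[0]
    f = X_design.shape[1] if f is None else f
    hstar = warning_leverage(f, p)

    high_h = (h >= hstar) | (h <= 0.0)
    high_r = np.abs(r) > residual_bound
    flags = np.where(
        high_h & high_r, "both",
        np.where(high_h, "high_leverage",
                 np.where(high_r, "outlier_residual", "in_domain")),
    )
    return LeverageReport(hat_diag=h, std_resid=r, warning_leverage=hstar, flags=flags)


def stats_table(reports: dict[str, list[StatReport]]) -> pd.DataFrame:
    """Comparator table: rows {MSE, AAD, R2, STD}, one column per model/partition."""
    columns = {}
    for model, reps in reports.items():
        for rep in reps:
            columns[f"{model}_{rep.label}"] = {
                "MSE": rep.mse, "AAD": rep.aad_percent, "R2": rep.r2, "STD": rep.std_resid,
            }
    return pd.DataFrame(columns).reindex(["MSE", "AAD", "R2", "STD"])
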