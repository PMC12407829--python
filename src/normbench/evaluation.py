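"""Model-fit and deviation-score error metrics.

Fit metrics (HC test set only): MSLL, SMSE, explained variance, Pearson
rho, and ICC(2,1) of deviation scores across subsampling iterations.
Deviation-score errors against the full-training-set reference model:
per-subject MSE across ROIs (with a conservative 3xIQR exclusion at the
condition level), per-ROI mean bias error (MBE), and cubic age curves of
the per-subject error.

Variance denominators use the unbiased (n-1) convention throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import NormativeModelResults, Prediction

__all__ = [
    "FitMetrics",
    "msll",
    "smse",
    "explained_variance",
    "pearson_rho",
    "icc_2_1",
    "evaluate_model",
    "z_mse",
    "iqr_keep_mask",
    "z_mbe",
    "age_error_curve",
]


@dataclass
class FitMetrics:
    """Fit metrics of one model under one sampling condition."""

    roi: str
    strategy: str
    n: int
    iteration: int
    msll: float
    smse: float
    ev: float
    rho: float
    converged: bool


def msll(mu_warped, total_sd, y_warped, train_mean: float, train_var: float) -> float:
    """Mean standardized log loss on the warped scale.

    Mean over test points of the model's negative predictive log density
    minus that of the trivial Gaussian predictor built from the warped
    training responses.  The warp Jacobians of the two densities cancel,
    so both terms are evaluated on the warped response.  Negative values
    mean the model beats the trivial predictor.
    """
    if train_var <= 0:
        raise ValueError("trivial predictor is degenerate: zero training variance")
    mu = np.asarray(mu_warped, dtype=float)
    sd = np.asarray(total_sd, dtype=float)
    y = np.asarray(y_warped, dtype=float)
    nll_model = 0.5 * np.log(2 * np.pi * sd**2) + (y - mu) ** 2 / (2 * sd**2)
    nll_triv = (0.5 * np.log(2 * np.pi * train_var)
                + (y - train_mean) ** 2 / (2 * train_var))
    return float(np.mean(nll_model - nll_triv))


def smse(y_pred, y_true) -> float:
    """Mean squared error standardized by the test-response variance."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    var = y_true.var(ddof=1)
    if var <= 0:
        raise ValueError("constant test responses: SMSE undefined")
    return float(np.mean((y_true - y_pred) ** 2) / var)


def explained_variance(y_pred, y_true) -> float:
    """EV = 1 - var(residual) / var(test); shift-invariant."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    var = y_true.var(ddof=1)
    if var <= 0:
        raise ValueError("constant test responses: EV undefined")
    return float(1.0 - np.var(y_true - y_pred, ddof=1) / var)


def pearson_rho(y_pred, y_true) -> float:
    """Pearson correlation of predictions and observations (NaN if constant)."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if y_pred.std() == 0 or y_true.std() == 0:
        warnings.warn("constant vector: Pearson rho undefined, reporting NaN",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.corrcoef(y_pred, y_true)[0, 1])


def icc_2_1(z_matrix) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``z_matrix`` is subjects x iterations for one ROI; the matrix must be
    complete (no silent listwise deletion).
    """
    x = np.asarray(z_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 subjects and >= 2 iterations")
    if np.any(~np.isfinite(x)):
        raise ValueError("ICC input must be complete (finite values only)")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    return float((ms_r - ms_e) / denom)


def evaluate_model(results: NormativeModelResults, test: pd.DataFrame,
                   roi: str | None = None, strategy: str = "representative",
                   n: int | None = None, iteration: int = 1,
                   prediction: Prediction | None = None,
                   mean_offset=0.0) -> FitMetrics:
    """Compute MSLL/SMSE/EV/rho for one fitted model on an HC test table."""
    roi = roi or results.roi
    hc = test[test["diagnosis"] == "HC"] if "diagnosis" in test.columns else test
    pred = prediction if prediction is not None else results.predict(
        hc, mean_offset=mean_offset)
    y = hc[roi].to_numpy(float)
    y_warped = results.warped_response(y)
    tm, tv = results.train_loss_reference
    # MSLL, EV and rho are computed on the warped (Gaussian) scale, the
    # scale the model is fitted on; this makes EV/rho exactly invariant
    # under the mean-only transfer recalibration.  SMSE stays in original
    # response units.
    return FitMetrics(
        roi=roi, strategy=strategy,
        n=n if n is not None else results.model.nobs, iteration=iteration,
        msll=msll(pred.mu_warped, pred.total_sd, y_warped, tm, tv),
        smse=smse(pred.point_prediction, y),
        ev=explained_variance(pred.mu_warped, y_warped),
        rho=pearson_rho(pred.mu_warped, y_warped),
        converged=results.converged,
    )


def _check_aligned(z_sub: pd.DataFrame, z_ref: pd.DataFrame) -> None:
    if not (z_sub.index.equals(z_ref.index) and z_sub.columns.equals(z_ref.columns)):
        raise ValueError("deviation matrices are not aligned on subjects x ROIs")


def z_mse(z_sub: pd.DataFrame, z_ref: pd.DataFrame) -> pd.Series:
    """Per-subject mean over ROIs of squared Z-score differences."""
    _check_aligned(z_sub, z_ref)
    return ((z_sub - z_ref) ** 2).mean(axis=1)


def iqr_keep_mask(values, factor: float = 3.0) -> np.ndarray:
    """True for values inside [Q1 - f*IQR, Q3 + f*IQR] (condition-level
    exclusion of rare extreme iterations)."""
    v = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v >= q1 - factor * iqr) & (v <= q3 + factor * iqr)


def z_mbe(z_sub: pd.DataFrame, z_ref: pd.DataFrame) -> pd.Series:
    """Per-ROI mean bias of subsample Z against reference Z.

    Negative values mean the subsample model *overestimates* deviations
    (its Z-scores sit below the reference).
    """
    _check_aligned(z_sub, z_ref)
    return (z_sub - z_ref).mean(axis=0)


def age_error_curve(mse_per_subject, ages):
    """Least-squares cubic polynomial of per-subject Z-error on age.

    Returns the coefficients in increasing-power order (c0..c3).
    """
    ages = np.asarray(ages, dtype=float)
    mse = np.asarray(mse_per_subject, dtype=float)
    if len(np.unique(ages)) < 4:
        raise ValueError("cubic age curve needs >= 4 distinct ages")
    poly = np.polynomial.Polynomial.fit(ages, mse, deg=3)
    return poly.convert().coef
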