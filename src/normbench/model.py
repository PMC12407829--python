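"""Warped Bayesian linear regression normative models.

One model per ROI: a Bayesian linear regression with Gaussian weight prior
``w ~ N(0, alpha^-1 I)`` and noise precision ``beta``, applied to the
SHASH-warped, train-standardized response ``ytilde = W((y - m)/s; a, b)``.
The four hyperparameters ``theta = (log alpha, log beta, a, log b)`` are
chosen by minimizing the negative log marginal likelihood (evidence) of
the warped response, including the warp Jacobian, with Powell's conjugate
direction method from the Gaussian-null start ``theta = 0``.

Posterior over weights at ``theta*``::

    A    = alpha I + beta Phi' Phi          (weight precision)
    mu_w = beta A^-1 Phi' ytilde

Predictions for a subject with covariate row ``phi``::

    mu*        = phi' mu_w                   (warped standardized space)
    epistemic  = phi' A^-1 phi               (parameter uncertainty)
    aleatoric  = 1 / beta                    (irreducible noise)
    Z          = (W(y_std) - mu*) / sqrt(aleatoric + epistemic)

Centile curves invert the warp: ``unstd(W^-1(mu* + sd * PhiN^-1(q)))``.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtri

from .basis import BasisSpec, FittedBasis
from .shash import WarpParams, shash_derivative, shash_inverse, shash_warp

__all__ = [
    "WarpedBLR",
    "NormativeModelResults",
    "Prediction",
    "negative_log_likelihood",
    "fit_cohort",
    "deviation_matrix",
]

_LOG2PI = math.log(2.0 * math.pi)
_BIG = 1e25


class _DesignOps:
    """Shared per-design precomputation: eigen-factorized Phi'Phi.

    ``A = alpha I + beta Phi'Phi`` diagonalizes in the eigenbasis of
    ``Phi'Phi``, so every likelihood evaluation costs O(N D) regardless of
    the hyperparameters; the factorization is shared by all ROIs fitted on
    the same training subjects.
    """

    def __init__(self, phi: np.ndarray):
        phi = np.asarray(phi, dtype=float)
        if phi.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        self.phi = phi
        self.n, self.d = phi.shape
        lam, v = np.linalg.eigh(phi.T @ phi)
        self.lam = np.clip(lam, 0.0, None)
        self.v = v
        self.phiv = phi @ v


class Prediction(NamedTuple):
    """Per-subject predictive quantities of a fitted normative model."""

    mu_warped: np.ndarray      # predictive mean, warped standardized space
    total_sd: np.ndarray       # sqrt(aleatoric + epistemic)
    aleatoric_var: float
    epistemic_var: np.ndarray
    point_prediction: np.ndarray  # original response units


class WarpedBLR:
    """Warped Bayesian linear regression model for one response vector.

    Parameters
    ----------
    endog : array-like
        Response vector (original units).
    exog : array-like
        Design matrix; build it with :func:`normbench.basis.build_design`
        or use :meth:`from_cohort`.
    standardize : bool
        Z-standardize the response on the training data before warping
        (default).  Disable only for closed-form checks.
    """

    def __init__(self, endog, exog, standardize: bool = True,
                 basis: FittedBasis | None = None, roi: str | None = None,
                 _ops: _DesignOps | None = None):
        y = np.asarray(endog, dtype=float).ravel()
        self._ops = _ops if _ops is not None else _DesignOps(np.asarray(exog))
        if len(y) != self._ops.n:
            raise ValueError("endog and exog row counts differ")
        if np.any(~np.isfinite(y)):
            raise ValueError("training responses must be finite")
        if standardize:
            self.y_mean = float(y.mean())
            self.y_sd = float(y.std(ddof=1))
            if self.y_sd == 0:
                raise ValueError("constant response: cannot standardize")
        else:
            self.y_mean, self.y_sd = 0.0, 1.0
        self.y = y
        self.y_std = (y - self.y_mean) / self.y_sd
        self.basis = basis
        self.roi = roi

    # -- likelihood ----------------------------------------------------
    @property
    def nobs(self) -> int:
        return self._ops.n

    @property
    def ncols(self) -> int:
        return self._ops.d

    def nloglike(self, theta) -> float:
        """Negative log marginal likelihood at theta = (ln a, ln b, a_w, ln b_w)."""
        log_alpha, log_beta, a, log_b = np.asarray(theta, dtype=float)
        if abs(log_alpha) > 30 or abs(log_beta) > 30 or abs(a) > 20 or abs(log_b) > 10:
            return _BIG
        alpha, beta, b = math.exp(log_alpha), math.exp(log_beta), math.exp(log_b)
        ops = self._ops
        with np.errstate(over="ignore", invalid="ignore"):
            yt = shash_warp(self.y_std, a, b)
            jac = np.log(shash_derivative(self.y_std, a, b)).sum()
            if not (np.all(np.isfinite(yt)) and np.isfinite(jac)):
                return _BIG
            c = ops.phiv.T @ yt
            dd = alpha + beta * ops.lam
            mu_v = beta * c / dd
            yy = yt @ yt
            resid_sq = yy - 2.0 * (mu_v @ c) + (ops.lam * mu_v) @ mu_v
            energy = 0.5 * beta * resid_sq + 0.5 * alpha * (mu_v @ mu_v)
            log_det_a = np.log(dd).sum()
            evidence = (0.5 * ops.d * log_alpha + 0.5 * ops.n * log_beta
                        - energy - 0.5 * log_det_a - 0.5 * ops.n * _LOG2PI)
            nll = -evidence - jac
        return float(nll) if np.isfinite(nll) else _BIG

    def posterior(self, alpha: float, beta: float,
                  warp: WarpParams | tuple = (0.0, 1.0)):
        """Weight posterior (mu_w, A) at fixed hyperparameters."""
        if not isinstance(warp, WarpParams):
            warp = WarpParams(*warp)
        ops = self._ops
        yt = shash_warp(self.y_std, warp.a, warp.b)
        dd = alpha + beta * ops.lam
        mu_v = beta * (ops.phiv.T @ yt) / dd
        mu_w = ops.v @ mu_v
        a_mat = (ops.v * dd) @ ops.v.T
        return mu_w, a_mat

    # -- construction / fitting ---------------------------------------
    @classmethod
    def from_cohort(cls, table: pd.DataFrame, roi: str,
                    basis: FittedBasis | BasisSpec | None = None) -> "WarpedBLR":
        """Build a per-ROI model from a cohort table, fitting the basis."""
        if roi not in table.columns:
            raise KeyError(f"ROI column {roi!r} not found in table")
        if basis is None or isinstance(basis, BasisSpec):
            basis = FittedBasis.fit(table, basis)
        phi = basis.transform(table)
        return cls(table[roi].to_numpy(float), phi, basis=basis, roi=roi)

    def fit(self, start=(0.0, 0.0, 0.0, 0.0), xtol: float = 1e-6,
            ftol: float = 1e-6, maxiter: int = 500) -> "NormativeModelResults":
        """Minimize the negative evidence with Powell's method."""
        if self.nobs < self.ncols + 2:
            warnings.warn(
                f"only {self.nobs} training subjects for {self.ncols} design "
                "columns; fit may be unstable", RuntimeWarning, stacklevel=2)
        start = np.asarray(start, dtype=float)
        nll0 = self.nloglike(start)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = optimize.minimize(
                self.nloglike, start, method="Powell",
                options={"xtol": xtol, "ftol": ftol, "maxiter": maxiter})
        theta = res.x if res.fun <= nll0 else start
        converged = bool(res.success) and res.fun <= nll0
        return NormativeModelResults(self, theta, converged=converged,
                                     nll=float(min(res.fun, nll0)),
                                     nll_start=float(nll0), nit=int(res.nit))


def negative_log_likelihood(theta, design, y) -> float:
    """Module-level NLL on a raw (design, response) pair, no standardization."""
    return WarpedBLR(y, design, standardize=False).nloglike(theta)


class NormativeModelResults:
    """Fitted per-ROI normative model: hyperparameters, weight posterior,
    standardizer and training summaries; produces predictions, deviation
    (Z) scores and centile curves."""

    def __init__(self, model: WarpedBLR, theta, converged: bool = True,
                 nll: float = np.nan, nll_start: float = np.nan, nit: int = 0):
        self.model = model
        self.params = np.asarray(theta, dtype=float)
        log_alpha, log_beta, a, log_b = self.params
        self.alpha = math.exp(log_alpha)
        self.beta = math.exp(log_beta)
        self.warp = WarpParams(a, math.exp(log_b))
        self.converged = converged
        self.nll = nll
        self.nll_start = nll_start
        self.nit = nit
        ops = model._ops
        yt = shash_warp(model.y_std, self.warp.a, self.warp.b)
        self._post_d = self.alpha + self.beta * ops.lam
        self._post_v = ops.v
        self.weight_mean = ops.v @ (self.beta * (ops.phiv.T @ yt) / self._post_d)
        # trivial-predictor reference for MSLL: moments of the warped
        # training response under the fitted warp
        self.train_loss_reference = (float(yt.mean()), float(yt.var(ddof=1)))

    # -- descriptive ---------------------------------------------------
    @property
    def roi(self) -> str | None:
        return self.model.roi

    @property
    def weight_precision(self) -> np.ndarray:
        """Posterior weight precision A = alpha I + beta Phi'Phi."""
        return (self._post_v * self._post_d) @ self._post_v.T

    @property
    def aleatoric_var(self) -> float:
        return 1.0 / self.beta

    def summary(self) -> str:
        lines = [
            "Warped Bayesian Linear Regression (normative model)",
            "=" * 53,
            f"ROI:               {self.roi or '<unnamed>'}",
            f"n train subjects:  {self.model.nobs}",
            f"design columns:    {self.model.ncols}",
            f"converged:         {self.converged}  (Powell, {self.nit} iter)",
            f"neg. log evidence: {self.nll:.4f}  (start {self.nll_start:.4f})",
            "-" * 53,
            f"alpha (prior prec):  {self.alpha:10.4f}",
            f"beta (noise prec):   {self.beta:10.4f}   aleatoric SD "
            f"{math.sqrt(self.aleatoric_var):.4f}",
            f"warp skew a:         {self.warp.a:10.4f}",
            f"warp shape b:        {self.warp.b:10.4f}",
            f"response mean/sd:    {self.model.y_mean:10.4f} / {self.model.y_sd:.4f}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<NormativeModelResults roi={self.roi!r} a={self.warp.a:.3f} "
                f"b={self.warp.b:.3f} beta={self.beta:.3f} converged={self.converged}>")

    # -- prediction ----------------------------------------------------
    def _design_for(self, subjects, unknown_site: str = "raise") -> np.ndarray:
        if isinstance(subjects, pd.DataFrame):
            if self.model.basis is None:
                raise ValueError("model was built from a raw design matrix; "
                                 "pass a design matrix, not a table")
            return self.model.basis.transform(subjects, unknown_site=unknown_site)
        return np.asarray(subjects, dtype=float)

    def predict(self, subjects, unknown_site: str = "raise",
                mean_offset=0.0) -> Prediction:
        """Predictive mean and decomposed uncertainty for new subjects."""
        phi = self._design_for(subjects, unknown_site)
        mu = phi @ self.weight_mean + mean_offset
        u = phi @ self._post_v
        epistemic = np.einsum("ij,ij->i", u, u / self._post_d)
        total_sd = np.sqrt(self.aleatoric_var + epistemic)
        point = self.unstandardize(shash_inverse(mu, self.warp.a, self.warp.b))
        return Prediction(mu, total_sd, self.aleatoric_var, epistemic, point)

    def unstandardize(self, y_std):
        return self.model.y_mean + self.model.y_sd * np.asarray(y_std, dtype=float)

    def warped_response(self, y):
        """Map observed responses to the warped standardized scale."""
        y_std = (np.asarray(y, dtype=float) - self.model.y_mean) / self.model.y_sd
        return shash_warp(y_std, self.warp.a, self.warp.b)

    def zscore(self, subjects: pd.DataFrame, roi: str | None = None,
               unknown_site: str = "raise", mean_offset=0.0) -> np.ndarray:
        """Deviation scores: warped residual over the full predictive SD.

        Missing ROI values propagate as NaN, never imputed.
        """
        roi = roi or self.roi
        if roi is None or roi not in subjects.columns:
            raise KeyError(f"ROI column {roi!r} not found in subject table")
        pred = self.predict(subjects, unknown_site=unknown_site,
                            mean_offset=mean_offset)
        yt = self.warped_response(subjects[roi].to_numpy(float))
        return (yt - pred.mu_warped) / pred.total_sd

    def centiles(self, ages, sex: str = "F", site: str | None = None,
                 quantiles=(0.05, 0.5, 0.95), mean_offset=0.0,
                 unknown_site: str = "raise") -> pd.DataFrame:
        """Centile curves over an age grid, in original response units."""
        quantiles = np.asarray(quantiles, dtype=float)
        if np.any(quantiles <= 0) or np.any(quantiles >= 1):
            raise ValueError("quantiles must lie strictly inside (0, 1)")
        ages = np.asarray(ages, dtype=float)
        if site is None:
            levels = self.model.basis.site_levels if self.model.basis else []
            site = levels[0] if levels else "site-01"
        grid = pd.DataFrame({"age": ages, "sex": sex, "site": site})
        pred = self.predict(grid, unknown_site=unknown_site,
                            mean_offset=mean_offset)
        out = pd.DataFrame({"age": ages})
        for q in quantiles:
            zq = ndtri(q)
            curve = shash_inverse(pred.mu_warped + pred.total_sd * zq,
                                  self.warp.a, self.warp.b)
            out[f"q{q:g}"] = self.unstandardize(curve)
        return out

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        basis = self.model.basis
        if basis is None:
            raise ValueError("only basis-bound models can be serialized")
        return {
            "roi": self.roi,
            "basis": {
                "spec": {
                    "spline_degree": basis.spec.spline_degree,
                    "n_interior_knots": basis.spec.n_interior_knots,
                    "include_sex": basis.spec.include_sex,
                    "spline_sex": basis.spec.spline_sex,
                    "include_site": basis.spec.include_site,
                },
                "age_min": basis.age_min,
                "age_max": basis.age_max,
                "site_levels": list(basis.site_levels),
            },
            "standardizer": {"y_mean": self.model.y_mean, "y_sd": self.model.y_sd},
            "theta": self.params.tolist(),
            "weight_mean": self.weight_mean.tolist(),
            "weight_precision": self.weight_precision.tolist(),
            "train_loss_reference": list(self.train_loss_reference),
            "converged": bool(self.converged),
            "nll": float(self.nll),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeModelResults":
        basis = FittedBasis(spec=BasisSpec(**d["basis"]["spec"]),
                            age_min=d["basis"]["age_min"],
                            age_max=d["basis"]["age_max"],
                            site_levels=list(d["basis"]["site_levels"]))
        obj = cls.__new__(cls)
        model = WarpedBLR.__new__(WarpedBLR)
        model.basis = basis
        model.roi = d["roi"]
        model.y_mean = d["standardizer"]["y_mean"]
        model.y_sd = d["standardizer"]["y_sd"]
        model.y = model.y_std = np.empty(0)
        model._ops = None
        obj.model = model
        obj.params = np.asarray(d["theta"], dtype=float)
        obj.alpha = math.exp(obj.params[0])
        obj.beta = math.exp(obj.params[1])
        obj.warp = WarpParams(obj.params[2], math.exp(obj.params[3]))
        obj.converged = bool(d["converged"])
        obj.nll = float(d.get("nll", np.nan))
        obj.nll_start = np.nan
        obj.nit = 0
        obj.weight_mean = np.asarray(d["weight_mean"], dtype=float)
        a_mat = np.asarray(d["weight_precision"], dtype=float)
        dd, v = np.linalg.eigh(a_mat)
        obj._post_d, obj._post_v = dd, v
        obj.train_loss_reference = tuple(d["train_loss_reference"])
        return obj

    @classmethod
    def load(cls, path: str | Path) -> "NormativeModelResults":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def fit_cohort(train: pd.DataFrame, rois: list[str] | None = None,
               basis: FittedBasis | BasisSpec | None = None,
               **fit_kw) -> dict[str, NormativeModelResults]:
    """Fit one normative model per ROI on a training table.

    The covariate basis and the design-matrix factorization are shared
    across ROIs, so the per-ROI cost is the Powell search only.
    """
    from .cohort import roi_columns

    if rois is None:
        rois = roi_columns(train)
    if basis is None or isinstance(basis, BasisSpec):
        basis = FittedBasis.fit(train, basis)
    phi = basis.transform(train)
    ops = _DesignOps(phi)
    out: dict[str, NormativeModelResults] = {}
    for roi in rois:
        m = WarpedBLR(train[roi].to_numpy(float), phi, basis=basis, roi=roi,
                      _ops=ops)
        out[roi] = m.fit(**fit_kw)
    return out


def deviation_matrix(models: dict[str, NormativeModelResults],
                     subjects: pd.DataFrame, unknown_site: str = "raise",
                     offsets: dict | None = None) -> pd.DataFrame:
    """Subjects x ROIs matrix of deviation scores from a fitted model set."""
    data = {}
    for roi, res in models.items():
        off = 0.0
        if offsets is not None:
            off = _offset_vector(offsets.get(roi, {}), subjects)
        data[roi] = res.zscore(subjects, unknown_site=unknown_site,
                               mean_offset=off)
    return pd.DataFrame(data, index=subjects["subject_id"].to_numpy())


def _offset_vector(site_deltas: dict, subjects: pd.DataFrame):
    if not site_deltas:
        return 0.0
    sites = subjects["site"].astype(str).to_numpy()
    return np.array([site_deltas.get(s, 0.0) for s in sites])
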