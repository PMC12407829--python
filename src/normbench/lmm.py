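"""Linear mixed-effects summaries of the benchmark tables.

Two model families, mirroring the benchmark's statistical analysis:

- fit metrics:  ``outcome ~ log(n) x strategy + (1 | ROI)``
- deviation outcomes (per-subject Z-error or tOC):
  ``outcome ~ log(n) x strategy x group + (1 | subject)``

Outcomes and log(n) are z-standardized before fitting so the fixed-effect
coefficients are comparable across metrics; the representative strategy
and the HC group are the reference levels.  Models are fitted by REML
with Wald p-values.  Per-ROI fixed-effects-only models are corrected
across ROIs with Benjamini-Hochberg FDR per term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = ["LMMTerm", "LMMResult", "fit_lmm_fit_metrics", "fit_lmm_deviation",
           "per_roi_lmm_fdr"]


@dataclass
class LMMTerm:
    term: str
    beta: float
    se: float
    p: float


@dataclass
class LMMResult:
    """Standardized fixed effects of one mixed model."""

    outcome: str
    formula: str
    terms: list[LMMTerm]
    random_effect_var: float
    n_obs: int
    converged: bool
    standardization: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.terms])

    def __getitem__(self, term: str) -> LMMTerm:
        for t in self.terms:
            if t.term == term:
                return t
        raise KeyError(term)


def _zstd(x: pd.Series) -> tuple:
    mu, sd = float(x.mean()), float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - mu) / sd, mu, sd


def _prepare(table: pd.DataFrame, outcome: str) -> tuple:
    d = table
    if "metric" in d.columns:
        d = d[d["metric"] == outcome]
    value_col = "value" if "value" in d.columns else outcome
    d = d.dropna(subset=[value_col]).copy()
    if len(d) == 0:
        raise ValueError(f"no rows for outcome {outcome!r}")
    key_cols = [c for c in ("arm", "roi", "subject_id", "strategy", "n", "iteration")
                if c in d.columns]
    if key_cols and d.duplicated(subset=key_cols).any():
        warnings.warn("duplicated condition rows present: estimates unchanged "
                      "but n_obs is inflated", UserWarning, stacklevel=3)
    d["value_std"], y_mu, y_sd = _zstd(d[value_col].astype(float))
    d["logn_std"], n_mu, n_sd = _zstd(np.log(d["n"].astype(float)))
    std = {"outcome_mean": y_mu, "outcome_sd": y_sd,
           "logn_mean": n_mu, "logn_sd": n_sd}
    return d, std


def _strategy_term(d: pd.DataFrame) -> str:
    if d["strategy"].nunique() < 2:
        return ""
    if "representative" not in set(d["strategy"]):
        raise ValueError("the representative strategy (reference level) is missing")
    return " * C(strategy, Treatment('representative'))"


def _fit_mixed(d: pd.DataFrame, formula: str, groups: pd.Series,
               outcome: str, std: dict) -> LMMResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, data=d, groups=groups)
        res, converged = None, False
        last_err = None
        # near-singular random-effect variances can break individual
        # optimizers; walk a small ladder of methods before giving up
        for i, method in enumerate((None, "powell", "nm")):
            try:
                kw = {} if method is None else {"method": method}
                res = model.fit(reml=True, **kw)
                converged = bool(res.converged) and i == 0
                break
            except Exception as exc:  # noqa: BLE001
                last_err = exc
        if res is None:
            raise RuntimeError(f"mixed model failed to fit: {last_err}")
    terms = [LMMTerm(term=name, beta=float(res.params[name]),
                     se=float(res.bse[name]), p=float(res.pvalues[name]))
             for name in res.fe_params.index]
    re_var = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
    return LMMResult(outcome=outcome, formula=formula, terms=terms,
                     random_effect_var=re_var, n_obs=int(res.nobs),
                     converged=converged, standardization=std)


def fit_lmm_fit_metrics(table: pd.DataFrame, outcome: str) -> LMMResult:
    """Mixed model of a fit metric: log(n) x strategy, random ROI intercept."""
    d, std = _prepare(table, outcome)
    if d["roi"].nunique() < 2:
        raise ValueError("need >= 2 ROIs for a ROI random intercept")
    formula = "value_std ~ logn_std" + _strategy_term(d)
    return _fit_mixed(d, formula, d["roi"], outcome, std)


def fit_lmm_deviation(table: pd.DataFrame, outcome: str) -> LMMResult:
    """Mixed model of a deviation outcome: log(n) x strategy x group,
    random subject intercept."""
    d, std = _prepare(table, outcome)
    if d["subject_id"].nunique() < 2:
        raise ValueError("need >= 2 individuals for a subject random intercept")
    formula = "value_std ~ logn_std" + _strategy_term(d)
    if d["group"].nunique() >= 2:
        formula += " * C(group, Treatment('HC'))"
    return _fit_mixed(d, formula, d["subject_id"], outcome, std)


def per_roi_lmm_fdr(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Per-ROI fixed-effects models with BH-FDR adjustment across ROIs.

    Returns one row per (roi, term) with raw and adjusted p-values.
    """
    d, _ = _prepare(table, outcome)
    rois = sorted(d["roi"].unique())
    if len(rois) < 2:
        raise ValueError("need >= 2 ROIs for an FDR correction across ROIs")
    rows = []
    for roi in rois:
        sub = d[d["roi"] == roi].copy()
        sub["value_std"], _, _ = _zstd(sub["value"].astype(float))
        sub["logn_std"], _, _ = _zstd(np.log(sub["n"].astype(float)))
        formula = "value_std ~ logn_std" + _strategy_term(sub)
        res = smf.ols(formula, data=sub).fit()
        for name in res.params.index:
            rows.append({"roi": roi, "term": name,
                         "beta": float(res.params[name]),
                         "p": float(res.pvalues[name])})
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for term, idx in out.groupby("term").groups.items():
        p = out.loc[idx, "p"].to_numpy()
        finite = np.isfinite(p)
        adj = np.full(len(p), np.nan)
        if finite.any():
            adj[finite] = multipletests(p[finite], method="fdr_bh")[1]
        out.loc[idx, "p_fdr"] = adj
    return out
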