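"""Best-effort plotting conveniences (centile curves, metric trends).

These helpers are illustrative, not part of the benchmark contract.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_centiles(results, ages=None, sex: str = "F", site: str | None = None,
                  quantiles=(0.05, 0.25, 0.5, 0.75, 0.95), ax=None,
                  observations: pd.DataFrame | None = None):
    """Centile fan of one fitted normative model over an age grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if ages is None:
        basis = results.model.basis if hasattr(results, "model") else None
        lo, hi = (basis.age_min, basis.age_max) if basis else (45.0, 82.0)
        ages = np.linspace(lo, hi, 100)
    curves = results.centiles(ages, sex=sex, site=site, quantiles=quantiles)
    for q in quantiles:
        ax.plot(curves["age"], curves[f"q{q:g}"],
                lw=2 if q == 0.5 else 1,
                color="C0" if q == 0.5 else "grey",
                label=f"{100 * q:g}th" if q in (min(quantiles), 0.5, max(quantiles))
                else None)
    if observations is not None:
        roi = results.roi
        ax.scatter(observations["age"], observations[roi], s=8, alpha=0.4,
                   color="C3")
    ax.set_xlabel("age (years)")
    ax.set_ylabel(results.roi or "response")
    ax.legend(frameon=False)
    return ax


def plot_metric_vs_n(fit_metrics: pd.DataFrame, metric: str, ax=None):
    """Mean metric value vs training size, one line per strategy."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    d = fit_metrics[fit_metrics["metric"] == metric]
    for strategy, sub in d.groupby("strategy"):
        trend = sub.groupby("n")["value"].mean()
        ax.plot(trend.index, trend.values, marker="o", ms=3, label=strategy)
    ax.set_xlabel("training sample size n")
    ax.set_ylabel(metric)
    ax.legend(frameon=False)
    return ax
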