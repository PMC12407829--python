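"""Outlier-based clinical readouts and HC-vs-AD classification.

A deviation score below -1.96 (the lower 2.5% of the normative range)
marks an atrophy outlier; only negative deviations are counted, matching
the atrophic character of Alzheimer's disease.  The total outlier count
(tOC) per subject is the number of ROIs flagged.  Group separation is
quantified by the fold-mean ROC-AUC of a support-vector classifier on
ROI-level deviation scores under stratified 10-fold cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "OUTLIER_THRESHOLD",
    "OutlierSummary",
    "outlier_mask",
    "toc",
    "outlier_percentages",
    "classify_groups",
]

log = logging.getLogger(__name__)

OUTLIER_THRESHOLD = -1.96


@dataclass
class OutlierSummary:
    """Percent of subjects flagged as outliers for one ROI and group."""

    roi: str
    group: str
    pct_outliers: float


def outlier_mask(z: pd.DataFrame, threshold: float = OUTLIER_THRESHOLD) -> pd.DataFrame:
    """Boolean subjects x ROIs mask of negative outliers (z < threshold).

    The inequality is strict; missing Z count as non-outlier (logged).
    """
    n_missing = int(z.isna().to_numpy().sum())
    if n_missing:
        log.warning("outlier_mask: %d missing deviation scores treated as "
                    "non-outliers", n_missing)
    return z < threshold


def toc(z: pd.DataFrame, threshold: float = OUTLIER_THRESHOLD) -> pd.Series:
    """Total outlier count per subject: ROIs with z below the threshold."""
    return outlier_mask(z, threshold).sum(axis=1)


def outlier_percentages(z: pd.DataFrame, groups,
                        threshold: float = OUTLIER_THRESHOLD) -> pd.DataFrame:
    """Percent outliers per ROI x group (long table)."""
    mask = outlier_mask(z, threshold)
    groups = pd.Series(np.asarray(groups), index=z.index)
    rows = []
    for group, sub in mask.groupby(groups):
        if len(sub) == 0:  # pragma: no cover - groupby drops empty groups
            continue
        pct = 100.0 * sub.mean(axis=0)
        rows += [OutlierSummary(roi=r, group=str(group), pct_outliers=float(p))
                 for r, p in pct.items()]
    if not rows:
        warnings.warn("no non-empty groups: outlier summary is empty",
                      RuntimeWarning, stacklevel=2)
    return pd.DataFrame([r.__dict__ for r in rows])


def classify_groups(z: pd.DataFrame, labels, folds: int = 10, seed: int = 0,
                    kernel: str = "linear", C: float = 1.0):
    """HC-vs-AD ROC-AUC of an SVC on deviation-score features.

    Features are standardized inside each training fold; subjects with any
    missing deviation score are excluded (logged).  Returns (mean AUC,
    per-fold AUCs).
    """
    labels = pd.Series(np.asarray(labels), index=z.index)
    complete = z.notna().all(axis=1)
    if (~complete).any():
        log.warning("classify_groups: dropping %d subjects with missing "
                    "deviation scores", int((~complete).sum()))
    x = z.loc[complete]
    y = (labels.loc[complete] == "AD").astype(int).to_numpy()
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both HC and AD must be present for classification")
    n_folds = folds
    if counts.min() < folds:
        n_folds = int(counts.min())
        warnings.warn(f"smallest class has {counts.min()} members; reducing "
                      f"folds to {n_folds}", RuntimeWarning, stacklevel=2)
    if n_folds < 2:
        raise ValueError("need at least 2 subjects per class for cross-validation")
    pipe = make_pipeline(StandardScaler(), SVC(kernel=kernel, C=C))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = cross_val_score(pipe, x.to_numpy(float), y, cv=cv, scoring="roc_auc")
    return float(aucs.mean()), aucs
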