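"""Adaptive transfer: pre-train on a large reference cohort, recalibrate
to a target cohort with a warped-space mean offset.

The adaptation assumes the age/sex trajectories learned on the reference
cohort are shared and only a cohort- (and site-) specific mean shift
differs.  Per ROI and target site, the offset is the mean warped-space
residual of the adaptation subjects::

    delta = mean_i [ W(y_std_i) - mu*_i ]

and adapted predictions are ``mu* + delta``.  Predictive variance, warp
and weights are untouched, so explained variance, correlation and the
within-site ranking of deviation scores are exactly invariant.

Target site labels unseen by the pretrained basis contribute zero to the
site-dummy block; their site effect is absorbed entirely into delta.  The
reference standardizer is reused for the target so offsets live on a
common scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import BasisSpec, FittedBasis
from .cohort import stratified_split
from .evaluation import FitMetrics, evaluate_model
from .model import NormativeModelResults, Prediction, fit_cohort

__all__ = ["AdaptationOffset", "AdaptedNormativeModel", "pretrain", "adapt",
           "transfer_benchmark"]


@dataclass
class AdaptationOffset:
    """Warped-space mean shift for one ROI at one target site."""

    roi: str
    target_site: str
    delta: float
    n_adapt: int


class AdaptedNormativeModel:
    """A pretrained model plus per-site mean offsets (mean-only adaptation)."""

    def __init__(self, base: NormativeModelResults,
                 offsets: list[AdaptationOffset]):
        self.base = base
        self.offsets = offsets
        self._deltas = {o.target_site: o.delta for o in offsets}

    @property
    def roi(self):
        return self.base.roi

    @property
    def converged(self):
        return self.base.converged

    def _offset_for(self, subjects: pd.DataFrame) -> np.ndarray:
        sites = subjects["site"].astype(str).to_numpy()
        unknown = sorted(set(sites) - set(self._deltas))
        if unknown:
            raise ValueError(f"no adaptation offset for site(s) {unknown}")
        return np.array([self._deltas[s] for s in sites])

    def predict(self, subjects: pd.DataFrame) -> Prediction:
        return self.base.predict(subjects, unknown_site="zero",
                                 mean_offset=self._offset_for(subjects))

    def zscore(self, subjects: pd.DataFrame, roi: str | None = None) -> np.ndarray:
        return self.base.zscore(subjects, roi=roi, unknown_site="zero",
                                mean_offset=self._offset_for(subjects))

    def centiles(self, ages, sex: str = "F", site: str | None = None,
                 quantiles=(0.05, 0.5, 0.95)) -> pd.DataFrame:
        if site is None:
            site = next(iter(self._deltas))
        return self.base.centiles(ages, sex=sex, site=site, quantiles=quantiles,
                                  mean_offset=self._deltas[site],
                                  unknown_site="zero")

    def to_dict(self) -> dict:
        d = self.base.to_dict()
        d["adaptation_offsets"] = [o.__dict__ for o in self.offsets]
        return d

    def save(self, path) -> None:
        """Serialize the pretrained model together with its offsets."""
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=1,
                                         sort_keys=True), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "AdaptedNormativeModel":
        import json
        from pathlib import Path

        d = json.loads(Path(path).read_text(encoding="utf-8"))
        offsets = [AdaptationOffset(**o) for o in d.pop("adaptation_offsets")]
        return cls(NormativeModelResults.from_dict(d), offsets)


def pretrain(reference: pd.DataFrame, rois: list[str] | None = None,
             basis: FittedBasis | BasisSpec | None = None,
             train_fraction: float = 0.8, seed: int = 0, **fit_kw):
    """Fit per-ROI models on 80% of a HC-only reference cohort.

    Returns (models, internal-holdout fit metrics).
    """
    if (reference["diagnosis"] != "HC").any():
        raise ValueError("reference cohort must be HC-only")
    train, holdout = stratified_split(reference, train_fraction=train_fraction,
                                     seed=seed)
    models = fit_cohort(train, rois=rois, basis=basis, **fit_kw)
    metrics = [evaluate_model(res, holdout, strategy="pretrain-holdout")
               for res in models.values()]
    return models, pd.DataFrame([m.__dict__ for m in metrics])


def adapt(models: dict[str, NormativeModelResults],
          adaptation: pd.DataFrame) -> dict[str, AdaptedNormativeModel]:
    """Recalibrate pretrained models to a target cohort (mean-only).

    ``adaptation`` must be HC subjects from the target cohort; one offset
    is estimated per ROI and target site.
    """
    if len(adaptation) == 0:
        raise ValueError("adaptation set is empty")
    if "diagnosis" in adaptation.columns and (adaptation["diagnosis"] != "HC").any():
        raise ValueError("adaptation subjects must be healthy controls")
    sites = adaptation["site"].astype(str).to_numpy()
    adapted: dict[str, AdaptedNormativeModel] = {}
    for roi, res in models.items():
        pred = res.predict(adaptation, unknown_site="zero")
        resid = res.warped_response(adaptation[roi].to_numpy(float)) - pred.mu_warped
        offsets = [
            AdaptationOffset(roi=roi, target_site=s,
                             delta=float(resid[sites == s].mean()),
                             n_adapt=int((sites == s).sum()))
            for s in sorted(set(sites))
        ]
        adapted[roi] = AdaptedNormativeModel(res, offsets)
    return adapted


def adapted_deviation_matrix(models: dict[str, AdaptedNormativeModel],
                             subjects: pd.DataFrame) -> pd.DataFrame:
    """Subjects x ROIs deviation scores from an adapted model set."""
    data = {roi: m.zscore(subjects) for roi, m in models.items()}
    return pd.DataFrame(data, index=subjects["subject_id"].to_numpy())


def evaluate_adapted(model: AdaptedNormativeModel, test: pd.DataFrame,
                     strategy: str, n: int, iteration: int) -> FitMetrics:
    """Fit metrics of an adapted model on the HC test set."""
    hc = test[test["diagnosis"] == "HC"] if "diagnosis" in test.columns else test
    return evaluate_model(model.base, hc, strategy=strategy, n=n,
                          iteration=iteration, prediction=model.predict(hc))


def transfer_benchmark(reference: pd.DataFrame, target: pd.DataFrame,
                       grid=None, strategies=None, root_seed: int = 0,
                       out_dir=None, **kwargs):
    """Paired within-cohort vs adapted benchmark on a shared test set.

    Convenience wrapper over :func:`normbench.benchmark.run_benchmark`
    with both arms enabled; each sampled subset serves simultaneously as
    the within-cohort training set and as the adaptation set.
    """
    from .benchmark import BenchmarkConfig, run_benchmark
    from .sampling import STRATEGIES, SizeGrid

    config = BenchmarkConfig(
        grid=grid or SizeGrid(), strategies=tuple(strategies or STRATEGIES),
        root_seed=root_seed, arms="both", out_dir=out_dir, **kwargs)
    return run_benchmark(config, target=target, reference=reference)
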