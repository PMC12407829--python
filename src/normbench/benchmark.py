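"""Benchmark orchestration: simulate -> split -> sample -> fit/adapt ->
predict -> evaluate -> clinical readouts, over the full condition grid.

Every condition (strategy x size x iteration) is deterministic under the
root seed, is computed independently, and is persisted as its own JSON
fragment when an output directory is given, so interrupted runs resume
without recomputation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .basis import BasisSpec
from .clinical import classify_groups, outlier_percentages, toc
from .cohort import (CohortSpec, generate_cohort, generate_reference_cohort,
                     reference_spec_from, stratified_split)
from .evaluation import evaluate_model, iqr_keep_mask, z_mbe, z_mse
from .model import deviation_matrix, fit_cohort
from .sampling import (STRATEGIES, SamplingSpec, SizeGrid, draw_sample,
                       enumerate_conditions)

log = logging.getLogger(__name__)

__all__ = ["BenchmarkConfig", "BenchmarkResults", "run_benchmark",
           "arm_difference"]

_TABLE_NAMES = ("fit_metrics", "z_errors", "mbe", "toc", "outliers", "auc")


@dataclass
class BenchmarkConfig:
    """Configuration of one full benchmark run."""

    cohort_spec: CohortSpec | None = None
    reference_spec: CohortSpec | None = None
    reference_offset: float = 0.1
    grid: SizeGrid = field(default_factory=SizeGrid)
    strategies: tuple = STRATEGIES
    sex_ratios: dict | None = None
    root_seed: int = 0
    arms: str = "within"  # within | transfer | both
    train_fraction: float = 0.8
    basis: BasisSpec | None = None
    svc_folds: int = 10
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.arms not in ("within", "transfer", "both"):
            raise ValueError("arms must be 'within', 'transfer' or 'both'")

    def to_dict(self) -> dict:
        d = {
            "cohort_spec": self.cohort_spec.to_dict() if self.cohort_spec else None,
            "reference_spec": (self.reference_spec.to_dict()
                               if self.reference_spec else None),
            "reference_offset": self.reference_offset,
            "grid": {"sizes": list(self.grid.sizes),
                     "iterations_per_size": self.grid.iterations_per_size,
                     "include_full": self.grid.include_full},
            "strategies": list(self.strategies),
            "sex_ratios": {k: [list(r) for r in v]
                           for k, v in (self.sex_ratios or {}).items()},
            "root_seed": self.root_seed,
            "arms": self.arms,
            "train_fraction": self.train_fraction,
            "svc_folds": self.svc_folds,
        }
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class BenchmarkResults:
    """Long result tables of one benchmark run plus the run manifest."""

    fit_metrics: pd.DataFrame
    z_errors: pd.DataFrame
    mbe: pd.DataFrame
    toc: pd.DataFrame
    outliers: pd.DataFrame
    auc: pd.DataFrame
    manifest: dict

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in _TABLE_NAMES:
            getattr(self, name).to_csv(out_dir / f"{name}.csv", index=False)
        (out_dir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True), encoding="utf-8")


def _condition_id(arm: str, spec: SamplingSpec) -> str:
    return f"{arm}_{spec.label}_n{spec.n}_i{spec.iteration}_s{spec.seed}"


def _condition_rows(arm: str, spec: SamplingSpec, models: dict, test: pd.DataFrame,
                    z_ref: pd.DataFrame, z_sub: pd.DataFrame,
                    fit_rows: list, svc_folds: int) -> dict:
    """Assemble the long-table rows of one fitted/adapted condition."""
    groups = test.set_index("subject_id")["diagnosis"]
    base = {"arm": arm, "strategy": spec.label, "n": spec.n,
            "iteration": spec.iteration}

    mse = z_mse(z_sub, z_ref)
    keep = iqr_keep_mask(mse.to_numpy())
    z_rows = [dict(base, subject_id=sid, group=groups[sid], metric="mse_z",
                   value=float(v), excluded=bool(not k))
              for (sid, v), k in zip(mse.items(), keep)]

    mbe = z_mbe(z_sub, z_ref)
    mbe_rows = [dict(base, roi=roi, metric="mbe_z", value=float(v))
                for roi, v in mbe.items()]

    toc_counts = toc(z_sub)
    toc_rows = [dict(base, subject_id=sid, group=groups[sid], toc=int(v))
                for sid, v in toc_counts.items()]

    pct = outlier_percentages(z_sub, groups.loc[z_sub.index])
    out_rows = [dict(base, **r) for r in pct.to_dict("records")]

    auc_rows = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean_auc, _ = classify_groups(z_sub, groups.loc[z_sub.index],
                                          folds=svc_folds, seed=spec.seed)
        auc_rows.append(dict(base, mean_auc=float(mean_auc)))
    except ValueError as exc:
        log.warning("classification skipped for %s: %s", _condition_id(arm, spec), exc)

    return {"fit_metrics": fit_rows, "z_errors": z_rows, "mbe": mbe_rows,
            "toc": toc_rows, "outliers": out_rows, "auc": auc_rows}


def _run_condition(arm: str, spec: SamplingSpec, pool: pd.DataFrame,
                   test: pd.DataFrame, z_ref: pd.DataFrame,
                   config: BenchmarkConfig, pre_models: dict | None,
                   pool_basis=None) -> dict:
    subset = draw_sample(pool, spec)
    base = {"arm": arm, "strategy": spec.label, "n": spec.n,
            "iteration": spec.iteration}
    if arm == "within":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            models = fit_cohort(subset, basis=pool_basis)
        z_sub = deviation_matrix(models, test)
        fit_rows = []
        for roi, res in models.items():
            fm = evaluate_model(res, test, strategy=spec.label, n=spec.n,
                                iteration=spec.iteration)
            for metric in ("msll", "smse", "ev", "rho"):
                fit_rows.append(dict(base, roi=roi, metric=metric,
                                     value=getattr(fm, metric),
                                     converged=fm.converged))
    else:
        from .transfer import adapt, adapted_deviation_matrix, evaluate_adapted

        adapted = adapt(pre_models, subset)
        z_sub = adapted_deviation_matrix(adapted, test)
        fit_rows = []
        for roi, am in adapted.items():
            fm = evaluate_adapted(am, test, strategy=spec.label, n=spec.n,
                                  iteration=spec.iteration)
            for metric in ("msll", "smse", "ev", "rho"):
                fit_rows.append(dict(base, roi=roi, metric=metric,
                                     value=getattr(fm, metric),
                                     converged=fm.converged))
    return _condition_rows(arm, spec, {}, test, z_ref, z_sub, fit_rows,
                           config.svc_folds)


def run_benchmark(config: BenchmarkConfig, target: pd.DataFrame | None = None,
                  reference: pd.DataFrame | None = None) -> BenchmarkResults:
    """Execute the full benchmark for one configuration.

    ``target``/``reference`` tables may be passed directly; otherwise they
    are generated from the specs in the config.  Partial failures are
    recorded per condition and the run continues.
    """
    if target is None:
        if config.cohort_spec is None:
            raise ValueError("either a target table or a cohort_spec is required")
        target = generate_cohort(config.cohort_spec)
    train, test = stratified_split(target, config.train_fraction,
                                   seed=config.root_seed)
    pool = train[train["diagnosis"] == "HC"]
    # the spline knot span and site levels are study-level quantities,
    # shared by the full-sample reference model and every subsample fit
    from .basis import FittedBasis
    pool_basis = FittedBasis.fit(pool, config.basis)

    out_dir = Path(config.out_dir) if config.out_dir else None
    frag_dir = None
    if out_dir is not None:
        frag_dir = out_dir / "conditions"
        frag_dir.mkdir(parents=True, exist_ok=True)

    arms = ("within", "transfer") if config.arms == "both" else (config.arms,)

    # reference models for the z-error comparison, one per arm
    z_refs: dict[str, pd.DataFrame] = {}
    pre_models = None
    if "within" in arms:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            full_models = fit_cohort(pool, basis=pool_basis)
        z_refs["within"] = deviation_matrix(full_models, test)
    if "transfer" in arms:
        from .transfer import adapt, adapted_deviation_matrix, pretrain

        if reference is None:
            ref_spec = config.reference_spec
            if ref_spec is None:
                ref_spec = reference_spec_from(config.cohort_spec)
            reference = generate_reference_cohort(ref_spec, config.reference_offset)
        pre_models, _ = pretrain(reference, basis=config.basis,
                                 seed=config.root_seed)
        full_adapted = adapt(pre_models, pool)
        z_refs["transfer"] = adapted_deviation_matrix(full_adapted, test)

    conditions = enumerate_conditions(config.grid, config.strategies,
                                      root_seed=config.root_seed,
                                      pool_size=len(pool),
                                      sex_ratios=config.sex_ratios)
    collected: dict[str, list] = {name: [] for name in _TABLE_NAMES}
    failures = []
    for arm in arms:
        for spec in conditions:
            cid = _condition_id(arm, spec)
            frag = frag_dir / f"{cid}.json" if frag_dir is not None else None
            if frag is not None and frag.exists():
                rows = json.loads(frag.read_text(encoding="utf-8"))
            else:
                try:
                    rows = _run_condition(arm, spec, pool, test, z_refs[arm],
                                          config, pre_models, pool_basis)
                except Exception as exc:  # noqa: BLE001 - keep the run going
                    log.error("condition %s failed: %s", cid, exc)
                    failures.append({"condition": cid, "error": str(exc)})
                    continue
                if frag is not None:
                    frag.write_text(json.dumps(rows), encoding="utf-8")
            for name in _TABLE_NAMES:
                collected[name].extend(rows[name])

    results = BenchmarkResults(
        **{name: pd.DataFrame(collected[name]) for name in _TABLE_NAMES},
        manifest={
            "config": config.to_dict(),
            "config_hash": config.config_hash,
            "n_pool": int(len(pool)),
            "n_test_hc": int((test["diagnosis"] == "HC").sum()),
            "n_test_ad": int((test["diagnosis"] == "AD").sum()),
            "n_conditions": len(conditions) * len(arms),
            "failures": failures,
        },
    )
    if out_dir is not None:
        results.save(out_dir)
    return results


def arm_difference(table: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Within-cohort minus adapted value per condition/metric (paired rows)."""
    keys = [c for c in table.columns
            if c not in ("arm", value_col, "converged", "excluded")]
    wide = table.pivot_table(index=keys, columns="arm", values=value_col,
                             aggfunc="first").reset_index()
    if not {"within", "transfer"} <= set(wide.columns):
        raise ValueError("table must contain both arms for a difference")
    wide["difference"] = wide["within"] - wide["transfer"]
    return wide
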