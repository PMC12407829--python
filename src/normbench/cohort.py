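"""Seed-reproducible synthetic cohorts for the normative-modeling benchmark.

The generator emulates the statistical structure of a single- or multi-site
ageing cohort with healthy controls (HC) and an Alzheimer's disease (AD)
group: regional brain measures (cortical thickness / subcortical volume
stand-ins) with a smooth declining age trend, a sex effect, per-site mean
offsets, SHASH-shaped (skewed, heavy-tailed) residuals, and medial-temporal
atrophy in AD.

Generating model, per ROI ``r`` and subject ``i``::

    eta_i = phi(age_i, sex_i)' w_true(r) + site_offset + eps_i,
    eps_i ~ N(0, 1/beta_true),
    eta_i -= ad_effect(r) / sqrt(beta_true)        (AD subjects only)
    x_i   = W^-1(u + v * eta_i; a_true, b_true)
    y_i   = roi_loc + roi_scale * x_i

``phi`` is the same clamped cubic B-spline + sex basis the model uses, so
model-true simulation and parameter recovery are well-posed.  The affine
latent calibration ``(u, v)`` is solved per ROI so that ``x`` has zero
mean and unit SD over the healthy controls: the model standardizes its
response on the training sample, and without this calibration the
standardized response would fall outside the SHASH family and the warp
parameters would not be recoverable.  ``u + v * eta`` is still Gaussian
and linear in the covariates, so the generating warp ``(a_true, b_true)``
is exactly the model's warp, while the effective noise precision becomes
``beta_true / v**2`` (reported in the ground-truth record).  Disable with
``normalize_latent=False`` for closed-form checks on the raw scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import generic_roi_names, medial_temporal_rois
from .basis import BasisSpec, FittedBasis

__all__ = [
    "META_COLUMNS",
    "CohortSpec",
    "roi_columns",
    "generate_cohort",
    "generate_reference_cohort",
    "reference_spec_from",
    "stratified_split",
    "write_cohort",
    "read_cohort",
]

META_COLUMNS = ["subject_id", "age", "sex", "site", "diagnosis"]

# fixed internal stream for the auto-built ground truth: the true weights
# depend only on n_rois, never on the sampling seed, so cohorts that share
# a spec share their generating parameters.
_TRUTH_SEED = 20240917


def roi_columns(table: pd.DataFrame) -> list[str]:
    """ROI measurement columns of a cohort table (everything non-meta)."""
    return [c for c in table.columns if c not in META_COLUMNS]


@dataclass
class CohortSpec:
    """Ground truth and demographics of one synthetic cohort.

    ``ad_effect`` holds the per-ROI Cohen's d of AD atrophy on the latent
    (warped Gaussian) scale; by default it is nonzero only on the
    designated medial-temporal-like ROIs.
    """

    n_hc: int = 865
    n_ad: int = 167
    age_min: float = 45.0
    age_max: float = 82.0
    sex_fraction_female: float = 0.58
    sites: tuple = (("site-01", 0.0),)
    n_rois: int = 30
    roi_names: list[str] | None = None
    true_weights: np.ndarray | None = None
    noise_precision_true: float = 4.0
    warp_true: tuple = (0.3, 1.4)
    ad_effect: np.ndarray | None = None
    ad_atrophy_d: float = 1.8
    age_density: str = "uniform"  # or "right_heavy" (Beta(5,2)-mapped ages)
    normalize_latent: bool = True
    roi_loc: float = 2.5
    roi_scale: float = 0.25
    seed: int = 0
    basis: BasisSpec = field(
        default_factory=lambda: BasisSpec(include_site=False)
    )

    def __post_init__(self) -> None:
        if self.n_hc < 0 or self.n_ad < 0:
            raise ValueError("n_hc and n_ad must be >= 0")
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        a, b = self.warp_true
        if not b > 0:
            raise ValueError("warp shape b_true must be > 0")
        if not self.noise_precision_true > 0:
            raise ValueError("noise precision beta_true must be > 0")
        if not self.age_max > self.age_min:
            raise ValueError("age_max must exceed age_min")
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise ValueError("sex_fraction_female must lie in [0, 1]")
        if self.age_density not in ("uniform", "right_heavy"):
            raise ValueError("age_density must be 'uniform' or 'right_heavy'")
        if self.roi_names is None:
            self.roi_names = generic_roi_names(self.n_rois)
        if len(self.roi_names) == 0:
            raise ValueError("roi_names must not be empty")
        if len(self.roi_names) != self.n_rois:
            raise ValueError("roi_names length must equal n_rois")
        gb = self._generating_basis()
        d_gen = gb.n_columns
        if self.true_weights is None:
            self.true_weights = _default_true_weights(gb, self.n_rois)
        self.true_weights = np.atleast_2d(np.asarray(self.true_weights, dtype=float))
        if self.true_weights.shape != (self.n_rois, d_gen):
            raise ValueError(
                f"true_weights must have shape ({self.n_rois}, {d_gen}), "
                f"got {self.true_weights.shape}"
            )
        if self.ad_effect is None:
            atrophic = set(medial_temporal_rois(self.roi_names))
            self.ad_effect = np.array(
                [self.ad_atrophy_d if r in atrophic else 0.0 for r in self.roi_names]
            )
        self.ad_effect = np.asarray(self.ad_effect, dtype=float)
        if self.ad_effect.shape != (self.n_rois,):
            raise ValueError("ad_effect must be a vector of length n_rois")
        if np.any(self.ad_effect < 0):
            raise ValueError("ad_effect entries must be >= 0 (atrophy magnitudes)")

    def _generating_basis(self) -> FittedBasis:
        return FittedBasis(spec=self.basis, age_min=self.age_min, age_max=self.age_max)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_weights"] = np.asarray(self.true_weights).tolist()
        d["ad_effect"] = np.asarray(self.ad_effect).tolist()
        d["sites"] = [[label, np.asarray(off).tolist() if np.ndim(off) else off]
                      for label, off in self.sites]
        d["basis"] = dataclasses.asdict(self.basis)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["sites"] = tuple((label, off) for label, off in d["sites"])
        d["true_weights"] = np.asarray(d["true_weights"], dtype=float)
        d["ad_effect"] = np.asarray(d["ad_effect"], dtype=float)
        d["warp_true"] = tuple(d["warp_true"])
        d["basis"] = BasisSpec(**d["basis"])
        return cls(**d)


def _default_true_weights(gb: FittedBasis, n_rois: int) -> np.ndarray:
    """Smooth declining age curves with mild per-ROI variation.

    Spline weights placed at the Greville abscissae reproduce a chosen
    polynomial exactly, so each ROI's latent mean curve is a mildly curved
    decline over the age span, with amplitude 0.8-1.6 latent SD units and
    a small sex effect.
    """
    k = gb.spec.spline_degree
    t = gb.knots
    greville = np.array([t[j + 1: j + 1 + k].mean() for j in range(gb.n_spline)])
    u = (greville - gb.age_min) / (gb.age_max - gb.age_min) - 0.5
    rng = np.random.default_rng(_TRUTH_SEED)
    weights = np.zeros((n_rois, gb.n_columns))
    for r in range(n_rois):
        amp = rng.uniform(0.8, 1.6)
        curv = rng.uniform(-0.3, 0.3)
        sex_w = rng.uniform(-0.3, 0.3)
        col = 1
        weights[r, col: col + gb.n_spline] = -amp * u + curv * (u**2 - 1.0 / 12.0)
        if gb.spec.include_sex:
            weights[r, col + gb.n_spline] = sex_w
    return weights


def _draw_ages(rng: np.random.Generator, n: int, spec: CohortSpec) -> np.ndarray:
    if spec.age_density == "right_heavy":
        u = rng.beta(5.0, 2.0, size=n)
    else:
        u = rng.random(n)
    return spec.age_min + u * (spec.age_max - spec.age_min)


def _latent_calibration(eta_ref: np.ndarray, a: float, b: float) -> tuple:
    """Solve (u, v) so W^-1(u + v*eta) has zero mean / unit SD on eta_ref."""
    from scipy import optimize

    from .shash import shash_inverse

    def moments(uv):
        u, v = uv
        x = shash_inverse(u + abs(v) * eta_ref, a, b)
        return [x.mean(), x.std(ddof=1) - 1.0]

    s0 = shash_inverse(eta_ref, a, b).std(ddof=1)
    v0 = 1.0 / s0 if s0 > 0 else 1.0
    sol = optimize.root(moments, x0=[0.0, v0], method="hybr")
    if not (sol.success or np.max(np.abs(sol.fun)) < 1e-8):
        raise RuntimeError("latent calibration failed to converge")
    return float(sol.x[0]), float(abs(sol.x[1]))


def generate_cohort(spec: CohortSpec, return_truth: bool = False):
    """Draw one cohort table; identical spec + seed give identical output.

    With ``return_truth=True`` also returns a per-ROI DataFrame of the
    effective generating parameters (warp, effective noise precision,
    latent calibration) used by parameter-recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_hc + spec.n_ad
    if n == 0:
        raise ValueError("cohort is empty: n_hc + n_ad must be >= 1")
    ages = _draw_ages(rng, n, spec)
    sex = np.where(rng.random(n) < spec.sex_fraction_female, "F", "M")
    site_labels = [label for label, _ in spec.sites]
    site_idx = rng.integers(0, len(spec.sites), size=n)
    diagnosis = np.array(["HC"] * spec.n_hc + ["AD"] * spec.n_ad)

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:05d}" for i in range(n)],
            "age": ages,
            "sex": sex,
            "site": [site_labels[j] for j in site_idx],
            "diagnosis": diagnosis,
        }
    )

    gb = spec._generating_basis()
    phi = gb.transform(table)
    beta = spec.noise_precision_true
    noise_sd = 0.0 if np.isinf(beta) else 1.0 / np.sqrt(beta)
    a_true, b_true = spec.warp_true
    from .shash import shash_inverse

    is_hc = diagnosis == "HC"
    site_offsets = np.array(
        [np.broadcast_to(np.asarray(off, dtype=float), (spec.n_rois,))
         for _, off in spec.sites]
    )  # (n_sites, n_rois)

    values = np.empty((n, spec.n_rois))
    truth_rows = []
    for r in range(spec.n_rois):
        eta = phi @ spec.true_weights[r] + site_offsets[site_idx, r]
        if noise_sd > 0:
            eta = eta + rng.normal(0.0, noise_sd, size=n)
        eta[~is_hc] -= spec.ad_effect[r] * noise_sd
        u, v = 0.0, 1.0
        if spec.normalize_latent:
            ref = eta[is_hc] if is_hc.any() else eta
            u, v = _latent_calibration(ref, a_true, b_true)
        x = shash_inverse(u + v * eta, a_true, b_true)
        values[:, r] = spec.roi_loc + spec.roi_scale * x
        if return_truth:
            truth_rows.append({
                "roi": spec.roi_names[r], "a": a_true, "b": b_true,
                "beta_eff": (np.inf if noise_sd == 0
                             else spec.noise_precision_true / v**2),
                "calib_u": u, "calib_v": v,
            })
    table = pd.concat(
        [table, pd.DataFrame(values, columns=spec.roi_names, index=table.index)],
        axis=1)
    if return_truth:
        return table, pd.DataFrame(truth_rows)
    return table


def reference_spec_from(spec: CohortSpec, n_hc: int = 5000, n_sites: int = 3,
                        seed: int | None = None) -> CohortSpec:
    """Derive an HC-only multi-site reference spec sharing the ground truth.

    Emulates a large reference cohort (UK Biobank stand-in) drawn from the
    same generating process as the target cohort but with its own sites and
    sampling stream.
    """
    sites = tuple((f"ref-site-{k + 1:02d}", 0.0) for k in range(n_sites))
    return dataclasses.replace(
        spec,
        n_hc=n_hc,
        n_ad=0,
        sites=sites,
        seed=spec.seed + 1_000_003 if seed is None else seed,
    )


def generate_reference_cohort(spec: CohortSpec, offset: float) -> pd.DataFrame:
    """HC-only reference cohort with a constant acquisition shift.

    ``offset`` is added to every ROI value (observed units), emulating the
    systematic mean difference between a large reference cohort and the
    target cohort (e.g. scanner/protocol effects).
    """
    if spec.n_ad != 0:
        raise ValueError("reference cohorts are HC-only: spec.n_ad must be 0")
    table = generate_cohort(spec)
    rois = roi_columns(table)
    table[rois] = table[rois] + float(offset)
    return table


def stratified_split(table: pd.DataFrame, train_fraction: float = 0.8,
                     age_bin_width: float = 5.0, seed: int = 0):
    """Split HC into train/test stratified on site x sex x age bin.

    The test set receives the held-out HC plus every AD subject.  Age bins
    are half-open ``[lo, lo + width)`` anchored at the youngest subject.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    hc = table[table["diagnosis"] == "HC"]
    if len(hc) == 0:
        raise ValueError("table contains no HC subjects to split")
    rng = np.random.default_rng(seed)
    age0 = float(table["age"].min())
    bins = np.floor((hc["age"].to_numpy(float) - age0) / age_bin_width).astype(int)
    strata = pd.DataFrame(
        {"site": hc["site"].astype(str).to_numpy(), "sex": hc["sex"].astype(str).to_numpy(),
         "bin": bins},
        index=hc.index,
    )
    train_idx: list = []
    for _, grp in strata.groupby(["site", "sex", "bin"], sort=True):
        idx = np.array(grp.index)
        rng.shuffle(idx)
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        train_idx.extend(idx[:n_train])
    train_mask = table.index.isin(train_idx)
    train = table.loc[train_mask].copy()
    test = table.loc[~train_mask].copy()
    return train, test


def write_cohort(table: pd.DataFrame, path: str | Path,
                 spec: CohortSpec | None = None) -> None:
    """Write a cohort as UTF-8 CSV, with a sidecar JSON of the spec."""
    path = Path(path)
    table.to_csv(path, index=False)
    if spec is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(spec.to_dict(), indent=1), encoding="utf-8")


def read_cohort(path: str | Path):
    """Read a cohort CSV (and its sidecar spec, if present)."""
    path = Path(path)
    table = pd.read_csv(path)
    sidecar = path.with_suffix(".json")
    spec = None
    if sidecar.exists():
        spec = CohortSpec.from_dict(json.loads(sidecar.read_text(encoding="utf-8")))
    return table, spec
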