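"""Training-set subsampling under controlled size and covariate-shift schemes.

Four strategies draw ``n`` healthy controls from a training pool:

- ``representative``: 10 age-quantile bins (equal occupancy), equal per-bin
  allocation, global sex balance within one subject.
- ``left_skewed`` / ``right_skewed``: 10 equal-width age bins weighted by a
  Beta(2,5) / Beta(5,2) density at the bin midpoints, over/under-sampling
  younger/older subjects; sex stays balanced.
- ``sex_imbalanced``: representative age sampling within each sex at a
  fixed female:male ratio (e.g. 1:4, 1:10, 4:1, 10:1).

Each (strategy, n, iteration) condition carries a deterministic seed
derived by hashing the root seed with the condition labels.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STRATEGIES",
    "save_sample_ids",
    "write_conditions_manifest",
    "SamplingSpec",
    "SizeGrid",
    "quantile_bins",
    "beta_bin_weights",
    "representative_sample",
    "skewed_sample",
    "sex_imbalanced_sample",
    "draw_sample",
    "enumerate_conditions",
    "derive_seed",
]

log = logging.getLogger(__name__)

STRATEGIES = ("representative", "left_skewed", "right_skewed", "sex_imbalanced")

_BETA_PARAMS = {"left_skewed": (2.0, 5.0), "right_skewed": (5.0, 2.0)}


@dataclass(frozen=True)
class SamplingSpec:
    """One subsampling condition."""

    strategy: str
    n: int
    n_bins: int = 10
    sex_ratio: tuple = (1, 1)  # (n_female, n_male) proportions
    iteration: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.n < 1:
            raise ValueError("sample size n must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        f, m = self.sex_ratio
        if f <= 0 or m <= 0:
            raise ValueError("sex_ratio components must be positive")

    @property
    def beta_params(self) -> tuple | None:
        return _BETA_PARAMS.get(self.strategy)

    @property
    def label(self) -> str:
        if self.strategy == "sex_imbalanced":
            f, m = self.sex_ratio
            return f"sex_{f}F{m}M"
        return self.strategy


@dataclass(frozen=True)
class SizeGrid:
    """Ordered training-set sizes plus the iteration count per size.

    Default grid: 5-to-200 in steps of 5, then 250-to-600 in steps of 50,
    with the full pool appended as a single-iteration condition.
    """

    sizes: tuple = field(
        default_factory=lambda: tuple(range(5, 201, 5)) + tuple(range(250, 601, 50))
    )
    iterations_per_size: int = 10
    include_full: bool = True

    def __post_init__(self) -> None:
        sizes = tuple(self.sizes)
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("sizes must be strictly increasing")
        object.__setattr__(self, "sizes", sizes)


def derive_seed(root_seed: int, strategy: str, n, iteration: int,
                sex_ratio: tuple = (1, 1)) -> int:
    """Stable per-condition seed: SHA-256 of the condition labels."""
    key = f"{root_seed}|{strategy}|{sex_ratio[0]}:{sex_ratio[1]}|{n}|{iteration}"
    digest = hashlib.sha256(key.encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def quantile_bins(ages, n_bins: int = 10) -> np.ndarray:
    """Rank-based age bins with occupancies differing by at most one.

    Bins are ordered by age; ties are broken by stable input order, so the
    assignment is deterministic even for degenerate (all-equal) ages.
    """
    ages = np.asarray(ages, dtype=float)
    if len(ages) < n_bins:
        raise ValueError(f"need at least {n_bins} subjects for {n_bins} bins")
    order = np.argsort(ages, kind="stable")
    bins = np.empty(len(ages), dtype=int)
    for k, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = k
    return bins


def beta_bin_weights(n_bins: int, alpha: float, beta: float) -> np.ndarray:
    """Normalized Beta(alpha, beta) pdf evaluated at bin midpoints."""
    mids = (np.arange(n_bins) + 0.5) / n_bins
    w = stats.beta.pdf(mids, alpha, beta)
    return w / w.sum()


def _allocate(capacities: np.ndarray, targets: np.ndarray,
              weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Cap per-bin targets at capacity, redistributing any shortfall to the
    remaining bins in proportion to their (renormalized) weights."""
    alloc = np.minimum(targets, capacities)
    shortfall = int(targets.sum() - alloc.sum())
    while shortfall > 0:
        room = capacities - alloc
        open_bins = room > 0
        if not open_bins.any():
            raise ValueError("pool exhausted: cannot reach the requested n")
        w = np.where(open_bins, np.maximum(weights, 1e-12), 0.0)
        extra = rng.multinomial(shortfall, w / w.sum())
        alloc = np.minimum(alloc + extra, capacities)
        shortfall = int(targets.sum() - alloc.sum())
    return alloc


def _equal_targets(n: int, n_bins: int, rng: np.random.Generator) -> np.ndarray:
    base, rem = divmod(n, n_bins)
    targets = np.full(n_bins, base)
    if rem:
        targets[rng.choice(n_bins, size=rem, replace=False)] += 1
    return targets


def _sex_counts(n: int, sex_ratio: tuple, rng: np.random.Generator) -> tuple:
    f, m = sex_ratio
    if (f, m) == (1, 1):
        n_f = n // 2
        if n % 2:
            n_f += int(rng.integers(2))  # odd n: the extra subject's sex is random
    else:
        n_f = int(np.floor(n * f / (f + m) + 0.5))
    return n_f, n - n_f


def _split_sexes(alloc: np.ndarray, f_cap: np.ndarray, m_cap: np.ndarray,
                 n_f: int) -> np.ndarray:
    """Per-bin female counts summing to (as close as feasible) n_f.

    Each bin k contributes x_k females with alloc_k - x_k males; the split
    tracks the global female share as closely as bin availability allows.
    """
    lower = np.maximum(0, alloc - m_cap)
    upper = np.minimum(alloc, f_cap)
    target = int(np.clip(n_f, lower.sum(), upper.sum()))
    if target != n_f:
        log.warning("sex balance shortfall: wanted %d females, feasible %d",
                    n_f, target)
    x = lower.copy()
    share = target / alloc.sum() if alloc.sum() else 0.0
    for _ in range(target - int(lower.sum())):
        room = x < upper
        deficit = np.where(room, alloc * share - x, -np.inf)
        x[int(np.argmax(deficit))] += 1
    return x


def _binned_sample(pool: pd.DataFrame, spec: SamplingSpec,
                   weights: np.ndarray | None) -> pd.DataFrame:
    """Joint age-bin allocation with a global ±1 sex balance."""
    rng = np.random.default_rng(spec.seed)
    ages = pool["age"].to_numpy(float)
    if weights is None:
        bins = quantile_bins(ages, spec.n_bins)
        w = np.ones(spec.n_bins)
        targets = _equal_targets(spec.n, spec.n_bins, rng)
    else:
        edges = np.linspace(ages.min(), ages.max(), spec.n_bins + 1)
        bins = np.clip(np.digitize(ages, edges[1:-1]), 0, spec.n_bins - 1)
        w = weights
        targets = rng.multinomial(spec.n, weights)
    capacities = np.bincount(bins, minlength=spec.n_bins)
    alloc = _allocate(capacities, targets, w, rng)
    sex = pool["sex"].astype(str).to_numpy()
    f_cap = np.bincount(bins[sex == "F"], minlength=spec.n_bins)
    m_cap = capacities - f_cap
    n_f, _ = _sex_counts(spec.n, (1, 1), rng)
    fem_alloc = _split_sexes(alloc, f_cap, m_cap, n_f)
    idx_pool = pool.index.to_numpy()
    picked = []
    for k in range(spec.n_bins):
        for label, count in (("F", fem_alloc[k]), ("M", alloc[k] - fem_alloc[k])):
            if count == 0:
                continue
            members = idx_pool[(bins == k) & (sex == label)]
            picked.append(rng.choice(members, size=count, replace=False))
    idx = np.concatenate(picked)
    return pool.loc[np.sort(idx)].copy()


def _per_sex_sample(pool: pd.DataFrame, spec: SamplingSpec) -> pd.DataFrame:
    """Fixed female/male counts; representative quantile bins within sex."""
    rng = np.random.default_rng(spec.seed)
    n_f, n_m = _sex_counts(spec.n, spec.sex_ratio, rng)
    sex = pool["sex"].astype(str).to_numpy()
    picked = []
    for label, n_s in (("F", n_f), ("M", n_m)):
        if n_s == 0:
            continue
        sub = pool[sex == label]
        if len(sub) < n_s:
            raise ValueError(
                f"insufficient {label} subjects: need {n_s}, have {len(sub)}")
        n_bins = min(spec.n_bins, len(sub))
        bins = quantile_bins(sub["age"].to_numpy(float), n_bins)
        capacities = np.bincount(bins, minlength=n_bins)
        alloc = _allocate(capacities, _equal_targets(n_s, n_bins, rng),
                          np.ones(n_bins), rng)
        idx_sub = sub.index.to_numpy()
        for k in range(n_bins):
            if alloc[k]:
                picked.append(rng.choice(idx_sub[bins == k], size=alloc[k],
                                         replace=False))
    idx = np.concatenate(picked)
    return pool.loc[np.sort(idx)].copy()


def _sample(pool: pd.DataFrame, spec: SamplingSpec,
            weights: np.ndarray | None) -> pd.DataFrame:
    if spec.n > len(pool):
        raise ValueError(f"requested n={spec.n} exceeds pool size {len(pool)}")
    if spec.strategy == "sex_imbalanced":
        return _per_sex_sample(pool, spec)
    return _binned_sample(pool, spec, weights)


def representative_sample(pool: pd.DataFrame, spec: SamplingSpec) -> pd.DataFrame:
    """Age-distribution-preserving, sex-balanced sample of size spec.n."""
    if spec.strategy != "representative":
        raise ValueError("spec.strategy must be 'representative'")
    return _sample(pool, spec, weights=None)


def skewed_sample(pool: pd.DataFrame, spec: SamplingSpec) -> pd.DataFrame:
    """Beta-weighted age-skewed, sex-balanced sample of size spec.n."""
    if spec.strategy not in _BETA_PARAMS:
        raise ValueError("spec.strategy must be 'left_skewed' or 'right_skewed'")
    a, b = spec.beta_params
    return _sample(pool, spec, weights=beta_bin_weights(spec.n_bins, a, b))


def sex_imbalanced_sample(pool: pd.DataFrame, spec: SamplingSpec) -> pd.DataFrame:
    """Representative-age sample at a fixed female:male ratio."""
    if spec.strategy != "sex_imbalanced":
        raise ValueError("spec.strategy must be 'sex_imbalanced'")
    return _sample(pool, spec, weights=None)


_DISPATCH = {
    "representative": representative_sample,
    "left_skewed": skewed_sample,
    "right_skewed": skewed_sample,
    "sex_imbalanced": sex_imbalanced_sample,
}


def draw_sample(pool: pd.DataFrame, spec: SamplingSpec) -> pd.DataFrame:
    """Dispatch to the sampler for spec.strategy."""
    return _DISPATCH[spec.strategy](pool, spec)


def enumerate_conditions(grid: SizeGrid, strategies=STRATEGIES,
                         root_seed: int = 0, pool_size: int | None = None,
                         sex_ratios: dict | None = None) -> list[SamplingSpec]:
    """Cartesian product sizes x strategies x iterations with derived seeds.

    The full-pool size (if ``grid.include_full`` and ``pool_size`` given)
    is appended as a single-iteration condition per strategy.
    ``sex_ratios`` maps the ``sex_imbalanced`` strategy to a list of
    (F, M) ratios; each ratio becomes its own condition set.
    """
    sex_ratios = sex_ratios or {"sex_imbalanced": [(1, 4), (1, 10), (4, 1), (10, 1)]}
    specs: list[SamplingSpec] = []
    for strategy in strategies:
        ratios = sex_ratios.get(strategy, [(1, 1)]) if strategy == "sex_imbalanced" \
            else [(1, 1)]
        for ratio in ratios:
            sizes: list = [s for s in grid.sizes
                           if pool_size is None or s <= pool_size]
            for n in sizes:
                for it in range(1, grid.iterations_per_size + 1):
                    specs.append(SamplingSpec(
                        strategy=strategy, n=n, iteration=it, sex_ratio=ratio,
                        seed=derive_seed(root_seed, strategy, n, it, ratio)))
            if grid.include_full and pool_size is not None:
                specs.append(SamplingSpec(
                    strategy=strategy, n=pool_size, iteration=1, sex_ratio=ratio,
                    seed=derive_seed(root_seed, strategy, "full", 1, ratio)))
    return specs


def save_sample_ids(sample: pd.DataFrame, spec: SamplingSpec, out_dir) -> "Path":
    """Persist a drawn sample as a plain subject-id list.

    The filename encodes strategy, sex ratio, n, iteration and seed, so a
    condition can be re-identified (and re-drawn) from the file name alone.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / (f"{spec.label}_n{spec.n}_i{spec.iteration}"
                      f"_s{spec.seed}.txt")
    path.write_text("\n".join(sample["subject_id"].astype(str)) + "\n",
                    encoding="utf-8")
    return path


def write_conditions_manifest(specs, path) -> pd.DataFrame:
    """Write the full condition list (one row per SamplingSpec) as CSV."""
    from pathlib import Path

    rows = [{"strategy": s.strategy, "label": s.label, "n": s.n,
             "n_bins": s.n_bins, "sex_ratio_f": s.sex_ratio[0],
             "sex_ratio_m": s.sex_ratio[1], "iteration": s.iteration,
             "seed": s.seed} for s in specs]
    manifest = pd.DataFrame(rows)
    manifest.to_csv(Path(path), index=False)
    return manifest
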