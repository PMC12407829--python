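"""Design-matrix construction: cubic B-spline age basis + sex + site dummies.

The age trend is expanded on a clamped cubic B-spline basis with three
interior knots evenly spaced over the training age range.  Sex enters as a
single binary column (F = 0, M = 1); sites are dummy-coded against the
first (sorted) training site.  An explicit intercept column is kept in
front of the spline block; the resulting one-dimensional collinearity
(the clamped spline block sums to one) is absorbed by the Gaussian weight
prior of the Bayesian regression, so no spline column is dropped.

Ages outside the training span are clamped to it before evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = ["BasisSpec", "FittedBasis", "build_design"]


@dataclass(frozen=True)
class BasisSpec:
    """Configuration of the normative-model covariate basis."""

    spline_degree: int = 3
    n_interior_knots: int = 3
    include_sex: bool = True
    spline_sex: bool = False  # optionally interact the age spline with sex
    include_site: bool = True

    def __post_init__(self) -> None:
        if self.spline_degree < 1:
            raise ValueError("spline_degree must be >= 1")
        if self.n_interior_knots < 0:
            raise ValueError("n_interior_knots must be >= 0")


@dataclass
class FittedBasis:
    """A basis bound to a training cohort: knot span, sex/site levels."""

    spec: BasisSpec
    age_min: float
    age_max: float
    site_levels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.age_max > self.age_min:
            raise ValueError("degenerate age span: age_max must exceed age_min")
        k = self.spec.spline_degree
        interior = np.linspace(self.age_min, self.age_max, self.spec.n_interior_knots + 2)[1:-1]
        self.knots = np.concatenate(
            [np.full(k + 1, self.age_min), interior, np.full(k + 1, self.age_max)]
        )
        if np.any(np.diff(interior) <= 0) and len(interior) > 1:
            raise ValueError("interior knots must be strictly increasing")

    # -- construction -------------------------------------------------
    @classmethod
    def fit(cls, table: pd.DataFrame, spec: BasisSpec | None = None) -> "FittedBasis":
        """Learn the knot span and site levels from a training table."""
        spec = spec or BasisSpec()
        ages = np.asarray(table["age"], dtype=float)
        if ages.size == 0:
            raise ValueError("cannot fit a basis on an empty table")
        sites = sorted(table["site"].astype(str).unique()) if spec.include_site else []
        return cls(spec=spec, age_min=float(ages.min()), age_max=float(ages.max()),
                   site_levels=sites)

    # -- properties ----------------------------------------------------
    @property
    def n_spline(self) -> int:
        return len(self.knots) - self.spec.spline_degree - 1

    @property
    def column_names(self) -> list[str]:
        names = ["intercept"] + [f"bspline_{j}" for j in range(self.n_spline)]
        if self.spec.include_sex:
            names.append("sex_M")
        if self.spec.spline_sex:
            names += [f"bspline_{j}:sex_M" for j in range(self.n_spline)]
        names += [f"site[{s}]" for s in self.site_levels[1:]]
        return names

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    # -- evaluation ----------------------------------------------------
    def spline_matrix(self, ages: np.ndarray) -> np.ndarray:
        ages = np.clip(np.asarray(ages, dtype=float), self.age_min, self.age_max)
        dm = BSpline.design_matrix(ages, self.knots, self.spec.spline_degree,
                                   extrapolate=False)
        return np.asarray(dm.todense())

    def transform(self, table: pd.DataFrame, unknown_site: str = "raise") -> np.ndarray:
        """Evaluate the fitted basis on new subjects.

        Parameters
        ----------
        unknown_site:
            ``"raise"`` errors on a site label unseen at training time;
            ``"zero"`` leaves the whole site-dummy block at zero for such
            subjects (used by transfer adaptation, where the site shift is
            absorbed into the adaptation offset instead).
        """
        n = len(table)
        blocks = [np.ones((n, 1)), self.spline_matrix(np.asarray(table["age"], dtype=float))]
        if self.spec.include_sex or self.spec.spline_sex:
            sex = table["sex"].astype(str).to_numpy()
            bad = set(np.unique(sex)) - {"F", "M"}
            if bad:
                raise ValueError(f"unknown sex labels: {sorted(bad)}")
            male = (sex == "M").astype(float)[:, None]
        if self.spec.include_sex:
            blocks.append(male)
        if self.spec.spline_sex:
            blocks.append(blocks[1] * male)
        if self.site_levels:
            site = table["site"].astype(str).to_numpy()
            unseen = sorted(set(site) - set(self.site_levels))
            if unseen and unknown_site == "raise":
                raise ValueError(
                    f"site label(s) {unseen} were not present in the training data"
                )
            dummies = np.zeros((n, len(self.site_levels) - 1))
            for j, level in enumerate(self.site_levels[1:]):
                dummies[:, j] = (site == level).astype(float)
            blocks.append(dummies)
        return np.hstack(blocks)


def build_design(table: pd.DataFrame, basis: FittedBasis | BasisSpec | None = None,
                 unknown_site: str = "raise") -> np.ndarray:
    """Build (or fit-and-build) the design matrix for a subject table."""
    if basis is None or isinstance(basis, BasisSpec):
        basis = FittedBasis.fit(table, basis)
    return basis.transform(table, unknown_site=unknown_site)
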