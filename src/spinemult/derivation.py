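"""Derive multiplier sets from growth references and compare them.

A growth reference (database) is a set of sitting-height-for-age curves,
one per percentile or SD line and sex. The multiplier at an age is the
sitting height at skeletal maturity divided by the sitting height at that
age, ``M = Lm / L``, computed separately for every percentile curve.

The scientific claim behind the method is *percentile invariance*: the
multiplier curves of different percentile lines nearly coincide, so a
single table serves all children. This module quantifies how nearly
(:func:`variability_stats`), collapses a set to its cross-percentile mean
curve (:func:`mean_multiplier_curve`), and measures agreement between two
references via polynomial regression of one mean curve on the other
(:func:`compare_multiplier_sets`).

Databases with different age grids are matched exactly by total months;
no interpolation is performed between grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DerivationError, DomainError
from .reference_tables import AgeYM, Sex

__all__ = [
    "GrowthRecord",
    "GrowthDatabase",
    "MultiplierSet",
    "VariabilityReport",
    "SexVariability",
    "ComparisonResult",
    "DEFAULT_MATURITY",
    "derive_multipliers",
    "variability_stats",
    "mean_multiplier_curve",
    "compare_multiplier_sets",
]

#: Skeletal maturity ages of the packaged table, in total months.
DEFAULT_MATURITY: dict[Sex, int] = {Sex.MALE: 216, Sex.FEMALE: 192}


@dataclass(frozen=True)
class GrowthRecord:
    """One reference measurement: sitting height of a (sex, percentile)
    curve at one age. The record at maturity age carries Lm."""

    sex: Sex
    percentile: str
    age: AgeYM
    sitting_height: float  # cm

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex.parse(self.sex))
        object.__setattr__(self, "percentile", str(self.percentile))
        if not self.sitting_height > 0:
            raise DomainError(
                f"sitting height must be positive, got {self.sitting_height} "
                f"({self.sex.value}, {self.percentile}, {self.age})"
            )


class GrowthDatabase:
    """A percentile-structured sitting-height reference.

    Percentile labels are opaque strings ("P50", "-2.5SD", ...); no ordering
    or spacing between them is assumed. Each (sex, percentile, age) key is
    unique, and every (sex, percentile) curve present must include a record
    at that sex's maturity age — the denominator curve needs its Lm.
    """

    def __init__(
        self,
        records: Iterable[GrowthRecord],
        maturity_age: Mapping[Sex, int] | None = None,
        provenance: str = "user-supplied",
    ):
        self.maturity_age = dict(DEFAULT_MATURITY if maturity_age is None else {
            Sex.parse(s): int(t) for s, t in maturity_age.items()
        })
        self.provenance = provenance
        records = list(records)
        seen: set[tuple[Sex, str, int]] = set()
        for rec in records:
            key = (rec.sex, rec.percentile, rec.age.total_months)
            if key in seen:
                raise DomainError(
                    f"duplicate record for ({rec.sex.value}, {rec.percentile}, {rec.age})"
                )
            seen.add(key)
        self._records = sorted(
            records, key=lambda r: (r.sex.value, r.percentile, r.age.total_months)
        )
        for sex, percentile in {(r.sex, r.percentile) for r in records}:
            mat = self.maturity_age.get(sex)
            if mat is None:
                raise DomainError(f"no maturity age configured for sex {sex.value!r}")
            if (sex, percentile, mat) not in seen:
                raise DerivationError(
                    f"curve ({sex.value}, {percentile}) has no record at maturity age "
                    f"{AgeYM.from_total_months(mat)}"
                )

    @property
    def records(self) -> list[GrowthRecord]:
        return list(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sex": [r.sex.value for r in self._records],
                "percentile": [r.percentile for r in self._records],
                "total_months": [r.age.total_months for r in self._records],
                "sitting_height_cm": [r.sitting_height for r in self._records],
            }
        )

    def scaled(self, factor: float) -> "GrowthDatabase":
        """Same database with every height multiplied by ``factor``
        (unit change / scale-invariance checks)."""
        if not factor > 0:
            raise DomainError(f"scale factor must be positive, got {factor}")
        return GrowthDatabase(
            (
                GrowthRecord(r.sex, r.percentile, r.age, r.sitting_height * factor)
                for r in self._records
            ),
            maturity_age=self.maturity_age,
            provenance=self.provenance,
        )


@dataclass(frozen=True)
class MultiplierSet:
    """Derived multipliers, one per (sex, percentile, age).

    Stored as a DataFrame with columns ``sex, percentile, total_months,
    multiplier``. M = 1 at maturity age for every curve by construction.
    """

    frame: pd.DataFrame
    provenance: str = "derived"

    def __post_init__(self) -> None:
        required = ["sex", "percentile", "total_months", "multiplier"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise DomainError(f"multiplier set frame missing columns {missing}")
        frame = self.frame[required].sort_values(required[:3]).reset_index(drop=True)
        if (frame["multiplier"] <= 0).any():
            bad = frame[frame["multiplier"] <= 0].iloc[0]
            raise DomainError(
                f"non-positive multiplier {bad['multiplier']} at "
                f"({bad['sex']}, {bad['percentile']}, {bad['total_months']} months)"
            )
        object.__setattr__(self, "frame", frame)

    def sexes(self) -> list[Sex]:
        return [Sex(s) for s in self.frame["sex"].unique()]

    def percentiles(self, sex: Sex | str) -> list[str]:
        sex = Sex.parse(sex)
        return sorted(self.frame.loc[self.frame["sex"] == sex.value, "percentile"].unique())

    def curve(self, sex: Sex | str, percentile: str) -> pd.Series:
        """Multiplier-vs-age series for one percentile curve."""
        sex = Sex.parse(sex)
        sel = self.frame[
            (self.frame["sex"] == sex.value) & (self.frame["percentile"] == percentile)
        ]
        return sel.set_index("total_months")["multiplier"].sort_index()


def derive_multipliers(db: GrowthDatabase) -> MultiplierSet:
    """Compute M = Lm / L for every record of the database.

    Lm is the sitting height of the same (sex, percentile) curve at that
    sex's maturity age. The database invariants guarantee Lm exists; its
    own maturity records yield M = 1 exactly.
    """
    frame = db.to_frame()
    mat_ages = frame["sex"].map(lambda s: db.maturity_age[Sex(s)])
    maturity = frame[frame["total_months"] == mat_ages]
    lm = maturity.set_index(["sex", "percentile"])["sitting_height_cm"]
    keys = pd.MultiIndex.from_frame(frame[["sex", "percentile"]])
    frame = frame.assign(multiplier=lm.reindex(keys).to_numpy() / frame["sitting_height_cm"])
    return MultiplierSet(
        frame=frame[["sex", "percentile", "total_months", "multiplier"]],
        provenance=f"derived from {db.provenance}",
    )


@dataclass(frozen=True)
class SexVariability:
    """Cross-percentile multiplier variability for one sex.

    ``per_age`` maps total months to the maximum absolute deviation of any
    percentile's multiplier from the cross-percentile mean at that age.
    ``mean_variability`` averages that series over the age grid (unweighted);
    ``max_variability`` is its maximum.
    """

    per_age: Mapping[int, float]
    mean_variability: float
    max_variability: float


@dataclass(frozen=True)
class VariabilityReport:
    """Variability per sex plus the pooled summary over both sexes.

    Pooled values treat every (sex, age) cell equally: the pooled mean is
    the unweighted mean of all per-age values of both sexes, the pooled max
    their maximum. All values are zero when only one percentile is present.
    """

    per_sex: Mapping[Sex, SexVariability]
    mean_variability: float
    max_variability: float

    def for_sex(self, sex: Sex | str) -> SexVariability:
        sex = Sex.parse(sex)
        try:
            return self.per_sex[sex]
        except KeyError:
            raise DomainError(f"no variability data for sex {sex.value!r}")


def variability_stats(mset: MultiplierSet) -> VariabilityReport:
    """Quantify how far individual percentile curves stray from their mean.

    At each age (per sex) the statistic is
    ``max_p | M_p - mean_p(M_p) |`` over the percentiles tabulated at that
    age. Perfectly percentile-invariant multipliers give zero everywhere.
    """
    frame = mset.frame
    if frame.empty:
        raise DomainError("multiplier set is empty")
    per_sex: dict[Sex, SexVariability] = {}
    all_values: list[np.ndarray] = []
    for sex_value, sub in frame.groupby("sex", sort=True):
        pivot = sub.pivot(index="total_months", columns="percentile", values="multiplier")
        dev = (pivot.sub(pivot.mean(axis=1), axis=0)).abs().max(axis=1)
        per_sex[Sex(sex_value)] = SexVariability(
            per_age=dev.to_dict(),
            mean_variability=float(dev.mean()),
            max_variability=float(dev.max()),
        )
        all_values.append(dev.to_numpy())
    pooled = np.concatenate(all_values)
    return VariabilityReport(
        per_sex=per_sex,
        mean_variability=float(pooled.mean()),
        max_variability=float(pooled.max()),
    )


def mean_multiplier_curve(mset: MultiplierSet, sex: Sex | str) -> pd.Series:
    """Unweighted mean multiplier across percentile labels at each age,
    indexed by total months."""
    sex = Sex.parse(sex)
    sub = mset.frame[mset.frame["sex"] == sex.value]
    if sub.empty:
        raise DomainError(f"multiplier set has no entries for sex {sex.value!r}")
    curve = sub.groupby("total_months")["multiplier"].mean().sort_index()
    curve.name = f"mean_multiplier_{sex.value}"
    return curve


@dataclass(frozen=True)
class ComparisonResult:
    """Agreement between two multiplier sets on their shared age grid.

    The mean curve of ``b`` is regressed on a degree-``degree`` polynomial
    in the mean curve of ``a`` (ordinary least squares). ``r_squared`` and
    ``rmse`` describe the fit residuals; ``max_abs_difference`` is the raw
    (pre-fit) maximum gap between the two mean curves.
    """

    degree: int
    r_squared: float
    rmse: float
    max_abs_difference: float
    n_shared_ages: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise DomainError(f"R^2 out of [0, 1]: {self.r_squared}")
        if self.rmse < 0:
            raise DomainError(f"negative RMSE: {self.rmse}")


def compare_multiplier_sets(
    a: MultiplierSet,
    b: MultiplierSet,
    sex: Sex | str,
    degree: int,
) -> ComparisonResult:
    """Polynomial-regression agreement of two references' mean curves.

    Ages are matched exactly by total months; at least ``degree + 1``
    shared ages are required for the fit to be determined.
    """
    if degree < 0:
        raise DomainError(f"polynomial degree must be non-negative, got {degree}")
    curve_a = mean_multiplier_curve(a, sex)
    curve_b = mean_multiplier_curve(b, sex)
    shared = curve_a.index.intersection(curve_b.index)
    if len(shared) < degree + 1:
        raise DomainError(
            f"only {len(shared)} shared ages between the two sets; "
            f"a degree-{degree} fit needs at least {degree + 1}"
        )
    x = curve_a.loc[shared].to_numpy(dtype=float)
    y = curve_b.loc[shared].to_numpy(dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(x, y, deg=degree)
    residuals = y - np.polynomial.polynomial.polyval(x, coeffs)
    sse = float(np.sum(residuals**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if sst == 0.0 else max(0.0, min(1.0, 1.0 - sse / sst))
    return ComparisonResult(
        degree=degree,
        r_squared=r_squared,
        rmse=float(np.sqrt(sse / len(shared))),
        max_abs_difference=float(np.max(np.abs(x - y))),
        n_shared_ages=int(len(shared)),
    )
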