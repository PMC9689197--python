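"""Synthetic percentile-structured growth databases with known truth.

Real sitting-height references cannot be redistributed, so derivation,
variability, and comparison are exercised against generated databases
whose exact ground-truth multipliers are known by construction. Curves
are built by *inverting* a seed multiplier table — ``L(age) = Lm / M(age)``
— rather than by an independent parametric growth model, so the generator
is the algebraic inverse of :func:`~spinemult.derivation.derive_multipliers`
and round-trip recovery is exact in the noise-free case.

Two generation modes:

``proportional``
    Every percentile curve is a scalar multiple of the inverted seed
    curve (each percentile has its own mature height). All percentiles
    then share *identical* multipliers: perfect percentile invariance.

``sd_offset``
    Percentile curves are the inverted median curve plus a signed offset
    index times an age-dependent spread that shrinks linearly (in total
    months, from birth to maturity) from ``spread_at_birth`` to
    ``spread_at_maturity``. This emulates SD-line references, where the
    multipliers of different lines differ most at the youngest ages and
    converge toward maturity.

Measurement noise is multiplicative relative Normal noise (error scales
with size). Records at maturity age are always emitted and always
noise-free, so the derivation numerator is exact and the noise-free
round-trip bound is provable.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .reference_tables import AgeYM, MultiplierTable, Sex, load_packaged_table
from .derivation import GrowthDatabase, GrowthRecord, MultiplierSet

__all__ = [
    "SyntheticConfig",
    "generate_database",
    "ground_truth",
    "DEFAULT_MATURE_HEIGHTS",
]

#: Default mature sitting heights (cm) for a single median percentile;
#: typical adult values: ~92 cm for men, ~86 cm for women.
DEFAULT_MATURE_HEIGHTS: dict[Sex, dict[str, float]] = {
    Sex.MALE: {"P50": 92.0},
    Sex.FEMALE: {"P50": 86.0},
}


def _default_age_grid() -> list[AgeYM]:
    """Yearly grid from 1 to 15 years — inside both sexes' table domains."""
    return [AgeYM(y, 0) for y in range(1, 16)]


@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for one synthetic database.

    ``mature_heights`` maps sex to {percentile label: mature sitting height
    in cm}. ``sd_offsets`` optionally fixes each label's signed offset
    index for ``sd_offset`` mode (e.g. {"-2.5SD": -2.5, "0SD": 0.0, ...});
    by default labels get evenly spaced integer offsets centered at 0, in
    sorted label order. ``noise_sd`` is the relative SD of multiplicative
    measurement noise (0 disables it)."""

    seed_table: MultiplierTable | None = None
    mature_heights: Mapping[Sex, Mapping[str, float]] | None = None
    mode: str = "proportional"
    spread_at_birth: float = 3.0  # cm, sd_offset mode
    spread_at_maturity: float = 1.0  # cm, sd_offset mode
    noise_sd: float = 0.0
    age_grid: Sequence[AgeYM] | None = None
    sd_offsets: Mapping[str, float] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("proportional", "sd_offset"):
            raise DomainError(f"unknown mode {self.mode!r}; expected 'proportional' or 'sd_offset'")
        if not 0 <= self.noise_sd < 0.2:
            raise DomainError(f"noise_sd must be in [0, 0.2), got {self.noise_sd}")
        if self.spread_at_birth < 0 or self.spread_at_maturity < 0:
            raise DomainError("spreads must be non-negative")
        if self.spread_at_maturity > self.spread_at_birth:
            raise DomainError(
                f"spread_at_maturity ({self.spread_at_maturity}) must not exceed "
                f"spread_at_birth ({self.spread_at_birth}): spread shrinks toward maturity"
            )
        for per_sex in self.resolved_mature_heights().values():
            for label, h in per_sex.items():
                if not h > 0:
                    raise DomainError(f"mature height for {label!r} must be positive, got {h}")

    def resolved_table(self) -> MultiplierTable:
        return self.seed_table if self.seed_table is not None else load_packaged_table()

    def resolved_mature_heights(self) -> dict[Sex, dict[str, float]]:
        raw = self.mature_heights if self.mature_heights is not None else DEFAULT_MATURE_HEIGHTS
        return {Sex.parse(s): dict(v) for s, v in raw.items()}

    def resolved_age_grid(self) -> list[AgeYM]:
        grid = list(self.age_grid) if self.age_grid is not None else _default_age_grid()
        return sorted(set(grid), key=lambda a: a.total_months)

    def offsets_for(self, labels: Sequence[str]) -> dict[str, float]:
        """Signed offset index per percentile label (sd_offset mode)."""
        labels = sorted(labels)
        if self.sd_offsets is not None:
            missing = [p for p in labels if p not in self.sd_offsets]
            if missing:
                raise DomainError(f"sd_offsets missing labels {missing}")
            return {p: float(self.sd_offsets[p]) for p in labels}
        # evenly spaced integers centered at 0, mimicking SD lines
        n = len(labels)
        return {p: float(k) for p, k in zip(labels, range(-(n // 2), -(n // 2) + n))}


def _curves_for_sex(
    cfg: SyntheticConfig, table: MultiplierTable, sex: Sex, ages: list[int]
) -> dict[str, dict[int, float]]:
    """Noise-free height curves per percentile at the given ages (total
    months), maturity age included."""
    heights = cfg.resolved_mature_heights()[sex]
    maturity = table.maturity_age(sex)
    m = table.entries[sex]
    curves: dict[str, dict[int, float]] = {}
    if cfg.mode == "proportional":
        for label, lm in heights.items():
            curves[label] = {t: lm / m[t] for t in ages}
            curves[label][maturity] = lm
    else:  # sd_offset
        base_lm = median(heights.values())
        offsets = cfg.offsets_for(list(heights))

        def spread(t: int) -> float:
            frac = t / maturity
            return cfg.spread_at_birth + (cfg.spread_at_maturity - cfg.spread_at_birth) * frac

        for label, k in offsets.items():
            curves[label] = {t: base_lm / m[t] + k * spread(t) for t in ages}
            curves[label][maturity] = base_lm + k * cfg.spread_at_maturity
    return curves


def _grid_months(cfg: SyntheticConfig, table: MultiplierTable, sex: Sex) -> list[int]:
    first, maturity = table.first_age(sex), table.maturity_age(sex)
    months = []
    for age in cfg.resolved_age_grid():
        t = age.total_months
        if not first <= t <= maturity:
            raise DomainError(
                f"grid age {age} outside the seed table domain for {sex.value} "
                f"({AgeYM.from_total_months(first)}..{AgeYM.from_total_months(maturity)})"
            )
        if t != maturity:  # maturity handled separately, noise-free
            months.append(t)
    return months


def generate_database(cfg: SyntheticConfig) -> GrowthDatabase:
    """Generate a synthetic growth database from a config.

    Identical configs (same ``rng_seed``) generate identical databases.
    Noise multiplies each non-maturity height by ``1 + eps`` with
    ``eps ~ Normal(0, noise_sd)``; maturity records are exact.
    """
    table = cfg.resolved_table()
    rng = np.random.default_rng(cfg.rng_seed)
    records: list[GrowthRecord] = []
    maturity_age = {}
    for sex in sorted(cfg.resolved_mature_heights(), key=lambda s: s.value):
        maturity = table.maturity_age(sex)
        maturity_age[sex] = maturity
        ages = _grid_months(cfg, table, sex)
        curves = _curves_for_sex(cfg, table, sex, ages)
        for label in sorted(curves):
            curve = curves[label]
            for t in ages:
                h = curve[t]
                if cfg.noise_sd > 0:
                    h *= 1.0 + rng.normal(0.0, cfg.noise_sd)
                if not h > 0:
                    raise DomainError(
                        f"generated non-positive height at ({sex.value}, {label}, "
                        f"{AgeYM.from_total_months(t)}); reduce offsets/spread/noise"
                    )
                records.append(GrowthRecord(sex, label, AgeYM.from_total_months(t), h))
            records.append(
                GrowthRecord(sex, label, AgeYM.from_total_months(maturity), curve[maturity])
            )
    return GrowthDatabase(
        records,
        maturity_age=maturity_age,
        provenance=f"synthetic ({cfg.mode}, seed {cfg.rng_seed})",
    )


def ground_truth(cfg: SyntheticConfig) -> MultiplierSet:
    """The exact multiplier set implied by the config, before noise.

    Proportional mode replicates the seed table for every percentile;
    sd_offset truth is computed analytically from the constructed curves:
    ``M_p(age) = L_p(maturity) / L_p(age)``.
    """
    table = cfg.resolved_table()
    rows = []
    for sex in sorted(cfg.resolved_mature_heights(), key=lambda s: s.value):
        maturity = table.maturity_age(sex)
        ages = _grid_months(cfg, table, sex)
        curves = _curves_for_sex(cfg, table, sex, ages)
        for label in sorted(curves):
            curve = curves[label]
            lm = curve[maturity]
            for t in [*ages, maturity]:
                rows.append((sex.value, label, t, lm / curve[t]))
    frame = pd.DataFrame(rows, columns=["sex", "percentile", "total_months", "multiplier"])
    return MultiplierSet(frame=frame, provenance=f"ground truth ({cfg.mode})")
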