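"""Clinical prediction formulas built on a multiplier table.

All operations share one pattern: look up the age- and sex-specific
multiplier M and apply simple arithmetic to a single current measurement.

* mature sitting height:        ``Lm = S * M``
* single-vertebra mature height: ``Lv = L_segment * M / n_vertebrae``
  (5 lumbar, 12 thoracic vertebrae; equal per-vertebra contribution)
* growth remaining:             ``G = L * (M - 1)``
* arthrodesis growth loss:      ``Ge = L_segment * (M - 1) / n_vertebrae * Vf``
  where Vf is the number of vertebrae fused
* limb-lengthening target (achondroplasia planning): ``47/53`` of the
  predicted mature sitting height, restoring the adult ("Vitruvian")
  proportion of 53% sitting height to 47% lower extremity
* mature standing height:        ``sitting / 0.53``

Thoracic and lumbar predictions use the sitting-height table: segment
multipliers are nearly identical to the sitting-height multiplier. The
cervical spine does NOT share that multiplier (its multipliers are
substantially higher); cervical predictions require a user-supplied
cervical table passed via ``table=``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Mapping

from .errors import DomainError
from .reference_tables import (
    AgeYM,
    MultiplierTable,
    Sex,
    load_packaged_table,
    lookup_multiplier,
)

__all__ = [
    "SpineSegment",
    "ArthrodesisPlan",
    "PredictionResult",
    "LOWER_EXTREMITY_FRACTION",
    "SITTING_HEIGHT_FRACTION",
    "predict_mature_sitting_height",
    "predict_single_vertebra_height",
    "growth_remaining",
    "arthrodesis_growth_loss",
    "limb_lengthening_target",
    "estimate_mature_standing_height",
]

#: Adult lower extremity : sitting height proportion, kept as an exact
#: rational. Rounding to the familiar "88.6%" happens only at display.
LOWER_EXTREMITY_FRACTION = Fraction(47, 53)
#: Sitting height as a fraction of adult standing height (53%).
SITTING_HEIGHT_FRACTION = Fraction(53, 100)


class SpineSegment(Enum):
    """Spine segment with its (fixed) vertebra count."""

    LUMBAR = ("lumbar", 5)
    THORACIC = ("thoracic", 12)

    def __init__(self, label: str, vertebra_count: int):
        self.label = label
        self.vertebra_count = vertebra_count

    @classmethod
    def parse(cls, value: "SpineSegment | str") -> "SpineSegment":
        if isinstance(value, SpineSegment):
            return value
        for seg in cls:
            if seg.label == str(value).strip().lower():
                return seg
        raise DomainError(f"unrecognized spine segment {value!r}; expected 'lumbar' or 'thoracic'")


@dataclass(frozen=True)
class ArthrodesisPlan:
    """A planned spinal fusion: which segment, its current length, and how
    many of its vertebrae will be fused at the given age."""

    segment: SpineSegment
    current_segment_length: float  # cm
    n_fused: int
    sex: Sex
    age: AgeYM

    def __post_init__(self) -> None:
        object.__setattr__(self, "segment", SpineSegment.parse(self.segment))
        object.__setattr__(self, "sex", Sex.parse(self.sex))
        if self.current_segment_length <= 0:
            raise DomainError(
                f"segment length must be positive, got {self.current_segment_length}"
            )
        count = self.segment.vertebra_count
        if not 1 <= self.n_fused <= count:
            raise DomainError(
                f"n_fused must be in 1..{count} for the {self.segment.label} "
                f"segment, got {self.n_fused}"
            )


@dataclass(frozen=True)
class PredictionResult:
    """Outcome of one clinical formula.

    ``predicted_value`` is in cm; ``multiplier_used`` is the dimensionless M
    that entered the arithmetic; ``inputs`` echoes the measurements so a
    rendered record is self-contained; ``post_maturity`` is raised when the
    age was clamped to maturity (M forced to 1)."""

    formula: str
    predicted_value: float
    multiplier_used: float
    inputs: Mapping[str, object] = field(default_factory=dict)
    post_maturity: bool = False

    def __post_init__(self) -> None:
        if self.predicted_value < 0:
            raise DomainError(f"predicted value must be non-negative, got {self.predicted_value}")
        if self.multiplier_used < 1:
            raise DomainError(f"multiplier must be >= 1, got {self.multiplier_used}")
        object.__setattr__(self, "inputs", dict(self.inputs))


def _resolve_multiplier(
    table: MultiplierTable | None,
    sex: Sex | str,
    age: AgeYM,
    clamp_post_maturity: bool,
):
    if table is None:
        table = load_packaged_table()
    return lookup_multiplier(table, sex, age, clamp_post_maturity=clamp_post_maturity)


def _require_positive(value: float, name: str) -> float:
    if not value > 0:
        raise DomainError(f"{name} must be positive, got {value}")
    return float(value)


def predict_mature_sitting_height(
    sitting_height: float,
    sex: Sex | str,
    age: AgeYM,
    *,
    table: MultiplierTable | None = None,
    clamp_post_maturity: bool = False,
) -> PredictionResult:
    """Predict sitting height at skeletal maturity: ``Lm = S * M``."""
    s = _require_positive(sitting_height, "sitting height")
    m, post = _resolve_multiplier(table, sex, age, clamp_post_maturity)
    return PredictionResult(
        formula="mature_sitting_height",
        predicted_value=s * m,
        multiplier_used=m,
        inputs={"sitting_height_cm": s, "sex": Sex.parse(sex).value, "age": str(age)},
        post_maturity=post,
    )


def predict_single_vertebra_height(
    segment_length: float,
    segment: SpineSegment | str,
    sex: Sex | str,
    age: AgeYM,
    *,
    table: MultiplierTable | None = None,
    clamp_post_maturity: bool = False,
) -> PredictionResult:
    """Predict the mature height of a single vertebra in a segment.

    The whole-segment mature length ``L_segment * M`` is split equally over
    the segment's vertebrae: divided by 5 for the lumbar spine, by 12 for
    the thoracic spine.
    """
    segment = SpineSegment.parse(segment)
    length = _require_positive(segment_length, "segment length")
    m, post = _resolve_multiplier(table, sex, age, clamp_post_maturity)
    return PredictionResult(
        formula=f"single_{segment.label}_vertebra_height",
        predicted_value=length * m / segment.vertebra_count,
        multiplier_used=m,
        inputs={
            "segment": segment.label,
            "segment_length_cm": length,
            "sex": Sex.parse(sex).value,
            "age": str(age),
        },
        post_maturity=post,
    )


def growth_remaining(
    length: float,
    sex: Sex | str,
    age: AgeYM,
    *,
    table: MultiplierTable | None = None,
    clamp_post_maturity: bool = False,
) -> PredictionResult:
    """Growth remaining in a spine section: mature length minus current
    length, ``G = L * M - L = L * (M - 1)``."""
    length = _require_positive(length, "length")
    m, post = _resolve_multiplier(table, sex, age, clamp_post_maturity)
    return PredictionResult(
        formula="growth_remaining",
        predicted_value=length * m - length,
        multiplier_used=m,
        inputs={"length_cm": length, "sex": Sex.parse(sex).value, "age": str(age)},
        post_maturity=post,
    )


def arthrodesis_growth_loss(
    plan: ArthrodesisPlan,
    *,
    table: MultiplierTable | None = None,
    clamp_post_maturity: bool = False,
) -> PredictionResult:
    """Height lost to a spinal fusion: the growth remaining of one vertebra
    in the segment, times the number of vertebrae fused (Vf).

    ``Ge = L_segment * (M - 1) / n_vertebrae * Vf``
    """
    count = plan.segment.vertebra_count
    m, post = _resolve_multiplier(table, plan.sex, plan.age, clamp_post_maturity)
    length = plan.current_segment_length
    per_vertebra = (length * m - length) / count
    return PredictionResult(
        formula="arthrodesis_growth_loss",
        predicted_value=per_vertebra * plan.n_fused,
        multiplier_used=m,
        inputs={
            "segment": plan.segment.label,
            "segment_length_cm": length,
            "n_fused": plan.n_fused,
            "sex": plan.sex.value,
            "age": str(plan.age),
        },
        post_maturity=post,
    )


def limb_lengthening_target(predicted_mature_sitting_height: float) -> float:
    """Lower-extremity length that restores adult Vitruvian proportions,
    given a predicted mature sitting height: 47/53 of it (~88.6%).

    Used when planning limb lengthening in achondroplasia, where the trunk
    is near-normal and the limbs are short.
    """
    h = _require_positive(predicted_mature_sitting_height, "predicted mature sitting height")
    return h * 47 / 53


def estimate_mature_standing_height(predicted_mature_sitting_height: float) -> float:
    """Mature standing height implied by a mature sitting height, using the
    adult proportion sitting height = 53% of standing height."""
    h = _require_positive(predicted_mature_sitting_height, "predicted mature sitting height")
    # h / 0.53 computed as h * 100 / 53 so that sitting + limb target
    # recompose to standing height as an exact rational identity
    return h * 100 / 53
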