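"""Typed data model for the exposure-assessment pipeline.

The pipeline consumes two tables — laboratory concentration measurements
(mg contaminant per kg food, possibly left-censored at the method's limit
of detection) and per-person daily consumption amounts (g/day per food
category) — plus an assessment configuration carrying the regulatory
residue limit, the provisional tolerable weekly intake (PTWI), the
age-group definitions with their standard body weights, and the mapping
between concentration-table food types and consumption-table categories.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "ConcentrationRecord",
    "ConsumptionRecord",
    "AgeGroupSpec",
    "AssessmentConfig",
    "MIN_AGE_YEARS",
    "default_age_groups",
    "default_food_map",
    "default_config",
    "FOOD_CATEGORIES",
]

#: Youngest age (years) admitted to the assessment; infants are excluded.
MIN_AGE_YEARS = 2.0

#: Consumption-survey food categories used in the exposure computation.
FOOD_CATEGORIES = (
    "instant_noodles",
    "jellyfish",
    "flour_products",
    "puffed_food",
    "deep_fried_dough_sticks",
    "other_fried_foods",
    "vegetables",
    "aquatic_products",
    "corn_flour",
    "algae_products",
)


class ConcentrationRecord(BaseModel):
    """One laboratory measurement of one food sample.

    ``detected=False`` marks a nondetect: the analyte was below the limit
    of detection (LOD). Before imputation a nondetect carries no value;
    after LOD/2 substitution the value is filled in while ``detected``
    stays False, so the censoring status is never lost.
    """

    sample_id: str
    year: int
    food_type: str
    value_mg_per_kg: Optional[float] = Field(default=None, ge=0.0)
    lod_mg_per_kg: float = Field(gt=0.0)
    detected: bool

    @model_validator(mode="after")
    def _detected_has_value(self) -> "ConcentrationRecord":
        if self.detected and self.value_mg_per_kg is None:
            raise ValueError("detected record must carry a value")
        return self


class ConsumptionRecord(BaseModel):
    """One surveyed person's daily intake of one food category."""

    person_id: str
    age_years: float = Field(ge=MIN_AGE_YEARS)
    food_type: str
    amount_g_per_day: float = Field(ge=0.0)


class AgeGroupSpec(BaseModel):
    """Half-open age interval [age_min, age_max) with its standard body weight.

    ``age_max_years=None`` leaves the interval open above (the oldest group).
    """

    label: str
    age_min_years: float
    age_max_years: Optional[float] = None
    standard_bw_kg: float = Field(gt=0.0)

    def contains(self, age_years: float) -> bool:
        if age_years < self.age_min_years:
            return False
        return self.age_max_years is None or age_years < self.age_max_years


class AssessmentConfig(BaseModel):
    """Assessment parameters: limits, age groups, and the food-category map.

    ``food_map`` translates concentration-table food types into the
    consumption-table categories the exposure computation is keyed on; it
    must cover every category used. ``nondetect_policy`` is the GEMS/Food
    LOD/2 substitution, valid while the nondetect rate stays below
    ``censoring_rate_threshold``. ``rounding_dp`` applies at the report
    boundary only — internal arithmetic is full precision.
    """

    residue_limit_mg_per_kg: float = Field(default=100.0, gt=0.0)
    ptwi_mg_per_kg_bw_week: float = Field(default=2.0, gt=0.0)
    age_groups: list[AgeGroupSpec]
    food_map: dict[str, str]
    nondetect_policy: Literal["half_lod"] = "half_lod"
    censoring_rate_threshold: float = Field(default=0.6, gt=0.0, le=1.0)
    rounding_dp: int = Field(default=2, ge=0)

    @field_validator("age_groups")
    @classmethod
    def _groups_ordered_disjoint_covering(
        cls, groups: list[AgeGroupSpec]
    ) -> list[AgeGroupSpec]:
        if not groups:
            raise ValueError("at least one age group is required")
        if groups[0].age_min_years != MIN_AGE_YEARS:
            raise ValueError(f"first age group must start at {MIN_AGE_YEARS}")
        for lo, hi in zip(groups, groups[1:]):
            if lo.age_max_years is None:
                raise ValueError("only the last age group may be open above")
            if lo.age_max_years != hi.age_min_years:
                raise ValueError(
                    f"age groups must tile [2, inf): gap or overlap between "
                    f"{lo.label!r} and {hi.label!r}"
                )
        if groups[-1].age_max_years is not None:
            raise ValueError("last age group must be open above (cover [2, inf))")
        return groups

    @model_validator(mode="after")
    def _food_map_covers_categories(self) -> "AssessmentConfig":
        missing = set(self.food_map.values()) - set(self.food_map)
        # values that are themselves unmapped keys are fine; nothing to check
        # beyond non-emptiness here — totality over the categories actually
        # used is enforced where the map is applied.
        del missing
        if not self.food_map:
            raise ValueError("food_map must not be empty")
        return self

    @property
    def food_categories(self) -> list[str]:
        """Distinct consumption categories, in first-appearance order."""
        seen: dict[str, None] = {}
        for cat in self.food_map.values():
            seen.setdefault(cat)
        return list(seen)

    def assign_age_group(self, age_years: float) -> AgeGroupSpec:
        for group in self.age_groups:
            if group.contains(age_years):
                return group
        raise ValueError(f"age {age_years} not covered by any age group")

    def map_food(self, food_type: str) -> str:
        try:
            return self.food_map[food_type]
        except KeyError:
            allowed = ", ".join(sorted(self.food_map))
            raise ValueError(
                f"unknown food_type {food_type!r}; allowed: {allowed}"
            ) from None

    def config_hash(self) -> str:
        """Stable content hash, embedded in run manifests."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_age_groups() -> list[AgeGroupSpec]:
    """Six age groups with standard body weights 20/40/50/60/60/60 kg."""
    bounds = [(2, 8, 20), (8, 13, 40), (13, 20, 50), (20, 50, 60), (50, 66, 60)]
    groups = [
        AgeGroupSpec(
            label=f"{lo} <= age < {hi}",
            age_min_years=float(lo),
            age_max_years=float(hi),
            standard_bw_kg=float(bw),
        )
        for lo, hi, bw in bounds
    ]
    groups.append(
        AgeGroupSpec(
            label="66 <= age",
            age_min_years=66.0,
            age_max_years=None,
            standard_bw_kg=60.0,
        )
    )
    return groups


def default_food_map() -> dict[str, str]:
    """Identity map over the survey categories plus known aliases.

    Concentration tables sometimes label the fried-dough category
    "deep-fried twisted cruller" where consumption surveys say
    "deep-fried dough sticks"; the alias reconciles them.
    """
    mapping = {cat: cat for cat in FOOD_CATEGORIES}
    mapping["deep_fried_twisted_cruller"] = "deep_fried_dough_sticks"
    return mapping


def default_config() -> AssessmentConfig:
    return AssessmentConfig(
        age_groups=default_age_groups(),
        food_map=default_food_map(),
    )
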