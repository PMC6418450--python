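"""End-to-end orchestration: raw tables -> imputation -> summaries -> exposure."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .censoring import CensoringSummary, impute_nondetects
from .exposure import ExposureResult, assess_groups
from .records import AssessmentConfig, ConcentrationRecord, ConsumptionRecord
from .summaries import (
    ConcentrationSummary,
    ConsumptionSummary,
    summarize_concentration,
    summarize_consumption,
)

__all__ = ["AssessmentRun", "concentration_means", "consumption_by_group", "run_assessment"]


@dataclass(frozen=True)
class AssessmentRun:
    """Everything one pipeline run produces."""

    censoring: list[CensoringSummary]
    yearly_summaries: list[ConcentrationSummary]
    food_summaries: list[ConcentrationSummary]
    results: list[ExposureResult]


def concentration_means(
    records: Sequence[ConcentrationRecord], config: AssessmentConfig
) -> dict[str, float]:
    """Mean concentration (mg/kg) per consumption category, post-imputation.

    Food types are translated through the config's food map; samples from
    types mapping to the same category pool into one mean.
    """
    imputed, _ = impute_nondetects(records, config)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for r in imputed:
        cat = config.map_food(r.food_type)
        sums[cat] = sums.get(cat, 0.0) + r.value_mg_per_kg
        counts[cat] = counts.get(cat, 0) + 1
    return {cat: sums[cat] / counts[cat] for cat in sums}


def consumption_by_group(
    records: Sequence[ConsumptionRecord], config: AssessmentConfig
) -> dict[str, dict[str, ConsumptionSummary]]:
    """Per-age-group, per-category consumption summaries (zeros included)."""
    grouped: dict[str, dict[str, list[ConsumptionRecord]]] = {}
    for r in records:
        group = config.assign_age_group(r.age_years)
        grouped.setdefault(group.label, {}).setdefault(r.food_type, []).append(r)
    return {
        label: {
            food: summarize_consumption(rs, stratum=f"{label}/{food}")
            for food, rs in foods.items()
        }
        for label, foods in grouped.items()
    }


def run_assessment(
    conc_records: Sequence[ConcentrationRecord],
    cons_records: Sequence[ConsumptionRecord],
    config: AssessmentConfig,
) -> AssessmentRun:
    """Full deterministic assessment from raw records.

    Imputes nondetects (failing if any stratum breaches the censoring
    threshold), builds yearly and per-food concentration summaries,
    per-group consumption summaries, and the per-group exposure results.
    """
    imputed, censoring = impute_nondetects(conc_records, config)

    by_year: dict[int, list[ConcentrationRecord]] = {}
    by_food: dict[str, list[ConcentrationRecord]] = {}
    for r in imputed:
        by_year.setdefault(r.year, []).append(r)
        by_food.setdefault(r.food_type, []).append(r)
    limit = config.residue_limit_mg_per_kg
    yearly = [
        summarize_concentration(by_year[y], limit, stratum=str(y))
        for y in sorted(by_year)
    ]
    foods = [
        summarize_concentration(by_food[f], limit, stratum=f)
        for f in sorted(by_food)
    ]

    conc_means = concentration_means(conc_records, config)
    cons = consumption_by_group(cons_records, config)
    results = assess_groups(conc_means, cons, config)
    return AssessmentRun(
        censoring=censoring,
        yearly_summaries=yearly,
        food_summaries=foods,
        results=results,
    )
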