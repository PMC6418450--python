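"""Deterministic point-estimate exposure assessment.

Per age group, daily dietary exposure to the contaminant is the sum over
food categories of mean concentration (mg/kg) times consumed amount
(g/day) divided by 1,000:

    E_mean  = sum_f  C_f * Q_f   / 1000      (mg/day)
    E_p95   = sum_f  C_f * Q95_f / 1000      (mg/day)

where C_f is the mean concentration in food f, Q_f the group's mean
consumption, and Q95_f its 95th-percentile consumption. Note E_p95
combines mean concentration with P95 consumption food-by-food and then
sums; it is a conservative high-consumer screen, not a true 95th
percentile of the exposure distribution.

Weekly intake normalizes by the group's standard body weight:

    W = E * 7 / bw               (mg/kg bw/week)

and the margin of safety is W divided by the provisional tolerable
weekly intake (PTWI); MOS >= 1 flags unacceptable risk. All arithmetic
is full precision; rounding is a report-boundary concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .records import AgeGroupSpec, AssessmentConfig
from .summaries import ConsumptionSummary

__all__ = [
    "FoodExposure",
    "ExposureResult",
    "mean_daily_exposure",
    "p95_daily_exposure",
    "weekly_intake",
    "margin_of_safety",
    "contribution_percentages",
    "assess_groups",
]


@dataclass(frozen=True)
class FoodExposure:
    """Per-food exposure terms for one age group (mg/day) and share of total."""

    food_type: str
    mean_daily_mg: float
    p95_daily_mg: float
    contribution_pct: float


@dataclass(frozen=True)
class ExposureResult:
    """Full exposure assessment for one age group."""

    group: AgeGroupSpec
    per_food: tuple[FoodExposure, ...]
    total_mean_daily_mg: float
    total_p95_daily_mg: float
    weekly_mean_mg_per_kg: float
    weekly_p95_mg_per_kg: float
    mos_mean: float
    mos_p95: float
    risk_flag: bool


def _daily_terms(
    conc_by_food: Mapping[str, float], cons_by_food: Mapping[str, float]
) -> tuple[float, dict[str, float]]:
    orphans = sorted(set(cons_by_food) - set(conc_by_food))
    if orphans:
        raise ValueError(
            "consumption categories without concentration data: "
            + ", ".join(orphans)
        )
    terms = {
        food: conc_by_food[food] * amount / 1000.0
        for food, amount in cons_by_food.items()
    }
    return sum(terms.values()), terms


def mean_daily_exposure(
    conc_mean_by_food: Mapping[str, float],
    cons_mean_by_food: Mapping[str, float],
) -> tuple[float, dict[str, float]]:
    """Total and per-food mean daily exposure (mg/day).

    ``conc_mean_by_food`` in mg/kg, ``cons_mean_by_food`` in g/day; both
    keyed by consumption category (apply the config's food map upstream).
    """
    return _daily_terms(conc_mean_by_food, cons_mean_by_food)


def p95_daily_exposure(
    conc_mean_by_food: Mapping[str, float],
    cons_p95_by_food: Mapping[str, float],
) -> tuple[float, dict[str, float]]:
    """Total and per-food high-consumer daily exposure (mean conc × P95 cons)."""
    return _daily_terms(conc_mean_by_food, cons_p95_by_food)


def weekly_intake(daily_mg: float, bw_kg: float) -> float:
    """Daily exposure (mg/day) to weekly intake per kg body weight."""
    if bw_kg <= 0:
        raise ValueError(f"body weight must be positive, got {bw_kg}")
    return daily_mg * 7.0 / bw_kg


def margin_of_safety(
    weekly_mg_per_kg: float, ptwi_mg_per_kg_week: float
) -> tuple[float, bool]:
    """Ratio of weekly intake to the PTWI; ratio >= 1 flags unacceptable risk."""
    if ptwi_mg_per_kg_week <= 0:
        raise ValueError(f"PTWI must be positive, got {ptwi_mg_per_kg_week}")
    ratio = weekly_mg_per_kg / ptwi_mg_per_kg_week
    return ratio, ratio >= 1.0


def contribution_percentages(
    per_food_mg: Mapping[str, float], total_mg: float
) -> dict[str, float]:
    """Each food's percentage share of the total exposure (sums to 100)."""
    if total_mg <= 0:
        raise ValueError("total exposure must be positive for contributions")
    return {food: 100.0 * term / total_mg for food, term in per_food_mg.items()}


def assess_groups(
    conc_mean_by_food: Mapping[str, float],
    cons_summaries: Mapping[str, Mapping[str, ConsumptionSummary]],
    config: AssessmentConfig,
) -> list[ExposureResult]:
    """One ExposureResult per configured age group.

    ``conc_mean_by_food`` maps concentration-table food types (translated
    through ``config.food_map``) to mean mg/kg. ``cons_summaries`` maps
    age-group label -> consumption category -> ConsumptionSummary.
    Results follow ``config.age_groups`` order.
    """
    conc = {}
    for food_type, mean in conc_mean_by_food.items():
        category = config.map_food(food_type)
        if category in conc and conc[category] != mean:
            raise ValueError(
                f"conflicting concentration means for category {category!r}"
            )
        conc[category] = mean

    results: list[ExposureResult] = []
    for group in config.age_groups:
        try:
            by_food = cons_summaries[group.label]
        except KeyError:
            raise ValueError(
                f"no consumption summaries for age group {group.label!r}"
            ) from None
        cons_mean = {f: s.mean for f, s in by_food.items()}
        cons_p95 = {f: s.p95 for f, s in by_food.items()}
        try:
            total_mean, terms_mean = mean_daily_exposure(conc, cons_mean)
            total_p95, terms_p95 = p95_daily_exposure(conc, cons_p95)
            weekly_mean = weekly_intake(total_mean, group.standard_bw_kg)
            weekly_p95 = weekly_intake(total_p95, group.standard_bw_kg)
            mos_mean, flag = margin_of_safety(weekly_mean, config.ptwi_mg_per_kg_bw_week)
            mos_p95, _ = margin_of_safety(weekly_p95, config.ptwi_mg_per_kg_bw_week)
            if total_mean > 0:
                contrib = contribution_percentages(terms_mean, total_mean)
            else:
                contrib = {f: 0.0 for f in terms_mean}
        except ValueError as exc:
            raise ValueError(f"group {group.label!r}: {exc}") from exc
        per_food = tuple(
            FoodExposure(
                food_type=food,
                mean_daily_mg=terms_mean[food],
                p95_daily_mg=terms_p95[food],
                contribution_pct=contrib[food],
            )
            for food in cons_mean
        )
        results.append(
            ExposureResult(
                group=group,
                per_food=per_food,
                total_mean_daily_mg=total_mean,
                total_p95_daily_mg=total_p95,
                weekly_mean_mg_per_kg=weekly_mean,
                weekly_p95_mg_per_kg=weekly_p95,
                mos_mean=mos_mean,
                mos_p95=mos_p95,
                risk_flag=flag,
            )
        )
    return results
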