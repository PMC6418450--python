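"""Published surveillance aggregates used as reference inputs.

These are the printed summary tables of a six-year aluminum monitoring
program in Tianjin (2010–2015): yearly and per-food concentration
summaries (1,263 food samples), daily consumption summaries from a
1,814-person dietary survey, and the per-food exposure matrix by age
group. The pipeline's deterministic arithmetic (pooling, exceedance
aggregation, weekly intake, margin of safety) reproduces the program's
headline figures from these aggregates alone, which makes them useful
both as a worked example and as exact regression fixtures.

Only aggregates are published — no sample-level data — so the raw-data
path of the pipeline is exercised with the synthetic generator instead.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import AssessmentConfig, default_config
from .summaries import ConcentrationSummary, ConsumptionSummary

__all__ = ["ReferenceAggregates", "reference_aggregates"]

# year: (n, mean, sd, min, max, p25, p50, p75, p95, exceed_n)
_YEARLY = {
    2010: (90, 41.20, 45.01, 12.50, 221.00, 12.50, 12.50, 47.50, 139.00, 10),
    2011: (110, 44.91, 45.87, 12.50, 245.00, 12.50, 12.50, 64.00, 141.00, 14),
    2012: (200, 216.06, 368.11, 12.50, 2810.00, 12.50, 51.70, 294.50, 929.50, 77),
    2013: (282, 71.15, 158.56, 5.00, 1127.40, 5.00, 11.25, 32.00, 432.00, 44),
    2014: (112, 95.77, 190.64, 0.13, 855.00, 0.75, 1.19, 32.70, 530.00, 27),
    2015: (469, 125.31, 315.65, 0.35, 2240.00, 1.00, 5.80, 52.90, 757.00, 95),
}

# food type: (n, mean, sd, min, max, p25, p50, p75, p95, exceed_n)
_BY_FOOD = {
    "bakery_pastry": (48, 11.34, 23.79, 1.00, 103.00, 1.00, 1.00, 12.50, 78.30, 1),
    "fermented_pastry": (67, 97.05, 118.36, 1.00, 389.00, 1.00, 50.00, 165.00, 338.00, 22),
    "nonfermented_pastry": (33, 137.24, 189.54, 1.00, 674.00, 1.00, 1.00, 234.00, 530.00, 14),
    "dumpling_skin_wonton": (14, 79.39, 41.05, 12.50, 142.00, 50.00, 62.50, 115.00, 142.00, 5),
    "noodles": (60, 49.27, 112.82, 1.00, 531.00, 1.00, 2.85, 32.65, 317.50, 7),
    "wheat_flour": (69, 370.91, 370.22, 2.80, 1780.00, 13.00, 311.00, 651.00, 944.00, 43),
    "vermicelli": (89, 51.71, 82.27, 1.00, 365.00, 12.50, 12.50, 53.40, 275.00, 14),
    "vegetables": (40, 58.88, 181.31, 0.35, 1160.00, 0.84, 21.50, 63.50, 83.55, 1),
    "puffed_food": (219, 19.91, 31.81, 1.00, 220.80, 5.00, 12.50, 12.50, 79.00, 8),
    "aquatic_animal_products": (70, 2.26, 5.58, 0.13, 36.60, 0.51, 0.92, 1.66, 3.65, 0),
    "algae_products": (115, 269.82, 545.00, 1.00, 2810.00, 1.00, 15.00, 360.00, 1780.00, 36),
    "honey": (10, 5.69, 8.03, 1.00, 22.30, 1.00, 1.00, 10.70, 22.30, 0),
    "jellyfish": (30, 433.28, 402.11, 1.00, 1390.00, 8.00, 421.00, 613.00, 1340.00, 20),
    "steamed_cold_noodles": (83, 207.62, 242.91, 5.00, 1127.40, 5.00, 122.60, 354.40, 665.10, 44),
    "gluten": (11, 65.64, 56.64, 12.50, 193.00, 12.50, 58.00, 93.00, 193.00, 2),
    "other_fried_foods": (20, 43.78, 38.26, 1.00, 139.00, 12.50, 43.50, 68.00, 122.00, 2),
    "infant_supplementary_food": (93, 15.76, 13.84, 5.00, 59.80, 5.00, 9.33, 21.80, 47.00, 0),
    "infant_formula_food": (65, 10.10, 9.40, 1.03, 52.90, 5.00, 5.55, 13.00, 24.00, 0),
    "fried_cake_twisted_cruller": (77, 137.23, 252.44, 1.00, 1360.00, 12.50, 39.00, 122.00, 735.00, 23),
    "corn_flour": (50, 262.10, 403.84, 2.90, 2000.00, 11.00, 89.25, 322.00, 949.00, 25),
}

# category: (n_persons, mean, sd, min, max, p25, p50, p75, p95) in g/day
_CONSUMPTION = {
    "instant_noodles": (1812, 13.84, 32.22, 0.00, 600.00, 0.00, 3.33, 15.00, 51.43),
    "jellyfish": (1209, 1.55, 7.44, 0.00, 200.00, 0.00, 0.00, 1.10, 6.67),
    "flour_products": (1813, 127.89, 145.95, 0.00, 1200.00, 35.00, 85.71, 150.00, 480.00),
    "puffed_food": (1811, 9.76, 38.99, 0.00, 600.00, 0.00, 0.00, 3.33, 50.00),
    "other_fried_foods": (1813, 2.96, 14.88, 0.00, 400.00, 0.00, 0.00, 0.55, 14.29),
    "vegetables": (1811, 212.33, 147.93, 0.00, 1274.29, 110.94, 171.43, 271.26, 495.71),
    "aquatic_products": (1811, 33.95, 56.59, 0.00, 1658.10, 11.10, 21.50, 37.76, 106.07),
    "deep_fried_dough_sticks": (1813, 19.10, 33.66, 0.00, 400.00, 0.00, 7.14, 22.86, 72.86),
    "corn_flour": (1812, 14.04, 28.49, 0.00, 428.57, 0.82, 6.00, 14.29, 57.14),
    "algae_products": (1812, 1.01, 5.73, 0.00, 200.00, 0.00, 0.07, 0.57, 3.33),
}

# food category: six (mean, p95) mg/day pairs, ordered by age group
_EXPOSURE_MATRIX = {
    "instant_noodles": [(0.90, 2.53), (0.89, 2.11), (1.70, 5.91), (0.40, 1.69), (0.17, 0.99), (0.16, 1.13)],
    "jellyfish": [(0.32, 1.86), (1.20, 4.33), (1.06, 4.33), (0.64, 3.09), (0.37, 1.44), (0.08, 0.58)],
    "flour_products": [(35.18, 111.27), (30.75, 74.18), (36.97, 111.27), (50.91, 200.29), (63.71, 222.55), (57.08, 200.29)],
    "puffed_food": [(0.21, 0.68), (0.45, 1.99), (0.50, 1.99), (0.03, 0.14), (0.00, 0.00), (0.00, 0.00)],
    "deep_fried_dough_sticks": [(2.13, 9.61), (2.86, 9.61), (4.49, 19.21), (2.26, 9.41), (1.95, 8.23), (1.43, 5.88)],
    "other_fried_foods": [(0.23, 0.63), (0.10, 0.50), (0.37, 2.19), (0.07, 0.41), (0.04, 0.23), (0.02, 0.15)],
    "vegetables": [(9.12, 25.23), (11.01, 29.05), (16.28, 41.22), (12.99, 28.09), (11.90, 25.21), (10.51, 22.15)],
    "aquatic_products": [(0.06, 0.24), (0.07, 0.21), (0.11, 0.33), (0.07, 0.22), (0.08, 0.22), (0.05, 0.17)],
    "corn_flour": [(3.67, 12.17), (1.97, 7.49), (2.31, 7.86), (4.39, 14.98), (5.26, 14.98), (4.84, 11.23)],
    "algae_products": [(0.15, 0.63), (0.25, 0.58), (0.63, 2.31), (0.27, 1.16), (0.13, 0.63), (0.10, 0.39)],
}

# Printed per-group totals (the tables' "Sum" row), mg/day
_PRINTED_TOTALS_MEAN = [51.97, 49.54, 64.41, 72.04, 83.61, 74.28]
_PRINTED_TOTALS_P95 = [164.85, 130.04, 196.64, 259.49, 274.47, 241.96]

# Printed weekly intake (mg/kg bw/week) and margin of safety, per group
_PRINTED_WEEKLY_MEAN = [18.19, 8.67, 9.02, 8.40, 9.75, 8.67]
_PRINTED_MOS_MEAN = [9.09, 4.33, 4.51, 4.20, 4.88, 4.33]
_PRINTED_WEEKLY_P95 = [57.70, 22.76, 27.53, 30.27, 32.02, 28.23]
_PRINTED_MOS_P95 = [28.85, 11.38, 13.76, 15.14, 16.01, 14.11]


def _conc_summary(stratum: str, row: tuple) -> ConcentrationSummary:
    n, mean, sd, mn, mx, p25, p50, p75, p95, exceed_n = row
    return ConcentrationSummary(
        stratum=stratum, n=n, mean=mean, sd=sd, min=mn, max=mx,
        p25=p25, p50=p50, p75=p75, p95=p95,
        exceed_n=exceed_n, exceed_pct=100.0 * exceed_n / n,
    )


@dataclass(frozen=True)
class ReferenceAggregates:
    """Printed aggregates of the reference surveillance program.

    ``exposure_mean`` / ``exposure_p95`` map age-group label -> food
    category -> mg/day; ``printed_total_*`` carry the tables' own "Sum"
    row, and ``printed_weekly_*`` / ``printed_mos_*`` the published
    weekly-intake and margin-of-safety figures (all 2 dp as printed).
    """

    yearly_concentration: list[ConcentrationSummary]
    by_food_concentration: list[ConcentrationSummary]
    consumption: list[ConsumptionSummary]
    exposure_mean: dict[str, dict[str, float]]
    exposure_p95: dict[str, dict[str, float]]
    printed_total_mean: dict[str, float]
    printed_total_p95: dict[str, float]
    printed_weekly_mean: dict[str, float]
    printed_weekly_p95: dict[str, float]
    printed_mos_mean: dict[str, float]
    printed_mos_p95: dict[str, float]
    config: AssessmentConfig

    @property
    def total_samples(self) -> int:
        return sum(s.n for s in self.yearly_concentration)


def reference_aggregates() -> ReferenceAggregates:
    """The published aggregates as typed summary objects plus the config."""
    config = default_config()
    labels = [g.label for g in config.age_groups]
    exposure_mean = {
        lab: {food: pairs[i][0] for food, pairs in _EXPOSURE_MATRIX.items()}
        for i, lab in enumerate(labels)
    }
    exposure_p95 = {
        lab: {food: pairs[i][1] for food, pairs in _EXPOSURE_MATRIX.items()}
        for i, lab in enumerate(labels)
    }
    return ReferenceAggregates(
        yearly_concentration=[
            _conc_summary(str(year), row) for year, row in _YEARLY.items()
        ],
        by_food_concentration=[
            _conc_summary(food, row) for food, row in _BY_FOOD.items()
        ],
        consumption=[
            ConsumptionSummary(
                stratum=cat, n_persons=row[0], mean=row[1], sd=row[2],
                min=row[3], max=row[4], p25=row[5], p50=row[6],
                p75=row[7], p95=row[8],
            )
            for cat, row in _CONSUMPTION.items()
        ],
        exposure_mean=exposure_mean,
        exposure_p95=exposure_p95,
        printed_total_mean=dict(zip(labels, _PRINTED_TOTALS_MEAN)),
        printed_total_p95=dict(zip(labels, _PRINTED_TOTALS_P95)),
        printed_weekly_mean=dict(zip(labels, _PRINTED_WEEKLY_MEAN)),
        printed_weekly_p95=dict(zip(labels, _PRINTED_WEEKLY_P95)),
        printed_mos_mean=dict(zip(labels, _PRINTED_MOS_MEAN)),
        printed_mos_p95=dict(zip(labels, _PRINTED_MOS_P95)),
        config=config,
    )
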