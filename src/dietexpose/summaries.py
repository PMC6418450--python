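"""Descriptive statistics and residue-limit exceedance per stratum.

Produces the surveillance-table shape: n, mean (SD), range, quartiles,
P95, and the count/percentage of samples above the regulatory residue
limit, for concentration strata (by year or food type) and consumption
strata (by food category, optionally per age group). Pooling across
strata uses sample-size weights for means and plain sums for exceedance
counts, so pooled figures equal the statistics of the concatenated data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import ConcentrationRecord, ConsumptionRecord

__all__ = [
    "ConcentrationSummary",
    "ConsumptionSummary",
    "quantile",
    "summarize_concentration",
    "summarize_consumption",
    "pooled_mean",
    "pooled_exceedance",
]


@dataclass(frozen=True)
class ConcentrationSummary:
    stratum: str
    n: int
    mean: float
    sd: float
    min: float
    max: float
    p25: float
    p50: float
    p75: float
    p95: float
    exceed_n: int
    exceed_pct: float

    def __post_init__(self):
        if not (self.min <= self.p25 <= self.p50 <= self.p75 <= self.p95 <= self.max):
            raise ValueError(f"quantiles out of order in stratum {self.stratum!r}")
        if not 0 <= self.exceed_n <= self.n:
            raise ValueError("exceed_n outside [0, n]")


@dataclass(frozen=True)
class ConsumptionSummary:
    stratum: str
    n_persons: int
    mean: float
    sd: float
    min: float
    max: float
    p25: float
    p50: float
    p75: float
    p95: float

    def __post_init__(self):
        if not (self.min <= self.p25 <= self.p50 <= self.p75 <= self.p95 <= self.max):
            raise ValueError(f"quantiles out of order in stratum {self.stratum!r}")


def quantile(values: Sequence[float], p: float) -> float:
    """Order statistic by linear interpolation at positions (k-1)/(n-1).

    The convention of the mainstream numeric stacks; single-element and
    constant inputs return that value for every p.
    """
    if len(values) == 0:
        raise ValueError("quantile of empty input")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    return float(np.quantile(np.asarray(values, dtype=float), p, method="linear"))


def _sd(values: np.ndarray) -> float:
    # n-1 denominator; a single observation has undefined spread -> 0 by convention
    return float(values.std(ddof=1)) if values.size > 1 else 0.0


def summarize_concentration(
    records: Sequence[ConcentrationRecord],
    limit_mg_per_kg: float,
    stratum: str = "all",
) -> ConcentrationSummary:
    """Summary statistics and exceedance for an imputed concentration stratum.

    Requires every record to carry a value (run imputation first).
    Exceedance counts values strictly above the residue limit.
    """
    if not records:
        raise ValueError(f"no samples in stratum {stratum!r}")
    missing = [r.sample_id for r in records if r.value_mg_per_kg is None]
    if missing:
        raise ValueError(
            f"stratum {stratum!r}: {len(missing)} record(s) without value "
            "(impute nondetects first)"
        )
    values = np.array([r.value_mg_per_kg for r in records], dtype=float)
    exceed_n = int((values > limit_mg_per_kg).sum())
    return ConcentrationSummary(
        stratum=stratum,
        n=len(records),
        mean=float(values.mean()),
        sd=_sd(values),
        min=float(values.min()),
        max=float(values.max()),
        p25=quantile(values, 0.25),
        p50=quantile(values, 0.50),
        p75=quantile(values, 0.75),
        p95=quantile(values, 0.95),
        exceed_n=exceed_n,
        exceed_pct=100.0 * exceed_n / len(records),
    )


def summarize_consumption(
    records: Sequence[ConsumptionRecord], stratum: str = "all"
) -> ConsumptionSummary:
    """Per-person g/day statistics for one food category (zero intakes count)."""
    if not records:
        raise ValueError(f"no persons in stratum {stratum!r}")
    values = np.array([r.amount_g_per_day for r in records], dtype=float)
    return ConsumptionSummary(
        stratum=stratum,
        n_persons=len(records),
        mean=float(values.mean()),
        sd=_sd(values),
        min=float(values.min()),
        max=float(values.max()),
        p25=quantile(values, 0.25),
        p50=quantile(values, 0.50),
        p75=quantile(values, 0.75),
        p95=quantile(values, 0.95),
    )


def pooled_mean(summaries: Sequence[ConcentrationSummary]) -> float:
    """Sample-size-weighted mean across strata.

    Equals the mean of the concatenated samples when the summaries were
    computed from them (exact, full precision).
    """
    if not summaries:
        raise ValueError("no summaries to pool")
    total_n = sum(s.n for s in summaries)
    if total_n == 0:
        raise ValueError("pooled sample size is zero")
    return sum(s.n * s.mean for s in summaries) / total_n


def pooled_exceedance(summaries: Sequence[ConcentrationSummary]) -> tuple[int, float]:
    """Total exceedance count and percentage across strata."""
    if not summaries:
        raise ValueError("no summaries to pool")
    total_n = sum(s.n for s in summaries)
    count = sum(s.exceed_n for s in summaries)
    return count, 100.0 * count / total_n
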