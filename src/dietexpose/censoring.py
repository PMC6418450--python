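"""Left-censored (nondetect) concentration handling.

Measurements below the analytical limit of detection (LOD) carry no
value. Under the GEMS/Food convention, when fewer than 60% of a stratum's
samples are nondetects, each nondetect is substituted by half its own
LOD. A nondetect rate at or above the threshold is an error here — the
substitution rule is only defensible below it, and silently degrading
would bias the exposure estimates.

Strata are food_type × year by default, matching how the surveillance
summaries are built; LODs may differ between records (methods improve
across years) and substitution always uses the record's own LOD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import AssessmentConfig, ConcentrationRecord

__all__ = ["CensoringSummary", "CensoringRateError", "censoring_rate", "impute_nondetects"]


class CensoringRateError(ValueError):
    """Nondetect rate at or above the configured threshold for a stratum."""

    def __init__(self, stratum: str, rate: float, threshold: float):
        self.stratum = stratum
        self.rate = rate
        super().__init__(
            f"stratum {stratum!r}: nondetect rate {rate:.2%} >= "
            f"threshold {threshold:.0%}; LOD/2 substitution not applicable"
        )


@dataclass(frozen=True)
class CensoringSummary:
    """Nondetect bookkeeping for one stratum.

    ``substitution_value_mg_per_kg`` is LOD/2 when the stratum has a single
    LOD, NaN when LODs are mixed (each record then uses its own LOD/2).
    """

    stratum: str
    n_total: int
    n_nondetect: int
    rate: float
    substitution_value_mg_per_kg: float


def _summary(records: Sequence[ConcentrationRecord], stratum: str) -> CensoringSummary:
    n = len(records)
    n_nd = sum(1 for r in records if not r.detected)
    lods = {r.lod_mg_per_kg for r in records}
    sub = next(iter(lods)) / 2.0 if len(lods) == 1 else math.nan
    return CensoringSummary(
        stratum=stratum,
        n_total=n,
        n_nondetect=n_nd,
        rate=n_nd / n,
        substitution_value_mg_per_kg=sub,
    )


def censoring_rate(
    records: Sequence[ConcentrationRecord], stratum: str = "all"
) -> CensoringSummary:
    """Exact nondetect fraction of a (non-empty) record set."""
    if not records:
        raise ValueError(f"no samples in stratum {stratum!r}")
    return _summary(records, stratum)


def _stratum_key(record: ConcentrationRecord) -> str:
    return f"{record.food_type}/{record.year}"


def impute_nondetects(
    records: Sequence[ConcentrationRecord],
    config: AssessmentConfig,
    *,
    by_stratum: bool = True,
) -> tuple[list[ConcentrationRecord], list[CensoringSummary]]:
    """Substitute LOD/2 for every nondetect; detected records pass through.

    Returns the records in input order (all values present) and one
    censoring summary per stratum. Fails with :class:`CensoringRateError`
    if any stratum's nondetect rate reaches ``config.censoring_rate_threshold``.
    Idempotent: records whose value is already filled are unchanged.
    """
    if not records:
        raise ValueError("no samples in stratum 'all'")

    groups: dict[str, list[ConcentrationRecord]] = {}
    for r in records:
        key = _stratum_key(r) if by_stratum else "all"
        groups.setdefault(key, []).append(r)

    summaries = [_summary(g, key) for key, g in groups.items()]
    for s in summaries:
        if s.rate >= config.censoring_rate_threshold:
            raise CensoringRateError(s.stratum, s.rate, config.censoring_rate_threshold)

    out: list[ConcentrationRecord] = []
    for r in records:
        if r.value_mg_per_kg is None:
            out.append(r.model_copy(update={"value_mg_per_kg": r.lod_mg_per_kg / 2.0}))
        else:
            out.append(r)
    return out, summaries
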