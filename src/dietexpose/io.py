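"""Readers and writers: CSV tables, YAML config, and report documents.

Conventions: comma-separated UTF-8 CSV with a header row and "." decimal
separator. A nondetect concentration is encoded as an empty value field
with detected=0. Rounding (half-up, ``config.rounding_dp`` places) happens
only here, at the report boundary.
"""

from __future__ import annotations

import csv
import io as _io
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import IO, Iterable, Union

import yaml

from .records import (
    MIN_AGE_YEARS,
    AgeGroupSpec,
    AssessmentConfig,
    ConcentrationRecord,
    ConsumptionRecord,
)

__all__ = [
    "TableParseError",
    "read_concentration_table",
    "read_consumption_table",
    "write_concentration_table",
    "write_consumption_table",
    "load_config",
    "dump_config",
    "write_report",
    "round_half_up",
]

Source = Union[str, Path, IO[str]]

CONCENTRATION_COLUMNS = ["sample_id", "year", "food_type", "value", "lod", "detected"]
CONSUMPTION_COLUMNS = ["person_id", "age_years", "food_type", "amount_g_per_day"]


class TableParseError(ValueError):
    """Raised when one or more table rows fail to parse or validate.

    Collects every offending row (1-based data-row numbers) so that
    input row count always equals parsed + rejected.
    """

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"row {n}: {msg}" for n, msg in errors)
        super().__init__(f"{len(errors)} bad row(s): {lines}")


def round_half_up(x: float, dp: int) -> float:
    """Round half away from zero at ``dp`` decimals (report convention)."""
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _open_source(source: Source):
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline=""), True
    return source, False


def _check_header(reader: csv.DictReader, expected: list[str]) -> None:
    got = reader.fieldnames
    if got is None or list(got) != expected:
        raise TableParseError(
            [(0, f"expected header {','.join(expected)}, got {got}")]
        )


def read_concentration_table(
    source: Source, config: AssessmentConfig
) -> list[ConcentrationRecord]:
    """Parse a concentration CSV into validated records.

    Every row either parses or is rejected with its row number; food types
    are validated against the config's food map. Pre-imputation invariant
    is enforced: detected=0 rows must have an empty value and vice versa.
    """
    handle, owned = _open_source(source)
    records: list[ConcentrationRecord] = []
    errors: list[tuple[int, str]] = []
    try:
        reader = csv.DictReader(handle)
        _check_header(reader, CONCENTRATION_COLUMNS)
        for i, row in enumerate(reader, start=1):
            try:
                detected_raw = (row["detected"] or "").strip()
                if detected_raw not in {"0", "1"}:
                    raise ValueError(f"detected must be 0 or 1, got {detected_raw!r}")
                detected = detected_raw == "1"
                value_raw = (row["value"] or "").strip()
                if detected and value_raw == "":
                    raise ValueError("detected row with empty value")
                if not detected and value_raw != "":
                    raise ValueError("nondetect row must have empty value")
                food_type = row["food_type"].strip()
                if food_type not in config.food_map:
                    allowed = ", ".join(sorted(config.food_map))
                    raise ValueError(
                        f"unknown food_type {food_type!r}; allowed: {allowed}"
                    )
                records.append(
                    ConcentrationRecord(
                        sample_id=row["sample_id"],
                        year=int(row["year"]),
                        food_type=food_type,
                        value_mg_per_kg=float(value_raw) if detected else None,
                        lod_mg_per_kg=float(row["lod"]),
                        detected=detected,
                    )
                )
            except (ValueError, TypeError, KeyError) as exc:
                errors.append((i, str(exc)))
    finally:
        if owned:
            handle.close()
    if errors:
        raise TableParseError(errors)
    return records


def read_consumption_table(source: Source) -> list[ConsumptionRecord]:
    """Parse a consumption CSV; persons younger than 2 years are rejected."""
    handle, owned = _open_source(source)
    records: list[ConsumptionRecord] = []
    errors: list[tuple[int, str]] = []
    try:
        reader = csv.DictReader(handle)
        _check_header(reader, CONSUMPTION_COLUMNS)
        for i, row in enumerate(reader, start=1):
            try:
                age = float(row["age_years"])
                if age < MIN_AGE_YEARS:
                    raise ValueError(
                        f"age {age} below minimum {MIN_AGE_YEARS} "
                        "(infants are excluded from the assessment)"
                    )
                amount = float(row["amount_g_per_day"])
                if amount < 0:
                    raise ValueError(f"negative amount {amount}")
                records.append(
                    ConsumptionRecord(
                        person_id=row["person_id"],
                        age_years=age,
                        food_type=row["food_type"].strip(),
                        amount_g_per_day=amount,
                    )
                )
            except (ValueError, TypeError, KeyError) as exc:
                errors.append((i, str(exc)))
    finally:
        if owned:
            handle.close()
    if errors:
        raise TableParseError(errors)
    return records


def write_concentration_table(
    records: Iterable[ConcentrationRecord], dest: Source
) -> None:
    handle, owned = (
        (open(dest, "w", encoding="utf-8", newline=""), True)
        if isinstance(dest, (str, Path))
        else (dest, False)
    )
    try:
        writer = csv.writer(handle)
        writer.writerow(CONCENTRATION_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.sample_id,
                    r.year,
                    r.food_type,
                    "" if r.value_mg_per_kg is None else repr(r.value_mg_per_kg),
                    repr(r.lod_mg_per_kg),
                    int(r.detected),
                ]
            )
    finally:
        if owned:
            handle.close()


def write_consumption_table(
    records: Iterable[ConsumptionRecord], dest: Source
) -> None:
    handle, owned = (
        (open(dest, "w", encoding="utf-8", newline=""), True)
        if isinstance(dest, (str, Path))
        else (dest, False)
    )
    try:
        writer = csv.writer(handle)
        writer.writerow(CONSUMPTION_COLUMNS)
        for r in records:
            writer.writerow(
                [r.person_id, repr(r.age_years), r.food_type, repr(r.amount_g_per_day)]
            )
    finally:
        if owned:
            handle.close()


def load_config(source: Source) -> AssessmentConfig:
    """Build an AssessmentConfig from a YAML document.

    Expected keys: residue_limit, ptwi, age_groups (list of
    {label, min, max, bw}; max may be null for the open top group),
    food_map, nondetect_policy, censoring_rate_threshold, rounding_dp.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(source)
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    required = ["residue_limit", "ptwi", "age_groups", "food_map"]
    for key in required:
        if key not in raw:
            raise ValueError(f"missing config key {key!r}")
    groups = [
        AgeGroupSpec(
            label=g["label"],
            age_min_years=float(g["min"]),
            age_max_years=None if g.get("max") is None else float(g["max"]),
            standard_bw_kg=float(g["bw"]),
        )
        for g in raw["age_groups"]
    ]
    return AssessmentConfig(
        residue_limit_mg_per_kg=float(raw["residue_limit"]),
        ptwi_mg_per_kg_bw_week=float(raw["ptwi"]),
        age_groups=groups,
        food_map=dict(raw["food_map"]),
        nondetect_policy=raw.get("nondetect_policy", "half_lod"),
        censoring_rate_threshold=float(raw.get("censoring_rate_threshold", 0.6)),
        rounding_dp=int(raw.get("rounding_dp", 2)),
    )


def dump_config(config: AssessmentConfig, dest: Source) -> None:
    doc = {
        "residue_limit": config.residue_limit_mg_per_kg,
        "ptwi": config.ptwi_mg_per_kg_bw_week,
        "age_groups": [
            {
                "label": g.label,
                "min": g.age_min_years,
                "max": g.age_max_years,
                "bw": g.standard_bw_kg,
            }
            for g in config.age_groups
        ],
        "food_map": config.food_map,
        "nondetect_policy": config.nondetect_policy,
        "censoring_rate_threshold": config.censoring_rate_threshold,
        "rounding_dp": config.rounding_dp,
    }
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
    else:
        yaml.safe_dump(doc, dest, sort_keys=False)


def write_report(results, format: str = "csv", *, rounding_dp: int = 2) -> str:
    """Render exposure results as a CSV or Markdown table.

    One row per age group: per-food mean exposures, total, weekly intake,
    margin of safety (mean and P95 variants). Values are rounded half-up
    to ``rounding_dp`` here and nowhere earlier.
    """
    results = list(results)
    if not results:
        raise ValueError("nothing to report: empty result list")
    foods = [fe.food_type for fe in results[0].per_food]
    if not foods:
        raise ValueError("nothing to report: empty per-food breakdown")
    header = (
        ["group", "bw_kg"]
        + [f"mean_{f}" for f in foods]
        + [
            "total_mean_mg_day",
            "total_p95_mg_day",
            "weekly_mean_mg_kg_week",
            "weekly_p95_mg_kg_week",
            "mos_mean",
            "mos_p95",
            "risk_flag",
        ]
    )
    rows = []
    for res in results:
        r = lambda x: round_half_up(x, rounding_dp)  # noqa: E731
        rows.append(
            [res.group.label, res.group.standard_bw_kg]
            + [r(fe.mean_daily_mg) for fe in res.per_food]
            + [
                r(res.total_mean_daily_mg),
                r(res.total_p95_daily_mg),
                r(res.weekly_mean_mg_per_kg),
                r(res.weekly_p95_mg_per_kg),
                r(res.mos_mean),
                r(res.mos_p95),
                int(res.risk_flag),
            ]
        )
    if format == "csv":
        buf = _io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(header)
        writer.writerows(rows)
        return buf.getvalue()
    if format == "markdown":
        lines = ["| " + " | ".join(header) + " |"]
        lines.append("|" + "|".join(["---"] * len(header)) + "|")
        for row in rows:
            lines.append("| " + " | ".join(str(c) for c in row) + " |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r}")
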