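"""Session records, per-target tables and descriptive summaries.

The clinical study behind this toolkit reported, for each of 15 targeted
liver tumors, the tumor size, the distance of the ablation device tip from
the target centre, the time to reach the target and the verification
modality, plus the residual 5-mm periablational margin percentage computed
by the confirmation software. Those per-target tables ship with the
package as CSV fixtures and every quantity is summarised as mean +/- sample
standard deviation (n-1 denominator), with rounding applied only at
presentation (one decimal).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("ablateguide")

ALLOWED_MODALITIES = {"US", "CT", ""}

#: required columns of the session-record schema (documented in README)
REQUIRED_COLUMNS = ("patient", "target")
NUMERIC_COLUMNS = ("size_cm", "tip_distance_mm", "time_to_target_min",
                   "residual_margin_pct")


class SchemaError(ValueError):
    """CSV header or content violates the session-record schema."""


class EmptySummaryError(ValueError):
    """No values available for the requested field."""


@dataclass
class SessionRecord:
    """One targeted tumor: identity, size, accuracy, timing, confirmation."""

    patient: str
    target: str
    size_cm: float | None = None
    tip_distance_mm: float | None = None
    time_to_target_min: float | None = None
    modality: str = ""
    residual_margin_pct: float | None = None
    complete_ablation: bool | None = None
    margin_success: bool | None = None
    technical_success: bool | None = None

    def __post_init__(self) -> None:
        if self.size_cm is not None and self.size_cm <= 0:
            raise SchemaError(f"size must be > 0, got {self.size_cm}")
        if self.tip_distance_mm is not None and self.tip_distance_mm < 0:
            raise SchemaError(f"distance must be >= 0, got {self.tip_distance_mm}")
        if self.modality not in ALLOWED_MODALITIES:
            raise SchemaError(f"modality must be US or CT, got {self.modality!r}")


@dataclass
class SummaryStats:
    """Descriptive summary of one numeric field across records."""

    field_name: str
    n: int
    mean: float
    sd: float
    min: float
    max: float
    single_value: bool = False

    def presentation(self) -> str:
        """'mean ± sd' at one decimal, the convention of the study tables."""
        return f"{self.mean:.1f} ± {self.sd:.1f}"


def _parse_number(cell, column: str, row: int) -> float | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    s = str(cell).strip()
    if not s:
        return None
    if "," in s:
        fixed = s.replace(",", ".")
        log.warning("normalised decimal-comma cell %r -> %r (column %s, row %d)",
                    s, fixed, column, row)
        s = fixed
    try:
        return float(s)
    except ValueError as exc:
        raise SchemaError(f"cannot parse {column}={s!r} in row {row}") from exc


def load_records(path: str | Path) -> list[SessionRecord]:
    """Load typed session records from CSV.

    Decimal-comma cells (European formatting, e.g. ``"2,2"``) are
    normalised to decimal points with a logged warning. A missing required
    column raises :class:`SchemaError`.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    known_numeric = [c for c in NUMERIC_COLUMNS if c in df.columns]
    records = []
    for i, row in df.iterrows():
        kwargs = {"patient": str(row["patient"]), "target": str(row["target"])}
        for c in known_numeric:
            kwargs[c] = _parse_number(row[c], c, i)
        if "modality" in df.columns:
            kwargs["modality"] = str(row["modality"]).strip()
        for c in ("complete_ablation", "margin_success", "technical_success"):
            if c in df.columns and str(row[c]).strip():
                kwargs[c] = str(row[c]).strip().lower() in ("1", "true", "yes")
        records.append(SessionRecord(**kwargs))
    return records


def load_table1() -> list[SessionRecord]:
    """The packaged per-target accuracy/timing table (15 records)."""
    with resources.as_file(resources.files("ablateguide.data")
                           / "table1_sessions.csv") as p:
        return load_records(p)


def load_table2() -> list[SessionRecord]:
    """The packaged per-target residual 5-mm margin table (15 records)."""
    with resources.as_file(resources.files("ablateguide.data")
                           / "table2_margins.csv") as p:
        return load_records(p)


def summarize(records: list[SessionRecord], field_name: str) -> SummaryStats:
    """n, mean, sample SD (n-1), min and max of one numeric field.

    Arithmetic is exact on the provided values; rounding happens only in
    :meth:`SummaryStats.presentation`.
    """
    values = [getattr(r, field_name) for r in records
              if getattr(r, field_name) is not None]
    if not values:
        raise EmptySummaryError(f"no values for field {field_name!r}")
    arr = np.asarray(values, dtype=float)
    single = len(arr) == 1
    sd = 0.0 if single else float(np.std(arr, ddof=1))
    return SummaryStats(field_name=field_name, n=len(arr),
                        mean=float(arr.mean()), sd=sd,
                        min=float(arr.min()), max=float(arr.max()),
                        single_value=single)


def render_report(records: list[SessionRecord], out_dir: str | Path,
                  stem: str = "report",
                  settings: dict | None = None) -> dict[str, Path]:
    """Write CSV + JSON mirroring the per-target table layout.

    The CSV carries one row per target plus an ``Overall`` row with
    ``mean ± sd`` presentation for each numeric field present; the JSON
    report repeats the records and summaries and embeds every configurable
    setting passed in ``settings`` so that each run is self-describing.
    Output bytes are deterministic for fixed input.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = ["patient", "target"] + [c for c in NUMERIC_COLUMNS
                                    if any(getattr(r, c) is not None for r in records)]
    if any(r.modality for r in records):
        cols.append("modality")
    flag_cols = [c for c in ("complete_ablation", "margin_success", "technical_success")
                 if any(getattr(r, c) is not None for r in records)]
    cols += flag_cols

    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in cols})
    overall = {c: "" for c in cols}
    overall["patient"] = "Overall"
    summaries = {}
    for c in cols:
        if c in NUMERIC_COLUMNS:
            try:
                s = summarize(records, c)
            except EmptySummaryError:
                continue
            summaries[c] = s
            overall[c] = s.presentation()
    df = pd.DataFrame(rows + ([overall] if records else []), columns=cols)
    csv_path = out_dir / f"{stem}.csv"
    df.to_csv(csv_path, index=False)

    payload = {
        "schema": "ablateguide.report/1",
        "records": rows,
        "summaries": {
            k: {"n": s.n, "mean": s.mean, "sd": s.sd,
                "min": s.min, "max": s.max,
                "presentation": s.presentation()}
            for k, s in summaries.items()
        },
        "settings": settings or {},
    }
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return {"csv": csv_path, "json": json_path}
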