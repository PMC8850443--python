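"""Canonical record schema, validation, readers/writers and corpus-level filters.

The corpus is a flat collection of :class:`SimulationRecord` objects, one per
simulated yield projection.  External files (CSV or multi-sheet xlsx) are bound
to the canonical schema through a :class:`ColumnMapping`, so deposited header
spellings never leak into the rest of the code base.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from statistics import fmean
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CROPS",
    "SCALES",
    "CLIMATE_FAMILIES",
    "ADAPTATION_OPTIONS",
    "FIELD_ORDER",
    "SimulationRecord",
    "CounterfactualYields",
    "ColumnMapping",
    "RejectedRow",
    "CorpusReadResult",
    "COUNTRY_REGIONS",
    "region_for_country",
    "validate_record",
    "read_corpus",
    "write_corpus",
    "average_over_esms",
    "filter_top_producers",
    "records_to_frame",
    "frame_to_records",
]

CROPS = ("maize", "rice", "soybean", "wheat")
SCALES = ("site", "region", "country_aggregated_grid", "global_grid")
CLIMATE_FAMILIES = ("CMIP3", "CMIP5", "SRES", "other")
ADAPTATION_OPTIONS = (
    "fertiliser",
    "irrigation",
    "cultivar",
    "planting_time",
    "soil_organic_matter",
    "tillage",
    "others",
)

#: Default preindustrial-vs-current global-warming reference offset (degC).
PREINDUSTRIAL_OFFSET = 0.8

# Minimal country -> IPCC-style region lookup used instead of polygon overlays.
COUNTRY_REGIONS: dict[str, str] = {
    "China": "Asia",
    "India": "Asia",
    "Japan": "Asia",
    "Bangladesh": "Asia",
    "Indonesia": "Asia",
    "USA": "North America",
    "Canada": "North America",
    "Mexico": "Central and South America",
    "Brazil": "Central and South America",
    "Argentina": "Central and South America",
    "France": "Europe",
    "Germany": "Europe",
    "Spain": "Europe",
    "Italy": "Europe",
    "Nigeria": "Africa",
    "Kenya": "Africa",
    "Egypt": "Africa",
    "South Africa": "Africa",
    "Australia": "Australasia",
}


def region_for_country(country: str, table: Mapping[str, str] | None = None) -> str:
    """Look up the region group for a country name; unknown names map to "other"."""
    table = COUNTRY_REGIONS if table is None else table
    return table.get(country, "other")


@dataclass
class SimulationRecord:
    """One harmonized crop-yield projection.

    Yields are t/ha, temperatures degC, precipitation mm, impacts percent.
    Optional quantities are ``None`` when not reported by the source study.
    """

    study_id: str
    crop: str
    country: str
    lat: float
    lon: float
    scale: str
    scenario: str
    adaptation: bool
    ref_label: str = ""
    pub_year: int | None = None
    site_label: str = ""
    region_group: str = ""
    climate_family: str = "other"
    esm: str = "ensemble_mean"
    future_start: int | None = None
    future_end: int | None = None
    future_mid: int | None = None
    base_start: int | None = None
    base_end: int | None = None
    base_mid: int | None = None
    Yb: float | None = None
    Yf: float | None = None
    YI_raw: float | None = None
    YI_2005: float | None = None
    dTl: float | None = None
    dTl_2005: float | None = None
    dTg_2005: float | None = None
    dTg_pi: float | None = None
    dPr: float | None = None
    dPr_2005: float | None = None
    Tave: float | None = None
    Tave_w: float | None = None
    Pr_base: float | None = None
    co2_included: bool = True
    co2_ppm: float | None = None
    adaptation_options: set[str] = field(default_factory=set)
    imputed_fields: set[str] = field(default_factory=set)
    remark: str = ""

    def __post_init__(self) -> None:
        # Midpoint years: half-years round down, matching integer midpoints
        # such as 2020/2050/2080 used throughout.
        if self.future_mid is None and None not in (self.future_start, self.future_end):
            self.future_mid = (self.future_start + self.future_end) // 2
        if self.base_mid is None and None not in (self.base_start, self.base_end):
            self.base_mid = (self.base_start + self.base_end) // 2

    def copy(self) -> "SimulationRecord":
        rec = dataclasses.replace(self)
        rec.adaptation_options = set(self.adaptation_options)
        rec.imputed_fields = set(self.imputed_fields)
        return rec


@dataclass(frozen=True)
class CounterfactualYields:
    """Paired climate-change / no-climate-change yield averages (t/ha)."""

    Yf_cc: float
    Yb_cc: float
    Yf_ncc: float
    Yb_ncc: float

    def __post_init__(self) -> None:
        if self.Yb_cc <= 0:
            raise ValueError("Yb_cc must be positive")
        if min(self.Yf_cc, self.Yb_cc, self.Yf_ncc, self.Yb_ncc) < 0:
            raise ValueError("yields must be non-negative")


FIELD_ORDER: tuple[str, ...] = tuple(f.name for f in dataclasses.fields(SimulationRecord))

#: Fields that hold per-run numeric outcomes and are averaged across ESMs.
NUMERIC_OUTCOME_FIELDS = (
    "Yb",
    "Yf",
    "YI_raw",
    "YI_2005",
    "dTl",
    "dTl_2005",
    "dTg_2005",
    "dTg_pi",
    "dPr",
    "dPr_2005",
    "co2_ppm",
)

_INT_FIELDS = {"pub_year", "future_start", "future_end", "future_mid", "base_start", "base_end", "base_mid"}
_FLOAT_FIELDS = {
    "lat",
    "lon",
    "Yb",
    "Yf",
    "YI_raw",
    "YI_2005",
    "dTl",
    "dTl_2005",
    "dTg_2005",
    "dTg_pi",
    "dPr",
    "dPr_2005",
    "Tave",
    "Tave_w",
    "Pr_base",
    "co2_ppm",
}
_BOOL_FIELDS = {"co2_included", "adaptation"}
_SET_FIELDS = {"adaptation_options", "imputed_fields"}

REQUIRED_FIELDS = (
    "study_id",
    "crop",
    "country",
    "lat",
    "lon",
    "scale",
    "scenario",
    "adaptation",
)


class MappingError(ValueError):
    """ColumnMapping is internally inconsistent or does not fit the file."""


@dataclass
class ColumnMapping:
    """Binds canonical field names to source column headers.

    ``columns`` maps canonical field -> source header.  ``unit_scales`` holds
    optional multiplicative factors applied on read (e.g. kg/ha -> t/ha), so a
    record always stores exactly one unit system.
    """

    columns: dict[str, str] = field(default_factory=lambda: {f: f for f in FIELD_ORDER})
    missing_values: tuple[str, ...] = ("", "NA", "n/a")
    sheet: str = "Projected_impacts"
    unit_scales: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [f for f in REQUIRED_FIELDS if f not in self.columns]
        if missing:
            raise MappingError(f"mapping does not cover required fields: {missing}")
        seen: dict[str, str] = {}
        for canonical, header in self.columns.items():
            if header in seen:
                raise MappingError(
                    f"column {header!r} mapped by both {seen[header]!r} and {canonical!r}"
                )
            seen[header] = canonical

    def is_missing(self, raw: str) -> bool:
        return raw.strip() in self.missing_values


@dataclass(frozen=True)
class RejectedRow:
    row_number: int
    reasons: tuple[str, ...]


@dataclass
class CorpusReadResult:
    records: list[SimulationRecord]
    rejects: list[RejectedRow]

    @property
    def n_total(self) -> int:
        return len(self.records) + len(self.rejects)


def validate_record(
    rec: SimulationRecord,
    preindustrial_offset: float = PREINDUSTRIAL_OFFSET,
    offset_tol: float = 0.05,
) -> list[str]:
    """Return a list of invariant violations (empty when the record is valid)."""
    reasons: list[str] = []
    if rec.crop not in CROPS:
        reasons.append(f"crop {rec.crop!r} not in {CROPS}")
    if rec.scale not in SCALES:
        reasons.append(f"scale {rec.scale!r} not in {SCALES}")
    if rec.climate_family not in CLIMATE_FAMILIES:
        reasons.append(f"climate_family {rec.climate_family!r} not in {CLIMATE_FAMILIES}")
    if not -90.0 <= rec.lat <= 90.0:
        reasons.append(f"lat {rec.lat} outside [-90, 90]")
    if not -180.0 <= rec.lon <= 180.0:
        reasons.append(f"lon {rec.lon} outside [-180, 180]")
    if rec.Yb is not None and rec.Yb <= 0:
        reasons.append(f"Yb {rec.Yb} not positive")
    if rec.Yf is not None and rec.Yf < 0:
        reasons.append(f"Yf {rec.Yf} negative")
    if rec.YI_raw is not None and rec.YI_raw < -100.0 - 1e-9:
        reasons.append(f"YI_raw {rec.YI_raw} below -100%")
    periods = (rec.base_start, rec.base_mid, rec.base_end, rec.future_start, rec.future_mid, rec.future_end)
    if None not in periods:
        bs, bm, be, fs, fm, fe = periods
        if not (bs <= bm <= be < fs <= fm <= fe):
            reasons.append(f"period ordering violated: base {bs}-{bm}-{be}, future {fs}-{fm}-{fe}")
    if rec.dTg_2005 is not None and rec.dTg_pi is not None:
        if abs((rec.dTg_pi - rec.dTg_2005) - preindustrial_offset) > offset_tol:
            reasons.append(
                f"dTg_pi - dTg_2005 = {rec.dTg_pi - rec.dTg_2005:.3f} "
                f"!= offset {preindustrial_offset}"
            )
    if rec.adaptation_options and not rec.adaptation:
        reasons.append("adaptation_options given but adaptation flag is false")
    unknown = rec.adaptation_options - set(ADAPTATION_OPTIONS)
    if unknown:
        reasons.append(f"unknown adaptation options {sorted(unknown)}")
    return reasons


# ---------------------------------------------------------------------------
# serialization


def _format_value(name: str, value) -> str:
    if value is None:
        return ""
    if name in _BOOL_FIELDS:
        return "yes" if value else "no"
    if name in _SET_FIELDS:
        return ";".join(sorted(value))
    if name in _FLOAT_FIELDS:
        return repr(float(value))
    return str(value)


def _parse_value(name: str, raw: str, mapping: ColumnMapping):
    if name in _SET_FIELDS:
        raw = raw.strip()
        return set(p for p in raw.split(";") if p) if raw else set()
    if mapping.is_missing(raw):
        return None
    raw = raw.strip()
    if name in _BOOL_FIELDS:
        low = raw.lower()
        if low in ("yes", "true", "1"):
            return True
        if low in ("no", "false", "0"):
            return False
        raise ValueError(f"cannot parse boolean {raw!r} for field {name}")
    if name in _INT_FIELDS:
        return int(float(raw))
    if name in _FLOAT_FIELDS:
        value = float(raw)
        scale = mapping.unit_scales.get(name)
        return value * scale if scale is not None else value
    return raw


def _row_to_record(row: Mapping[str, str], mapping: ColumnMapping) -> SimulationRecord:
    kwargs = {}
    for canonical, header in mapping.columns.items():
        raw = row.get(header)
        if raw is None:
            continue
        value = _parse_value(canonical, str(raw), mapping)
        if value is not None:
            # missing cells fall back to field defaults, never to 0
            kwargs[canonical] = value
    for required in REQUIRED_FIELDS:
        if required not in kwargs:
            raise ValueError(f"required field {required!r} missing")
    return SimulationRecord(**kwargs)


def _read_rows_csv(path: Path) -> tuple[list[str], list[dict[str, str]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise MappingError(f"{path} has no header row")
        return list(reader.fieldnames), [dict(r) for r in reader]


def _read_rows_xlsx(path: Path, sheet: str) -> tuple[list[str], list[dict[str, str]]]:
    from openpyxl import load_workbook

    wb = load_workbook(path, read_only=True, data_only=True)
    if sheet not in wb.sheetnames:
        raise MappingError(f"sheet {sheet!r} not found in {path} (has {wb.sheetnames})")
    ws = wb[sheet]
    rows = ws.iter_rows(values_only=True)
    header = [str(h) if h is not None else "" for h in next(rows)]
    out = []
    for row in rows:
        if all(v is None for v in row):
            continue
        out.append({h: ("" if v is None else str(v)) for h, v in zip(header, row)})
    wb.close()
    return header, out


def read_corpus(path, mapping: ColumnMapping | None = None) -> CorpusReadResult:
    """Read a corpus file (CSV or xlsx) into validated records.

    Rows breaking a schema invariant are not dropped silently: they are
    returned in :attr:`CorpusReadResult.rejects` with the offending reasons, so
    accepted + rejected always equals the number of input rows.
    """
    mapping = mapping or ColumnMapping()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        header, rows = _read_rows_xlsx(path, mapping.sheet)
    else:
        header, rows = _read_rows_csv(path)
    absent = [h for h in mapping.columns.values() if h not in header]
    if absent:
        raise MappingError(f"mapping references absent columns: {absent}")

    records: list[SimulationRecord] = []
    rejects: list[RejectedRow] = []
    for i, row in enumerate(rows, start=2):  # 1-based with header row
        try:
            rec = _row_to_record(row, mapping)
        except (ValueError, TypeError) as exc:
            rejects.append(RejectedRow(i, (str(exc),)))
            continue
        reasons = validate_record(rec)
        if reasons:
            rejects.append(RejectedRow(i, tuple(reasons)))
        else:
            records.append(rec)
    return CorpusReadResult(records, rejects)


def write_corpus(records: Iterable[SimulationRecord], path, mapping: ColumnMapping | None = None) -> Path:
    """Write records with a deterministic column order; CSV or single-sheet xlsx.

    Two writes of the same records produce byte-identical CSV files, and
    ``read_corpus(write_corpus(records))`` reproduces records field-for-field.
    """
    mapping = mapping or ColumnMapping()
    path = Path(path)
    fields = [f for f in FIELD_ORDER if f in mapping.columns]
    header = [mapping.columns[f] for f in fields]
    table = [[_format_value(f, getattr(rec, f)) for f in fields] for rec in records]
    if path.suffix.lower() == ".xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = mapping.sheet
        ws.append(header)
        for row in table:
            ws.append(row)
        wb.save(path)
    else:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(header)
            writer.writerows(table)
    return path


def write_reject_report(rejects: Sequence[RejectedRow], path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["row_number", "reasons"])
        for rej in rejects:
            writer.writerow([rej.row_number, " | ".join(rej.reasons)])
    return path


# ---------------------------------------------------------------------------
# corpus-level operations

DEFAULT_ESM_GROUP_KEYS = tuple(
    f
    for f in FIELD_ORDER
    if f not in NUMERIC_OUTCOME_FIELDS and f not in ("esm", "imputed_fields")
)


def average_over_esms(
    records: Sequence[SimulationRecord],
    group_keys: Sequence[str] = DEFAULT_ESM_GROUP_KEYS,
) -> list[SimulationRecord]:
    """Collapse multiple earth-system-model runs into one ensemble-mean record.

    Records sharing ``group_keys`` are averaged over every numeric outcome
    field; all other (non-numeric, non-key) fields must agree within a group or
    a ``ValueError`` is raised.  Output order follows first appearance.
    """

    def key_of(rec: SimulationRecord):
        return tuple(
            frozenset(v) if isinstance(v, set) else v
            for v in (getattr(rec, k) for k in group_keys)
        )

    groups: dict[tuple, list[SimulationRecord]] = {}
    for rec in records:
        groups.setdefault(key_of(rec), []).append(rec)

    check_fields = [
        f
        for f in FIELD_ORDER
        if f not in group_keys and f not in NUMERIC_OUTCOME_FIELDS and f not in ("esm", "imputed_fields")
    ]
    out: list[SimulationRecord] = []
    for members in groups.values():
        first = members[0]
        for f in check_fields:
            values = {
                frozenset(v) if isinstance(v, set) else v for v in (getattr(m, f) for m in members)
            }
            if len(values) > 1:
                raise ValueError(f"conflicting values for non-numeric field {f!r}: {values}")
        merged = first.copy()
        merged.esm = "ensemble_mean"
        merged.imputed_fields = set().union(*(m.imputed_fields for m in members))
        for f in NUMERIC_OUTCOME_FIELDS:
            present = [getattr(m, f) for m in members if getattr(m, f) is not None]
            setattr(merged, f, fmean(present) if present else None)
        out.append(merged)
    return out


GRID_SCALES = ("country_aggregated_grid", "global_grid")


def filter_top_producers(
    records: Sequence[SimulationRecord],
    production_table: Mapping[tuple[str, str], float],
    coverage: float = 0.95,
) -> list[SimulationRecord]:
    """Keep grid-aggregated records only for top-producing countries.

    For each crop, countries are ranked by descending production share and the
    minimal prefix whose cumulative share reaches ``coverage`` is retained.
    Site- and region-scale records pass through untouched.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")

    shares_by_crop: dict[str, list[tuple[str, float]]] = {}
    for (crop, country), share in production_table.items():
        shares_by_crop.setdefault(crop, []).append((country, share))

    keep: dict[str, set[str]] = {}
    for crop, pairs in shares_by_crop.items():
        pairs.sort(key=lambda cs: (-cs[1], cs[0]))
        kept, cum = set(), 0.0
        for country, share in pairs:
            kept.add(country)
            cum += share
            if cum >= coverage - 1e-12:
                break
        keep[crop] = kept

    out = []
    for rec in records:
        if rec.scale not in GRID_SCALES:
            out.append(rec)
            continue
        if rec.crop not in keep:
            raise KeyError(f"crop {rec.crop!r} absent from production table")
        if rec.country in keep[rec.crop]:
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# pandas bridge


def records_to_frame(records: Sequence[SimulationRecord]):
    """Represent records as a pandas DataFrame (sets joined by ';')."""
    import pandas as pd

    rows = []
    for rec in records:
        row = {}
        for f in FIELD_ORDER:
            v = getattr(rec, f)
            row[f] = ";".join(sorted(v)) if isinstance(v, set) else v
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FIELD_ORDER))


def frame_to_records(frame) -> list[SimulationRecord]:
    import math

    records = []
    for row in frame.to_dict("records"):
        kwargs = {}
        for f in FIELD_ORDER:
            v = row.get(f)
            if isinstance(v, float) and math.isnan(v):
                v = None
            if f in _SET_FIELDS:
                v = set(p for p in str(v or "").split(";") if p)
            elif f in _INT_FIELDS and v is not None:
                v = int(v)
            kwargs[f] = v
        records.append(SimulationRecord(**kwargs))
    return records
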