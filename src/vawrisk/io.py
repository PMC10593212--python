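"""Municipality indicator ingestion and performance-table construction.

A municipality is described by five binary protection-equipment flags
(specialised police station, programs/actions for women, campaigns against
violence, a municipal rights body, and a human-rights protection policy),
three socioeconomic indicators (HDI, GDP per capita, Gini) and an optional
count of violence complaints.  The five flags are aggregated into the
Support and Protection Index (SPI) and, together with HDI, GDP per capita
and Gini, min-max normalised to [0, 1] to form the performance table that
the multicriteria sorter consumes.

Missing-data policy: a record with *every* indicator absent is excluded
from classification (it carries no information); any individually missing
indicator is treated as "no resource", i.e. it enters the performance
table as 0 after normalisation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyTableError, FormatError, ParseError

#: order of the five equipment flags in the canonical CSV and in
#: ``MunicipalRecord.equipment``
EQUIPMENT_FIELDS = (
    "eq_police_station",
    "eq_programs",
    "eq_campaigns",
    "eq_rights_body",
    "eq_hr_policy",
)

#: indicator columns that decide whether a record is "fully missing"
INDICATOR_FIELDS = EQUIPMENT_FIELDS + ("hdi", "gdp_per_capita", "gini")

#: canonical CSV header (``complaints`` is optional on input)
CSV_COLUMNS = ("id", "name") + INDICATOR_FIELDS + ("complaints",)

#: criterion codes in performance-table column order
CRITERIA_CODES = ("C1", "C2", "C3", "C4")

#: reason string recorded for fully-missing exclusions
NO_DATA_REASON = "no data provided"


@dataclass(frozen=True)
class MunicipalRecord:
    """One municipality's raw indicators.

    ``equipment`` always holds five 0/1 integers; a flag whose source cell
    was empty is 0 and its field name appears in ``missing``.  ``hdi``,
    ``gdp_per_capita``, ``gini`` and ``complaints`` are ``None`` when
    missing.  ``latent_capacity`` is populated only by the synthetic
    generator (never read from or written to CSV) so tests can compare
    the classifier output with the ground-truth protection capacity.
    """

    id: str
    name: str
    equipment: tuple[int, int, int, int, int]
    hdi: float | None
    gdp_per_capita: float | None
    gini: float | None
    complaints: int | None = None
    missing: frozenset[str] = field(default_factory=frozenset)
    latent_capacity: float | None = None

    def __post_init__(self) -> None:
        if len(self.equipment) != 5:
            raise ValueError("equipment must hold exactly five flags")
        for flag in self.equipment:
            if flag not in (0, 1):
                raise ValueError(f"equipment flag {flag!r} not in {{0, 1}}")
        if self.hdi is not None and not 0.0 <= self.hdi <= 1.0:
            raise ValueError(f"hdi {self.hdi} outside [0, 1]")
        if self.gini is not None and not 0.0 <= self.gini <= 1.0:
            raise ValueError(f"gini {self.gini} outside [0, 1]")
        if self.gdp_per_capita is not None and self.gdp_per_capita < 0:
            raise ValueError(f"gdp_per_capita {self.gdp_per_capita} negative")
        if self.complaints is not None and self.complaints < 0:
            raise ValueError(f"complaints {self.complaints} negative")

    @property
    def fully_missing(self) -> bool:
        """True when every indicator was absent in the source."""
        return set(INDICATOR_FIELDS) <= set(self.missing)


@dataclass(frozen=True)
class PerformanceTable:
    """Normalised alternatives x criteria matrix ready for sorting.

    ``values`` is an (n_alternatives, 4) array of g_j(x_i) in [0, 1] with
    columns C1=SPI, C2=HDI, C3=GDP per capita, C4=Gini.  ``excluded`` maps
    the ids removed before classification to the reason.
    """

    alternatives: tuple[str, ...]
    criteria: tuple[str, ...]
    values: np.ndarray
    excluded: dict[str, str] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.alternatives), len(self.criteria)):
            raise ValueError("values shape does not match alternatives x criteria")
        if v.size and (np.isnan(v).any() or v.min() < 0 or v.max() > 1):
            raise ValueError("performance values must all lie in [0, 1]")
        if set(self.excluded) & set(self.alternatives):
            raise ValueError("excluded ids must not appear among alternatives")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.alternatives),
                            columns=list(self.criteria))

    def row(self, alt_id: str) -> np.ndarray:
        return self.values[self.alternatives.index(alt_id)]


def compute_spi(equipment: Sequence[int]) -> int:
    """Raw Support and Protection Index: sum of the five equipment flags.

    Returns an integer in [0, 5]; flags absent in the source count 0.
    Normalisation is applied separately over the dataset.
    """
    if len(equipment) != 5:
        raise ValueError("SPI requires exactly five equipment flags")
    for flag in equipment:
        if flag not in (0, 1):
            raise ValueError(f"equipment flag {flag!r} not in {{0, 1}}")
    return int(sum(equipment))


def minmax_normalize(value: float, vmin: float, vmax: float) -> float:
    """Linear rescale of ``value`` from [vmin, vmax] onto [0, 1].

    Values outside the interval are clamped so the [0, 1] invariant holds
    even under externally fixed bounds; a degenerate interval (vmax == vmin)
    maps everything to 0.
    """
    if vmax < vmin:
        raise ValueError(f"vmax {vmax} < vmin {vmin}")
    if vmax == vmin:
        return 0.0
    x = (value - vmin) / (vmax - vmin)
    return min(1.0, max(0.0, x))


def _parse_cell(raw: str, row: int, col: str, caster) -> float | int | None:
    text = raw.strip()
    if text == "":
        return None
    try:
        return caster(text)
    except ValueError as exc:
        raise ParseError(
            f"row {row}, column {col!r}: cannot parse {raw!r}") from exc


def _parse_flag(text: str) -> int:
    value = int(float(text))
    if value not in (0, 1):
        raise ValueError(text)
    return value


def read_municipal_csv(path: str | Path) -> list[MunicipalRecord]:
    """Read the canonical municipality indicator CSV.

    The header must contain ``id, name`` plus all indicator columns;
    ``complaints`` is optional.  Empty cells are recorded in ``missing``.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        required = [c for c in CSV_COLUMNS if c != "complaints"]
        for col in required:
            if col not in header:
                raise FormatError(f"required column {col!r} missing from header")
        has_complaints = "complaints" in header

        records: list[MunicipalRecord] = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            missing: set[str] = set()
            flags = []
            for col in EQUIPMENT_FIELDS:
                value = _parse_cell(row[col] or "", i, col, _parse_flag)
                if value is None:
                    missing.add(col)
                    value = 0
                flags.append(value)
            numeric = {}
            for col in ("hdi", "gdp_per_capita", "gini"):
                value = _parse_cell(row[col] or "", i, col, float)
                if value is None:
                    missing.add(col)
                numeric[col] = value
            complaints = None
            if has_complaints:
                raw = row.get("complaints") or ""
                complaints = _parse_cell(raw, i, "complaints",
                                         lambda t: int(float(t)))
                if complaints is None:
                    missing.add("complaints")
            else:
                missing.add("complaints")
            records.append(MunicipalRecord(
                id=(row["id"] or "").strip(),
                name=(row["name"] or "").strip(),
                equipment=tuple(flags),
                hdi=numeric["hdi"],
                gdp_per_capita=numeric["gdp_per_capita"],
                gini=numeric["gini"],
                complaints=complaints,
                missing=frozenset(missing),
            ))
    return records


def write_municipal_csv(records: Iterable[MunicipalRecord],
                        path: str | Path) -> None:
    """Write records in the canonical CSV layout (missing cell = empty)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            row: list[str] = [rec.id, rec.name]
            for col, flag in zip(EQUIPMENT_FIELDS, rec.equipment):
                row.append("" if col in rec.missing else str(flag))
            for col in ("hdi", "gdp_per_capita", "gini"):
                value = getattr(rec, col)
                row.append("" if value is None else repr(value))
            row.append("" if rec.complaints is None else str(rec.complaints))
            writer.writerow(row)


def records_to_frame(records: Iterable[MunicipalRecord]) -> pd.DataFrame:
    """Raw (un-normalised) indicator table, one row per record."""
    rows = []
    for rec in records:
        row = {"id": rec.id, "name": rec.name}
        row.update({col: (pd.NA if col in rec.missing else flag)
                    for col, flag in zip(EQUIPMENT_FIELDS, rec.equipment)})
        row.update(hdi=rec.hdi, gdp_per_capita=rec.gdp_per_capita,
                   gini=rec.gini, complaints=rec.complaints)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[MunicipalRecord]:
    """Build records from a DataFrame with the canonical columns.

    NaN / None cells count as missing, mirroring empty CSV cells.
    """
    for col in CSV_COLUMNS[:-1]:
        if col not in df.columns:
            raise FormatError(f"required column {col!r} missing from frame")
    has_complaints = "complaints" in df.columns
    records = []
    for _, row in df.iterrows():
        missing: set[str] = set()
        flags = []
        for col in EQUIPMENT_FIELDS:
            value = row[col]
            if pd.isna(value):
                missing.add(col)
                flags.append(0)
            else:
                flags.append(int(value))
        numeric = {}
        for col in ("hdi", "gdp_per_capita", "gini"):
            value = row[col]
            if pd.isna(value):
                missing.add(col)
                numeric[col] = None
            else:
                numeric[col] = float(value)
        complaints = None
        if has_complaints and not pd.isna(row["complaints"]):
            complaints = int(row["complaints"])
        else:
            missing.add("complaints")
        records.append(MunicipalRecord(
            id=str(row["id"]), name=str(row["name"]), equipment=tuple(flags),
            hdi=numeric["hdi"], gdp_per_capita=numeric["gdp_per_capita"],
            gini=numeric["gini"], complaints=complaints,
            missing=frozenset(missing)))
    return records


def build_performance_table(
    records: Sequence[MunicipalRecord],
    bounds: dict[str, tuple[float, float]] | None = None,
) -> PerformanceTable:
    """Assemble the normalised alternatives x criteria matrix.

    SPI is computed as the raw flag sum and then min-max normalised like
    the other criteria.  Normalisation bounds default to the per-criterion
    min/max observed among the classifiable records; ``bounds`` (keyed by
    criterion code) pins them externally so limit profiles keep their
    meaning across datasets.  Fully-missing records are excluded with
    reason ``"no data provided"``; individually missing indicators become
    0 after normalisation.
    """
    excluded = {r.id: NO_DATA_REASON for r in records if r.fully_missing}
    usable = [r for r in records if not r.fully_missing]
    if not usable:
        raise EmptyTableError("all records are fully missing")

    raw = {
        "C1": [float(compute_spi(r.equipment)) for r in usable],
        "C2": [r.hdi for r in usable],
        "C3": [r.gdp_per_capita for r in usable],
        "C4": [r.gini for r in usable],
    }
    values = np.zeros((len(usable), len(CRITERIA_CODES)))
    for j, code in enumerate(CRITERIA_CODES):
        col = raw[code]
        present = [v for v in col if v is not None]
        if bounds and code in bounds:
            vmin, vmax = bounds[code]
        elif present:
            vmin, vmax = min(present), max(present)
        else:
            vmin = vmax = 0.0
        for i, v in enumerate(col):
            values[i, j] = 0.0 if v is None else minmax_normalize(v, vmin, vmax)

    return PerformanceTable(
        alternatives=tuple(r.id for r in usable),
        criteria=CRITERIA_CODES,
        values=values,
        excluded=excluded,
        names={r.id: r.name for r in records},
    )
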