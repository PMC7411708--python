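"""Solvent-table data model and CSV I/O.

A :class:`SolventTable` is an ordered collection of named solvent records,
each carrying a subset of the numeric property schema (missing values are
``NaN``), optional hazard metadata for SH&E scoring, and free-form tags
(e.g. ``protic``, ``biobased``).

CSV dialect: comma separator, ``.`` decimal mark, UTF-8, header row, empty
cell = MISSING; property columns named exactly as in the schema (spaces
replaced by underscores).  ``Name`` is required, ``CAS`` and ``Tags``
(semicolon-separated) optional; hazard columns are ``H3xx`` / ``H4xx``
(semicolon-separated GHS codes or the literal ``UNKNOWN``), ``REACH_status``
and the boolean flags ``High_resistivity``, ``Peroxide_former``,
``High_energy_decomposition``.  Unknown columns are preserved as passthrough
metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem21 import HazardProfile
from .errors import DegenerateDataError, MissingDataError, ParseError, SchemaError
from .schema import (
    CAS_COLUMN,
    HAZARD_COLUMNS,
    NAME_COLUMN,
    TAGS_COLUMN,
    Schema,
    default_schema,
)

__all__ = [
    "SolventRecord",
    "HazardInfo",
    "SolventTable",
    "FeatureMatrix",
    "FilterCriterion",
    "read_solvent_table",
    "write_solvent_table",
    "feature_matrix",
    "apply_filters",
    "select_feature_columns",
]

MISSING = float("nan")


def is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


@dataclass(frozen=True)
class HazardInfo:
    """Raw hazard metadata as stored in the table (no boiling point)."""

    h3xx: Optional[frozenset[str]] = None
    h4xx: Optional[frozenset[str]] = None
    reach_status: str = "full"
    high_resistivity: bool = False
    peroxide_former: bool = False
    high_energy_decomposition: bool = False


@dataclass
class SolventRecord:
    """One solvent: name, CAS, property values, hazard metadata, tags."""

    name: str
    cas: Optional[str] = None
    properties: dict[str, float] = field(default_factory=dict)
    hazard: Optional[HazardInfo] = None
    tags: frozenset[str] = frozenset()
    extra: dict[str, str] = field(default_factory=dict)

    def get(self, prop: str) -> float:
        """Property value, NaN when missing."""
        v = self.properties.get(prop, MISSING)
        return MISSING if is_missing(v) else float(v)

    def has(self, prop: str) -> bool:
        return not is_missing(self.properties.get(prop, MISSING))

    def hansen(self):
        """Hansen parameter triple; raises when any component is missing."""
        from .hansen import HansenParameters

        triple = [self.get(f"Hansen_delta_{c}") for c in "DPH"]
        if any(math.isnan(v) for v in triple):
            raise MissingDataError(
                f"solvent {self.name!r} lacks a complete Hansen parameter triple"
            )
        return HansenParameters(*triple)

    def hazard_profile(self) -> HazardProfile:
        """Assemble the scoring profile from properties + hazard metadata.

        Records without hazard metadata get UNKNOWN H3xx/H4xx sets, the
        conservative incomplete-data branch of the scoring rubric.
        """
        bp = self.get("Boiling_point")
        if math.isnan(bp):
            raise ValueError(f"solvent {self.name!r} has no boiling point to score")
        fp = self.get("Flash_point")
        ait = self.get("Autoignition_temperature")
        hz = self.hazard if self.hazard is not None else HazardInfo()
        return HazardProfile(
            boiling_point=bp,
            flash_point=None if math.isnan(fp) else fp,
            autoignition_temperature=None if math.isnan(ait) else ait,
            high_resistivity=hz.high_resistivity,
            peroxide_former=hz.peroxide_former,
            high_energy_decomposition=hz.high_energy_decomposition,
            h3xx=hz.h3xx,
            h4xx=hz.h4xx,
            reach_status=hz.reach_status,
        )

    def validate(self, schema: Schema) -> None:
        for prop in self.properties:
            if prop not in schema:
                raise SchemaError(
                    f"solvent {self.name!r}: property {prop!r} not in schema"
                )
        for c in "DPH":
            v = self.get(f"Hansen_delta_{c}")
            if not math.isnan(v) and v < 0:
                raise ValueError(
                    f"solvent {self.name!r}: Hansen delta {c} must be >= 0"
                )
        bp, mp = self.get("Boiling_point"), self.get("Melting_point")
        if not math.isnan(bp) and not math.isnan(mp) and bp <= mp:
            raise ValueError(
                f"solvent {self.name!r}: boiling point ({bp}) must exceed "
                f"melting point ({mp})"
            )


class SolventTable:
    """Ordered solvent records with a shared property schema.

    Record names are unique case-insensitively; lookups by name are
    case-insensitive as well.
    """

    def __init__(self, records: Iterable[SolventRecord], schema: Optional[Schema] = None):
        self.schema = schema if schema is not None else default_schema()
        self.records = list(records)
        seen: dict[str, str] = {}
        for rec in self.records:
            key = rec.name.casefold()
            if key in seen:
                raise ValueError(f"duplicate solvent name: {rec.name!r}")
            seen[key] = rec.name
            rec.validate(self.schema)
        self._index = {rec.name.casefold(): rec for rec in self.records}

    # -- container protocol --------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, name: str) -> bool:
        return name.casefold() in self._index

    @property
    def names(self) -> list[str]:
        return [rec.name for rec in self.records]

    def get(self, name: str) -> SolventRecord:
        try:
            return self._index[name.casefold()]
        except KeyError:
            raise KeyError(f"no solvent named {name!r} in table") from None

    def subset(self, names: Sequence[str]) -> "SolventTable":
        return SolventTable([self.get(n) for n in names], schema=self.schema)

    # -- pandas bridge -------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, list] = {NAME_COLUMN: self.names}
        if any(rec.cas for rec in self.records):
            cols[CAS_COLUMN] = [rec.cas or "" for rec in self.records]
        for prop in self.schema.names:
            cols[prop] = [rec.get(prop) for rec in self.records]
        if any(rec.hazard is not None for rec in self.records):
            def hz(rec):
                return rec.hazard if rec.hazard is not None else HazardInfo()

            cols["H3xx"] = [_format_codes(hz(r).h3xx) for r in self.records]
            cols["H4xx"] = [_format_codes(hz(r).h4xx) for r in self.records]
            cols["REACH_status"] = [hz(r).reach_status for r in self.records]
            cols["High_resistivity"] = [int(hz(r).high_resistivity) for r in self.records]
            cols["Peroxide_former"] = [int(hz(r).peroxide_former) for r in self.records]
            cols["High_energy_decomposition"] = [
                int(hz(r).high_energy_decomposition) for r in self.records
            ]
        if any(rec.tags for rec in self.records):
            cols[TAGS_COLUMN] = [";".join(sorted(rec.tags)) for rec in self.records]
        extra_keys: list[str] = []
        for rec in self.records:
            for k in rec.extra:
                if k not in extra_keys:
                    extra_keys.append(k)
        for k in extra_keys:
            cols[k] = [rec.extra.get(k, "") for rec in self.records]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        write_solvent_table(self, path)


# -- CSV I/O ----------------------------------------------------------------

def _parse_codes(cell: str) -> Optional[frozenset[str]]:
    cell = cell.strip()
    if cell.upper() == "UNKNOWN":
        return None
    if not cell:
        return frozenset()
    return frozenset(c.strip().upper() for c in cell.split(";") if c.strip())


def _format_codes(codes: Optional[frozenset[str]]) -> str:
    return "UNKNOWN" if codes is None else ";".join(sorted(codes))


def _parse_flag(cell: str) -> bool:
    return cell.strip().lower() in {"1", "true", "yes", "x"}


def read_solvent_table(path, schema: Optional[Schema] = None) -> SolventTable:
    """Read a solvent table from a CSV file.

    Empty cells in property columns become MISSING; non-numeric tokens raise
    :class:`ParseError` naming the offending row and column.
    """
    schema = schema if schema is not None else default_schema()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, sep=",", encoding="utf-8")
    columns = list(frame.columns)
    name_col = next((c for c in columns if c.casefold() == NAME_COLUMN.casefold()), None)
    if name_col is None:
        raise SchemaError(f"CSV header lacks a {NAME_COLUMN!r} column: {columns}")
    cas_col = next((c for c in columns if c.casefold() == CAS_COLUMN.casefold()), None)
    hazard_cols = {c for c in columns if c in HAZARD_COLUMNS}
    known = {name_col, cas_col, TAGS_COLUMN} | hazard_cols | set(schema.names)
    extra_cols = [c for c in columns if c not in known]

    records = []
    for i, row in frame.iterrows():
        props: dict[str, float] = {}
        for prop in schema.names:
            if prop not in columns:
                continue
            cell = str(row[prop]).strip()
            if not cell:
                props[prop] = MISSING
                continue
            try:
                props[prop] = float(cell)
            except ValueError:
                raise ParseError(
                    f"row {i + 2}, column {prop!r}: non-numeric value {cell!r}"
                ) from None
        hazard = None
        if hazard_cols:
            hazard = HazardInfo(
                h3xx=_parse_codes(str(row["H3xx"])) if "H3xx" in hazard_cols else None,
                h4xx=_parse_codes(str(row["H4xx"])) if "H4xx" in hazard_cols else None,
                reach_status=(
                    str(row["REACH_status"]).strip() or "full"
                    if "REACH_status" in hazard_cols
                    else "full"
                ),
                high_resistivity=(
                    _parse_flag(str(row["High_resistivity"]))
                    if "High_resistivity" in hazard_cols
                    else False
                ),
                peroxide_former=(
                    _parse_flag(str(row["Peroxide_former"]))
                    if "Peroxide_former" in hazard_cols
                    else False
                ),
                high_energy_decomposition=(
                    _parse_flag(str(row["High_energy_decomposition"]))
                    if "High_energy_decomposition" in hazard_cols
                    else False
                ),
            )
        tags = frozenset()
        if TAGS_COLUMN in columns:
            cell = str(row[TAGS_COLUMN]).strip()
            if cell:
                tags = frozenset(t.strip() for t in cell.split(";") if t.strip())
        records.append(
            SolventRecord(
                name=str(row[name_col]).strip(),
                cas=str(row[cas_col]).strip() or None if cas_col else None,
                properties=props,
                hazard=hazard,
                tags=tags,
                extra={c: str(row[c]) for c in extra_cols},
            )
        )
    return SolventTable(records, schema=schema)


def write_solvent_table(table: SolventTable, path) -> None:
    """Write a table back to CSV (MISSING -> empty cell, 12 significant digits)."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty solvent table")
    frame = table.to_dataframe()
    frame.to_csv(path, index=False, float_format="%.12g", na_rep="", encoding="utf-8")


# -- feature matrix ---------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Scaled, weighted numeric matrix ready for clustering or MDS."""

    rows: list[str]
    columns: list[str]
    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.isnan(self.values).any():
            raise MissingDataError("feature matrix contains MISSING entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def feature_matrix(
    table: SolventTable,
    columns: Optional[Sequence[str]] = None,
    weights: Optional[Mapping[str, float]] = None,
    scaling: str = "minmax",
) -> FeatureMatrix:
    """Build the scaled feature matrix over the selected property columns.

    ``minmax`` (default) maps each column to [0, 1] (dataset minimum -> 0,
    maximum -> 1; constant columns -> 0.5) before multiplying by the column
    weight, so values lie in [0, weight].  ``zscore`` standardises instead.
    MISSING entries are an error: resolve them first with
    :func:`select_feature_columns`.
    """
    columns = list(columns) if columns is not None else list(table.schema.names)
    for col in columns:
        if col not in table.schema:
            raise SchemaError(f"unknown property column {col!r}")
    weights = dict(weights or {})
    for col, w in weights.items():
        if col not in table.schema:
            raise SchemaError(f"unknown property column in weights: {col!r}")
        if not w > 0:
            raise ValueError(f"weight for {col!r} must be > 0, got {w}")
    w_vec = np.array([weights.get(c, 1.0) for c in columns], dtype=float)

    raw = np.array([[rec.get(c) for c in columns] for rec in table], dtype=float)
    if np.isnan(raw).any():
        bad = [columns[j] for j in np.where(np.isnan(raw).any(axis=0))[0]]
        raise MissingDataError(
            f"MISSING values in columns {bad}; use select_feature_columns to "
            "drop incomplete properties before building the feature matrix"
        )
    if scaling == "minmax":
        lo = raw.min(axis=0)
        hi = raw.max(axis=0)
        span = hi - lo
        degenerate = span == 0
        span_safe = np.where(degenerate, 1.0, span)
        scaled = (raw - lo) / span_safe
        scaled[:, degenerate] = 0.5
    elif scaling == "zscore":
        mu = raw.mean(axis=0)
        sd = raw.std(axis=0, ddof=0)
        sd_safe = np.where(sd == 0, 1.0, sd)
        scaled = (raw - mu) / sd_safe
        scaled[:, sd == 0] = 0.0
    else:
        raise ValueError(f"unknown scaling {scaling!r} (choose 'minmax' or 'zscore')")
    return FeatureMatrix(
        rows=table.names, columns=columns, values=scaled * w_vec, weights=w_vec
    )


# -- filters ----------------------------------------------------------------

@dataclass(frozen=True)
class FilterCriterion:
    """Inclusive range criterion on one property column."""

    property: str
    low: float = float("-inf")
    high: float = float("inf")

    def __post_init__(self):
        if not self.low <= self.high:
            raise ValueError(
                f"filter on {self.property!r}: low ({self.low}) > high ({self.high})"
            )

    @classmethod
    def parse(cls, spec: str) -> "FilterCriterion":
        """Parse ``"Boiling_point:70:139"`` (empty bound = unbounded)."""
        parts = spec.split(":")
        if len(parts) != 3:
            raise ValueError(f"criterion spec must be 'property:low:high', got {spec!r}")
        prop, lo, hi = parts
        return cls(
            property=prop,
            low=float(lo) if lo.strip() else float("-inf"),
            high=float(hi) if hi.strip() else float("inf"),
        )

    def accepts(self, record: SolventRecord) -> bool:
        v = record.get(self.property)
        return not math.isnan(v) and self.low <= v <= self.high


def apply_filters(
    table: SolventTable, criteria: Sequence[FilterCriterion]
) -> SolventTable:
    """Conjunction of inclusive range filters.

    Records with a MISSING value in any filtered property are excluded
    (conservative).
    """
    for crit in criteria:
        if crit.property not in table.schema:
            raise SchemaError(f"unknown property in filter: {crit.property!r}")
    kept = [rec for rec in table if all(c.accepts(rec) for c in criteria)]
    return SolventTable(kept, schema=table.schema)


# -- missing-property handling ----------------------------------------------

def select_feature_columns(
    table: SolventTable, query: Optional[str] = None
) -> list[str]:
    """Property columns usable for clustering given the missing-value pattern.

    When a query solvent is named, first drop every property MISSING for the
    query; then drop any remaining property that is MISSING for any solvent
    in the table.  Column order is preserved.
    """
    if len(table) == 0:
        raise DegenerateDataError("empty solvent table")
    columns = list(table.schema.names)
    if query is not None:
        q = table.get(query)
        columns = [c for c in columns if q.has(c)]
    columns = [c for c in columns if all(rec.has(c) for rec in table)]
    if not columns:
        raise DegenerateDataError(
            "no property column is complete for every solvent; impute or drop "
            "records before clustering"
        )
    return columns
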