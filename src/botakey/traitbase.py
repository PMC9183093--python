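"""Typed trait schemas and trait matrices for multi-access identification keys.

A flora is stored as a *trait matrix*: one row per plant taxon, one column per
observable character. Quantitative characters are stored as min/max column
pairs (the "loose borders" of the key), phenology as a circular since/until
month pair, qualitative characters as delimited token sets, and free-form
notes as text. The canonical on-disk form is UTF-8 CSV with a header row.
"""
from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Optional, Sequence, Union

__all__ = [
    "TraitDef",
    "TraitSchema",
    "TaxonRow",
    "TraitMatrix",
    "Finding",
    "ValidationReport",
    "SchemaMismatchError",
    "CellParseError",
    "default_schema",
    "load_trait_matrix",
    "validate_matrix",
    "write_trait_matrix",
    "normalize_token",
    "apply_schema_config",
    "load_schema_config",
]

Kind = Literal["numeric_pair", "month_window", "categorical", "text"]

_WS = re.compile(r"\s+")


def normalize_token(token: str) -> str:
    """Trim, case-fold and collapse internal whitespace of a categorical token.

    Idempotent: normalizing an already-normalized token is the identity.
    """
    return _WS.sub(" ", token.strip()).casefold()


class SchemaMismatchError(ValueError):
    """A header label does not correspond to any schema column."""


class CellParseError(ValueError):
    """A cell's content cannot be parsed under its trait's kind."""

    def __init__(self, taxon: str, trait_id: str, raw: str, why: str):
        self.taxon, self.trait_id, self.raw = taxon, trait_id, raw
        super().__init__(f"row {taxon!r}, column {trait_id!r}: {why} (got {raw!r})")


@dataclass(frozen=True)
class TraitDef:
    """One key column: an observable character of the plants.

    ``group`` names the min/max (or since/until) pair a bound belongs to;
    tolerances and observations address paired traits through it. Unpaired
    traits have ``group == trait_id``.
    """

    trait_id: str
    label: str
    kind: Kind
    units: str = ""
    paired_with: str = ""
    bound: Optional[Literal["lower", "upper"]] = None
    group: str = ""
    vocabulary: Optional[frozenset[str]] = None
    integer: bool = False

    def __post_init__(self):
        if self.kind not in ("numeric_pair", "month_window", "categorical", "text"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind in ("numeric_pair", "month_window"):
            if not self.paired_with or self.bound is None:
                raise ValueError(
                    f"{self.trait_id}: {self.kind} traits occur in complete "
                    "min/max (since/until) pairs"
                )
        if not self.group:
            object.__setattr__(self, "group", self.trait_id)
        if self.vocabulary is not None:
            object.__setattr__(
                self, "vocabulary", frozenset(normalize_token(t) for t in self.vocabulary)
            )


@dataclass(frozen=True)
class TraitSchema:
    """Ordered list of trait definitions plus parsing conventions."""

    name_column: str
    traits: tuple[TraitDef, ...]
    multi_value_delimiter: str = ";"
    missing_tokens: tuple[str, ...] = ("", "NA")

    def __post_init__(self):
        object.__setattr__(self, "traits", tuple(self.traits))
        ids = [t.trait_id for t in self.traits]
        if len(set(ids)) != len(ids):
            raise ValueError("trait_id values must be unique within a schema")
        if self.name_column in ids:
            raise ValueError("name_column must not be among trait ids")
        by_id = {t.trait_id: t for t in self.traits}
        for t in self.traits:
            if t.paired_with:
                other = by_id.get(t.paired_with)
                if other is None or other.paired_with != t.trait_id:
                    raise ValueError(f"{t.trait_id}: dangling pair reference")
        # lookup caches (the filtering loop resolves traits constantly)
        object.__setattr__(self, "_by_id", by_id)
        object.__setattr__(self, "_pairs", {
            t.group: (t, by_id[t.paired_with])
            for t in self.traits if t.bound == "lower"
        })

    def __iter__(self) -> Iterator[TraitDef]:
        return iter(self.traits)

    @property
    def trait_ids(self) -> tuple[str, ...]:
        return tuple(t.trait_id for t in self.traits)

    def trait(self, trait_id: str) -> TraitDef:
        try:
            return self._by_id[trait_id]
        except KeyError:
            raise KeyError(trait_id) from None

    def resolve(self, key: str) -> TraitDef:
        """Find a trait by id, group id, or label (case-insensitive label)."""
        t = self._by_id.get(key)
        if t is not None:
            return t
        pair = self._pairs.get(key)
        if pair is not None:
            return pair[0]
        lowered = key.strip().casefold()
        for t in self.traits:
            if t.label.casefold() == lowered:
                return t
        raise KeyError(key)

    def pairs(self) -> dict[str, tuple[TraitDef, TraitDef]]:
        """Map group id -> (lower-bound trait, upper-bound trait)."""
        return self._pairs

    def is_missing(self, raw: str) -> bool:
        return raw.strip() in self.missing_tokens or raw.strip() == ""


#: cell value types: float/int (numeric or month), frozenset[str], or str
CellValue = Union[float, int, frozenset, str]


@dataclass
class TaxonRow:
    """One plant taxon and its (possibly sparse) trait values."""

    taxon_name: str
    values: dict[str, CellValue] = field(default_factory=dict)

    def get(self, trait_id: str):
        return self.values.get(trait_id)


@dataclass
class TraitMatrix:
    """The flora database: an ordered set of taxon rows under one schema."""

    schema: TraitSchema
    rows: list[TaxonRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[TaxonRow]:
        return iter(self.rows)

    @property
    def taxon_names(self) -> list[str]:
        return [r.taxon_name for r in self.rows]

    def row(self, taxon_name: str) -> TaxonRow:
        for r in self.rows:
            if r.taxon_name == taxon_name:
                return r
        raise KeyError(taxon_name)


@dataclass(frozen=True)
class Finding:
    row: str
    trait_id: str
    severity: Literal["error", "warning"]
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def __len__(self) -> int:
        return len(self.findings)


# ---------------------------------------------------------------------------
# default schema: the 30 characters of the legume key, plus the name column
# ---------------------------------------------------------------------------

def _pair(gid, lo_id, hi_id, lo_label, hi_label, units, kind="numeric_pair", integer=False):
    lo = TraitDef(lo_id, lo_label, kind, units, paired_with=hi_id, bound="lower",
                  group=gid, integer=integer)
    hi = TraitDef(hi_id, hi_label, kind, units, paired_with=lo_id, bound="upper",
                  group=gid, integer=integer)
    return lo, hi


def default_schema() -> TraitSchema:
    """The standard 31-column key layout for the Sardinian legume flora.

    Thirty trait columns — eight quantitative min/max pairs, one circular
    flowering-month window, nine qualitative characters and three free-text
    note columns — plus the taxon-name column.
    """
    alt = _pair("altitude", "altitude_min", "altitude_max",
                "minimum altitude", "maximum altitude", "m a.s.l.")
    height = _pair("plant_height", "height_min", "height_max",
                   "minimum height", "maximum height", "cm")
    flowering = _pair("flowering", "flowering_since", "flowering_until",
                      "flowering since (month)", "flowering until (month)",
                      "month", kind="month_window", integer=True)
    leaflets = _pair("leaflet_count", "leaflet_count_min", "leaflet_count_max",
                     "minimum number of leaflets", "maximum number of leaflets",
                     "", integer=True)
    lwidth = _pair("leaflet_width", "leaflet_width_min", "leaflet_width_max",
                   "leaflet minimum width", "leaflet maximum width", "mm")
    llength = _pair("leaflet_length", "leaflet_length_min", "leaflet_length_max",
                    "leaflet minimum length", "leaflet maximum length", "mm")
    flowers = _pair("flower_count", "flower_count_min", "flower_count_max",
                    "minimum n. of flowers per inflorescence",
                    "maximum n. of flowers per inflorescence", "", integer=True)
    fhead = _pair("flowerhead_length", "flowerhead_length_min", "flowerhead_length_max",
                  "minimum length of flowerhead", "maximum length of flowerhead", "mm")
    corolla = _pair("corolla_length", "corolla_length_min", "corolla_length_max",
                    "minimum length of corolla", "maximum length of corolla", "mm")

    cat = lambda tid, label: TraitDef(tid, label, "categorical")
    txt = lambda tid, label: TraitDef(tid, label, "text")

    traits = (
        *alt,
        *height,
        *flowering,
        cat("leaf_shape", "leaf shape"),
        *leaflets,
        cat("leaflet_shape", "leaflets shape"),
        *lwidth,
        *llength,
        cat("inflorescence_type", "inflorescence type"),
        *flowers,
        *fhead,
        cat("corolla_color", "corolla color"),
        *corolla,
        cat("legume_type", "legume type"),
        txt("other_notes", "other notes"),
        cat("habitat", "habitat"),
        txt("habitat_notes", "habitat notes"),
        cat("substrate", "substrate"),
        cat("abundance", "abundance"),
        cat("endemism", "endemism"),
        txt("geographical_notes", "geographical notes"),
    )
    return TraitSchema(name_column="taxon", traits=traits)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_cell(raw: str, trait: TraitDef, schema: TraitSchema, taxon: str) -> CellValue:
    raw = raw.strip()
    if trait.kind in ("numeric_pair", "month_window"):
        try:
            value = float(raw)
        except ValueError:
            raise CellParseError(taxon, trait.trait_id, raw, "expected a number") from None
        if trait.integer:
            if value != int(value):
                raise CellParseError(taxon, trait.trait_id, raw, "expected an integer")
            return int(value)
        return value
    if trait.kind == "categorical":
        tokens = raw.split(schema.multi_value_delimiter)
        return frozenset(normalize_token(t) for t in tokens if t.strip())
    return raw  # text


def _read_source(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    text = str(source)
    if "\n" not in text and "," not in text and Path(text).exists():
        return Path(text).read_text(encoding="utf-8")
    return text


def load_trait_matrix(source, schema: TraitSchema) -> TraitMatrix:
    """Parse delimited text (content string, path, or file object) into a matrix.

    Header labels may be trait ids or human-readable labels. Cells equal to a
    missing token are left absent; categorical cells are split on the schema's
    multi-value delimiter with tokens trimmed and case-folded.
    """
    text = _read_source(source)
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise SchemaMismatchError("empty input: no header row") from None

    columns: list[Optional[TraitDef]] = []
    name_idx = None
    for i, label in enumerate(header):
        label = label.strip()
        if label == schema.name_column or (
            name_idx is None and label.casefold() == schema.name_column.casefold()
        ):
            name_idx = i
            columns.append(None)
            continue
        try:
            columns.append(schema.resolve(label))
        except KeyError:
            raise SchemaMismatchError(f"unknown header label {label!r}") from None
    if name_idx is None:
        raise SchemaMismatchError(f"missing name column {schema.name_column!r}")

    rows = []
    for cells in reader:
        if not any(c.strip() for c in cells):
            continue
        name = cells[name_idx].strip() if name_idx < len(cells) else ""
        values: dict[str, CellValue] = {}
        for i, trait in enumerate(columns):
            if trait is None or i >= len(cells):
                continue
            raw = cells[i]
            if schema.is_missing(raw):
                continue
            values[trait.trait_id] = _parse_cell(raw, trait, schema, name)
        rows.append(TaxonRow(taxon_name=name, values=values))
    return TraitMatrix(schema=schema, rows=rows)


def validate_matrix(matrix: TraitMatrix) -> ValidationReport:
    """Check every row invariant; problems are findings, never exceptions."""
    report = ValidationReport()
    schema = matrix.schema
    seen: set[str] = set()
    pairs = schema.pairs()
    for row in matrix.rows:
        if not row.taxon_name:
            report.findings.append(Finding("", "", "error", "empty taxon name"))
        elif row.taxon_name in seen:
            report.findings.append(
                Finding(row.taxon_name, "", "error", "duplicate taxon name")
            )
        seen.add(row.taxon_name)

        for trait_id in row.values:
            if trait_id not in schema.trait_ids:
                report.findings.append(
                    Finding(row.taxon_name, trait_id, "error", "unknown trait id")
                )

        for gid, (lo, hi) in pairs.items():
            lo_v, hi_v = row.get(lo.trait_id), row.get(hi.trait_id)
            if lo.kind == "month_window":
                for t, v in ((lo, lo_v), (hi, hi_v)):
                    if v is not None and not (1 <= int(v) <= 12):
                        report.findings.append(Finding(
                            row.taxon_name, t.trait_id, "error",
                            f"month {v} outside 1-12"))
                continue  # wrapping windows are legal: no min<=max constraint
            if lo_v is not None and hi_v is not None and lo_v > hi_v:
                report.findings.append(Finding(
                    row.taxon_name, lo.trait_id, "error",
                    f"min > max ({lo_v} > {hi_v}) in pair {gid!r}"))

        for trait in schema:
            if trait.kind == "categorical" and trait.vocabulary is not None:
                cell = row.get(trait.trait_id)
                if cell:
                    bad = set(cell) - trait.vocabulary
                    if bad:
                        report.findings.append(Finding(
                            row.taxon_name, trait.trait_id, "error",
                            f"tokens outside vocabulary: {sorted(bad)}"))
    return report


def _format_cell(value: CellValue, trait: TraitDef, schema: TraitSchema) -> str:
    if isinstance(value, frozenset):
        return (schema.multi_value_delimiter + " ").join(sorted(value))
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def write_trait_matrix(matrix: TraitMatrix) -> str:
    """Serialize to CSV text; load(write(m)) reproduces m field for field."""
    schema = matrix.schema
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow([schema.name_column, *schema.trait_ids])
    missing = schema.missing_tokens[0]
    for row in matrix.rows:
        cells = [row.taxon_name]
        for trait in schema:
            v = row.get(trait.trait_id)
            cells.append(missing if v is None else _format_cell(v, trait, schema))
        writer.writerow(cells)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# YAML configuration overrides
# ---------------------------------------------------------------------------

def apply_schema_config(schema: TraitSchema, config: Mapping) -> TraitSchema:
    """Override delimiter, missing tokens, and per-trait vocabularies.

    Recognized keys: ``multi_value_delimiter`` (str), ``missing_tokens``
    (list of str), ``vocabulary`` (mapping trait_id -> list of tokens).
    """
    delim = config.get("multi_value_delimiter", schema.multi_value_delimiter)
    missing = tuple(config.get("missing_tokens", schema.missing_tokens))
    vocab = config.get("vocabulary", {})
    traits = tuple(
        replace(t, vocabulary=frozenset(vocab[t.trait_id]))
        if t.trait_id in vocab else t
        for t in schema.traits
    )
    return TraitSchema(schema.name_column, traits, delim, missing)


def load_schema_config(path) -> dict:
    import yaml

    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("schema configuration must be a mapping")
    return data
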