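"""Plant-bacterium occurrence records and their tally aggregations.

The substrate is a tidy table of literature-derived associations: one row per
(plant taxon, bacterial taxon, category, source) with three record categories:

* ``symbiont`` — the bacterium shown to be the nitrogen-fixing nodule inducer
  (e.g. by re-nodulation tests on the original host);
* ``nodule_endophyte`` — a bacterium co-occurring inside nodules without being
  responsible for nodulation;
* ``tissue_endophyte`` — a bacterium isolated from surface-sterilized
  non-nodular tissue (root, stem, leaf).

Duplicates are legal: the same plant-bacterium pair may recur across sources.
Aggregations follow the conventions of occurrence meta-analysis: per-taxon
occurrence tallies at genus or species rank, distinct-taxon counts, plant
promiscuity (how many distinct bacterial taxa a plant hosts) and bacterial
host range (how many distinct plants a bacterium occurs with).
"""
from __future__ import annotations

import csv
import io
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional

import pandas as pd

__all__ = [
    "CATEGORIES",
    "OccurrenceRecord",
    "OccurrenceTable",
    "SynonymTable",
    "CountTable",
    "PromiscuitySummary",
    "CategoryError",
    "CyclicSynonymError",
    "normalize_taxon_name",
    "resolve_plant_name",
    "load_occurrences",
    "write_occurrences",
    "tally_by_plant",
    "tally_by_bacterium",
    "count_distinct_taxa",
    "plant_promiscuity",
    "bacterial_host_range",
    "expand_counts",
]

Category = Literal["symbiont", "nodule_endophyte", "tissue_endophyte"]
CATEGORIES: tuple[Category, ...] = ("symbiont", "nodule_endophyte", "tissue_endophyte")

_WS = re.compile(r"\s+")


class CategoryError(ValueError):
    """A record carries a category outside the three recognized classes."""


class CyclicSynonymError(ValueError):
    """The synonym table contains a resolution cycle."""


def normalize_taxon_name(name: str) -> str:
    """Canonical spacing and capitalization: genus capitalized, rest lower.

    'Genus sp.' placeholders keep their lower-case 'sp.' epithet.
    """
    parts = _WS.sub(" ", name.strip()).split(" ")
    if not parts or not parts[0]:
        return ""
    genus = parts[0][0].upper() + parts[0][1:].lower()
    rest = [p.lower() for p in parts[1:]]
    return " ".join([genus, *rest])


def genus_of(name: str) -> str:
    """Genus = first whitespace-separated token of the binomial."""
    return normalize_taxon_name(name).split(" ")[0]


@dataclass(frozen=True)
class SynonymTable:
    """Former name -> current name; resolution is transitive and acyclic."""

    mapping: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_csv(cls, source) -> "SynonymTable":
        text = _read_source(source)
        reader = csv.DictReader(io.StringIO(text))
        mapping = {
            normalize_taxon_name(r["former_name"]): normalize_taxon_name(r["current_name"])
            for r in reader
        }
        return cls(mapping)

    def resolve(self, name: str) -> str:
        return resolve_plant_name(name, self)


def resolve_plant_name(name: str, synonyms: Optional[SynonymTable] = None) -> str:
    """Map a (possibly former) name to current nomenclature, normalized.

    Chains (a -> b, b -> c) resolve transitively, bounded by the table size;
    a longer walk means a cycle and raises :class:`CyclicSynonymError`.
    """
    current = normalize_taxon_name(name)
    if synonyms is None:
        return current
    seen = {current}
    for _ in range(len(synonyms.mapping) + 1):
        nxt = synonyms.mapping.get(current)
        if nxt is None:
            return current
        if nxt in seen:
            raise CyclicSynonymError(f"synonym cycle through {nxt!r}")
        seen.add(nxt)
        current = nxt
    return current


@dataclass(frozen=True)
class OccurrenceRecord:
    plant_name: str
    bacterial_name: str
    category: Category
    source_id: str = ""

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise CategoryError(
                f"category {self.category!r} not in {sorted(CATEGORIES)}")
        if not self.plant_name or not self.bacterial_name:
            raise ValueError("plant and bacterial names must be non-empty")


@dataclass
class OccurrenceTable:
    records: list[OccurrenceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[OccurrenceRecord]:
        return iter(self.records)

    def in_category(self, category: Category) -> "OccurrenceTable":
        if category not in CATEGORIES:
            raise CategoryError(f"category {category!r} not in {sorted(CATEGORIES)}")
        return OccurrenceTable([r for r in self.records if r.category == category])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.plant_name, r.bacterial_name, r.category, r.source_id)
             for r in self.records],
            columns=["plant_name", "bacterial_name", "category", "source_id"],
        )


def _read_source(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    text = str(source)
    if "\n" not in text and Path(text).exists():
        return Path(text).read_text(encoding="utf-8")
    return text


def load_occurrences(source, synonyms: Optional[SynonymTable] = None) -> OccurrenceTable:
    """Parse an occurrence CSV (plant_name, bacterial_name, category, source_id).

    Plant names are passed through synonym resolution; an unknown category
    token raises :class:`CategoryError` naming the offending row.
    """
    text = _read_source(source)
    reader = csv.DictReader(io.StringIO(text))
    records = []
    for i, row in enumerate(reader, start=2):  # header is line 1
        category = (row.get("category") or "").strip()
        if category not in CATEGORIES:
            raise CategoryError(
                f"line {i}: category {category!r} not in {sorted(CATEGORIES)}")
        records.append(OccurrenceRecord(
            plant_name=resolve_plant_name(row["plant_name"], synonyms),
            bacterial_name=normalize_taxon_name(row["bacterial_name"]),
            category=category,
            source_id=(row.get("source_id") or "").strip(),
        ))
    return OccurrenceTable(records)


def write_occurrences(table: OccurrenceTable) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["plant_name", "bacterial_name", "category", "source_id"])
    for r in table:
        writer.writerow([r.plant_name, r.bacterial_name, r.category, r.source_id])
    return buf.getvalue()


# ---------------------------------------------------------------------------
# tallies
# ---------------------------------------------------------------------------

Level = Literal["genus", "species"]


@dataclass(frozen=True)
class CountTable:
    """Labelled integer tallies at one grouping level.

    ``level`` is one of plant-genus, plant-species, bacterial-genus,
    bacterial-species. Tally outputs carry unique labels; tables transcribed
    from printed sources may repeat a label and are flagged by
    ``labels_unique``.
    """

    level: str
    entries: tuple[tuple[str, int], ...]

    def __post_init__(self):
        for label, n in self.entries:
            if n < 1:
                raise ValueError(f"count for {label!r} must be >= 1")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def total(self) -> int:
        return sum(n for _, n in self.entries)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.entries)

    @property
    def labels_unique(self) -> bool:
        return len(set(self.labels)) == len(self.entries)

    def count(self, label: str) -> int:
        return sum(n for lbl, n in self.entries if lbl == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["label", "count"])

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["label", "count"])
        writer.writerows(self.entries)
        return buf.getvalue()

    @classmethod
    def from_csv(cls, source, level: str) -> "CountTable":
        text = _read_source(source)
        reader = csv.DictReader(io.StringIO(text))
        return cls(level, tuple((r["label"], int(r["count"])) for r in reader))


def _label(name: str, level: Level) -> str:
    if level == "genus":
        return genus_of(name)
    if level == "species":
        return normalize_taxon_name(name)
    raise ValueError(f"level must be 'genus' or 'species', got {level!r}")


def tally_by_plant(table: OccurrenceTable, level: Level = "species") -> CountTable:
    """Occurrence count per plant label; alphabetical; counts sum to len(table)."""
    counts = Counter(_label(r.plant_name, level) for r in table)
    return CountTable(f"plant-{level}", tuple(sorted(counts.items())))


def tally_by_bacterium(table: OccurrenceTable, category: Category,
                       level: Level = "species") -> CountTable:
    """Occurrence count per bacterial label, restricted to one category."""
    counts = Counter(
        _label(r.bacterial_name, level) for r in table.in_category(category))
    return CountTable(f"bacterial-{level}", tuple(sorted(counts.items())))


def count_distinct_taxa(table: OccurrenceTable, category: Category) -> int:
    """Number of distinct bacterial species-level labels within a category.

    Distinctness is by normalized name string; identical printed labels
    merge even where a source meant separate strains.
    """
    return len({normalize_taxon_name(r.bacterial_name)
                for r in table.in_category(category)})


@dataclass(frozen=True)
class PromiscuitySummary:
    """Distinct-partner counts: plants' symbiont/endophyte diversity, and
    per-bacterium host breadth within one category."""

    plants: tuple[tuple[str, int, int], ...] = ()
    bacteria: tuple[tuple[str, int], ...] = ()

    def to_frame(self) -> pd.DataFrame:
        if self.plants:
            return pd.DataFrame(
                self.plants,
                columns=["plant", "n_symbiont_taxa", "n_nodule_endophyte_taxa"])
        return pd.DataFrame(self.bacteria, columns=["bacterium", "n_plants"])


def plant_promiscuity(table: OccurrenceTable) -> PromiscuitySummary:
    """Per plant, distinct symbiont taxa and distinct nodule-endophyte taxa.

    Plants are listed alphabetically; repeated pairs across sources dedup.
    """
    partners: dict[str, dict[str, set]] = defaultdict(
        lambda: {"symbiont": set(), "nodule_endophyte": set()})
    for r in table:
        if r.category in ("symbiont", "nodule_endophyte"):
            partners[normalize_taxon_name(r.plant_name)][r.category].add(
                normalize_taxon_name(r.bacterial_name))
    rows = tuple(
        (plant, len(d["symbiont"]), len(d["nodule_endophyte"]))
        for plant, d in sorted(partners.items())
    )
    return PromiscuitySummary(plants=rows)


def bacterial_host_range(table: OccurrenceTable, category: Category) -> PromiscuitySummary:
    """Per bacterial species, distinct plant taxa it occurs with in a category.

    Sorted by descending host count, ties alphabetically.
    """
    hosts: dict[str, set] = defaultdict(set)
    for r in table.in_category(category):
        hosts[normalize_taxon_name(r.bacterial_name)].add(
            normalize_taxon_name(r.plant_name))
    rows = tuple(sorted(
        ((b, len(p)) for b, p in hosts.items()),
        key=lambda item: (-item[1], item[0]),
    ))
    return PromiscuitySummary(bacteria=rows)


def expand_counts(counts: CountTable, category: Category,
                  placeholder_scheme: str = "Placeholdera partner{i}",
                  seed: int = 0) -> OccurrenceTable:
    """Reconstruct a record-level table from a marginal count table.

    Printed tallies only carry one margin; the opposite partner of each
    record is therefore a deterministic synthetic placeholder. Tallying the
    output at the table's own level reproduces the input counts exactly.
    """
    if category not in CATEGORIES:
        raise CategoryError(f"category {category!r} not in {sorted(CATEGORIES)}")
    plant_side = counts.level.startswith("plant")
    records = []
    i = 0
    for label, n in counts.entries:
        for _ in range(n):
            partner = placeholder_scheme.format(i=i)
            i += 1
            if plant_side:
                records.append(OccurrenceRecord(label, partner, category,
                                                source_id=f"expanded:{seed}"))
            else:
                records.append(OccurrenceRecord(partner, label, category,
                                                source_id=f"expanded:{seed}"))
    return OccurrenceTable(records)
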