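"""Deterministic synthetic data: random floras, specimens, occurrence tables.

Everything here exists to exercise the key engine and the tally operations
without any external download: floras with paired min/max numeric traits,
circular flowering windows (wrapping the year boundary with configurable
probability), multi-valued categorical cells and missing data; specimen
answer sheets drawn from a chosen taxon's own stored ranges; and occurrence
tables with the three record categories.

All generators take an explicit integer seed and use a private
``numpy.random.Generator``; identical configuration implies byte-identical
output. The generators aim at structural realism (value scales in the units
of each character, sparsity, wrap-around phenology), not at mimicking the
trait distributions of any real flora.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .keyengine import Observation
from .micromap import CATEGORIES, OccurrenceRecord, OccurrenceTable
from .traitbase import TaxonRow, TraitMatrix, TraitSchema, default_schema

__all__ = [
    "FloraSimConfig",
    "OccurrenceSimConfig",
    "generate_flora",
    "draw_specimen",
    "generate_occurrences",
    "DEFAULT_VOCABULARIES",
    "DEFAULT_NUMERIC_PROFILES",
]

_SYLLABLES = [
    "ba", "co", "da", "fe", "gi", "lo", "ma", "ni", "pu", "ra", "se", "ti",
    "ve", "xa", "zo", "bre", "cla", "dro", "fla", "gra",
]

#: token pools for the qualitative characters of the default legume schema
DEFAULT_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "leaf_shape": ("trifoliolate", "pinnate", "palmate", "simple", "bipinnate"),
    "leaflet_shape": ("ovate", "obovate", "lanceolate", "linear", "elliptic",
                      "oblong", "cordate"),
    "inflorescence_type": ("raceme", "umbel", "head", "spike", "solitary",
                           "panicle"),
    "corolla_color": ("yellow", "white", "pink", "purple", "blue", "red",
                      "cream", "violet"),
    "legume_type": ("straight", "curved", "coiled", "inflated", "flattened",
                    "segmented"),
    "habitat": ("grassland", "garrigue", "maquis", "woodland", "coastal sands",
                "cliffs", "cultivated fields", "roadsides"),
    "substrate": ("calcareous", "siliceous", "clay", "sandy", "rocky",
                  "indifferent"),
    "abundance": ("very common", "common", "scattered", "rare", "very rare"),
    "endemism": ("no", "sardinia", "sardinia-corsica", "tyrrhenian islands"),
}

_NOTE_WORDS = ("windswept", "cliffs", "coastal", "dunes", "pastures", "margins",
               "fallow", "stony", "slopes", "riverbanks", "hedgerows", "scrub")

#: per-pair (low, high) sampling scale in the character's units: interval
#: midpoints are drawn uniformly in [low, high], widths up to (high - low) / 2
DEFAULT_NUMERIC_PROFILES: dict[str, tuple[float, float]] = {
    "altitude": (0.0, 1800.0),      # m a.s.l.
    "plant_height": (5.0, 200.0),   # cm
    "leaflet_count": (1.0, 25.0),
    "leaflet_width": (1.0, 30.0),   # mm
    "leaflet_length": (2.0, 60.0),  # mm
    "flower_count": (1.0, 40.0),
    "flowerhead_length": (2.0, 40.0),  # mm
    "corolla_length": (2.0, 30.0),     # mm
}


@dataclass(frozen=True)
class FloraSimConfig:
    """Study conditions for a synthetic flora.

    ``missing_rate`` blanks cells independently (bounds of a pair blank
    together, keeping pairs complete); ``wrap_probability`` is the chance a
    flowering window crosses the year boundary (autumn-to-spring flowering).
    """

    n_taxa: int = 100
    schema: Optional[TraitSchema] = None
    missing_rate: float = 0.15
    numeric_profiles: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NUMERIC_PROFILES))
    vocabularies: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_VOCABULARIES))
    wrap_probability: float = 0.15
    max_tokens_per_cell: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 0:
            raise ValueError("n_taxa must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        for gid, (lo, hi) in self.numeric_profiles.items():
            if hi <= lo:
                raise ValueError(f"profile for {gid!r}: width must be > 0")


@dataclass(frozen=True)
class OccurrenceSimConfig:
    """Study conditions for a synthetic occurrence table."""

    n_plants: int = 30
    n_bacteria: int = 40
    n_records: int = 500
    category_mixture: tuple[float, float, float] = (0.45, 0.40, 0.15)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_plants, self.n_bacteria) < 1 or self.n_records < 0:
            raise ValueError("sizes must be positive (records may be 0)")
        if abs(sum(self.category_mixture) - 1.0) > 1e-9:
            raise ValueError("category mixture must sum to 1")


def _binomial_name(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        genus = "".join(rng.choice(_SYLLABLES, size=3)).capitalize()
        epithet = "".join(rng.choice(_SYLLABLES, size=3))
        name = f"{genus} {epithet}"
        if name not in used:
            used.add(name)
            return name


def generate_flora(config: FloraSimConfig) -> TraitMatrix:
    """Generate a valid random trait matrix under the configured conditions."""
    schema = config.schema or default_schema()
    rng = np.random.default_rng(config.seed)
    pairs = schema.pairs()
    used: set[str] = set()
    rows = []
    for _ in range(config.n_taxa):
        row = TaxonRow(taxon_name=_binomial_name(rng, used))
        for gid, (lo_def, hi_def) in pairs.items():
            if rng.random() < config.missing_rate:
                continue
            if lo_def.kind == "month_window":
                since = int(rng.integers(1, 13))
                if rng.random() < config.wrap_probability:
                    until = int(1 + (since - 2 - int(rng.integers(0, 3))) % 12)
                else:
                    until = int(rng.integers(since, 13))
                row.values[lo_def.trait_id] = since
                row.values[hi_def.trait_id] = until
                continue
            low, high = config.numeric_profiles.get(gid, (0.0, 100.0))
            mid = rng.uniform(low, high)
            half_width = rng.uniform(0, (high - low) / 4)
            lo_v, hi_v = mid - half_width, mid + half_width
            lo_v, hi_v = max(lo_v, low), min(hi_v, high)
            if lo_def.integer:
                lo_v, hi_v = int(round(lo_v)), int(round(hi_v))
                hi_v = max(lo_v, hi_v)
            else:
                lo_v, hi_v = round(lo_v, 1), round(max(lo_v, hi_v), 1)
            row.values[lo_def.trait_id] = lo_v
            row.values[hi_def.trait_id] = hi_v
        for trait in schema:
            if trait.bound is not None:
                continue
            if rng.random() < config.missing_rate:
                continue
            if trait.kind == "categorical":
                pool = config.vocabularies.get(
                    trait.trait_id, ("alpha", "beta", "gamma", "delta"))
                k = int(rng.integers(1, min(config.max_tokens_per_cell,
                                            len(pool)) + 1))
                picks = rng.choice(len(pool), size=k, replace=False)
                row.values[trait.trait_id] = frozenset(pool[int(p)] for p in picks)
            elif trait.kind == "text":
                words = rng.choice(_NOTE_WORDS, size=3, replace=False)
                row.values[trait.trait_id] = " ".join(words)
        rows.append(row)
    return TraitMatrix(schema=schema, rows=rows)


def _months_in_window(since: int, until: int) -> list[int]:
    if since <= until:
        return list(range(since, until + 1))
    return list(range(since, 13)) + list(range(1, until + 1))


def draw_specimen(matrix: TraitMatrix, taxon: str, noise: float = 0.0,
                  answer_rate: float = 1.0, seed: int = 0) -> list[Observation]:
    """Draw an answer sheet for a specimen of ``taxon`` from its stored ranges.

    Each character with data is answered with probability ``answer_rate``:
    numeric answers are drawn uniformly inside the taxon's [min, max] and
    perturbed by a uniform error in [-noise, +noise]; months are drawn inside
    the circular window; categorical answers pick one stored token; text
    answers pick one word of the stored note. Unanswered characters yield
    skipped observations. With ``noise`` at 0 the sheet always satisfies the
    source taxon at slack 0; with noise e it does so at slack >= e.
    """
    if noise < 0:
        raise ValueError("noise must be >= 0")
    row = matrix.row(taxon)  # raises KeyError for an unknown taxon
    rng = np.random.default_rng(seed)
    schema = matrix.schema
    observations: list[Observation] = []
    for gid, (lo_def, hi_def) in schema.pairs().items():
        lo_v, hi_v = row.get(lo_def.trait_id), row.get(hi_def.trait_id)
        if lo_v is None and hi_v is None:
            continue
        if rng.random() > answer_rate:
            observations.append(Observation.skipped(gid))
            continue
        if lo_def.kind == "month_window":
            if lo_v is None or hi_v is None:
                months = list(range(1, 13))  # half-open window matches any month
            else:
                months = _months_in_window(int(lo_v), int(hi_v))
            observations.append(Observation(gid, int(rng.choice(months))))
        else:
            lo_b = lo_v if lo_v is not None else hi_v
            hi_b = hi_v if hi_v is not None else lo_v
            value = rng.uniform(float(lo_b), float(hi_b))
            value += rng.uniform(-noise, noise)
            observations.append(Observation(gid, float(value)))
    for trait in schema:
        if trait.bound is not None:
            continue
        cell = row.get(trait.trait_id)
        if cell is None:
            continue
        if rng.random() > answer_rate:
            observations.append(Observation.skipped(trait.trait_id))
            continue
        if trait.kind == "categorical":
            tokens = sorted(cell)
            observations.append(
                Observation(trait.trait_id, tokens[int(rng.integers(len(tokens)))]))
        else:
            words = str(cell).split()
            observations.append(
                Observation(trait.trait_id, words[int(rng.integers(len(words)))]))
    return observations


def generate_occurrences(config: OccurrenceSimConfig) -> OccurrenceTable:
    """Random occurrence table with the configured category mixture."""
    rng = np.random.default_rng(config.seed)
    used: set[str] = set()
    plants = [_binomial_name(rng, used) for _ in range(config.n_plants)]
    bacteria = [_binomial_name(rng, used) for _ in range(config.n_bacteria)]
    records = []
    for i in range(config.n_records):
        records.append(OccurrenceRecord(
            plant_name=plants[int(rng.integers(config.n_plants))],
            bacterial_name=bacteria[int(rng.integers(config.n_bacteria))],
            category=CATEGORIES[int(rng.choice(3, p=config.category_mixture))],
            source_id=f"sim:{config.seed}:{i}",
        ))
    return OccurrenceTable(records)
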