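"""Packaged reference tallies from the Sardinian legume-microbe survey.

These are transcriptions of the printed summary tables of a literature
meta-analysis of bacteria associated with the legumes of the Sardinian flora
checklist: per-plant study-occurrence counts, nitrogen-fixing symbiont counts
(at genus and species rank), nodule-endophyte entries and non-nodular tissue
endophyte entries, plus a small table of plant-name synonyms attested in the
same survey.

The tables are marginal counts; the underlying record-level associations are
not public, so :func:`botakey.micromap.expand_counts` reconstructs synthetic
record tables with placeholder partners where record-level input is needed.

Transcription notes
-------------------
* Symbiont counts come in two layers. The printed genus totals (13 genera,
  summing to 241) are the authoritative totals; the 74 species rows sum to
  242 because the printed Rhizobium rows exceed their genus total by one
  while one Mesorhizobium species count (wenxinie, blank in print) is
  restored as 1 by subtraction from its genus total.
* The nodule-endophyte table repeats three labels (Paenibacillus sp.,
  Stenotrophomonas sp., Streptomyces sp.), evidently distinct taxa that share
  a printed name; entry count (142) and distinct-label count (139) therefore
  differ.
"""
from __future__ import annotations

from importlib import resources

from .micromap import CountTable, OccurrenceTable, SynonymTable, expand_counts

__all__ = [
    "plant_study_counts",
    "symbiont_genus_counts",
    "symbiont_species_counts",
    "nodule_endophyte_counts",
    "tissue_endophyte_counts",
    "plant_synonyms",
    "symbiont_records",
    "nodule_endophyte_records",
    "tissue_endophyte_records",
]


def _read(name: str) -> str:
    return (resources.files("botakey.data") / name).read_text(encoding="utf-8")


def plant_study_counts() -> CountTable:
    """Occurrences per plant species across the surveyed literature (104 rows)."""
    return CountTable.from_csv(_read("plant_study_counts.csv"), "plant-species")


def symbiont_genus_counts() -> CountTable:
    """Printed symbiont occurrence totals per bacterial genus (authoritative)."""
    return CountTable.from_csv(_read("symbiont_genus_counts.csv"), "bacterial-genus")


def symbiont_species_counts() -> CountTable:
    """Symbiont occurrences per bacterial species (74 rows)."""
    return CountTable.from_csv(_read("symbiont_species_counts.csv"), "bacterial-species")


def nodule_endophyte_counts() -> CountTable:
    """Nodule-endophyte occurrence counts, one entry per printed taxon (142)."""
    return CountTable.from_csv(_read("nodule_endophyte_counts.csv"), "bacterial-species")


def tissue_endophyte_counts() -> CountTable:
    """Non-nodular tissue endophyte occurrence counts (33 entries)."""
    return CountTable.from_csv(_read("tissue_endophyte_counts.csv"), "bacterial-species")


def plant_synonyms() -> SynonymTable:
    """Former plant names -> current nomenclature, as attested in the survey."""
    return SynonymTable.from_csv(_read("plant_synonyms.csv"))


def symbiont_records() -> OccurrenceTable:
    """Record-level symbiont table expanded from the species-rank counts."""
    return expand_counts(symbiont_species_counts(), "symbiont")


def nodule_endophyte_records() -> OccurrenceTable:
    return expand_counts(nodule_endophyte_counts(), "nodule_endophyte")


def tissue_endophyte_records() -> OccurrenceTable:
    return expand_counts(tissue_endophyte_counts(), "tissue_endophyte")
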