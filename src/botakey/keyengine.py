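"""Subtractive-key identification: predicates, progressive filtering, sessions.

The engine answers one question at a time against a trait matrix and keeps
only the taxa compatible with every answer so far (a conjunctive, multi-access
key). Design principles:

* *forgiving-missing* — a taxon with no data for a character can never be
  excluded by an answer on that character;
* *skip semantics* — a skipped question leaves the candidate list untouched;
* *loose borders* — numeric comparisons accept a per-character absolute slack
  widening the stored [min, max] interval on both sides;
* order of questions is entirely the caller's; the terminal list may hold
  zero, one, or several taxa, all legal outcomes.

The engine is fully deterministic.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence, Union

from .traitbase import TaxonRow, TraitDef, TraitMatrix, normalize_token

__all__ = [
    "Observation",
    "Tolerance",
    "CandidateSet",
    "Session",
    "UnknownTraitError",
    "EmptyHistoryError",
    "match_numeric",
    "match_month",
    "match_categorical",
    "match_text",
    "match_taxon",
    "new_session",
    "apply_filter",
    "undo",
    "identify",
]

logger = logging.getLogger(__name__)


class UnknownTraitError(KeyError):
    """An observation references a trait absent from the schema."""


class EmptyHistoryError(RuntimeError):
    """undo() called on a session with no applied steps."""


@dataclass(frozen=True)
class Observation:
    """A single answered (or skipped) question about the specimen.

    ``trait_id`` may be a trait id, a pair group id (e.g. ``plant_height``
    for a measurement matched against the height_min/height_max columns), or
    a column label. Skipped observations carry no value.
    """

    trait_id: str
    value: Union[float, int, str, None] = None
    status: Literal["answered", "skipped"] = "answered"

    def __post_init__(self):
        if self.status == "skipped" and self.value is not None:
            raise ValueError("skipped observations carry no value")
        if self.status == "answered" and self.value is None:
            raise ValueError("answered observations need a value")

    @classmethod
    def skipped(cls, trait_id: str) -> "Observation":
        return cls(trait_id, None, "skipped")


@dataclass(frozen=True)
class Tolerance:
    """Per-character absolute slack, in the character's own units."""

    absolute_slack: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for key, s in self.absolute_slack.items():
            if s < 0:
                raise ValueError(f"slack for {key!r} must be >= 0")

    def slack_for(self, group: str) -> float:
        return float(self.absolute_slack.get(group, 0.0))


@dataclass(frozen=True)
class CandidateSet:
    """Surviving taxa, in matrix order."""

    names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names


Outcome = Literal["no_match", "determined", "ambiguous"]


@dataclass(frozen=True)
class Session:
    """A filtering history: observations applied and candidate snapshots.

    ``snapshots[0]`` is the full flora; one further snapshot is appended per
    *answered* step (skips are recorded in the history but change nothing).
    """

    matrix: TraitMatrix
    tolerance: Tolerance = field(default_factory=Tolerance)
    observations: tuple[Observation, ...] = ()
    snapshots: tuple[CandidateSet, ...] = ()

    @property
    def candidates(self) -> CandidateSet:
        return self.snapshots[-1]

    @property
    def outcome(self) -> Outcome:
        n = len(self.candidates)
        return "no_match" if n == 0 else "determined" if n == 1 else "ambiguous"

    @property
    def counts(self) -> list[int]:
        """The 'rows disappearing' trace: candidate count after each snapshot."""
        return [len(s) for s in self.snapshots]

    def log_records(self) -> list[dict]:
        """Machine-readable step log (one dict per observation, JSON-friendly)."""
        records = []
        k = 0  # answered steps consumed
        for i, obs in enumerate(self.observations):
            if obs.status == "answered":
                k += 1
            snap = self.snapshots[k]
            rec = {
                "step": i + 1,
                "trait": obs.trait_id,
                "value": obs.value,
                "status": obs.status,
                "remaining": len(snap),
            }
            if len(snap) <= 10:
                rec["remaining_names"] = list(snap.names)
            records.append(rec)
        return records


# ---------------------------------------------------------------------------
# per-character predicates
# ---------------------------------------------------------------------------

def match_numeric(observed: float, lower: Optional[float], upper: Optional[float],
                  slack: float = 0.0) -> bool:
    """Closed-interval test with symmetric slack; missing bounds are unbounded."""
    if slack < 0:
        raise ValueError("slack must be >= 0")
    if lower is not None and observed < lower - slack:
        return False
    if upper is not None and observed > upper + slack:
        return False
    return True


def match_month(observed: int, since: Optional[int], until: Optional[int]) -> bool:
    """Circular month-window test; windows may wrap the year boundary.

    A window [11, 2] means November through February: months {11, 12, 1, 2}.
    """
    if not 1 <= observed <= 12:
        raise ValueError(f"observed month {observed} outside 1-12")
    if since is None or until is None:
        return True
    if since <= until:
        return since <= observed <= until
    return observed >= since or observed <= until


def match_categorical(observed: str, cell: Optional[frozenset]) -> bool:
    """Token membership; both sides normalized; a missing cell matches anything."""
    if cell is None:
        return True
    return normalize_token(observed) in {normalize_token(t) for t in cell}


def match_text(observed: str, cell: Optional[str]) -> bool:
    """Case-insensitive substring containment against a notes column."""
    if cell is None:
        return True
    return observed.strip().casefold() in cell.casefold()


def _match_one(row: TaxonRow, trait: TraitDef, matrix: TraitMatrix,
               obs: Observation, tolerance: Tolerance) -> bool:
    schema = matrix.schema
    if trait.kind == "numeric_pair":
        lo_def, hi_def = schema.pairs()[trait.group]
        return match_numeric(
            float(obs.value),
            row.get(lo_def.trait_id),
            row.get(hi_def.trait_id),
            tolerance.slack_for(trait.group),
        )
    if trait.kind == "month_window":
        lo_def, hi_def = schema.pairs()[trait.group]
        since, until = row.get(lo_def.trait_id), row.get(hi_def.trait_id)
        return match_month(int(obs.value), since if since is None else int(since),
                           until if until is None else int(until))
    if trait.kind == "categorical":
        cell = row.get(trait.trait_id)
        if (trait.vocabulary is not None
                and normalize_token(str(obs.value)) not in trait.vocabulary):
            logger.warning(
                "token %r is outside the vocabulary of %s %s",
                obs.value, trait.trait_id, sorted(trait.vocabulary),
            )
        return match_categorical(str(obs.value), cell)
    return match_text(str(obs.value), row.get(trait.trait_id))


def match_taxon(matrix: TraitMatrix, row: TaxonRow,
                observations: Iterable[Observation],
                tolerance: Optional[Tolerance] = None) -> bool:
    """Conjunction of the per-character predicates over all answered questions."""
    tolerance = tolerance or Tolerance()
    for obs in observations:
        if obs.status == "skipped":
            continue
        try:
            trait = matrix.schema.resolve(obs.trait_id)
        except KeyError:
            raise UnknownTraitError(obs.trait_id) from None
        if not _match_one(row, trait, matrix, obs, tolerance):
            return False
    return True


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def new_session(matrix: TraitMatrix, tolerance: Optional[Tolerance] = None) -> Session:
    full = CandidateSet(tuple(matrix.taxon_names))
    return Session(matrix, tolerance or Tolerance(), (), (full,))


def apply_filter(session: Session, observation: Observation) -> Session:
    """Apply one question; answered steps intersect, skips are neutral."""
    observations = session.observations + (observation,)
    if observation.status == "skipped":
        return Session(session.matrix, session.tolerance, observations,
                       session.snapshots)
    rows = {r.taxon_name: r for r in session.matrix.rows}
    survivors = tuple(
        name for name in session.candidates
        if match_taxon(session.matrix, rows[name], [observation], session.tolerance)
    )
    return Session(session.matrix, session.tolerance, observations,
                   session.snapshots + (CandidateSet(survivors),))


def undo(session: Session) -> Session:
    """Remove the last question (and its snapshot, if it was answered)."""
    if not session.observations:
        raise EmptyHistoryError("nothing to undo: no applied steps")
    last = session.observations[-1]
    snapshots = session.snapshots
    if last.status == "answered":
        snapshots = snapshots[:-1]
    return Session(session.matrix, session.tolerance,
                   session.observations[:-1], snapshots)


def identify(matrix: TraitMatrix, observations: Sequence[Observation],
             tolerance: Optional[Tolerance] = None) -> Session:
    """Run a whole answer sheet through the key and return the full session."""
    session = new_session(matrix, tolerance)
    for obs in observations:
        session = apply_filter(session, obs)
    return session
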