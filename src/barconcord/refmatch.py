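"""Best-match comparison of study sequences against a local reference library.

Each study sequence is compared with every reference sequence; the matches
retained are the closest ones (at most ``max_matches``) whose similarity
(1 - p-distance over the shared sites) reaches ``min_similarity``, with
provisionally named references excluded by default.  Each retained match is
classified by name agreement, and per-morphospecies flags mark barcode
novelty (all best matches more distant than a divergence threshold) and
first-barcode status (described name absent from the reference library).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .distances import DistanceMatrix
from .io import Provenance, SpecimenRecord

__all__ = [
    "MatchClass",
    "Match",
    "MatchRecord",
    "best_matches",
    "best_match_table",
    "flag_novelty",
    "flag_first_barcode",
    "normalize_name",
]


def normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip())


class MatchClass:
    NAME_MATCH = "NAME_MATCH"
    NAME_MISMATCH = "NAME_MISMATCH"
    PROVISIONAL_INVOLVED = "PROVISIONAL_INVOLVED"


@dataclass(frozen=True)
class Match:
    reference_id: str
    reference_name: str
    distance: float
    classification: str


@dataclass
class MatchRecord:
    """Ordered best matches of one query against the reference library."""

    query_id: str
    matches: list[Match]

    @property
    def best_distance(self) -> float | None:
        return self.matches[0].distance if self.matches else None


def _classify(query: SpecimenRecord, reference: SpecimenRecord) -> str:
    if query.provisional or reference.provisional:
        return MatchClass.PROVISIONAL_INVOLVED
    if normalize_name(query.morphospecies) == normalize_name(
        reference.morphospecies
    ):
        return MatchClass.NAME_MATCH
    return MatchClass.NAME_MISMATCH


def best_matches(
    query: SpecimenRecord,
    references: Sequence[SpecimenRecord],
    dm: DistanceMatrix,
    max_matches: int = 100,
    min_similarity: float = 0.80,
    exclude_provisional_refs: bool = True,
) -> MatchRecord:
    """Closest reference-library matches for one query sequence.

    Undefined distances (insufficient overlap) are omitted; ordering is by
    distance then reference id, so the list is fully deterministic.  An empty
    list is a valid result meaning no reference reached the similarity floor.
    """
    out: list[Match] = []
    for ref in references:
        if ref.specimen_id == query.specimen_id:
            continue
        if exclude_provisional_refs and ref.provisional:
            continue
        if ref.specimen_id not in dm._index or query.specimen_id not in dm._index:
            continue
        d = dm.get(query.specimen_id, ref.specimen_id)
        if math.isnan(d) or 1.0 - d < min_similarity:
            continue
        out.append(
            Match(ref.specimen_id, normalize_name(ref.morphospecies), d,
                  _classify(query, ref))
        )
    out.sort(key=lambda m: (m.distance, m.reference_id))
    return MatchRecord(query.specimen_id, out[:max_matches])


def best_match_table(
    records: Sequence[SpecimenRecord],
    dm: DistanceMatrix,
    max_matches: int = 100,
    min_similarity: float = 0.80,
    exclude_provisional_refs: bool = True,
) -> dict[str, MatchRecord]:
    """Best-match lists for every STUDY record against the EXTERNAL records."""
    references = [r for r in records if r.provenance == Provenance.EXTERNAL]
    return {
        r.specimen_id: best_matches(
            r, references, dm, max_matches, min_similarity,
            exclude_provisional_refs,
        )
        for r in records
        if r.provenance == Provenance.STUDY
    }


def flag_novelty(
    records: Sequence[SpecimenRecord],
    match_table: dict[str, MatchRecord],
    threshold: float = 0.05,
) -> set[str]:
    """Morphospecies whose sequences are all divergent from the library.

    A morphospecies is divergent-novel when the minimum best-match distance
    over all of its study sequences exceeds ``threshold``; a sequence with an
    empty match list counts as exceeding any threshold.  Monotone: raising
    the threshold can only shrink the flagged set.
    """
    min_by_morpho: dict[str, float] = {}
    for rec in records:
        if rec.provenance != Provenance.STUDY:
            continue
        if rec.specimen_id not in match_table:
            continue
        best = match_table[rec.specimen_id].best_distance
        value = math.inf if best is None else best
        name = normalize_name(rec.morphospecies)
        min_by_morpho[name] = min(min_by_morpho.get(name, math.inf), value)
    return {name for name, v in min_by_morpho.items() if v > threshold}


def flag_first_barcode(
    records: Sequence[SpecimenRecord],
    reference_names: Iterable[str],
) -> set[str]:
    """Described (non-provisional) morphospecies absent from the library.

    Exact match on whitespace-normalized names; provisional morphospecies are
    never flagged here — their status is handled by provisional resolution.
    """
    known = {normalize_name(n) for n in reference_names}
    return {
        normalize_name(r.morphospecies)
        for r in records
        if r.provenance == Provenance.STUDY
        and not r.provisional
        and normalize_name(r.morphospecies) not in known
    }
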