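"""Uncorrected p-distances with pairwise deletion, and overlap trimming.

The p-distance between two aligned sequences is the proportion of compared
sites at which they differ, where compared sites are the positions at which
*both* sequences carry an unambiguous base (A, C, G or T).  Gaps, ``?`` and
IUPAC ambiguity codes (including N) are excluded per pair — pairwise deletion,
not complete deletion.  Pairs sharing fewer than ``min_overlap`` compared
sites are flagged undefined (NaN) rather than reported as a noisy estimate.

p-distances are not assumed to satisfy the triangle inequality anywhere in
this package; they are treated purely as dissimilarities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import AlignedSequence, Provenance, SpecimenRecord

__all__ = [
    "DistanceMatrix",
    "encode_alignment",
    "p_distance_matrix",
    "trim_to_common_overlap",
    "max_within",
]

_BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_alignment(sequences: Sequence[AlignedSequence]) -> np.ndarray:
    """Encode sequences as an (n, L) int8 matrix; non-ACGT sites become -1."""
    if not sequences:
        raise ValueError("empty alignment")
    lengths = {s.aligned_length for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences must share one aligned length, got {sorted(lengths)}")
    (L,) = lengths
    mat = np.full((len(sequences), L), -1, dtype=np.int8)
    for i, seq in enumerate(sequences):
        row = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
        for base, code in _BASE_CODES.items():
            mat[i, row == ord(base)] = code
    return mat


@dataclass
class DistanceMatrix:
    """Symmetric pairwise p-distance matrix with per-pair site-overlap counts.

    ``d[i, j]`` is NaN when ``overlap[i, j]`` fell below the ``min_overlap``
    used to build the matrix; the raw overlap counts are kept so callers with
    stricter overlap requirements (e.g. the 300 bp best-match rule) can mask
    further.
    """

    ids: list[str]
    d: np.ndarray
    overlap: np.ndarray
    min_overlap: int

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.overlap.shape != (n, n):
            raise ValueError("matrix shapes must match the id list")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in distance matrix")
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def index(self, specimen_id: str) -> int:
        return self._index[specimen_id]

    def get(self, a: str, b: str) -> float:
        """Distance between two ids (NaN if undefined)."""
        return float(self.d[self._index[a], self._index[b]])

    def defined(self, a: str, b: str) -> bool:
        return not math.isnan(self.get(a, b))

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = np.array([self._index[i] for i in ids])
        return DistanceMatrix(
            list(ids),
            self.d[np.ix_(idx, idx)].copy(),
            self.overlap[np.ix_(idx, idx)].copy(),
            self.min_overlap,
        )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                cells = [
                    "NA" if math.isnan(v) else f"{v:.8g}" for v in self.d[i]
                ]
                fh.write(sid + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path, min_overlap: int = 0) -> "DistanceMatrix":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            n = len(header)
            d = np.zeros((n, n))
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split("\t")
                d[i] = [math.nan if c == "NA" else float(c) for c in parts[1:]]
        overlap = np.where(np.isnan(d), 0, min_overlap)
        np.fill_diagonal(overlap, min_overlap)
        return cls(header, d, overlap.astype(np.int64), min_overlap)


def p_distance_matrix(
    sequences: Sequence[AlignedSequence], min_overlap: int = 100
) -> DistanceMatrix:
    """All-pairs uncorrected p-distances under pairwise deletion.

    Vectorized as one matrix product per base: with V the validity mask and
    M_b the per-base indicator, overlap = V Vᵀ and matches = Σ_b M_b M_bᵀ.
    """
    mat = encode_alignment(sequences)
    valid = (mat >= 0).astype(np.float64)
    overlap = valid @ valid.T
    matches = np.zeros_like(overlap)
    for code in range(4):
        mb = (mat == code).astype(np.float64)
        matches += mb @ mb.T
    overlap_i = np.rint(overlap).astype(np.int64)
    mismatches = np.rint(overlap - matches).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(overlap_i > 0, mismatches / np.maximum(overlap_i, 1), np.nan)
    d[overlap_i < min_overlap] = np.nan
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([s.sequence_id for s in sequences], d, overlap_i,
                          min_overlap)


def trim_to_common_overlap(
    sequences: Sequence[AlignedSequence], min_common: int = 150
) -> tuple[list[AlignedSequence], list[str]]:
    """Drop short/fragmentary sequences until every kept pair shares a core.

    The *common overlap* is the number of alignment columns at which every
    kept sequence carries an unambiguous base.  Greedy rule: repeatedly remove
    the sequence whose removal most increases the common overlap, breaking
    ties by fewest unambiguous sites then lexicographic id, until the common
    overlap reaches ``min_common``.  Returns (kept sequences in input order,
    removed ids in removal order).
    """
    if not sequences:
        raise ValueError("empty alignment")
    mat = encode_alignment(sequences)
    valid = mat >= 0
    ids = [s.sequence_id for s in sequences]
    alive = list(range(len(sequences)))

    def common(members: list[int]) -> int:
        return int(valid[members].all(axis=0).sum())

    removed: list[str] = []
    while common(alive) < min_common:
        if len(alive) <= 2:
            raise ValueError(
                f"cannot reach a common overlap of {min_common} sites even "
                f"with 2 sequences (best: {common(alive)})"
            )
        sub = valid[alive]
        invalid_count = (~sub).sum(axis=0)  # per column
        # removing row r recovers exactly the columns where r is the sole gap
        gains = ((~sub) & (invalid_count == 1)[None, :]).sum(axis=1)
        n_valid = sub.sum(axis=1)
        order = sorted(
            range(len(alive)),
            key=lambda r: (-gains[r], n_valid[r], ids[alive[r]]),
        )
        victim = alive[order[0]]
        removed.append(ids[victim])
        alive.remove(victim)
    alive_set = set(alive)
    kept = [s for i, s in enumerate(sequences) if i in alive_set]
    return kept, removed


def max_within(
    dm: DistanceMatrix,
    records: Sequence[SpecimenRecord],
    morphospecies: str,
    restrict: Provenance | None = None,
) -> float | None:
    """Maximum defined pairwise p-distance within one morphospecies.

    ``restrict`` limits the comparison to one provenance (e.g. study-only).
    Returns None when fewer than 2 matching specimens have sequences, or when
    no pair among them has a defined distance.
    """
    members = [
        r.specimen_id
        for r in records
        if r.morphospecies == morphospecies
        and (restrict is None or r.provenance == restrict)
        and r.specimen_id in dm._index
    ]
    if len(members) < 2:
        return None
    best: float | None = None
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            v = dm.get(a, b)
            if not math.isnan(v) and (best is None or v > best):
                best = v
    return best
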