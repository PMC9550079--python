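"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import math

import pytest

from barconcord import AlignedSequence, Provenance, SpecimenRecord

BASES = "ACGT"


def naive_p_distance(a: str, b: str) -> tuple[float | None, int]:
    """Position-by-position p-distance oracle with pairwise deletion.

    Returns (distance or None when no comparable site, compared-site count).
    """
    mismatches = compared = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in BASES and y in BASES:
            compared += 1
            if x != y:
                mismatches += 1
    return (mismatches / compared if compared else None), compared


class UnionFind:
    """Independent union-find used as clustering oracle."""

    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def groups(self):
        out = {}
        for item in self.parent:
            out.setdefault(self.find(item), set()).add(item)
        return {frozenset(v) for v in out.values()}


def as_group_sets(partition) -> set[frozenset]:
    return set(partition.groups().values())


def make_records(labels: dict[str, str], provisional=(), external=(),
                 taxon_class="Testa") -> list[SpecimenRecord]:
    return [
        SpecimenRecord(
            specimen_id=sid,
            morphospecies=label,
            provisional=sid in provisional or label in provisional,
            provenance=(
                Provenance.EXTERNAL if sid in external else Provenance.STUDY
            ),
            taxon_class=taxon_class,
        )
        for sid, label in labels.items()
    ]


@pytest.fixture
def toy_alignment() -> list[AlignedSequence]:
    return [
        AlignedSequence("s1", "ACGTACGTAC"),
        AlignedSequence("s2", "ACGTACGTAA"),
        AlignedSequence("s3", "ACGAACGTAC"),
    ]


def assert_partitions_equal(p1, p2) -> None:
    assert as_group_sets(p1) == as_group_sets(p2)
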