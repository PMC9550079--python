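"""Readers, writers and joint validation for the pipeline's file formats.

All on-disk artifacts are plain text: aligned FASTA (gap ``-``), tab-separated
metadata and partition tables (``#`` comment lines ignored), Newick trees and
JSON reports.  Specimen metadata distinguishes sequences produced by the study
at hand (``STUDY``) from reference-library sequences pulled in for comparison
(``EXTERNAL``); that distinction later drives the H/A context of discordance
records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO

__all__ = [
    "Provenance",
    "SpecimenRecord",
    "AlignedSequence",
    "Partition",
    "read_alignment",
    "write_alignment",
    "read_metadata",
    "write_metadata",
    "read_partition",
    "write_partition",
    "read_ultrametric_tree",
    "cross_validate",
    "suggest_provisional",
    "ValidationIssue",
    "ValidationReport",
]

#: residues that count as informative for distance computation
CANONICAL_BASES = frozenset("ACGT")
#: full accepted alphabet; IUPAC ambiguity codes degrade to N downstream
IUPAC_EXTRA = frozenset("RYSWKMBDHVN")
ALLOWED_RESIDUES = CANONICAL_BASES | IUPAC_EXTRA | frozenset("-?")


class Provenance(str, Enum):
    """Origin of a specimen's sequence: this study or an external library."""

    STUDY = "STUDY"
    EXTERNAL = "EXTERNAL"


@dataclass(frozen=True)
class SpecimenRecord:
    """One vouchered specimen with its morphology-based identification.

    ``morphospecies`` is the name assigned by a taxonomist; ``provisional``
    marks open-nomenclature identifications (e.g. "Ophiocoma sp.") that could
    not be tied to a described species.  The flag is explicit metadata: it is
    an expert judgment, never inferred silently from the label text (see
    :func:`suggest_provisional` for an advisory helper).
    """

    specimen_id: str
    morphospecies: str
    provisional: bool
    provenance: Provenance
    taxon_class: str | None = None
    locality: str | None = None
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValueError("specimen_id must be non-empty")
        if not self.morphospecies:
            raise ValueError(
                f"specimen {self.specimen_id!r}: morphospecies must be non-empty"
            )
        if not isinstance(self.provenance, Provenance):
            object.__setattr__(self, "provenance", Provenance(self.provenance))


@dataclass(frozen=True)
class AlignedSequence:
    """A row of a multiple alignment of COI barcode fragments."""

    sequence_id: str
    residues: str

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        bad = set(residues) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.sequence_id!r}: disallowed residues {sorted(bad)}"
            )
        if not any(c not in "-?" for c in residues):
            raise ValueError(
                f"sequence {self.sequence_id!r}: no non-gap residue present"
            )
        object.__setattr__(self, "residues", residues)

    @property
    def aligned_length(self) -> int:
        return len(self.residues)


class PartitionError(ValueError):
    pass


@dataclass
class Partition:
    """One delimitation method's assignment of specimens to putative species.

    Group ids are opaque labels; only the induced set partition matters.
    """

    method_name: str
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        for sid, gid in self.assignment.items():
            if not sid or gid is None or gid == "":
                raise PartitionError(
                    f"partition {self.method_name!r}: empty id in ({sid!r}, {gid!r})"
                )

    @property
    def scope(self) -> frozenset[str]:
        return frozenset(self.assignment)

    def groups(self) -> dict[str, frozenset[str]]:
        """Group id -> member specimen ids."""
        out: dict[str, set[str]] = {}
        for sid, gid in self.assignment.items():
            out.setdefault(gid, set()).add(sid)
        return {g: frozenset(m) for g, m in out.items()}

    def n_groups(self) -> int:
        return len(set(self.assignment.values()))

    def restrict(self, ids: Iterable[str]) -> "Partition":
        keep = set(ids)
        return Partition(
            self.method_name,
            {s: g for s, g in self.assignment.items() if s in keep},
        )

    def same_group(self, a: str, b: str) -> bool:
        return self.assignment[a] == self.assignment[b]


# ---------------------------------------------------------------------------
# FASTA

def read_alignment(path: str | Path) -> list[AlignedSequence]:
    """Read an aligned FASTA file into :class:`AlignedSequence` records.

    Order-preserving; residues are uppercased.  Raises on duplicate ids and
    on ragged alignments (every record must share one aligned length).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    out: list[AlignedSequence] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        out.append(AlignedSequence(rec.id, str(rec.seq)))
    lengths = {s.aligned_length for s in out}
    if len(lengths) > 1:
        by_len: dict[int, list[str]] = {}
        for s in out:
            by_len.setdefault(s.aligned_length, []).append(s.sequence_id)
        raise ValueError(
            f"{path}: ragged alignment, lengths {sorted(by_len)}; "
            f"offending ids per length: {by_len}"
        )
    return out


def write_alignment(sequences: Sequence[AlignedSequence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for seq in sequences:
            fh.write(f">{seq.sequence_id}\n{seq.residues}\n")


# ---------------------------------------------------------------------------
# Metadata TSV

_REQUIRED_COLUMNS = ("specimen_id", "morphospecies", "provisional", "provenance")
_OPTIONAL_COLUMNS = ("taxon_class", "locality")
_BOOL_VALUES = {"true": True, "false": False, "1": True, "0": False}


def _tsv_rows(path: Path) -> Iterable[list[str]]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield line.split("\t")


def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read the specimen metadata table.

    Required columns: specimen_id, morphospecies, provisional (true/false),
    provenance (STUDY/EXTERNAL).  Unknown extra columns are preserved in
    ``record.extra``.
    """
    path = Path(path)
    rows = iter(_tsv_rows(path))
    try:
        header = next(rows)
    except StopIteration:
        raise ValueError(f"{path}: empty metadata file") from None
    missing = [c for c in _REQUIRED_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    idx = {name: i for i, name in enumerate(header)}
    records: list[SpecimenRecord] = []
    seen: set[str] = set()
    for lineno, row in enumerate(rows, start=2):
        if len(row) != len(header):
            raise ValueError(f"{path}: row {lineno} has {len(row)} fields, "
                             f"expected {len(header)}")
        cell = {name: row[i] for name, i in idx.items()}
        sid = cell["specimen_id"]
        if sid in seen:
            raise ValueError(f"{path}: duplicate specimen_id {sid!r}")
        seen.add(sid)
        prov_raw = cell["provisional"].strip().lower()
        if prov_raw not in _BOOL_VALUES:
            raise ValueError(
                f"{path}: specimen {sid!r}: provisional must be true/false, "
                f"got {cell['provisional']!r}"
            )
        try:
            provenance = Provenance(cell["provenance"].strip().upper())
        except ValueError:
            raise ValueError(
                f"{path}: specimen {sid!r}: provenance {cell['provenance']!r} "
                f"not in {[p.value for p in Provenance]}"
            ) from None
        extra = {
            name: cell[name]
            for name in header
            if name not in _REQUIRED_COLUMNS + _OPTIONAL_COLUMNS
        }
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                morphospecies=cell["morphospecies"],
                provisional=_BOOL_VALUES[prov_raw],
                provenance=provenance,
                taxon_class=cell.get("taxon_class") or None,
                locality=cell.get("locality") or None,
                extra=extra,
            )
        )
    return records


def write_metadata(records: Sequence[SpecimenRecord], path: str | Path) -> None:
    extra_cols = sorted({k for r in records for k in r.extra})
    header = list(_REQUIRED_COLUMNS + _OPTIONAL_COLUMNS) + extra_cols
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for r in records:
            row = [
                r.specimen_id,
                r.morphospecies,
                "true" if r.provisional else "false",
                r.provenance.value,
                r.taxon_class or "",
                r.locality or "",
            ] + [r.extra.get(c, "") for c in extra_cols]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Partition TSV

def read_partition(path: str | Path, method_name: str | None = None) -> Partition:
    """Read a two-column (specimen_id, group_id) partition table.

    A ``# method: <name>`` comment line supplies the method name unless
    overridden by the argument.  Duplicate rows are deduplicated; the same
    specimen with two different groups is a conflict error.
    """
    path = Path(path)
    embedded = None
    assignment: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("method:"):
                    embedded = body.split(":", 1)[1].strip()
                continue
            parts = line.split("\t")
            if parts == ["specimen_id", "group_id"]:
                continue
            if len(parts) != 2:
                raise PartitionError(f"{path}: line {lineno}: expected 2 fields")
            sid, gid = parts
            if sid in assignment and assignment[sid] != gid:
                raise PartitionError(
                    f"{path}: specimen {sid!r} assigned to both "
                    f"{assignment[sid]!r} and {gid!r}"
                )
            assignment[sid] = gid
    name = method_name or embedded
    if not name:
        raise PartitionError(f"{path}: no method name given or embedded")
    if not assignment:
        raise PartitionError(f"{path}: empty partition")
    return Partition(name, assignment)


def write_partition(partition: Partition, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# method: {partition.method_name}\n")
        fh.write("specimen_id\tgroup_id\n")
        for sid in sorted(partition.assignment):
            fh.write(f"{sid}\t{partition.assignment[sid]}\n")


# ---------------------------------------------------------------------------
# Trees

def read_ultrametric_tree(
    path: str | Path, rel_tolerance: float = 1e-6
) -> dendropy.Tree:
    """Read a rooted Newick tree and verify it is ultrametric.

    All root-to-tip path lengths must agree within ``rel_tolerance`` of the
    tree height.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick", rooting="force-rooted")
    check_ultrametric(tree, rel_tolerance)
    return tree


def check_ultrametric(tree: dendropy.Tree, rel_tolerance: float = 1e-6) -> float:
    """Return the tree height; raise if root-to-tip depths disagree."""
    depths = []
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    if len(depths) < 3:
        raise ValueError("tree must have at least 3 tips")
    height = max(depths)
    if height <= 0:
        raise ValueError("tree has zero height")
    if (height - min(depths)) > rel_tolerance * height:
        raise ValueError(
            f"tree is not ultrametric: root-to-tip depths span "
            f"[{min(depths):.6g}, {height:.6g}]"
        )
    return height


# ---------------------------------------------------------------------------
# Joint validation

@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "warning" | "error"
    code: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    def to_json(self) -> str:
        return json.dumps(
            [i.__dict__ for i in self.issues], indent=2, sort_keys=True
        )


def cross_validate(
    sequences: Sequence[AlignedSequence] | None = None,
    records: Sequence[SpecimenRecord] | None = None,
    trees: Sequence[dendropy.Tree] | None = None,
    partitions: Sequence[Partition] | None = None,
    strict: bool = False,
) -> ValidationReport:
    """Cross-check ids across sequences, metadata, trees and partitions.

    Report-only by default; with ``strict=True`` any issue raises.
    """
    report = ValidationReport()

    def note(code: str, message: str) -> None:
        report.issues.append(ValidationIssue("warning", code, message))

    seq_ids = {s.sequence_id for s in sequences} if sequences else None
    rec_ids = {r.specimen_id for r in records} if records else None
    if seq_ids is not None and rec_ids is not None:
        for sid in sorted(seq_ids - rec_ids):
            note("sequence-without-metadata", f"sequence {sid!r} absent from metadata")
        for sid in sorted(rec_ids - seq_ids):
            note("metadata-without-sequence", f"specimen {sid!r} has no sequence")
    if trees and seq_ids is not None:
        for t_i, tree in enumerate(trees):
            tips = {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon}
            for tip in sorted(tips - seq_ids):
                note("tree-tip-without-sequence",
                     f"tree {t_i}: tip {tip!r} absent from sequences")
    if partitions:
        known = seq_ids if seq_ids is not None else rec_ids
        if known is not None:
            for part in partitions:
                for sid in sorted(part.scope - known):
                    note("partition-id-unknown",
                         f"partition {part.method_name!r}: unknown id {sid!r}")
    if strict and report.issues:
        raise ValueError(
            "strict validation failed:\n"
            + "\n".join(i.message for i in report.issues)
        )
    return report


_PROVISIONAL_HINTS = (" sp.", " cf.", " aff.", " sp ", " indet")


def suggest_provisional(morphospecies: str) -> bool:
    """Advisory: does the label *look* like an open-nomenclature name?

    Never used to set the provisional flag automatically; that flag records
    an expert judgment and is explicit metadata.
    """
    label = f" {morphospecies.lower()} "
    return any(h in label for h in _PROVISIONAL_HINTS) or label.rstrip().endswith(
        " sp."
    )
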