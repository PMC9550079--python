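"""Classify discordances between morphospecies and molecular partitions.

For every morphospecies the delimitation partitions are interrogated twice:
once restricted to the study's own specimens (context ``H``) and once over
the merged study + external-reference scope (context ``A``).  A morphospecies
whose specimens land in two or more putative species under some method has a
*splitting* issue (``S``); distinct morphospecies sharing one putative
species have a *lumping* issue (``L``).  The resolution flag ``R`` marks
issues on which the evaluable methods disagree (some but not all show the
issue); ``_`` marks unanimous issues.  ``H`` strictly dominates ``A``: an
issue already visible within the study data is tagged ``H`` even if also
visible after merging.

Provisionally named morphospecies additionally get a resolution verdict:
whether they stand alone as separate putative species, group with a described
species, or behave differently across methods, together with the nearest
reference-library match below a divergence ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .io import Partition, Provenance, SpecimenRecord
from .refmatch import MatchRecord, normalize_name

__all__ = [
    "Category",
    "DiscordanceRecord",
    "split_status",
    "lump_partners",
    "classify_discordances",
    "ProvisionalVerdict",
    "resolve_provisional",
    "SummaryTables",
    "summarize",
]


class Category:
    CONCORDANT = "CONCORDANT"
    SPLIT = "SPLIT"
    LUMP = "LUMP"


@dataclass(frozen=True)
class DiscordanceRecord:
    """One verdict: a split, a lump (over a label set), or concordance."""

    morphospecies: tuple[str, ...]
    category: str
    resolution_flag: bool = False  # True printed "R": methods disagree
    context: str | None = None  # "H" or "A"; None for concordant records
    methods_triggering: frozenset[str] = frozenset()
    methods_evaluable: frozenset[str] = frozenset()
    detail: str = ""

    def __post_init__(self) -> None:
        if self.category == Category.CONCORDANT:
            if self.resolution_flag or self.context is not None:
                raise ValueError("concordant records carry no flags")
        else:
            if not self.methods_triggering:
                raise ValueError(f"{self.category} requires >=1 triggering method")
            if not self.resolution_flag and (
                self.methods_triggering != self.methods_evaluable
            ):
                raise ValueError(
                    "flag '_' requires the triggering set to equal all "
                    "evaluable methods"
                )

    @property
    def code(self) -> str:
        """Rendered Categ.—Resol.—Context triple, e.g. ``S—R—A``."""
        if self.category == Category.CONCORDANT:
            return "concordant"
        letter = "S" if self.category == Category.SPLIT else "L"
        return f"{letter}—{'R' if self.resolution_flag else '_'}—{self.context}"


def _label_of(records: Sequence[SpecimenRecord]) -> dict[str, str]:
    return {r.specimen_id: normalize_name(r.morphospecies) for r in records}


def split_status(
    morphospecies: str,
    partitions: Sequence[Partition],
    records: Sequence[SpecimenRecord],
    restrict: Provenance | None = None,
) -> dict[str, bool | None]:
    """Per-method: does this morphospecies occupy >= 2 groups?

    ``None`` marks a method whose partition covers none of the morphospecies'
    specimens (not evaluable).  Singleton morphospecies are never split.
    """
    name = normalize_name(morphospecies)
    members = [
        r.specimen_id
        for r in records
        if normalize_name(r.morphospecies) == name
        and (restrict is None or r.provenance == restrict)
    ]
    out: dict[str, bool | None] = {}
    for part in partitions:
        present = [m for m in members if m in part.scope]
        if not present:
            out[part.method_name] = None
        else:
            out[part.method_name] = len({part.assignment[m] for m in present}) >= 2
    return out


def lump_partners(
    morphospecies: str,
    partitions: Sequence[Partition],
    records: Sequence[SpecimenRecord],
    restrict: Provenance | None = None,
) -> dict[str, set[str] | None]:
    """Per-method: other morphospecies sharing a putative species with this one."""
    name = normalize_name(morphospecies)
    label = _label_of(
        [r for r in records if restrict is None or r.provenance == restrict]
    )
    members = [sid for sid, lab in label.items() if lab == name]
    out: dict[str, set[str] | None] = {}
    for part in partitions:
        present = [m for m in members if m in part.scope]
        if not present:
            out[part.method_name] = None
            continue
        my_groups = {part.assignment[m] for m in present}
        partners = {
            lab
            for sid, lab in label.items()
            if sid in part.scope
            and part.assignment[sid] in my_groups
            and lab != name
        }
        out[part.method_name] = partners
    return out


def _split_records(
    morpho_names: list[str],
    records: Sequence[SpecimenRecord],
    parts_study: Sequence[Partition],
    parts_all: Sequence[Partition],
) -> list[DiscordanceRecord]:
    out = []
    for name in morpho_names:
        st_h = split_status(name, parts_study, records, Provenance.STUDY)
        st_a = split_status(name, parts_all, records)
        if any(v for v in st_h.values()):
            context, st = "H", st_h
        elif any(v for v in st_a.values()):
            context, st = "A", st_a
        else:
            continue
        triggering = frozenset(m for m, v in st.items() if v)
        evaluable = frozenset(m for m, v in st.items() if v is not None)
        out.append(
            DiscordanceRecord(
                (name,),
                Category.SPLIT,
                resolution_flag=triggering != evaluable,
                context=context,
                methods_triggering=triggering,
                methods_evaluable=evaluable,
                detail=f"split by {sorted(triggering)} of {sorted(evaluable)}",
            )
        )
    return out


def _lump_components(
    morpho_names: list[str],
    records: Sequence[SpecimenRecord],
    parts_study: Sequence[Partition],
    parts_all: Sequence[Partition],
) -> list[DiscordanceRecord]:
    # partner sets per morphospecies per scope
    partners_h = {
        n: lump_partners(n, parts_study, records, Provenance.STUDY)
        for n in morpho_names
    }
    partners_a = {n: lump_partners(n, parts_all, records) for n in morpho_names}

    # undirected co-lumping graph over morphospecies, union of both scopes
    adjacency: dict[str, set[str]] = {n: set() for n in morpho_names}
    for scope in (partners_h, partners_a):
        for n, per_method in scope.items():
            for ps in per_method.values():
                if ps:
                    adjacency[n].update(p for p in ps if p in adjacency)
                    for p in ps:
                        if p in adjacency:
                            adjacency[p].add(n)

    seen: set[str] = set()
    out = []
    for start in morpho_names:
        if start in seen or not adjacency[start]:
            seen.add(start)
            continue
        component = set()
        stack = [start]
        while stack:
            cur = stack.pop()
            if cur in component:
                continue
            component.add(cur)
            stack.extend(adjacency[cur] - component)
        seen |= component
        members = tuple(sorted(component))

        def scope_methods(partner_map):
            trig, evalu = set(), set()
            for n in members:
                for method, ps in partner_map[n].items():
                    if ps is None:
                        continue
                    evalu.add(method)
                    if ps & component:
                        trig.add(method)
            return frozenset(trig), frozenset(evalu)

        trig_h, eval_h = scope_methods(partners_h)
        if trig_h:
            context, triggering, evaluable = "H", trig_h, eval_h
        else:
            trig_a, eval_a = scope_methods(partners_a)
            context, triggering, evaluable = "A", trig_a, eval_a
        out.append(
            DiscordanceRecord(
                members,
                Category.LUMP,
                resolution_flag=triggering != evaluable,
                context=context,
                methods_triggering=triggering,
                methods_evaluable=evaluable,
                detail=f"lumped by {sorted(triggering)} of {sorted(evaluable)}",
            )
        )
    return out


def classify_discordances(
    records: Sequence[SpecimenRecord],
    partitions_study: Sequence[Partition],
    partitions_all: Sequence[Partition],
) -> list[DiscordanceRecord]:
    """Full per-morphospecies discordance classification.

    ``partitions_study`` and ``partitions_all`` must cover the same method
    set; the first is restricted to study specimens, the second spans the
    merged study + external scope.  Every study morphospecies yields either
    one concordant record or one or more S/L records (a morphospecies can
    carry both a split and a lump).
    """
    methods_study = {p.method_name for p in partitions_study}
    methods_all = {p.method_name for p in partitions_all}
    if methods_study != methods_all:
        raise ValueError(
            f"method sets differ between scopes: {sorted(methods_study)} vs "
            f"{sorted(methods_all)}"
        )
    morpho_names = sorted(
        {
            normalize_name(r.morphospecies)
            for r in records
            if r.provenance == Provenance.STUDY
        }
    )
    out = _split_records(morpho_names, records, partitions_study, partitions_all)
    out += _lump_components(morpho_names, records, partitions_study, partitions_all)
    discordant = {n for rec in out for n in rec.morphospecies}
    for name in morpho_names:
        if name not in discordant:
            out.append(DiscordanceRecord((name,), Category.CONCORDANT))
    return out


# ---------------------------------------------------------------------------
# Provisional-name resolution

@dataclass(frozen=True)
class ProvisionalVerdict:
    """Resolution of one provisionally named morphospecies.

    ``status``: SEPARATE (groups with no described-name record under any
    method), GROUPED_WITH (all methods agree on the described partner
    name(s)), or MIXED (methods disagree; see per-method detail).  The
    nearest-reference note reports the closest library match when its
    distance is below the ceiling, else NO_MATCH.
    """

    morphospecies: str
    status: str  # SEPARATE | GROUPED_WITH | MIXED
    grouped_with: tuple[str, ...] = ()
    per_method: dict = field(default_factory=dict)
    nearest_reference: str | None = None  # None means NO_MATCH
    nearest_distance: float | None = None

    @property
    def reference_note(self) -> str:
        if self.nearest_reference is None:
            return "NO_MATCH"
        return f"{self.nearest_reference} ({100 * self.nearest_distance:.2f}%)"


def resolve_provisional(
    morphospecies: str,
    partitions_all: Sequence[Partition],
    records: Sequence[SpecimenRecord],
    match_table: dict[str, MatchRecord] | None = None,
    threshold: float = 0.05,
) -> ProvisionalVerdict:
    name = normalize_name(morphospecies)
    provisional_labels = {
        normalize_name(r.morphospecies) for r in records if r.provisional
    }
    if name not in provisional_labels:
        raise ValueError(f"{morphospecies!r} is not flagged provisional")
    partners = lump_partners(name, partitions_all, records)
    described: dict[str, frozenset[str]] = {}
    for method, ps in partners.items():
        if ps is None:
            continue
        described[method] = frozenset(p for p in ps if p not in provisional_labels)
    if described and all(not v for v in described.values()):
        status, grouped = "SEPARATE", ()
    elif described and all(v for v in described.values()) and len(
        set(described.values())
    ) == 1:
        status, grouped = "GROUPED_WITH", tuple(sorted(next(iter(described.values()))))
    else:
        status, grouped = "MIXED", ()

    nearest_name = nearest_d = None
    if match_table:
        members = [
            r.specimen_id
            for r in records
            if normalize_name(r.morphospecies) == name
            and r.provenance == Provenance.STUDY
        ]
        best: tuple[float, str] | None = None
        for sid in members:
            rec = match_table.get(sid)
            if rec and rec.matches:
                m = rec.matches[0]
                if best is None or m.distance < best[0]:
                    best = (m.distance, m.reference_name)
        if best is not None and best[0] < threshold:
            nearest_d, nearest_name = best
    return ProvisionalVerdict(
        morphospecies=name,
        status=status,
        grouped_with=grouped,
        per_method={m: sorted(v) for m, v in described.items()},
        nearest_reference=nearest_name,
        nearest_distance=nearest_d,
    )


# ---------------------------------------------------------------------------
# Summary tables

@dataclass
class SummaryTables:
    by_class: pd.DataFrame  # one row per taxon class + "Total"
    discordance_tally: pd.DataFrame  # counts by category / flag / context


def summarize(
    records: Sequence[SpecimenRecord],
    partitions: Sequence[Partition],
    discordances: Sequence[DiscordanceRecord] | None = None,
) -> SummaryTables:
    """Headline counts: specimens, morphospecies, provisional names, and the
    number of putative species per method (groups containing at least one
    study specimen), per taxon class and overall."""
    study = [r for r in records if r.provenance == Provenance.STUDY]
    classes = sorted({r.taxon_class or "unassigned" for r in study})
    rows = []
    for cls in classes + ["Total"]:
        subset = (
            study
            if cls == "Total"
            else [r for r in study if (r.taxon_class or "unassigned") == cls]
        )
        ids = {r.specimen_id for r in subset}
        row = {
            "taxon_class": cls,
            "n_specimens": len(subset),
            "n_morphospecies": len(
                {normalize_name(r.morphospecies) for r in subset}
            ),
            "n_provisional": len(
                {
                    normalize_name(r.morphospecies)
                    for r in subset
                    if r.provisional
                }
            ),
        }
        for part in partitions:
            groups = {
                part.assignment[sid] for sid in ids if sid in part.scope
            }
            row[f"n_putative_{part.method_name}"] = len(groups)
        rows.append(row)
    by_class = pd.DataFrame(rows)

    tally_rows = []
    if discordances:
        counts: dict[tuple[str, str, str], int] = {}
        for rec in discordances:
            if rec.category == Category.CONCORDANT:
                key = ("CONCORDANT", "", "")
            else:
                key = (
                    rec.category,
                    "R" if rec.resolution_flag else "_",
                    rec.context or "",
                )
            counts[key] = counts.get(key, 0) + 1
        tally_rows = [
            {"category": c, "flag": f, "context": x, "count": n}
            for (c, f, x), n in sorted(counts.items())
        ]
    tally = pd.DataFrame(
        tally_rows, columns=["category", "flag", "context", "count"]
    )
    return SummaryTables(by_class=by_class, discordance_tally=tally)
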