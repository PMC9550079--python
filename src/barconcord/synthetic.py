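"""Synthetic aligned-barcode datasets with known species truth.

The generator emulates the statistical structure a barcode-gap analysis
assumes: clusters of near-identical sequences (within-species variation)
separated by much larger between-species divergences.  Species ancestors sit
on a simulated pure-birth tree whose depth is rescaled so the *closest* pair
of species diverges by the target interspecific p-distance; individuals then
evolve from their species ancestor so that within-species pairs hit the
target intraspecific p-distance in expectation.  Substitution follows a
Jukes-Cantor-style process: per site, a branch of length b (substitutions per
site) changes the base with probability 3/4 (1 - exp(-4b/3)), uniformly to
one of the other three bases, so realized p-distances match the targets in
expectation.

Scenario injections rewrite morphospecies *labels* only — the truth partition
(the species assignment) is never touched — so every injected discordance is
recoverable downstream:

* ``CrypticSplit``: two species share one label (a splitting issue);
* ``Lump``: one species carries two labels (a lumping issue);
* ``Misid``: random label swaps at a given rate;
* ``ProvisionalFraction``: a share of study morphospecies marked provisional;
* ``ShortFragment``: flank-masking of a share of study sequences.

Not emulated: codon structure, rate heterogeneity, selection, recombination
and coalescent demography.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .distances import p_distance_matrix
from .io import AlignedSequence, Partition, Provenance, SpecimenRecord

__all__ = [
    "CrypticSplit",
    "Lump",
    "Misid",
    "ProvisionalFraction",
    "ShortFragment",
    "SyntheticConfig",
    "GeneratedDataset",
    "generate",
    "calibration_report",
    "simulate_yule_tree",
]

_BASES = "ACGT"


def jc_branch_length(p: float) -> float:
    """Substitutions per site giving expected p-distance ``p`` (JC inversion)."""
    if not 0 <= p < 0.75:
        raise ValueError("target p-distance must be in [0, 0.75)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def jc_expected_p(branch_length: float) -> float:
    return 0.75 * (1.0 - math.exp(-4.0 * branch_length / 3.0))


@dataclass(frozen=True)
class CrypticSplit:
    """Give one morphospecies label to two distinct true species."""

    species_a: int
    species_b: int | None = None  # default: nearest neighbour of species_a


@dataclass(frozen=True)
class Lump:
    """Assign two morphospecies labels within one true species."""

    species: int


@dataclass(frozen=True)
class Misid:
    """Swap each study specimen's label to a random other species' label."""

    rate: float


@dataclass(frozen=True)
class ProvisionalFraction:
    """Mark a share of study morphospecies as provisionally named."""

    fraction: float


@dataclass(frozen=True)
class ShortFragment:
    """Mask the flanks of a share of study sequences down to ``length`` sites."""

    fraction: float
    length: int


Scenario = CrypticSplit | Lump | Misid | ProvisionalFraction | ShortFragment


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic barcode dataset.

    ``intra_divergence``/``inter_divergence`` are expected p-distances within
    a species and between the closest species pair; their ratio is the
    barcode-gap ratio.  ``reference_fraction`` of the specimens are labeled
    EXTERNAL (a local reference library with described names);
    ``ref_provisional_fraction`` of those get provisional labels to exercise
    the match-exclusion rules.  The seed is mandatory.
    """

    n_species: int = 8
    samples_per_species: int | Sequence[int] = 4
    seq_length: int = 650
    intra_divergence: float = 0.01
    inter_divergence: float = 0.10
    max_divergence: float = 0.25
    scenarios: tuple[Scenario, ...] = ()
    reference_fraction: float = 0.25
    ref_provisional_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inter_divergence <= self.intra_divergence:
            raise ValueError("inter_divergence must exceed intra_divergence")
        if not self.inter_divergence <= self.max_divergence < 0.75:
            raise ValueError("need inter_divergence <= max_divergence < 0.75")
        for frac in (self.reference_fraction, self.ref_provisional_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_species < 1 or self.seq_length < 1:
            raise ValueError("n_species and seq_length must be positive")

    def samples(self) -> list[int]:
        if isinstance(self.samples_per_species, int):
            return [self.samples_per_species] * self.n_species
        sizes = list(self.samples_per_species)
        if len(sizes) != self.n_species:
            raise ValueError("samples_per_species list must have n_species entries")
        return sizes


@dataclass
class GeneratedDataset:
    sequences: list[AlignedSequence]
    records: list[SpecimenRecord]
    truth: Partition
    ledger: list[dict]
    tree: dendropy.Tree
    config: SyntheticConfig


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Pure-birth tree with ``n_tips`` extant tips (ultrametric by design).

    The simulator stops at the n-th speciation, which leaves the youngest
    pair of tips with zero-length branches; the process is continued by one
    further exponential waiting time (rate ``n_tips * birth_rate``) added to
    every terminal branch, as in the reconstructed Yule process.
    """
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    tree.is_rooted = True
    extra = rng.expovariate(n_tips * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    return tree


def _mutate(seq: np.ndarray, branch_length: float, rng: np.random.Generator
            ) -> np.ndarray:
    p_change = jc_expected_p(branch_length)
    hit = rng.random(seq.size) < p_change
    out = seq.copy()
    # uniform choice among the three alternative bases
    out[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[c] for c in seq)


def generate(config: SyntheticConfig) -> GeneratedDataset:
    """Generate one dataset (sequences, metadata, truth partition, ledger,
    true ultrametric genealogy).  Byte-identical for a fixed config."""
    rng = np.random.default_rng(config.seed)
    k = config.n_species
    sizes = config.samples()

    # --- species ancestors on a rescaled pure-birth tree
    if k == 1:
        species_tree = None
        intra_height = jc_branch_length(config.intra_divergence) / 2.0
        intra_height_of = {0: intra_height}
        ancestors = {0: rng.integers(0, 4, size=config.seq_length, dtype=np.int8)}
        tip_order = [0]
    else:
        species_tree = simulate_yule_tree(
            k, seed=int(rng.integers(0, 2**31 - 1))
        )
        # affine recalibration of node heights: the shallowest split maps to
        # the sister-species target, the root to max_divergence (COI
        # saturates near 25%), keeping depth heterogeneity realistic
        depth: dict = {}
        for node in species_tree.preorder_node_iter():
            depth[node] = (
                0.0 if node.parent_node is None
                else depth[node.parent_node] + (node.edge.length or 0.0)
            )
        root_depth = max(depth[lf] for lf in species_tree.leaf_node_iter())
        height = {
            n: 0.0 if n.is_leaf() else root_depth - d
            for n, d in depth.items()
        }
        internal_heights = [
            height[n] for n in species_tree.preorder_internal_node_iter()
        ]
        h_min, h_root = min(internal_heights), max(internal_heights)
        target_min = jc_branch_length(config.inter_divergence) / 2.0
        target_root = jc_branch_length(config.max_divergence) / 2.0
        if h_root > h_min:
            alpha = (target_root - target_min) / (h_root - h_min)
            beta = target_min - alpha * h_min
        else:  # two species: a single split
            alpha, beta = target_min / h_min, 0.0

        def remap(h: float) -> float:
            return 0.0 if h == 0.0 else alpha * h + beta

        for node in species_tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = remap(height[node.parent_node]) - remap(
                    height[node]
                )
        intra_height = jc_branch_length(config.intra_divergence) / 2.0
        intra_height_of: dict[int, float] = {}

        root_seq = rng.integers(0, 4, size=config.seq_length, dtype=np.int8)
        seq_at: dict = {}
        for node in species_tree.preorder_node_iter():
            if node.parent_node is None:
                seq_at[node] = root_seq
            else:
                seq_at[node] = _mutate(
                    seq_at[node.parent_node], node.edge.length or 0.0, rng
                )
        leaves = sorted(
            species_tree.leaf_node_iter(), key=lambda n: n.taxon.label
        )
        ancestors = {i: seq_at[leaf] for i, leaf in enumerate(leaves)}
        tip_order = list(range(k))
        # graft individuals onto the species tree to form the genealogy:
        # a binary near-star ladder of coalescences staggered within 20%
        # below the mean within-species coalescent depth (keeps the tree
        # binary and ultrametric while sequences evolve star-like)
        for i, leaf in enumerate(leaves):
            size = sizes[i]
            # species differ in intraspecific diversity: jitter the
            # within-species depth by +/-25% around the target
            h_i = intra_height * float(rng.uniform(0.75, 1.25))
            intra_height_of[i] = h_i
            leaf_taxon = leaf.taxon
            leaf.taxon = None

            def make_tip(j: int) -> dendropy.Node:
                taxon = dendropy.Taxon(label=_individual_id(i, j))
                species_tree.taxon_namespace.add_taxon(taxon)
                return dendropy.Node(taxon=taxon)

            if size == 1:
                leaf.taxon = species_tree.taxon_namespace.new_taxon(
                    label=_individual_id(i, 0)
                )
            else:
                leaf.edge.length = (leaf.edge.length or 0.0) - h_i
                if leaf.edge.length <= 0:
                    raise ValueError(
                        "species terminal branch shorter than the "
                        "within-species depth; increase the gap ratio"
                    )
                event_heights = np.sort(
                    rng.uniform(0.8 * h_i, h_i * (1 - 1e-6),
                                size=max(size - 2, 0))
                )
                current = make_tip(0)
                current_height = 0.0
                for j in range(1, size - 1):
                    h = float(event_heights[j - 1])
                    internal = dendropy.Node()
                    internal.add_child(current)
                    current.edge.length = h - current_height
                    tip = make_tip(j)
                    internal.add_child(tip)
                    tip.edge.length = h
                    current, current_height = internal, h
                leaf.add_child(current)
                current.edge.length = h_i - current_height
                tip = make_tip(size - 1)
                leaf.add_child(tip)
                tip.edge.length = h_i
            species_tree.taxon_namespace.remove_taxon(leaf_taxon)

    # --- individuals
    sequences: list[AlignedSequence] = []
    species_of: dict[str, int] = {}
    for i in tip_order:
        for j in range(sizes[i]):
            sid = _individual_id(i, j)
            seq = _mutate(ancestors[i], intra_height_of[i], rng)
            sequences.append(AlignedSequence(sid, _decode(seq)))
            species_of[sid] = i

    # --- provenance split: per species, round(fraction * n) become EXTERNAL
    provenance: dict[str, Provenance] = {}
    for i in tip_order:
        ids = [_individual_id(i, j) for j in range(sizes[i])]
        n_ref = int(round(config.reference_fraction * len(ids)))
        for sid in ids[: len(ids) - n_ref]:
            provenance[sid] = Provenance.STUDY
        for sid in ids[len(ids) - n_ref:]:
            provenance[sid] = Provenance.EXTERNAL

    labels = {sid: _species_label(i) for sid, i in species_of.items()}
    provisional: dict[str, bool] = {sid: False for sid in labels}
    ledger: list[dict] = []

    # --- scenario injections (labels only; truth untouched)
    study_ids = [s for s in labels if provenance[s] == Provenance.STUDY]
    for scenario in config.scenarios:
        if isinstance(scenario, CrypticSplit):
            a = scenario.species_a
            b = scenario.species_b
            if b is None:
                b = _nearest_species(a, ancestors, k)
            for sid, sp in species_of.items():
                if sp == b:
                    labels[sid] = _species_label(a)
            ledger.append(
                {"type": "SPLIT", "label": _species_label(a),
                 "species": sorted([a, b])}
            )
        elif isinstance(scenario, Lump):
            members = [s for s, sp in species_of.items() if sp == scenario.species]
            if len(members) < 2:
                raise ValueError("Lump scenario needs >=2 individuals")
            second = _species_label(scenario.species) + "-B"
            for sid in members[len(members) // 2:]:
                labels[sid] = second
            # record the labels actually carried (an earlier injection may
            # have relabeled the first half)
            ledger.append(
                {"type": "LUMP",
                 "labels": sorted({labels[m] for m in members}),
                 "species": scenario.species}
            )
        elif isinstance(scenario, Misid):
            swapped = []
            for sid in study_ids:
                if rng.random() < scenario.rate:
                    other = int(rng.integers(0, k))
                    if other == species_of[sid]:
                        other = (other + 1) % k
                    labels[sid] = _species_label(other)
                    swapped.append(sid)
            ledger.append({"type": "MISID", "specimens": swapped})
        elif isinstance(scenario, ProvisionalFraction):
            study_labels = sorted({labels[s] for s in study_ids})
            n_prov = int(round(scenario.fraction * len(study_labels)))
            chosen = list(
                rng.choice(len(study_labels), size=n_prov, replace=False)
            )
            chosen_labels = {study_labels[c] for c in chosen}
            for sid in study_ids:
                if labels[sid] in chosen_labels:
                    provisional[sid] = True
            ledger.append(
                {"type": "PROVISIONAL", "labels": sorted(chosen_labels)}
            )
        elif isinstance(scenario, ShortFragment):
            n_short = int(round(scenario.fraction * len(study_ids)))
            chosen = sorted(
                rng.choice(len(study_ids), size=n_short, replace=False).tolist()
            )
            shortened = []
            for c in chosen:
                sid = study_ids[c]
                idx = next(
                    i for i, s in enumerate(sequences) if s.sequence_id == sid
                )
                seq = sequences[idx].residues
                keep = min(scenario.length, len(seq))
                start = (len(seq) - keep) // 2
                masked = (
                    "-" * start + seq[start: start + keep]
                    + "-" * (len(seq) - start - keep)
                )
                sequences[idx] = AlignedSequence(sid, masked)
                shortened.append(sid)
            ledger.append({"type": "SHORT_FRAGMENT", "specimens": shortened})
        else:  # pragma: no cover - guarded by the Scenario union
            raise ValueError(f"unknown scenario {scenario!r}")

    # reference records keep described species names; optionally some become
    # provisionally named to exercise the match-exclusion rules
    ref_ids = [s for s in labels if provenance[s] == Provenance.EXTERNAL]
    if config.ref_provisional_fraction > 0 and ref_ids:
        n_prov = int(round(config.ref_provisional_fraction * len(ref_ids)))
        for c in rng.choice(len(ref_ids), size=n_prov, replace=False):
            provisional[ref_ids[int(c)]] = True

    records = [
        SpecimenRecord(
            specimen_id=sid,
            morphospecies=labels[sid],
            provisional=provisional[sid],
            provenance=provenance[sid],
            taxon_class="Synthetica",
        )
        for sid in sorted(labels)
    ]
    truth = Partition(
        "truth", {sid: _species_label(i) for sid, i in species_of.items()}
    )
    tree = species_tree if k > 1 else None
    return GeneratedDataset(sequences, records, truth, ledger, tree, config)


def _individual_id(species: int, index: int) -> str:
    return f"SP{species + 1:02d}_I{index + 1:02d}"


def _species_label(species: int) -> str:
    return f"Species {species + 1:02d}"


def _nearest_species(a: int, ancestors: dict[int, np.ndarray], k: int) -> int:
    best, best_d = None, None
    for b in range(k):
        if b == a:
            continue
        d = float((ancestors[a] != ancestors[b]).mean())
        if best_d is None or d < best_d:
            best, best_d = b, d
    return best


def calibration_report(
    sequences: Sequence[AlignedSequence],
    labels: dict[str, str],
    min_overlap: int = 100,
) -> dict:
    """Realized divergence summary: per-species max intra, global min inter,
    gap ratio.  Inter is None (and the ratio undefined) with a single species."""
    dm = p_distance_matrix(list(sequences), min_overlap=min_overlap)
    per_species: dict[str, float] = {}
    min_inter = None
    max_intra_global = 0.0
    n = len(dm.ids)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(dm.d[i, j])
            if math.isnan(d):
                continue
            same = labels[dm.ids[i]] == labels[dm.ids[j]]
            if same:
                lab = labels[dm.ids[i]]
                per_species[lab] = max(per_species.get(lab, 0.0), d)
                max_intra_global = max(max_intra_global, d)
            else:
                min_inter = d if min_inter is None else min(min_inter, d)
    ratio = (
        None
        if min_inter is None or max_intra_global == 0
        else min_inter / max_intra_global
    )
    return {
        "max_intra_per_species": per_species,
        "max_intra": max_intra_global,
        "min_inter": min_inter,
        "gap_ratio": ratio,
    }
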