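import numpy as np
import pytest

import barconcord as bc
from barconcord.concordance import Category
from barconcord.io import Provenance

from .conftest import make_records


def part(name, assignment):
    return bc.Partition(name, assignment)


class TestSplitStatus:
    records = make_records({"a": "X", "b": "X", "c": "X", "d": "Y"})

    def test_one_group_not_split(self):
        p = part("m", {"a": "g1", "b": "g1", "c": "g1", "d": "g2"})
        assert bc.split_status("X", [p], self.records) == {"m": False}

    def test_two_groups_split(self):
        p = part("m", {"a": "g1", "b": "g2", "c": "g1", "d": "g3"})
        assert bc.split_status("X", [p], self.records) == {"m": True}

    def test_singleton_never_split(self):
        p = part("m", {"a": "g1", "b": "g1", "c": "g1", "d": "g2"})
        assert bc.split_status("Y", [p], self.records) == {"m": False}

    def test_absent_morphospecies_not_evaluable(self):
        p = part("m", {"d": "g2"})
        assert bc.split_status("X", [p], self.records) == {"m": None}


class TestLumpPartners:
    records = make_records(
        {"a": "X", "b": "Y", "c": "Z", "d": "X", "e": "W"}
    )

    def test_shared_group_yields_partner(self):
        p = part("m", {"a": "g1", "b": "g1", "c": "g2", "d": "g3", "e": "g4"})
        assert bc.lump_partners("X", [p], self.records) == {"m": {"Y"}}

    def test_pure_groups_yield_empty_set(self):
        p = part("m", {"a": "g1", "b": "g2", "c": "g3", "d": "g1", "e": "g4"})
        assert bc.lump_partners("X", [p], self.records) == {"m": set()}

    def test_three_way_group(self):
        p = part("m", {"a": "g1", "b": "g1", "c": "g1", "d": "g2", "e": "g3"})
        assert bc.lump_partners("X", [p], self.records) == {"m": {"Y", "Z"}}


def classify(records, parts_all):
    study = {
        r.specimen_id for r in records if r.provenance == Provenance.STUDY
    }
    parts_study = [p.restrict(study) for p in parts_all]
    return bc.classify_discordances(records, parts_study, parts_all)


def by_category(records_out):
    out = {}
    for rec in records_out:
        out.setdefault(rec.category, []).append(rec)
    return out


class TestClassify:
    def test_unanimous_split_within_study_data(self):
        records = make_records({"a": "X", "b": "X", "c": "Y"})
        parts = [
            part("m1", {"a": "g1", "b": "g2", "c": "g3"}),
            part("m2", {"a": "h1", "b": "h2", "c": "h3"}),
        ]
        out = classify(records, parts)
        split = by_category(out)[Category.SPLIT]
        assert len(split) == 1
        assert split[0].morphospecies == ("X",)
        assert split[0].code == "S—_—H"

    def test_partial_split_carries_resolution_flag(self):
        records = make_records({"a": "X", "b": "X", "c": "Y"})
        parts = [
            part("m1", {"a": "g1", "b": "g2", "c": "g3"}),
            part("m2", {"a": "h1", "b": "h1", "c": "h3"}),
        ]
        out = classify(records, parts)
        split = by_category(out)[Category.SPLIT][0]
        assert split.code == "S—R—H"
        assert split.methods_triggering == {"m1"}

    def test_lump_only_after_merging_external_data(self):
        records = make_records(
            {"a": "X", "b": "Y", "ext": "Y"}, external={"ext"}
        )
        parts = [
            part("m1", {"a": "g1", "b": "g2", "ext": "g1"}),
            part("m2", {"a": "h1", "b": "h2", "ext": "h1"}),
        ]
        out = classify(records, parts)
        lump = by_category(out)[Category.LUMP][0]
        assert lump.morphospecies == ("X", "Y")
        assert lump.code == "L—_—A"

    def test_h_context_dominates_a(self):
        records = make_records(
            {"a": "X", "b": "Y", "ext": "Y"}, external={"ext"}
        )
        parts = [part("m1", {"a": "g1", "b": "g1", "ext": "g1"})]
        out = classify(records, parts)
        lump = by_category(out)[Category.LUMP][0]
        assert lump.context == "H"

    def test_same_morphospecies_can_split_and_lump(self):
        records = make_records({"a": "X", "b": "X", "c": "Y"})
        parts = [part("m1", {"a": "g1", "b": "g2", "c": "g2"})]
        out = classify(records, parts)
        cats = by_category(out)
        assert cats[Category.SPLIT][0].morphospecies == ("X",)
        assert cats[Category.LUMP][0].morphospecies == ("X", "Y")

    def test_lump_component_emitted_once_for_connected_set(self):
        records = make_records({"a": "X", "b": "Y", "c": "Z"})
        parts = [
            part("m1", {"a": "g1", "b": "g1", "c": "g2"}),
            part("m2", {"a": "h1", "b": "h2", "c": "h2"}),
        ]
        out = classify(records, parts)
        lumps = by_category(out)[Category.LUMP]
        assert len(lumps) == 1
        assert lumps[0].morphospecies == ("X", "Y", "Z")

    def test_method_set_mismatch_rejected(self):
        records = make_records({"a": "X"})
        with pytest.raises(ValueError, match="method sets"):
            bc.classify_discordances(
                records, [part("m1", {"a": "g"})], [part("m2", {"a": "g"})]
            )

    def test_every_morphospecies_classified_exactly_once(self):
        # completeness: concordant XOR discordant, for every morphospecies
        ds = bc.generate(bc.SyntheticConfig(
            n_species=6, samples_per_species=4, seed=9,
            scenarios=(bc.CrypticSplit(0), bc.Lump(3)),
        ))
        dm = bc.p_distance_matrix(ds.sequences)
        parts = [bc.abgd_partition(dm, 0.02), bc.single_linkage_partition(dm)]
        out = classify(ds.records, parts)
        study_names = {
            r.morphospecies
            for r in ds.records
            if r.provenance == Provenance.STUDY
        }
        concordant = {
            r.morphospecies[0]
            for r in out
            if r.category == Category.CONCORDANT
        }
        discordant = {
            name
            for r in out
            if r.category != Category.CONCORDANT
            for name in r.morphospecies
        }
        assert concordant | discordant >= study_names
        assert not (concordant & discordant)

    def test_deterministic_output(self):
        records = make_records({"a": "X", "b": "X", "c": "Y"})
        parts = [part("m1", {"a": "g1", "b": "g2", "c": "g2"})]
        assert classify(records, parts) == classify(records, parts)


class TestResolveProvisional:
    def records(self):
        return make_records(
            {"p1": "Aster sp.", "p2": "Aster sp.", "r1": "Aster prima",
             "r2": "Aster secunda"},
            provisional={"p1", "p2"},
            external={"r1", "r2"},
        )

    def match_table(self, dist):
        m = bc.refmatch.Match("r1", "Aster prima", dist, "NAME_MATCH")
        return {
            "p1": bc.MatchRecord("p1", [m]),
            "p2": bc.MatchRecord("p2", []),
        }

    def test_separate_with_no_match(self):
        parts = [
            part("m1", {"p1": "g1", "p2": "g1", "r1": "g2", "r2": "g3"}),
            part("m2", {"p1": "h1", "p2": "h1", "r1": "h2", "r2": "h3"}),
        ]
        v = bc.resolve_provisional("Aster sp.", parts, self.records(),
                                   self.match_table(0.09))
        assert v.status == "SEPARATE"
        assert v.reference_note == "NO_MATCH"

    def test_grouped_with_described_species(self):
        parts = [
            part("m1", {"p1": "g1", "p2": "g1", "r1": "g1", "r2": "g3"}),
            part("m2", {"p1": "h1", "p2": "h1", "r1": "h1", "r2": "h3"}),
        ]
        v = bc.resolve_provisional("Aster sp.", parts, self.records(),
                                   self.match_table(0.008))
        assert v.status == "GROUPED_WITH"
        assert v.grouped_with == ("Aster prima",)
        assert "Aster prima" in v.reference_note

    def test_mixed_when_methods_disagree(self):
        parts = [
            part("m1", {"p1": "g1", "p2": "g1", "r1": "g1", "r2": "g3"}),
            part("m2", {"p1": "h1", "p2": "h1", "r1": "h2", "r2": "h3"}),
        ]
        v = bc.resolve_provisional("Aster sp.", parts, self.records())
        assert v.status == "MIXED"
        assert v.per_method == {"m1": ["Aster prima"], "m2": []}

    def test_non_provisional_rejected(self):
        with pytest.raises(ValueError, match="provisional"):
            bc.resolve_provisional("Aster prima", [], self.records())


class TestSummarize:
    def test_toy_counts(self):
        labels = {f"s{i}": ["X", "X", "X", "Y", "Y", "Z", "Z", "Z", "W",
                            "W"][i] for i in range(10)}
        records = make_records(labels, provisional={"W"})
        partition = part(
            "mx", {f"s{i}": f"g{i % 5}" for i in range(10)}
        )
        tables = bc.summarize(records, [partition])
        row = tables.by_class[tables.by_class.taxon_class == "Total"].iloc[0]
        assert (
            row.n_specimens,
            row.n_morphospecies,
            row.n_provisional,
            row.n_putative_mx,
        ) == (10, 4, 1, 5)

    def test_external_only_groups_not_counted(self):
        records = make_records(
            {"a": "X", "ext": "Y"}, external={"ext"}
        )
        partition = part("mx", {"a": "g1", "ext": "g2"})
        tables = bc.summarize(records, [partition])
        total = tables.by_class.iloc[-1]
        assert total.n_putative_mx == 1

    def test_counts_match_bruteforce_recount_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = 12
            labels = {
                f"s{i}": f"M{rng.integers(0, 4)}" for i in range(n)
            }
            records = make_records(labels)
            partition = part(
                "mx", {f"s{i}": f"g{rng.integers(0, 6)}" for i in range(n)}
            )
            tables = bc.summarize(records, [partition])
            total = tables.by_class.iloc[-1]
            assert total.n_specimens == n
            assert total.n_morphospecies == len(set(labels.values()))
            assert total.n_putative_mx == len(
                {partition.assignment[s] for s in labels}
            )

    def test_discordance_tally(self):
        records = make_records({"a": "X", "b": "X", "c": "Y"})
        parts = [part("m1", {"a": "g1", "b": "g2", "c": "g3"})]
        out = classify(records, parts)
        tables = bc.summarize(records, parts, out)
        tally = tables.discordance_tally
        srow = tally[tally.category == "SPLIT"].iloc[0]
        assert (srow.flag, srow.context, srow["count"]) == ("_", "H", 1)
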