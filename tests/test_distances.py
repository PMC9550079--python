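import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import barconcord as bc
from barconcord.distances import encode_alignment

from .conftest import naive_p_distance

ALPHABET = "ACGTN-"


def random_alignment(rng, n, length, alphabet=ALPHABET):
    return [
        bc.AlignedSequence(
            f"q{i:02d}",
            "".join(rng.choice(list(alphabet), size=length)),
        )
        for i in range(n)
    ]


class TestPDistance:
    def test_single_mismatch_in_four_sites(self):
        dm = bc.p_distance_matrix(
            [bc.AlignedSequence("a", "ACGT"), bc.AlignedSequence("b", "ACGA")],
            min_overlap=1,
        )
        assert dm.get("a", "b") == pytest.approx(0.25)

    def test_pairwise_deletion_skips_gapped_site(self):
        dm = bc.p_distance_matrix(
            [bc.AlignedSequence("a", "ACG-"), bc.AlignedSequence("b", "ACGT")],
            min_overlap=1,
        )
        assert dm.get("a", "b") == 0.0
        assert dm.overlap[0, 1] == 3

    def test_ambiguity_codes_excluded_like_n(self):
        dm = bc.p_distance_matrix(
            [bc.AlignedSequence("a", "RCGT"), bc.AlignedSequence("b", "ACGA")],
            min_overlap=1,
        )
        assert dm.overlap[0, 1] == 3
        assert dm.get("a", "b") == pytest.approx(1 / 3)

    def test_low_overlap_pair_is_undefined(self):
        dm = bc.p_distance_matrix(
            [bc.AlignedSequence("a", "AC--"), bc.AlignedSequence("b", "ACGT")],
            min_overlap=3,
        )
        assert math.isnan(dm.get("a", "b"))
        assert dm.get("a", "a") == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_recount_on_random_alignments(self, seed):
        rng = np.random.default_rng(seed)
        seqs = random_alignment(rng, 8, 300)
        dm = bc.p_distance_matrix(seqs, min_overlap=1)
        for i, a in enumerate(seqs):
            for j, b in enumerate(seqs):
                expect, overlap = naive_p_distance(a.residues, b.residues)
                assert dm.overlap[i, j] == overlap
                if i == j:
                    assert dm.d[i, j] == 0.0
                elif expect is None:
                    assert math.isnan(dm.d[i, j])
                else:
                    assert dm.d[i, j] == pytest.approx(expect)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.text(alphabet=ALPHABET, min_size=20, max_size=20),
            min_size=2,
            max_size=6,
        ).filter(lambda rows: all(set(r) - set("N-") for r in rows))
    )
    def test_symmetry_and_zero_diagonal(self, rows):
        seqs = [bc.AlignedSequence(f"h{i}", r) for i, r in enumerate(rows)]
        dm = bc.p_distance_matrix(seqs, min_overlap=1)
        assert np.allclose(np.diag(dm.d), 0.0)
        both = dm.d.copy()
        assert np.array_equal(np.isnan(both), np.isnan(both.T))
        both[np.isnan(both)] = -1
        assert np.allclose(both, both.T)
        assert np.array_equal(dm.overlap, dm.overlap.T)

    def test_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        dm = bc.p_distance_matrix(random_alignment(rng, 5, 60), min_overlap=30)
        path = tmp_path / "d.tsv"
        dm.write_tsv(path)
        back = bc.DistanceMatrix.read_tsv(path, min_overlap=30)
        assert back.ids == dm.ids
        assert np.allclose(
            np.nan_to_num(back.d, nan=-1), np.nan_to_num(dm.d, nan=-1)
        )


class TestTrim:
    def test_fully_overlapping_set_untouched(self):
        rng = np.random.default_rng(0)
        seqs = random_alignment(rng, 3, 200, alphabet="ACGT")
        kept, removed = bc.trim_to_common_overlap(seqs, min_common=150)
        assert removed == []
        assert kept == seqs

    def test_fragment_removed_to_restore_core(self):
        core = "ACGT" * 125  # 500 sites
        long_a = bc.AlignedSequence("long_a", core)
        long_b = bc.AlignedSequence("long_b", core[:-1] + "A")
        frag = bc.AlignedSequence("frag", "-" * 400 + core[400:])
        kept, removed = bc.trim_to_common_overlap(
            [long_a, frag, long_b], min_common=150
        )
        assert removed == ["frag"]
        assert [s.sequence_id for s in kept] == ["long_a", "long_b"]

    def test_error_when_unreachable_even_with_two(self):
        a = bc.AlignedSequence("a", "ACGT" + "-" * 96)
        b = bc.AlignedSequence("b", "-" * 96 + "ACGT")
        with pytest.raises(ValueError, match="common overlap"):
            bc.trim_to_common_overlap([a, b], min_common=150)

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_first_removal_beats_any_single_alternative(self, seed):
        # the first greedy removal achieves a common overlap at least as
        # large as removing any other single sequence would
        rng = np.random.default_rng(seed)
        seqs = random_alignment(rng, 10, 120, alphabet="ACGT-N")
        mat = encode_alignment(seqs)
        valid = mat >= 0

        def common(exclude):
            rows = [i for i in range(len(seqs)) if i != exclude]
            return int(valid[rows].all(axis=0).sum())

        baseline = int(valid.all(axis=0).sum())
        kept, removed = bc.trim_to_common_overlap(
            seqs, min_common=baseline + 1
        )
        if removed:
            first = [s.sequence_id for s in seqs].index(removed[0])
            best_single = max(common(i) for i in range(len(seqs)))
            assert common(first) == best_single


class TestMaxWithin:
    def make(self, residues_by_id, labels):
        seqs = [bc.AlignedSequence(k, v) for k, v in residues_by_id.items()]
        dm = bc.p_distance_matrix(seqs, min_overlap=1)
        from .conftest import make_records

        return dm, make_records(labels)

    def test_identical_pair_gives_zero(self):
        dm, recs = self.make(
            {"a": "ACGTACGT", "b": "ACGTACGT"}, {"a": "X", "b": "X"}
        )
        assert bc.max_within(dm, recs, "X") == 0.0

    def test_maximum_over_three_members(self):
        dm, recs = self.make(
            {"a": "AAAAAAAA", "b": "AAAAAAAT", "c": "AATTTTTT"},
            {"a": "X", "b": "X", "c": "X"},
        )
        assert bc.max_within(dm, recs, "X") == pytest.approx(6 / 8)

    def test_single_member_gives_none(self):
        dm, recs = self.make({"a": "ACGTACGT"}, {"a": "X"})
        assert bc.max_within(dm, recs, "X") is None

    def test_provenance_filter(self):
        dm, recs = self.make(
            {"a": "AAAAAAAA", "b": "TTTTAAAA"}, {"a": "X", "b": "X"}
        )
        recs = [
            r if r.specimen_id == "a"
            else bc.SpecimenRecord("b", "X", False, bc.Provenance.EXTERNAL)
            for r in recs
        ]
        assert bc.max_within(dm, recs, "X", bc.Provenance.STUDY) is None
        assert bc.max_within(dm, recs, "X") == pytest.approx(0.5)
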