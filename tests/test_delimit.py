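import itertools

import numpy as np
import pytest

import barconcord as bc
from barconcord.delimit import BestMatchResult, assign_group_by_best_match

from .conftest import UnionFind, as_group_sets


def matrix_from(ids, dist, min_overlap=100, overlap=650):
    n = len(ids)
    d = np.zeros((n, n))
    for (i, j), v in dist.items():
        d[i, j] = d[j, i] = v
    ov = np.full((n, n), overlap, dtype=np.int64)
    return bc.DistanceMatrix(list(ids), d, ov, min_overlap)


def two_cluster_toy():
    # two tight clusters: intra <= 0.01, inter >= 0.10
    ids = list("abcdef")
    dist = {}
    for i, j in itertools.combinations(range(6), 2):
        same = (i < 3) == (j < 3)
        dist[(i, j)] = 0.01 if same else 0.10 + 0.001 * (i + j)
    return matrix_from(ids, dist)


class TestAbgdPartition:
    def test_two_clean_clusters_found(self):
        part = bc.abgd_partition(two_cluster_toy(), prior=0.02)
        assert as_group_sets(part) == {
            frozenset("abc"), frozenset("def"),
        }

    def test_all_zero_distances_one_group(self):
        dm = matrix_from(list("abcd"), {})
        part = bc.abgd_partition(dm, prior=0.02)
        assert part.n_groups() == 1

    def test_single_specimen_is_singleton_group(self):
        dm = matrix_from(["only"], {})
        part = bc.abgd_partition(dm, prior=0.02)
        assert part.assignment.keys() == {"only"}

    def test_undefined_pairs_rejected(self):
        dm = two_cluster_toy()
        dm.d[0, 1] = dm.d[1, 0] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            bc.abgd_partition(dm, prior=0.02)

    @pytest.mark.parametrize("prior", [0.0001, 0.001, 0.011, 0.05, 0.09])
    def test_toy_recovered_for_every_prior_below_gap(self, prior):
        part = bc.abgd_partition(two_cluster_toy(), prior=prior)
        assert part.n_groups() == 2

    @pytest.mark.parametrize("seed", range(1, 51))
    def test_clean_gap_contract_on_synthetic_replicates(self, seed):
        # whenever realized max-intra a < min-inter b, every prior in [a, b)
        # must return the true species partition
        k = 2 + seed % 5
        ds = bc.generate(
            bc.SyntheticConfig(n_species=k, samples_per_species=4, seed=seed)
        )
        labels = ds.truth.assignment
        rep = bc.calibration_report(ds.sequences, labels)
        a, b = rep["max_intra"], rep["min_inter"]
        assert a < b, "generator did not realize a clean gap"
        dm = bc.p_distance_matrix(ds.sequences)
        for prior in np.linspace(a, b, 5, endpoint=False):
            part = bc.abgd_partition(dm, float(prior))
            assert as_group_sets(part) == as_group_sets(ds.truth)

    def test_priors_below_gap_only_oversplit_never_lump(self):
        ds = bc.generate(
            bc.SyntheticConfig(n_species=4, samples_per_species=5, seed=11)
        )
        dm = bc.p_distance_matrix(ds.sequences)
        truth = as_group_sets(ds.truth)
        b = bc.calibration_report(
            ds.sequences, ds.truth.assignment
        )["min_inter"]
        for prior, part, count in bc.abgd_scan(dm):
            if prior >= b:
                continue
            assert count >= len(truth)
            # every reported group is contained in one true species
            for group in as_group_sets(part):
                assert any(group <= t for t in truth)


class TestAbgdScan:
    def test_single_specimen_every_prior_one_group(self):
        dm = matrix_from(["x"], {})
        scan = bc.abgd_scan(dm)
        assert len(scan) == 20
        assert all(k == 1 for _, _, k in scan)

    def test_toy_two_groups_across_sweep(self):
        for prior, _, count in bc.abgd_scan(two_cluster_toy()):
            if prior < 0.10:
                assert count == 2


class TestSingleLinkage:
    def test_chain_links_into_one_group(self):
        dm = matrix_from(
            list("abc"), {(0, 1): 0.01, (1, 2): 0.01, (0, 2): 0.03}
        )
        part = bc.single_linkage_partition(dm, threshold=0.022)
        assert part.n_groups() == 1

    def test_all_pairs_above_threshold_all_singletons(self):
        dm = matrix_from(
            list("abc"), {(0, 1): 0.5, (1, 2): 0.4, (0, 2): 0.3}
        )
        part = bc.single_linkage_partition(dm, threshold=0.022)
        assert part.n_groups() == 3

    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        ids = [f"s{i}" for i in range(n)]
        dist = {
            (i, j): float(rng.uniform(0, 0.08))
            for i, j in itertools.combinations(range(n), 2)
        }
        dm = matrix_from(ids, dist)
        threshold = 0.022
        uf = UnionFind(ids)
        for (i, j), v in dist.items():
            if v <= threshold:
                uf.union(ids[i], ids[j])
        part = bc.single_linkage_partition(dm, threshold)
        assert as_group_sets(part) == uf.groups()


class TestBestMatchFallback:
    def setup_method(self):
        self.ids = ["query", "g1a", "g1b", "g2a"]
        self.partition = bc.Partition(
            "bin", {"g1a": "G1", "g1b": "G1", "g2a": "G2"}
        )

    def make(self, dq, overlap=650):
        dist = {(0, 1): dq[0], (0, 2): dq[1], (0, 3): dq[2],
                (1, 2): 0.001, (1, 3): 0.2, (2, 3): 0.2}
        return matrix_from(self.ids, dist, overlap=overlap)

    def test_close_match_adopts_group(self):
        dm = self.make([0.005, 0.01, 0.2])
        res = assign_group_by_best_match(
            "query", dm, self.partition
        )
        assert res.group_id == "G1"
        assert res.best_match_id == "g1a"

    def test_below_similarity_floor_unassigned(self):
        dm = self.make([0.02, 0.03, 0.2])
        res = assign_group_by_best_match("query", dm, self.partition)
        assert not res.assigned
        assert "similarity" in res.reason

    def test_tie_between_groups_unassigned(self):
        dm = self.make([0.005, 0.01, 0.005])
        res = assign_group_by_best_match("query", dm, self.partition)
        assert not res.assigned
        assert "tie" in res.reason

    def test_insufficient_overlap_unassigned(self):
        dm = self.make([0.005, 0.01, 0.2], overlap=200)
        res = assign_group_by_best_match(
            "query", dm, self.partition, min_overlap=300
        )
        assert res == BestMatchResult(
            None, reason="no defined pairs with sufficient overlap"
        )

    def test_query_in_scope_rejected(self):
        dm = self.make([0.005, 0.01, 0.2])
        with pytest.raises(ValueError, match="scope"):
            assign_group_by_best_match("g1a", dm, self.partition)


class TestSelectRepresentatives:
    def make_sequences(self):
        # one tight group of 5 with only 2 distinct haplotypes, plus a
        # distant singleton and a distant pair
        h1 = "A" * 300
        h2 = "A" * 299 + "T"
        far = "T" * 150 + "A" * 150
        far2 = "G" * 300
        seqs = [
            bc.AlignedSequence("a1", h1),
            bc.AlignedSequence("a2", h1),
            bc.AlignedSequence("a3", h2),
            bc.AlignedSequence("a4", h1),
            bc.AlignedSequence("a5", h2),
            bc.AlignedSequence("b1", far),
            bc.AlignedSequence("c1", far2),
            bc.AlignedSequence("c2", far2),
        ]
        return seqs, bc.p_distance_matrix(seqs, min_overlap=100)

    def test_group_sizes_and_haplotype_collapse(self):
        seqs, dm = self.make_sequences()
        reps = bc.select_representatives(seqs, dm, k=3, seed=0)
        by_prefix = {}
        for rep in reps:
            by_prefix.setdefault(rep.sequence_id[0], []).append(rep)
        # group of 5 with 2 haplotypes: at most 3 sampled, <= 2 survive
        assert 1 <= len(by_prefix["a"]) <= 2
        assert len(by_prefix["b"]) == 1  # singleton kept
        assert len(by_prefix["c"]) == 1  # duplicate haplotypes collapse
        assert len({r.residues for r in reps}) == len(reps)

    def test_seed_determinism(self):
        seqs, dm = self.make_sequences()
        first = bc.select_representatives(seqs, dm, k=3, seed=42)
        second = bc.select_representatives(seqs, dm, k=3, seed=42)
        assert [r.sequence_id for r in first] == [
            r.sequence_id for r in second
        ]


def test_partitions_cover_scope_with_disjoint_groups():
    ds = bc.generate(bc.SyntheticConfig(n_species=4, samples_per_species=3,
                                        seed=2))
    dm = bc.p_distance_matrix(ds.sequences)
    for part in (
        bc.abgd_partition(dm, 0.02),
        bc.single_linkage_partition(dm),
    ):
        groups = list(part.groups().values())
        assert all(groups)
        union = set().union(*groups)
        assert union == {s.sequence_id for s in ds.sequences}
        assert sum(len(g) for g in groups) == len(union)
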