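"""Consensus filtering, k-mer distances, and constrained clustering."""

import itertools

import numpy as np
import pytest

from anchorforge.orthology import (cluster_orthologs, distance_matrix,
                                   filter_clusters, filter_consensus,
                                   kmer_profile, pair_distance,
                                   OrthologCluster)
from anchorforge.seqmodel import SeqRecord

def _rec(i, seq, taxon=None, support=None):
    return SeqRecord(id=i, taxon=taxon or i, sequence=seq,
                     read_support=support)


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _mutate(rng, seq, n_subs):
    s = list(seq)
    for j in rng.choice(len(s), size=n_subs, replace=False):
        s[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[j]]
    return "".join(s)


class TestFilterConsensus:
    def test_boundary_34_removed_35_kept(self):
        recs = [_rec("a", "ACGT", support=34), _rec("b", "ACGT", support=35)]
        assert [r.id for r in filter_consensus(recs)] == ["b"]

    def test_empty_input(self):
        assert filter_consensus([]) == []

    def test_matches_brute_force_on_random_support(self, rng):
        recs = [_rec(f"r{i}", "ACGT", support=int(s))
                for i, s in enumerate(rng.integers(0, 100, size=100))]
        got = filter_consensus(recs)
        expect = [r for r in recs if r.read_support >= 35]
        assert [r.id for r in got] == [r.id for r in expect]

    def test_missing_support_is_an_error(self):
        with pytest.raises(ValueError, match="read_support"):
            filter_consensus([_rec("x", "ACGT")])


class TestKmerProfile:
    def test_hand_enumeration_small_k(self):
        prof = kmer_profile("ACGTAC", k=3)
        # contiguous {ACG, CGT, GTA, TAC}; strided span 7 > 6 adds none
        assert prof.kmers == frozenset({"ACG", "CGT", "GTA", "TAC"})

    def test_strided_kmers_take_every_third_base(self):
        # length 8, k=3, span 7: starts 0 and 1
        prof = kmer_profile("ACGTACGT", k=3)
        assert "ATG" in prof.kmers   # positions 0,3,6
        assert "CAT" in prof.kmers   # positions 1,4,7

    def test_homopolymer_collapses_to_one_kmer(self):
        prof = kmer_profile("A" * 50, k=20)
        assert prof.kmers == frozenset({"A" * 20})

    def test_profile_monotone_under_extension(self, rng):
        seq = _rand(rng, 120)
        assert kmer_profile(seq).kmers <= kmer_profile(seq + _rand(rng, 40)).kmers

    def test_short_sequence_gives_empty_profile(self):
        assert kmer_profile("ACGT", k=20).kmers == frozenset()

    def test_n_containing_kmers_excluded(self):
        prof = kmer_profile("AAANAAA", k=3)
        assert prof.kmers == frozenset({"AAA"})


class TestPairDistance:
    def test_identical_sequences_distance_zero(self, rng):
        seq = _rand(rng, 100)
        assert pair_distance(kmer_profile(seq), kmer_profile(seq)) == 0.0

    def test_disjoint_kmer_sets_distance_one(self):
        a, b = kmer_profile("A" * 40), kmer_profile("C" * 40)
        assert pair_distance(a, b) == 1.0

    def test_single_substitution_matches_set_arithmetic(self, rng):
        seq = _rand(rng, 100)
        other = _mutate(rng, seq, 1)
        got = pair_distance(kmer_profile(seq), kmer_profile(other))
        # oracle: enumerate both k-mer sets by hand
        def all_kmers(s, k=20):
            out = {s[i:i + k] for i in range(len(s) - k + 1)}
            span = 3 * (k - 1) + 1
            out |= {s[p:p + span:3] for p in range(len(s) - span + 1)}
            return out
        A, B = all_kmers(seq), all_kmers(other)
        assert got == pytest.approx(1 - len(A & B) / len(A | B))

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError, match="k mismatch"):
            pair_distance(kmer_profile("A" * 30, k=20),
                          kmer_profile("A" * 30, k=15))

    def test_symmetric_bounded_zero_diagonal(self, rng):
        recs = [_rec(f"s{i}", _rand(rng, 80)) for i in range(6)]
        dm = distance_matrix(recs)
        assert (dm.values >= 0).all() and (dm.values <= 1).all()
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)


def brute_average_linkage(records, dist):
    """O(n^3) reference: same constrained average-linkage, independent code."""
    d = dist.values
    clusters = [frozenset([i]) for i in range(len(records))]
    while True:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            taxa_a = {records[i].taxon for i in a}
            taxa_b = {records[i].taxon for i in b}
            if taxa_a & taxa_b:
                continue
            avg = float(np.mean([d[i, j] for i in a for j in b]))
            key = (avg, tuple(sorted((min(records[i].id for i in a),
                                      min(records[i].id for i in b)))))
            if best is None or key < best[0]:
                best = (key, a, b)
        if best is None:
            return {frozenset(records[i].id for i in c) for c in clusters}
        _, a, b = best
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]


class TestClusterOrthologs:
    def test_single_sequence_per_taxon_merges_to_one_cluster(self, rng):
        base = _rand(rng, 300)
        recs = [_rec(f"s{i}", _mutate(rng, base, 5), taxon=f"t{i}")
                for i in range(5)]
        clusters = cluster_orthologs(recs)
        assert len(clusters) == 1
        assert clusters[0].species_set == {f"t{i}" for i in range(5)}

    def test_planted_duplication_separates_copies(self, rng):
        copy1 = _rand(rng, 300)
        copy2 = _mutate(rng, copy1, 45)  # 15% inter-copy divergence
        recs = []
        for t in "ABC":
            recs.append(_rec(f"{t}_1", _mutate(rng, copy1, 6), taxon=t))
            recs.append(_rec(f"{t}_2", _mutate(rng, copy2, 6), taxon=t))
        clusters = cluster_orthologs(recs)
        parts = {frozenset(m.id for m in c.members) for c in clusters}
        assert parts == {frozenset({"A_1", "B_1", "C_1"}),
                         frozenset({"A_2", "B_2", "C_2"})}

    def test_subtree_duplication_gives_full_plus_partial_cluster(self, rng):
        # duplication on the branch to {B, C} only: one cluster with all
        # of A, B, C (copy 1) and a second with B, C (copy 2)
        copy1 = _rand(rng, 300)
        copy2 = _mutate(rng, copy1, 45)
        recs = [_rec("A_1", _mutate(rng, copy1, 6), taxon="A"),
                _rec("B_1", _mutate(rng, copy1, 6), taxon="B"),
                _rec("B_2", _mutate(rng, copy2, 6), taxon="B"),
                _rec("C_1", _mutate(rng, copy1, 6), taxon="C"),
                _rec("C_2", _mutate(rng, copy2, 6), taxon="C")]
        clusters = cluster_orthologs(recs)
        parts = {frozenset(m.id for m in c.members) for c in clusters}
        assert parts == {frozenset({"A_1", "B_1", "C_1"}),
                         frozenset({"B_2", "C_2"})}

    def test_never_two_sequences_from_one_taxon(self, rng):
        for _ in range(10):
            recs = [_rec(f"s{i}_{c}", _rand(rng, 120), taxon=f"t{i % 4}")
                    for i in range(8) for c in range(2)]
            for cluster in cluster_orthologs(recs):
                taxa = [m.taxon for m in cluster.members]
                assert len(set(taxa)) == len(taxa)

    def test_agrees_with_brute_force_reference(self, rng):
        for trial in range(10):
            n = int(rng.integers(4, 13))
            base = _rand(rng, 150)
            recs = [_rec(f"s{i:02d}", _mutate(rng, base, int(rng.integers(0, 30))),
                         taxon=f"t{i % 5}") for i in range(n)]
            dm = distance_matrix(recs)
            got = {frozenset(m.id for m in c.members)
                   for c in cluster_orthologs(recs, dist=dm)}
            assert got == brute_average_linkage(recs, dm)

    def test_result_independent_of_input_order(self, rng):
        base = _rand(rng, 200)
        recs = [_rec(f"s{i}", _mutate(rng, base, int(rng.integers(0, 40))),
                     taxon=f"t{i % 3}") for i in range(9)]
        parts1 = {frozenset(m.id for m in c.members)
                  for c in cluster_orthologs(recs)}
        perm = [recs[i] for i in rng.permutation(len(recs))]
        parts2 = {frozenset(m.id for m in c.members)
                  for c in cluster_orthologs(perm)}
        assert parts1 == parts2

    def test_max_distance_stops_merging(self, rng):
        recs = [_rec("a", _rand(rng, 100), taxon="A"),
                _rec("b", _rand(rng, 100), taxon="B")]
        clusters = cluster_orthologs(recs, max_distance=0.1)
        assert len(clusters) == 2


class TestFilterClusters:
    def _cluster(self, n_taxa):
        return OrthologCluster(
            "c", [_rec(f"t{i}", "ACGT" * 10, taxon=f"t{i}")
                  for i in range(n_taxa)])

    def test_araneae_scale_boundary(self):
        # 33 species: 25/33 = 0.758 kept, 24/33 = 0.727 removed
        kept = filter_clusters([self._cluster(25)], 33)
        removed = filter_clusters([self._cluster(24)], 33)
        assert len(kept) == 1 and removed == []

    def test_exact_threshold_kept(self):
        # 24/32 = exactly 0.75 -> kept ("fewer than 75%" removed)
        assert len(filter_clusters([self._cluster(24)], 32)) == 1

    def test_full_occupancy_kept(self):
        assert len(filter_clusters([self._cluster(10)], 10)) == 1

    def test_zero_fraction_keeps_everything(self):
        assert len(filter_clusters([self._cluster(1)], 50, 0.0)) == 1
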