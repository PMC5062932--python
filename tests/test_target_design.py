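"""Target selection, window identity, and exon-boundary detection."""

import itertools

import numpy as np
import pytest

from anchorforge.seqmodel import SeqRecord, revcomp
from anchorforge.simulate import simulate_reads, substream
from anchorforge.target_design import (
    filter_ortholog_alignments, lift_boundaries_to_alignment,
    map_exons_by_kmer, map_exons_by_reads, select_preliminary_targets,
    sliding_window_identity, split_alignment_at_boundaries, window_identity)

from tests.conftest import make_locus, random_locus


def brute_identity(seqs, start, width):
    """Independent oracle: loop over all pairs and columns."""
    vals = []
    for a, b in itertools.combinations(seqs, 2):
        match = comp = 0
        for j in range(start, start + width):
            if a[j] != "-" and b[j] != "-":
                comp += 1
                match += a[j] == b[j]
        if comp:
            vals.append(match / comp)
    return sum(vals) / len(vals) if vals else 0.0


class TestWindowIdentity:
    def test_identical_rows_score_one(self):
        msa = make_locus("L", ["ACGT" * 30] * 2)
        assert window_identity(msa, 0, 120).mean_pairwise_identity == 1.0

    def test_fully_divergent_rows_score_zero(self):
        msa = make_locus("L", ["A" * 120, "C" * 120])
        assert window_identity(msa, 0, 120).mean_pairwise_identity == 0.0

    def test_matches_brute_force_over_pairs_and_columns(self, rng):
        for _ in range(25):
            msa = random_locus(rng, 4, 30, gap_frac=0.15)
            seqs = [r.sequence for r in msa.rows]
            start = int(rng.integers(0, 20))
            got = window_identity(msa, start, 10).mean_pairwise_identity
            assert got == pytest.approx(brute_identity(seqs, start, 10))

    def test_gap_positions_are_excluded_not_mismatched(self):
        msa = make_locus("L", ["AC-T", "ACGT"])
        assert window_identity(msa, 0, 4).mean_pairwise_identity == 1.0

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match=">= 2 rows"):
            window_identity(make_locus("L", ["ACGT"]), 0, 4)

    def test_sliding_scan_agrees_with_single_windows(self, rng):
        msa = random_locus(rng, 5, 40, gap_frac=0.1)
        scan = sliding_window_identity(msa, width=10)
        for s in range(len(scan)):
            assert scan[s] == pytest.approx(
                window_identity(msa, s, 10).mean_pairwise_identity)


class TestFilterOrthologAlignments:
    def test_five_taxon_locus_dropped_regardless_of_identity(self):
        msa = make_locus("L", ["ACGT" * 40] * 5)
        assert filter_ortholog_alignments([msa]) == []

    def test_six_identical_rows_kept(self):
        msa = make_locus("L", ["ACGT" * 40] * 6)
        assert filter_ortholog_alignments([msa]) == [msa]

    def test_window_at_exactly_half_identity_dropped(self):
        # two rows agreeing on exactly every other column: every window
        # of even width scores exactly 0.5, and the > threshold is strict
        msa = make_locus("L", ["AC" * 60, "AG" * 60] * 3,
                         taxa=[f"t{i}" for i in range(6)])
        # pairs: identical-pattern pairs 1.0, cross pairs 0.5 -> drop only
        # when every pair is at 0.5; use exactly two rows instead
        two = make_locus("L2", ["AC" * 60, "AG" * 60])
        assert float(sliding_window_identity(two, 120).max()) == 0.5
        six = make_locus("L3", ["AC" * 60, "AG" * 60, "AT" * 60,
                                "CA" * 60, "GA" * 60, "TA" * 60])
        # within each triple pairs score 0.5 (shared column parity),
        # across triples 0.0; the best window is exactly at threshold
        assert float(sliding_window_identity(six, 120).max()) <= 0.5
        assert filter_ortholog_alignments([six]) == []
        del msa

    def test_adding_identical_row_never_drops_a_kept_locus(self, rng):
        for _ in range(10):
            msa = random_locus(rng, 6, 150)
            kept = bool(filter_ortholog_alignments([msa], min_identity=0.2))
            if not kept:
                continue
            bigger = make_locus(
                "L+", [r.sequence for r in msa.rows] + [msa.rows[0].sequence],
                taxa=[r.taxon for r in msa.rows] + ["extra"])
            assert filter_ortholog_alignments([bigger], min_identity=0.2)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _intron_between(rng, left_exon, right_exon, n):
    """Random intron whose flank bases differ from the adjacent exon bases
    (as real GT...AG junctions do) so the planted splice point is exact."""
    s = list(_random_seq(rng, n))
    if s[0] == right_exon[0]:
        s[0] = "A" if right_exon[0] != "A" else "C"
    if s[-1] == left_exon[-1]:
        s[-1] = "A" if left_exon[-1] != "A" else "C"
    return "".join(s)


class TestMapExonsByKmer:
    def test_contiguous_substring_is_single_exon(self, rng):
        genome_seq = _random_seq(rng, 2000)
        tr = SeqRecord(id="t", sequence=genome_seq[500:1100])
        emap = map_exons_by_kmer(tr, SeqRecord(id="g", sequence=genome_seq))
        assert emap.boundaries == []

    def test_planted_intron_recovered_exactly(self, rng):
        e1, e2 = _random_seq(rng, 200), _random_seq(rng, 300)
        intron = _intron_between(rng, e1, e2, 500)
        genome = SeqRecord(id="g", sequence=_random_seq(rng, 400) + e1 +
                           intron + e2 + _random_seq(rng, 400))
        tr = SeqRecord(id="t", sequence=e1 + e2)
        emap = map_exons_by_kmer(tr, genome)
        assert emap.boundaries == [200]

    def test_reverse_strand_gene_recovered(self, rng):
        e1, e2 = _random_seq(rng, 200), _random_seq(rng, 300)
        fwd = e1 + _intron_between(rng, e1, e2, 300) + e2
        genome = SeqRecord(id="g", sequence=revcomp(fwd))
        emap = map_exons_by_kmer(SeqRecord(id="t", sequence=e1 + e2), genome)
        assert emap.boundaries == [200]

    def test_no_match_yields_empty_map(self):
        tr = SeqRecord(id="t", sequence="A" * 100)
        genome = SeqRecord(id="g", sequence="C" * 1000)
        emap = map_exons_by_kmer(tr, genome)
        assert emap.boundaries == [] and emap.evidence == "genome_kmer"

    def test_recovers_planted_boundary_set_for_introns_at_least_k(self, rng):
        k = 40
        for trial in range(5):
            n_ex = int(rng.integers(2, 5))
            exons = [_random_seq(rng, int(rng.integers(120, 300)))
                     for _ in range(n_ex)]
            introns = [_intron_between(rng, exons[i], exons[i + 1],
                                       int(rng.integers(k, 400)))
                       for i in range(n_ex - 1)]
            parts = [exons[0]]
            for i, intr in enumerate(introns):
                parts += [intr, exons[i + 1]]
            genome = SeqRecord(id="g", sequence=_random_seq(rng, 200) +
                               "".join(parts) + _random_seq(rng, 200))
            truth = list(np.cumsum([len(e) for e in exons[:-1]]))
            emap = map_exons_by_kmer(SeqRecord(id="t", sequence="".join(exons)),
                                     genome, k=k)
            assert emap.boundaries == truth


class TestMapExonsByReads:
    def test_intronless_gene_yields_no_boundary(self, rng):
        tr_seq = _random_seq(rng, 600)
        genome = SeqRecord(id="g", sequence=tr_seq)
        reads, _ = simulate_reads(genome, length=150, coverage=15,
                                  error=0.0, seed=7)
        emap = map_exons_by_reads(SeqRecord(id="t", sequence=tr_seq), reads)
        assert emap.boundaries == []

    def test_junction_reads_locate_splice_point(self, rng):
        e1, e2 = _random_seq(rng, 300), _random_seq(rng, 300)
        intron = _random_seq(rng, 400)
        genome = SeqRecord(id="g", sequence=e1 + intron + e2)
        reads, _ = simulate_reads(genome, length=150, coverage=25,
                                  error=0.0, seed=11)
        emap = map_exons_by_reads(SeqRecord(id="t", sequence=e1 + e2), reads)
        assert len(emap.boundaries) >= 1
        assert min(abs(b - 300) for b in emap.boundaries) <= 2
        assert emap.evidence == "read_discordance"

    def test_reads_shorter_than_two_flanks_yield_empty_map(self, rng):
        tr_seq = _random_seq(rng, 300)
        reads = [SeqRecord(id=f"r{i}", sequence=tr_seq[i:i + 50])
                 for i in range(0, 200, 10)]
        emap = map_exons_by_reads(SeqRecord(id="t", sequence=tr_seq), reads,
                                  flank=30)
        assert emap.boundaries == []

    def test_no_reads_yields_empty_map(self):
        emap = map_exons_by_reads(SeqRecord(id="t", sequence="ACGT" * 50), [])
        assert emap.boundaries == []


class TestSelectPreliminaryTargets:
    def test_clean_alignment_gives_one_full_region(self):
        msa = make_locus("L", ["ACGT" * 50] * 4)
        regions = select_preliminary_targets(msa)
        assert [(r.start, r.stop) for r in regions] == [(0, 200)]

    def test_gap_column_splits_and_short_side_dropped(self):
        row = "A" * 100 + "-" + "C" * 159
        other = "A" * 100 + "G" + "C" * 159
        msa = make_locus("L", [row, other])
        regions = select_preliminary_targets(msa)
        assert [(r.start, r.stop) for r in regions] == [(101, 260)]

    def test_boundary_splits_alignment(self):
        msa = make_locus("L", ["ACGT" * 75] * 4)
        regions = select_preliminary_targets(msa, boundary_cols=[150])
        assert [(r.start, r.stop) for r in regions] == [(0, 150), (150, 300)]

    def test_regions_satisfy_all_constraints(self, rng):
        """Exhaustive-scan oracle: regions are maximal, disjoint, >= min_len,
        gap-free, and boundary-free on random gapped alignments."""
        for _ in range(20):
            msa = random_locus(rng, 5, 400, gap_frac=0.002)
            cuts = sorted(rng.choice(np.arange(1, 400), size=2, replace=False))
            regions = select_preliminary_targets(msa, cuts, min_len=50)
            gap_col = np.array([any(r.sequence[j] == "-" for r in msa.rows)
                                for j in range(400)])
            # oracle: every returned interval checks out
            prev_stop = -1
            for reg in regions:
                assert reg.stop - reg.start >= 50
                assert not gap_col[reg.start:reg.stop].any()
                assert not any(reg.start < c < reg.stop for c in cuts)
                assert reg.start >= prev_stop
                prev_stop = reg.stop
                # maximality: cannot extend either side
                if reg.start > 0:
                    assert gap_col[reg.start - 1] or reg.start in cuts
                if reg.stop < 400:
                    assert gap_col[reg.stop] or reg.stop in cuts
            # oracle count: brute interval scan finds the same intervals
            bad = gap_col.copy()
            edges = [0, *cuts, 400]
            expect = []
            for s, e in zip(edges, edges[1:]):
                j = s
                while j < e:
                    if bad[j]:
                        j += 1
                        continue
                    s0 = j
                    while j < e and not bad[j]:
                        j += 1
                    if j - s0 >= 50:
                        expect.append((s0, j))
            assert [(r.start, r.stop) for r in regions] == expect


class TestSplitAndLift:
    def test_no_boundaries_returns_parent(self):
        msa = make_locus("L", ["ACGT" * 10] * 3)
        (child,) = split_alignment_at_boundaries(msa, [])
        assert child.locus_id == "L" and child.n_cols == 40

    def test_children_partition_columns(self):
        msa = make_locus("L", ["ACGT" * 100] * 3)
        kids = split_alignment_at_boundaries(msa, [100, 250])
        assert [k.n_cols for k in kids] == [100, 150, 150]
        assert [k.locus_id for k in kids] == ["L_e1", "L_e2", "L_e3"]

    def test_concatenation_round_trips(self, rng):
        msa = random_locus(rng, 4, 200)
        cuts = sorted(int(c) for c in rng.choice(np.arange(1, 200), 3,
                                                 replace=False))
        kids = split_alignment_at_boundaries(msa, cuts)
        for i in range(4):
            rebuilt = "".join(k.rows[i].sequence for k in kids)
            assert rebuilt == msa.rows[i].sequence

    def test_boundary_outside_alignment_rejected(self):
        msa = make_locus("L", ["ACGT"] * 2)
        with pytest.raises(ValueError, match="outside"):
            split_alignment_at_boundaries(msa, [4])

    def test_lift_through_gapped_row(self):
        row = SeqRecord(id="x", sequence="AC--GT-A")
        # ungapped = ACGTA; cut before base 2 (G) -> column 4
        assert lift_boundaries_to_alignment(row, [2]) == [4]
        assert lift_boundaries_to_alignment(row, [5]) == [8]
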