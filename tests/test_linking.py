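"""CDS alignment, coordinate liftover, SNP linking, retention criteria."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polyload.coords import GAP, revcomp
from polyload.linking import (
    LinkedSitePair,
    SiteInfo,
    align_cds,
    link_snp_sites,
    map_alignment_to_genome,
    retention_filter,
)
from polyload.polarize import UNRESOLVED
from polyload.qc import HomoeologPair

from oracles import brute_force_global_alignment

dna = st.text(alphabet="ACGT", min_size=1, max_size=8)


class TestAlignCds:
    def test_identical_sequences_align_without_gaps(self):
        aln = align_cds("GATTACAAT", "GATTACAAT", match=1.0)
        assert aln.score == 9
        assert "-" not in aln.aligned_at + aln.aligned_dt

    def test_internal_deletion_yields_single_gap(self):
        seq = "GATTACAATCGG"
        deleted = seq[:4] + seq[7:]  # drop 3 nt
        aln = align_cds(seq, deleted)
        assert aln.aligned_at.replace("-", "") == seq
        assert aln.aligned_dt.count("-") == 3
        # one contiguous gap run
        gap_runs = [r for r in aln.aligned_dt.split("-") if r == ""]
        assert aln.aligned_dt.strip("-").count("--") <= 1
        assert "-" not in aln.aligned_at

    def test_all_mismatch_preferred_over_gaps(self):
        aln = align_cds("AAA", "TTT", match=1.0, mismatch=-1.0)
        assert aln.score == -3
        assert "-" not in aln.aligned_at + aln.aligned_dt

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError, match="non-DNA"):
            align_cds("ACGU", "ACGT")
        with pytest.raises(ValueError, match="empty"):
            align_cds("", "ACGT")

    @given(dna, dna)
    def test_score_matches_brute_force_optimum(self, a, b):
        aln = align_cds(a, b)
        expected = brute_force_global_alignment(a, b, 2.0, -3.0, -5.0, -2.0)
        assert aln.score == pytest.approx(expected)

    @given(dna, dna)
    def test_score_symmetric(self, a, b):
        assert align_cds(a, b).score == align_cds(b, a).score

    @given(dna, dna)
    def test_gap_removal_recovers_inputs(self, a, b):
        aln = align_cds(a, b)
        assert aln.aligned_at.replace("-", "") == a
        assert aln.aligned_dt.replace("-", "") == b


def simple_pair(strand_dt="+", intervals_at=None, intervals_dt=None):
    return HomoeologPair(
        pair_id="p0",
        gene_at="gA",
        gene_dt="gD",
        chrom_at="chrA",
        chrom_dt="chrD",
        intervals_at=intervals_at or [(100, 109)],
        intervals_dt=intervals_dt or [(100, 109)],
        strand_at="+",
        strand_dt=strand_dt,
    )


class TestMapAlignmentToGenome:
    def test_plus_strand_first_column(self):
        from polyload.linking import PairwiseAlignment

        aln = PairwiseAlignment("ACGTACGTA", "ACGTACGTA", 9)
        cols = map_alignment_to_genome(aln, simple_pair())
        assert cols[0] == (101, 101)
        assert cols[-1] == (109, 109)

    def test_minus_strand_walks_backwards(self):
        from polyload.linking import PairwiseAlignment

        aln = PairwiseAlignment("ACGTACGTA", "ACGTACGTA", 9)
        cols = map_alignment_to_genome(aln, simple_pair(strand_dt="-"))
        assert cols[0] == (101, 109)
        assert cols[-1] == (109, 101)

    def test_two_exon_walk(self):
        from polyload.linking import PairwiseAlignment

        pair = simple_pair(
            intervals_at=[(100, 103), (200, 203)], intervals_dt=[(100, 103), (200, 203)]
        )
        aln = PairwiseAlignment("ACGTAC", "ACGTAC", 6)
        cols = map_alignment_to_genome(aln, pair)
        assert [c[0] for c in cols] == [101, 102, 103, 201, 202, 203]

    def test_gap_columns_carry_sentinel(self):
        from polyload.linking import PairwiseAlignment

        pair = simple_pair(intervals_dt=[(100, 106)])
        aln = PairwiseAlignment("ACGTACGTA", "ACG---TAC", 0)
        cols = map_alignment_to_genome(aln, pair)
        assert cols[3] == (104, GAP)
        assert cols[8] == (109, 106)

    def test_length_mismatch_raises(self):
        from polyload.linking import PairwiseAlignment

        aln = PairwiseAlignment("ACGT", "ACGT", 4)
        with pytest.raises(ValueError, match="do not match"):
            map_alignment_to_genome(aln, simple_pair())


class TestLinkSnpSites:
    def make(self, strand_dt="+"):
        from polyload.linking import PairwiseAlignment

        pair = simple_pair(strand_dt=strand_dt)
        aln = PairwiseAlignment("ACGTACGTA", "ACGTACGTA", 9)
        return pair, map_alignment_to_genome(aln, pair)

    def test_same_strand_link(self):
        pair, cols = self.make()
        links = link_snp_sites([103], [], cols, pair)
        assert len(links) == 1
        assert (links[0].pos_at, links[0].pos_dt) == (103, 103)
        assert not links[0].opposite_strand

    def test_opposite_strand_flag(self):
        pair, cols = self.make(strand_dt="-")
        links = link_snp_sites([101], [], cols, pair)
        assert links[0].pos_dt == 109
        assert links[0].opposite_strand

    def test_mutual_snps_collapse_to_one_link(self):
        pair, cols = self.make()
        links = link_snp_sites([103], [103], cols, pair)
        assert len(links) == 1

    def test_snp_outside_cds_skipped(self):
        pair, cols = self.make()
        assert link_snp_sites([999], [], cols, pair) == []

    def test_gap_linked_snp_emitted_with_sentinel(self):
        from polyload.linking import PairwiseAlignment

        pair = simple_pair(intervals_dt=[(100, 106)])
        aln = PairwiseAlignment("ACGTACGTA", "ACG---TAC", 0)
        cols = map_alignment_to_genome(aln, pair)
        links = link_snp_sites([104], [], cols, pair)
        assert links[0].pos_dt == GAP


def link(pos_at=10, pos_dt=20, opposite=False):
    return LinkedSitePair("p0", pos_at, pos_dt, 0, opposite)


class TestRetentionFilter:
    def test_gap_link_fails_criterion_1(self):
        v = retention_filter([link(pos_dt=GAP)], {}, {})[0]
        assert not v.retained
        assert v.failed_criteria == (1,)

    def test_clean_private_derived_site_retained(self):
        ia = SiteInfo(ref="A", alleles=("A", "G"), anc="A", present={"A": True, "G": True})
        id_ = SiteInfo.monomorphic("A")
        v = retention_filter([link()], {10: ia}, {20: id_})[0]
        assert v.retained

    def test_three_alleles_fail_criterion_2(self):
        ia = SiteInfo(ref="A", alleles=("A", "G"), anc="A", present={"A": True, "G": True})
        id_ = SiteInfo(ref="A", alleles=("A", "C"), anc="A", present={"A": True, "C": True})
        v = retention_filter([link()], {10: ia}, {20: id_})[0]
        assert 2 in v.failed_criteria

    def test_unresolved_ancestral_fails_criterion_2(self):
        ia = SiteInfo(ref="A", alleles=("A", "G"), anc=UNRESOLVED, present={"G": True})
        id_ = SiteInfo.monomorphic("A")
        v = retention_filter([link()], {10: ia}, {20: id_})[0]
        assert 2 in v.failed_criteria

    def test_mismatched_ancestral_states_fail_criterion_2(self):
        ia = SiteInfo(ref="A", alleles=("A", "G"), anc="A", present={"A": True, "G": True})
        id_ = SiteInfo(ref="C", alleles=("C", "G"), anc="C", present={"C": True, "G": True})
        v = retention_filter([link()], {10: ia}, {20: id_})[0]
        assert 2 in v.failed_criteria

    def test_opposite_strand_complement_reconciles_ancestral(self):
        # ancestral A on the forward gene pairs with ancestral T on the
        # reverse-strand gene; derived G pairs with derived C
        ia = SiteInfo(ref="A", alleles=("A", "G"), anc="A", present={"A": True, "G": True})
        id_ = SiteInfo(ref="T", alleles=("T",), anc="T", present={"T": True})
        v = retention_filter([link(opposite=True)], {10: ia}, {20: id_})[0]
        assert v.retained

    def test_derived_in_both_subgenomes_fails_criterion_3(self):
        ia = SiteInfo(ref="A", alleles=("A", "G"), anc="A", present={"A": True, "G": True})
        id_ = SiteInfo(ref="A", alleles=("A", "G"), anc="A", present={"A": True, "G": True})
        v = retention_filter([link()], {10: ia}, {20: id_})[0]
        assert v.failed_criteria == (3,)

    def test_criterion_4_requires_fixed_segregating_contrast(self):
        ia = SiteInfo(
            ref="A", alleles=("A", "G"), anc="A", present={"A": True, "G": True},
            diploid_freq=1.0, subgenome_freqs=(0.5,),
        )
        id_ = SiteInfo.monomorphic("A")
        assert retention_filter([link()], {10: ia}, {20: id_}, criterion4=True)[0].retained
        ia2 = SiteInfo(
            ref="A", alleles=("A", "G"), anc="A", present={"A": True, "G": True},
            diploid_freq=1.0, subgenome_freqs=(1.0,),
        )
        v = retention_filter([link()], {10: ia2}, {20: id_}, criterion4=True)[0]
        assert 4 in v.failed_criteria


def test_strand_involution_preserves_linked_offsets():
    """Annotating the Dt gene on the opposite reference strand (the gene-
    oriented CDS, and hence the alignment, is unchanged) must link the same
    CDS base, with the genomic position given by the strand-reflected walk
    and the same alignment column retained either way."""
    from polyload.coords import genomic_to_cds

    rng = np.random.default_rng(5)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
    seq_dt = seq[:30] + ("T" if seq[30] != "T" else "C") + seq[31:]

    def build(strand_dt):
        return HomoeologPair(
            pair_id="p", gene_at="a", gene_dt="d", chrom_at="chrA", chrom_dt="chrD",
            intervals_at=[(100, 160)], intervals_dt=[(500, 560)],
            strand_at="+", strand_dt=strand_dt, seq_at=seq, seq_dt=seq_dt,
        )

    def one_link(pair):
        aln = align_cds(pair.seq_at, pair.seq_dt)
        cols = map_alignment_to_genome(aln, pair)
        return link_snp_sites([131], [], cols, pair)[0]

    fwd = one_link(build("+"))
    rev = one_link(build("-"))
    assert fwd.pos_at == rev.pos_at == 131
    assert fwd.column == rev.column
    # same CDS base either way: offset 30 of the gene-oriented sequence
    assert genomic_to_cds(fwd.pos_dt - 1, [(500, 560)], "+") == 30
    assert genomic_to_cds(rev.pos_dt - 1, [(500, 560)], "-") == 30
    assert (fwd.pos_dt, rev.pos_dt) == (531, 530)
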