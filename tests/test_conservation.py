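"""Rejected-substitutions scoring: 4-fold sites, neutral tree, Fitch, bins."""

import numpy as np
import pytest

from polyload import trees
from polyload.conservation import (
    NeutralTree,
    estimate_neutral_tree,
    fourfold_sites,
    gerp_bin,
    jc69_distance,
    rs_score,
    score_alignment,
    site_expected_subs,
    site_observed_subs,
)
from polyload.simulate import evolve_jc_alignment

from oracles import exhaustive_parsimony, path_union_length, random_tree


class TestFourfoldSites:
    def test_fourfold_family_in_every_species(self):
        aln = {"a": "GCTGCA", "b": "GCAGCG"}  # Ala codons throughout
        assert fourfold_sites(aln) == [2, 5]

    def test_twofold_family_excluded(self):
        aln = {"a": "TGTTGC", "b": "TGTTGT"}  # Cys family: not 4-fold
        assert fourfold_sites(aln) == []

    def test_mixed_fourfold_families_included(self):
        aln = {"a": "GCT", "b": "GTT"}  # Ala vs Val: both 4-fold families
        assert fourfold_sites(aln) == [2]

    def test_gapped_species_ignored_at_that_codon(self):
        aln = {"a": "GCT", "b": "---"}
        assert fourfold_sites(aln) == [2]

    def test_one_non_fourfold_species_blocks_the_codon(self):
        aln = {"a": "GCT", "b": "TGT"}
        assert fourfold_sites(aln) == []

    def test_gapped_reference_rejected(self):
        with pytest.raises(ValueError, match="ungapped"):
            fourfold_sites({"a": "GC-", "b": "GCT"}, reference="a")

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            fourfold_sites({"a": "GCTA"})


class TestNeutralTree:
    def test_jc69_closed_form(self):
        assert jc69_distance(0.10) == pytest.approx(0.1073, abs=5e-4)
        with pytest.raises(ValueError, match="saturated"):
            jc69_distance(0.8)

    def test_identical_sequences_give_zero_lengths(self):
        topo = trees.parse_newick("((a:1,b:1)ab:1,c:1)r;")
        nt = estimate_neutral_tree({"a": "ACGT" * 10, "b": "ACGT" * 10, "c": "ACGT" * 10}, topo)
        assert nt.total_length == pytest.approx(0.0, abs=1e-12)

    def test_pairwise_distance_recovered_for_three_taxa(self):
        # a and b differ at 10% of sites, c equals a: d(a,b) must split
        # additively and total path a-b equals JC69(0.10)
        rng = np.random.default_rng(0)
        n = 4000
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        b = list(a)
        idx = rng.choice(n, size=n // 10, replace=False)
        for i in idx:
            b[i] = "ACGT"[("ACGT".index(b[i]) + 1) % 4]
        b = "".join(b)
        topo = trees.parse_newick("((a:1,b:1)ab:1,c:1)r;")
        nt = estimate_neutral_tree({"a": a, "b": b, "c": a}, topo)
        d_ab = nt.root.find("a").length + nt.root.find("b").length
        assert d_ab == pytest.approx(jc69_distance(0.10), rel=1e-6)

    def test_branch_lengths_recovered_from_simulation(self, rng):
        newick = "((a:0.05,b:0.1)ab:0.05,(c:0.08,d:0.12)cd:0.04)r;"
        tree = trees.parse_newick(newick)
        aln = evolve_jc_alignment(tree, 10_000, rng)
        nt = estimate_neutral_tree(aln, tree)
        assert nt.total_length == pytest.approx(0.44, rel=0.10)

    def test_saturated_pair_names_the_pair(self):
        topo = trees.parse_newick("((a:1,b:1)ab:1,c:1)r;")
        aln = {"a": "AAAA", "b": "CCCC", "c": "AAAA"}
        with pytest.raises(ValueError, match=r"\(a,b\)"):
            estimate_neutral_tree(aln, topo)


@pytest.fixture()
def four_tip_tree():
    return NeutralTree(trees.parse_newick("((s1:1,s2:2)n12:0.5,(s3:1,s4:1)n34:0.5)r;"))


class TestSiteExpectedSubs:
    def test_all_species_present_gives_total_length(self, four_tip_tree):
        present = set(four_tip_tree.root.tip_names())
        assert site_expected_subs(four_tip_tree, present) == pytest.approx(6.0)

    def test_single_species_scores_zero(self, four_tip_tree):
        assert site_expected_subs(four_tip_tree, {"s1"}) == 0.0

    def test_subsets_match_enumeration_oracle(self, four_tip_tree, rng):
        tips = four_tip_tree.root.tip_names()
        for _ in range(10):
            k = int(rng.integers(2, 5))
            present = set(rng.choice(tips, size=k, replace=False))
            assert site_expected_subs(four_tip_tree, present) == pytest.approx(
                path_union_length(four_tip_tree.root, present)
            )

    def test_removing_a_species_never_increases_expectation(self, rng):
        for _ in range(10):
            tree = NeutralTree(random_tree(6, rng))
            tips = tree.root.tip_names()
            present = set(tips)
            while len(present) > 1:
                e_full = site_expected_subs(tree, present)
                drop = tips[int(rng.integers(len(tips)))]
                reduced = present - {drop}
                assert site_expected_subs(tree, reduced) <= e_full + 1e-12
                present = reduced


class TestSiteObservedSubs:
    def test_monomorphic_column(self, four_tip_tree):
        col = {t: "A" for t in four_tip_tree.root.tip_names()}
        assert site_observed_subs(col, four_tip_tree) == 0

    def test_clade_consistent_column_needs_one_change(self, four_tip_tree):
        col = {"s1": "A", "s2": "A", "s3": "C", "s4": "C"}
        assert site_observed_subs(col, four_tip_tree) == 1

    def test_crossing_column_needs_two_changes(self, four_tip_tree):
        col = {"s1": "A", "s2": "C", "s3": "A", "s4": "C"}
        assert site_observed_subs(col, four_tip_tree) == 2

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(15):
            tree = random_tree(int(rng.integers(3, 7)), rng)
            nt = NeutralTree(tree)
            col = {t: "ACGT"[rng.integers(4)] for t in tree.tip_names()}
            assert site_observed_subs(col, nt) == exhaustive_parsimony(tree, col)


class TestRsScoreAndBins:
    def test_rs_arithmetic(self):
        assert rs_score(3.0, 3) == 0.0
        assert rs_score(3.0, 1) == 2.0

    def test_perfectly_conserved_site_scores_total_length(self, four_tip_tree):
        aln = {t: "AAAA" for t in four_tip_tree.root.tip_names()}
        scores = score_alignment(aln, four_tip_tree)
        assert all(s.rs == pytest.approx(6.0) for s in scores)

    def test_rs_bounded_by_expectation(self, four_tip_tree, rng):
        aln = {
            t: "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
            for t in four_tip_tree.root.tip_names()
        }
        for s in score_alignment(aln, four_tip_tree):
            assert s.rs <= s.expected_subs + 1e-12

    def test_excluding_the_focal_genome_drops_its_row(self, four_tip_tree):
        aln = {t: "A" for t in four_tip_tree.root.tip_names()}
        aln["s1"] = "C"
        with_focal = score_alignment(aln, four_tip_tree)[0]
        without = score_alignment(aln, four_tip_tree, exclude={"s1"})[0]
        assert with_focal.observed_subs == 1
        assert without.observed_subs == 0

    @pytest.mark.parametrize(
        "rs,expected",
        [(-0.3, "none"), (0.0, "none"), (1.5, "mild"), (2.0, "mild"),
         (4.0, "moderate"), (5.9, "strong"), (7.2, "strong")],
    )
    def test_bins(self, rs, expected):
        assert gerp_bin(rs) == expected


def test_simulated_score_monotone_in_selection_strength(small_dataset):
    """The generator's conservation score must rank strongly selected
    variants above weakly selected ones (the relationship the deleteriousness
    bins rely on)."""
    df = small_dataset.variants.df
    dele = df.loc[df["deleterious"] & df["cls"].eq("nonsynonymous")]
    strong_s = dele.loc[dele["s"] >= dele["s"].quantile(0.8), "score"]
    weak_s = dele.loc[dele["s"] <= dele["s"].quantile(0.2), "score"]
    assert strong_s.mean() > weak_s.mean()
    non_dele = df.loc[~df["deleterious"] & df["cls"].ne("artifact"), "score"]
    assert (non_dele <= 0).all()
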