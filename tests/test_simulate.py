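"""Synthetic clade generator: retention model, artifacts, determinism, I/O."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyload.qc import CopyState, HEFilterConfig, he_filter, nullify_all_het
from polyload.simulate import (
    SimulationParams,
    _branch_table,
    plant_homoeologous_exchange,
    retention_probability,
    segregating_retention,
    simulate_clade,
    write_dataset,
)
from polyload.variants import VariantTable


class TestRetentionProbability:
    def test_neutral_limit(self):
        assert retention_probability(0.0, 0.25, 25000) == 1.0

    def test_full_masking_restores_neutral_behavior(self):
        assert retention_probability(0.05, 0.25, 25000, masking_m=1.0, is_polyploid=True) == 1.0

    def test_strong_selection_retained_less_than_weak(self):
        ne = 25000
        weak = retention_probability(1.0 / (2 * ne) / 0.25, 0.25, ne)
        strong = retention_probability(10.0 / (2 * ne) / 0.25, 0.25, ne)
        assert strong < weak < 1.0

    def test_monotone_nonincreasing_in_s(self):
        vals = [retention_probability(s, 0.25, 25000) for s in np.linspace(0, 0.01, 30)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_masking_raises_retention_on_polyploid_branches_only(self):
        base = retention_probability(0.002, 0.25, 25000, masking_m=0.8, is_polyploid=False)
        masked = retention_probability(0.002, 0.25, 25000, masking_m=0.8, is_polyploid=True)
        assert masked > base

    def test_degenerate_inputs_clamped(self):
        assert retention_probability(-1.0, 0.25, 25000) == 1.0
        assert 0.0 <= retention_probability(10.0, 2.0, 0.5) <= 1.0

    def test_segregating_retention_ignores_branch_ne(self):
        # the standing-variation path depends only on the reference Ne
        r = segregating_retention(0.001, 0.25, 25000)
        assert r == pytest.approx(1.0 / (1.0 + 2 * 25000 * 0.001 * 0.25))


class TestParamsValidation:
    def test_probabilities_checked(self):
        with pytest.raises(ValueError, match="masking_m"):
            SimulationParams(masking_m=1.5)

    def test_cds_length_multiple_of_three(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            SimulationParams(cds_length_bp=100)

    def test_tree_tip_mismatch_names_the_tip(self):
        bad = "((K1:1,(K2:1,K3:1)K23:1)KOG:1,((A1:1,WEIRD:1)A_side:1,D5:1)AD_split:1)root;"
        with pytest.raises(ValueError, match="WEIRD"):
            simulate_clade(SimulationParams(species_tree=bad, n_gene_pairs=3))
        missing = "((K1:1,(K2:1,K3:1)K23:1)KOG:1,((A1:1,AD1_At:1)A_side:1,D5:1)AD_split:1)root;"
        with pytest.raises(ValueError, match="AD1_Dt"):
            simulate_clade(SimulationParams(species_tree=missing, n_gene_pairs=3))


def test_zero_mutation_rate_gives_empty_vcf(tmp_path):
    ds = simulate_clade(SimulationParams(n_gene_pairs=5, mu=0.0, collapse_rate=0.0))
    assert ds.variants.n_variants == 0
    paths = write_dataset(ds, tmp_path)
    reread = VariantTable.read_vcf(paths["vcf"])
    assert reread.n_variants == 0
    assert reread.samples == ds.samples


def test_identical_seeds_are_byte_identical(tmp_path):
    params = SimulationParams(n_gene_pairs=20, he_rate=0.2, collapse_rate=0.01, seed=42)
    d1 = write_dataset(simulate_clade(params), tmp_path / "a")
    d2 = write_dataset(simulate_clade(params), tmp_path / "b")
    for key in d1:
        assert filecmp.cmp(d1[key], d2[key], shallow=False), key
    d3 = write_dataset(
        simulate_clade(SimulationParams(n_gene_pairs=20, he_rate=0.2, collapse_rate=0.01, seed=43)),
        tmp_path / "c",
    )
    assert not filecmp.cmp(d1["vcf"], d3["vcf"], shallow=False)


def test_write_read_round_trip_preserves_genotypes(tmp_path, small_dataset):
    paths = write_dataset(small_dataset, tmp_path)
    reread = VariantTable.read_vcf(paths["vcf"])
    assert reread.samples == small_dataset.samples
    assert reread.n_variants == small_dataset.variants.n_variants
    assert (reread.G == small_dataset.variants.G).all()
    assert reread.df["pos"].tolist() == small_dataset.variants.df["pos"].tolist()
    assert reread.df["ref"].tolist() == small_dataset.variants.df["ref"].tolist()


def test_bed_has_one_record_per_gene(tmp_path):
    ds = simulate_clade(SimulationParams(n_gene_pairs=10))
    paths = write_dataset(ds, tmp_path)
    lines = Path(paths["bed"]).read_text().strip().splitlines()
    assert len(lines) == 20


def test_every_variant_lies_inside_its_gene_cds(small_dataset):
    L = small_dataset.params.cds_length_bp
    df = small_dataset.variants.df
    for chrom in ("chrA", "chrD"):
        sub = df[df["chrom"] == chrom]
        for _, row in sub.iterrows():
            pair = small_dataset.pairs[row["pair_idx"]]
            ivs = pair.intervals_at if chrom == "chrA" else pair.intervals_dt
            assert any(s < row["pos"] <= e for s, e in ivs)


def test_outgroups_carry_ancestral_except_outgroup_private(small_dataset):
    from polyload import trees

    ds = small_dataset
    below = trees.clade_tipsets(ds.model.tree)
    og = set(ds.model.outgroups)
    og_cols = ds.variants.sample_index(
        [s for s in ds.samples if ds.species_of[s] in og]
    )
    df = ds.variants.df
    ingroup_origin = df["true_branch"].map(
        lambda b: b in below and not (below[b] & og)
    ).to_numpy()
    real = df["cls"].isin(["synonymous", "nonsynonymous"]).to_numpy()
    g_og = ds.variants.G[np.ix_(np.nonzero(ingroup_origin & real)[0], og_cols)]
    anc_is_ref = ~df.loc[ingroup_origin & real, "ref_is_derived"].to_numpy()
    # outgroup genotypes are hom-ancestral: 0 when REF is ancestral, 2 otherwise
    expected = np.where(anc_is_ref[:, None], 0, 2)
    assert (g_og == expected).all()


class TestPlantedHomoeologousExchange:
    def test_expected_fraction_before_noise(self):
        depths = pd.DataFrame(
            {"gene_id": ["gA", "gD"], "individual": ["i0", "i0"], "expected_depth": [30.0, 30.0]}
        )
        from polyload.qc import HomoeologPair

        pair = HomoeologPair("p0", "gA", "gD", "chrA", "chrD", [(0, 300)], [(0, 300)])
        plant_homoeologous_exchange(depths, pair, ["i0"], CopyState(1, 3), 30.0)
        da = depths.loc[depths.gene_id == "gA", "expected_depth"].iat[0]
        dd = depths.loc[depths.gene_id == "gD", "expected_depth"].iat[0]
        assert 100 * da / (da + dd) == pytest.approx(25.0)

    def test_unknown_pair_rejected(self):
        from polyload.qc import HomoeologPair

        pair = HomoeologPair("p0", "gX", "gY", "chrA", "chrD", [(0, 3)], [(0, 3)])
        depths = pd.DataFrame({"gene_id": [], "individual": [], "expected_depth": []})
        with pytest.raises(ValueError, match="no depth rows"):
            plant_homoeologous_exchange(depths, pair, ["i0"], CopyState(1, 3), 30.0)

    def test_noiseless_depths_realize_the_copy_state_exactly(self, small_dataset):
        ds = small_dataset  # depth_dispersion = 0
        piv = ds.depths.pivot_table(index="individual", columns="gene_id", values="mean_depth")
        planted = ds.he_truth[ds.he_truth.he_planted]
        assert len(planted) > 0
        for _, row in planted.iterrows():
            pair = ds.pairs[int(row.pair_id[1:])]
            for ind in ds.polyploid_individuals:
                da, dd = piv.at[ind, pair.gene_at], piv.at[ind, pair.gene_dt]
                assert da == pytest.approx(30.0 * row.at_copies / 2)
                assert dd == pytest.approx(30.0 * row.dt_copies / 2)


class TestPlantedCollapse:
    def test_planted_sites_are_exactly_the_nullified_sites(self, small_dataset):
        ds = small_dataset
        groups: dict[str, list[str]] = {}
        for s, sp in ds.species_of.items():
            groups.setdefault(sp, []).append(s)
        _, report = nullify_all_het(
            ds.variants,
            groups,
            merge_groups=[{"AD6", "AD7"}],
            outgroup_species=set(ds.model.outgroups),
        )
        planted = ds.variants.df.loc[ds.variants.df["collapse"], ["chrom", "pos"]]
        assert len(planted) > 0
        got = {(c, p) for c, p in zip(report["chrom"], report["pos"])}
        want = {(c, p) for c, p in zip(planted["chrom"], planted["pos"])}
        assert got == want
        assert len(report) == len(planted)  # exactly one group per planted site


class TestHeFilterRecoversPlantedPairs:
    def test_sensitivity_and_specificity_one_on_noiseless_depths(self, small_dataset):
        ds = small_dataset
        kept, report = he_filter(
            ds.pairs, ds.depths, HEFilterConfig(), ds.polyploid_individuals
        )
        removed = set(report.loc[report.status != "retained", "pair_id"])
        planted = set(ds.he_truth.loc[ds.he_truth.he_planted, "pair_id"])
        assert removed == planted


class TestStatisticalProperties:
    def small(self, **kw):
        base = dict(
            n_gene_pairs=60, cds_length_bp=300, he_rate=0.0, collapse_rate=0.0,
            conversion_rate=0.0,
        )
        base.update(kw)
        return SimulationParams(**base)

    def test_neutral_equivalence_class_proportions(self):
        """With no selection, retained class proportions follow frac_synonymous."""
        syn = total = 0
        for seed in range(12):
            ds = simulate_clade(self.small(dfe_mean_s=0.0, seed=seed))
            cls = ds.variants.df["cls"]
            syn += (cls == "synonymous").sum()
            total += len(cls)
        p_hat = syn / total
        se = np.sqrt(0.3 * 0.7 / total)
        assert abs(p_hat - 0.3) < 4 * se

    def test_no_masking_equal_deleterious_retention_per_branch_unit(self):
        """With masking off and equal Ne, deleterious retention per unit of
        branch length is the same on polyploid and diploid branches
        (two-sided paired test, alpha = 0.01, 50 seeds)."""
        poly_rates, dip_rates = [], []
        for seed in range(50):
            params = self.small(seed=1000 + seed)
            ds = simulate_clade(params)
            branches = {b.name: b for b in _branch_table(ds.model, params)}
            df = ds.variants.df
            dele = df.loc[df["deleterious"] & ~df["conversion"]]
            n_sites = params.n_gene_pairs * params.cds_length_bp
            poly_len = sum(b.length for b in branches.values() if b.is_polyploid)
            dip_len = sum(
                branches[n].length for n in ("A1", "D5")
            )
            n_poly = dele["true_branch"].map(
                lambda b: b in branches and branches[b].is_polyploid
            ).sum()
            n_dip = dele["true_branch"].isin(["A1", "D5"]).sum()
            poly_rates.append(n_poly / (poly_len * n_sites))
            dip_rates.append(n_dip / (dip_len * n_sites))
        t = stats.ttest_rel(poly_rates, dip_rates)
        assert t.pvalue > 0.01

    def test_strong_masking_raises_deleterious_proportion_on_polyploid_branches(self):
        """masking_m = 0.9: the proportion of retained nonsynonymous events
        that are deleterious is higher on polyploid than diploid branches in
        at least 95% of 50 seeds."""
        wins = 0
        for seed in range(50):
            params = self.small(masking_m=0.9, seed=2000 + seed)
            ds = simulate_clade(params)
            branches = {b.name: b for b in _branch_table(ds.model, params)}
            df = ds.variants.df
            nonsyn = df.loc[df["cls"] == "nonsynonymous"]
            on_poly = nonsyn["true_branch"].map(
                lambda b: b in branches and branches[b].is_polyploid
            )
            on_dip = nonsyn["true_branch"].isin(["A1", "D5"])
            prop_poly = nonsyn.loc[on_poly, "deleterious"].mean()
            prop_dip = nonsyn.loc[on_dip, "deleterious"].mean()
            wins += prop_poly > prop_dip
        assert wins >= 48  # >= 95% of 50 seeds

    def test_masking_monotonically_raises_expected_deleterious_load(self):
        """Mean retained deleterious count per seed never trends downward
        across the masking grid (one-sided trend over 10 seeds/point)."""
        grid = [0.0, 0.3, 0.6, 0.9]
        means = []
        for m in grid:
            counts = []
            for seed in range(10):
                ds = simulate_clade(self.small(masking_m=m, seed=3000 + seed))
                df = ds.variants.df
                branches = {b.name: b for b in _branch_table(ds.model, ds.params)}
                on_poly = df["true_branch"].map(
                    lambda b: b in branches and branches[b].is_polyploid
                )
                counts.append(int((df["deleterious"] & on_poly).sum()))
            means.append(np.mean(counts))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_depth_noise_model_dispersion_zero_is_deterministic(self):
        ds = simulate_clade(self.small(depth_dispersion=0.0, seed=5))
        assert (ds.depths["mean_depth"] == 30.0).all()
        ds2 = simulate_clade(self.small(depth_dispersion=0.01, seed=5))
        assert ds2.depths["mean_depth"].std() > 0
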