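"""End-to-end orchestration: qc -> linking -> polarize -> scores -> loads.

A single :class:`PipelineConfig` (usually parsed from YAML) either points at
input files (VCF, BED, CDS FASTA, depth TSV, species tree, sample map,
score track, deleterious flags, class annotations) or carries a ``simulate``
block, in which case the synthetic generator produces the inputs first.
Every stage writes its artifact into the output directory together with a
filter ledger (records in/out per stage), and a run with the same config
and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from . import trees
from .coords import GAP, genomic_to_cds
from .linking import (
    LinkedSitePair,
    SiteInfo,
    align_cds,
    link_snp_sites,
    map_alignment_to_genome,
    retention_filter,
)
from .load import (
    BINS,
    DEPTHS,
    bin_loads_table,
    load_summary,
    nucleotide_diversity,
    relative_increase_by_bin,
)
from .polarize import UNRESOLVED, SpeciesTreeModel, polarize_table
from .qc import HEFilterConfig, cds_length_filter, he_filter, nullify_all_het
from .variants import VariantTable

logger = logging.getLogger("polyload")

__all__ = ["PipelineConfig", "run_pipeline", "filter_ledger"]


@dataclass
class PipelineConfig:
    outdir: str
    inputs: dict[str, str] | None = None
    simulate: dict | None = None
    seed: int = 0
    outgroups: list[str] = field(default_factory=lambda: ["K1", "K2", "K3"])
    progenitors: dict[str, str] = field(default_factory=lambda: {"At": "A1", "Dt": "D5"})
    chrom_subgenome: dict[str, str] = field(default_factory=lambda: {"chrA": "At", "chrD": "Dt"})
    merge_groups: list[list[str]] = field(default_factory=lambda: [["AD6", "AD7"]])
    he: dict = field(default_factory=dict)
    min_outgroup_species: int = 2
    criterion4: bool = False
    pi_exclude_nullified: bool = True

    REQUIRED_INPUTS = (
        "vcf", "bed", "fasta", "depths", "species_tree", "samples",
        "scores", "deleterious_flags", "classes",
    )

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("exactly one of `inputs` or `simulate` must be given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate_inputs(self) -> None:
        assert self.inputs is not None
        missing = [k for k in self.REQUIRED_INPUTS if k not in self.inputs]
        if missing:
            raise ValueError(f"config lacks input paths: {missing}")
        absent = [p for p in self.inputs.values() if not Path(p).exists()]
        if absent:
            raise FileNotFoundError(f"input files not found: {absent}")

    def digest(self) -> str:
        """Hash of the analytic settings (paths excluded, so a run moved to
        a different directory keeps its digest)."""
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items() if k not in ("outdir", "inputs")},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def filter_ledger(stages: list[tuple[str, int, int]]) -> pd.DataFrame:
    """Tidy in/out record counts per filter stage."""
    return pd.DataFrame(stages, columns=["stage", "records_in", "records_out"])


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the report directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config_digest = config.digest()
    ledger: list[tuple[str, int, int]] = []

    # ------------------------------------------------------------- inputs
    if config.simulate is not None:
        from .simulate import SimulationParams, simulate_clade, write_dataset

        params = SimulationParams(**{**config.simulate, "seed": config.seed})
        ds = simulate_clade(params)
        paths = write_dataset(ds, out / "data")
        paths["classes"] = str(out / "data" / "classes.tsv")
        cls_df = ds.variants.df[["chrom", "pos", "cls"]].rename(columns={"cls": "class"})
        cls_df.to_csv(paths["classes"], sep="\t", index=False)
        config = dataclasses_replace_inputs(config, paths)
    config.validate_inputs()
    inp = config.inputs
    assert inp is not None

    pairs = pio.read_bed_pairs(inp["bed"])
    pio.attach_sequences(pairs, pio.read_cds_fasta(inp["fasta"]))
    variants = VariantTable.read_vcf(inp["vcf"])
    depths = pio.read_depths(inp["depths"])
    species_of = pio.read_samples(inp["samples"])
    model = SpeciesTreeModel(
        tree=pio.read_newick(inp["species_tree"]),
        outgroups=list(config.outgroups),
        progenitors=dict(config.progenitors),
    )
    scores = pio.read_score_track(inp["scores"]).set_index(["chrom", "pos"])["score"]
    flags = pio.read_deleterious_flags(inp["deleterious_flags"]).set_index(["chrom", "pos"])["deleterious"]
    classes = pd.read_csv(inp["classes"], sep="\t").set_index(["chrom", "pos"])["class"]

    # ------------------------------------------------------------------ qc
    he_cfg = HEFilterConfig(**config.he)
    n0 = len(pairs)
    pairs_len = cds_length_filter(pairs, he_cfg.max_cds_rel_diff)
    ledger.append(("cds_length_filter", n0, len(pairs_len)))

    poly_individuals = [
        s for s, sp in species_of.items() if sp in model.polyploid_species
    ]
    pairs_he, he_report = he_filter(pairs_len, depths, he_cfg, poly_individuals)
    ledger.append(("he_filter", len(pairs_len), len(pairs_he)))
    he_report.to_csv(out / "pair_filter.tsv", sep="\t", index=False)

    species_groups: dict[str, list[str]] = {}
    for sample, sp in species_of.items():
        species_groups.setdefault(sp, []).append(sample)
    nullified, null_report = nullify_all_het(
        variants,
        species_groups,
        merge_groups=[set(g) for g in config.merge_groups],
        outgroup_species=frozenset(config.outgroups),
    )
    ledger.append(
        ("nullify_all_het_sites", variants.n_variants, variants.n_variants - null_report[["chrom", "pos"]].drop_duplicates().shape[0])
    )
    null_report.to_csv(out / "nullified_sites.tsv", sep="\t", index=False)
    nullified.write_vcf(out / "nullified.vcf")

    # ------------------------------------------------- restrict to CDS sites
    keep_mask = np.zeros(nullified.n_variants, dtype=bool)
    pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom in nullified.df["chrom"].unique():
        pos_by_chrom[chrom] = nullified.df.loc[nullified.df["chrom"] == chrom, "pos"].to_numpy()
    pair_site_rows: dict[str, dict[str, list[int]]] = {}
    chrom_rows = {
        chrom: np.nonzero((nullified.df["chrom"] == chrom).to_numpy())[0]
        for chrom in pos_by_chrom
    }
    for pair in pairs_he:
        rows_at, rows_dt = [], []
        for gene_rows, chrom, ivs in (
            (rows_at, pair.chrom_at, pair.intervals_at),
            (rows_dt, pair.chrom_dt, pair.intervals_dt),
        ):
            rows = chrom_rows.get(chrom, np.array([], dtype=int))
            pos = pos_by_chrom.get(chrom, np.array([], dtype=int))
            for s, e in ivs:
                inside = rows[(pos > s) & (pos <= e)]
                gene_rows.extend(int(r) for r in inside)
        for r in rows_at + rows_dt:
            keep_mask[r] = True
        pair_site_rows[pair.pair_id] = {"at": rows_at, "dt": rows_dt}
    cds_variants = nullified.subset(keep_mask)
    ledger.append(("cds_restriction", nullified.n_variants, cds_variants.n_variants))
    new_row = np.full(nullified.n_variants, -1, dtype=int)
    new_row[np.nonzero(keep_mask)[0]] = np.arange(cds_variants.n_variants)
    for sites in pair_site_rows.values():
        sites["at"] = [int(new_row[r]) for r in sites["at"]]
        sites["dt"] = [int(new_row[r]) for r in sites["dt"]]

    # ------------------------------------------------------------ polarize
    pol_df, p, lineages, pol_report = polarize_table(
        cds_variants,
        species_of,
        model,
        config.chrom_subgenome,
        min_outgroup_species=config.min_outgroup_species,
    )
    ledger.append(("polarization", cds_variants.n_variants, len(pol_df)))

    # ------------------------------------------------------------- linking
    anc_frame = pol_report.pop("site_ancestral")
    anc_by_pos = {
        (c, int(q)): a
        for c, q, a in zip(anc_frame["chrom"], anc_frame["pos"], anc_frame["anc"])
    }
    groups = {"At": _group_cols(lineages, model, "At"), "Dt": _group_cols(lineages, model, "Dt")}
    pres_df = pol_df[["chrom", "pos"]].copy()
    for sub, cols in groups.items():
        pres_df[f"present_{sub}"] = np.nan_to_num(p[:, cols]).sum(axis=1) > 0
    pres_by_pos = pres_df.set_index(["chrom", "pos"])

    retained_positions: set[tuple[str, int]] = set()
    linked_rows = []
    n_links = 0
    for pair in pairs_he:
        aln = align_cds(pair.seq_at, pair.seq_dt)
        colmap = map_alignment_to_genome(aln, pair)
        snp_at = [int(cds_variants.df["pos"].iat[r]) for r in pair_site_rows[pair.pair_id]["at"]]
        snp_dt = [int(cds_variants.df["pos"].iat[r]) for r in pair_site_rows[pair.pair_id]["dt"]]
        linked = link_snp_sites(snp_at, snp_dt, colmap, pair)
        n_links += len(linked)
        info_at = _site_infos(
            pair, "at", linked, cds_variants, pair_site_rows[pair.pair_id]["at"],
            anc_by_pos, pres_by_pos, groups, p, lineages, model,
        )
        info_dt = _site_infos(
            pair, "dt", linked, cds_variants, pair_site_rows[pair.pair_id]["dt"],
            anc_by_pos, pres_by_pos, groups, p, lineages, model,
        )
        verdicts = retention_filter(linked, info_at, info_dt, criterion4=config.criterion4)
        for v in verdicts:
            linked_rows.append(
                (pair.pair_id, v.site.pos_at, v.site.pos_dt, v.site.opposite_strand,
                 "retained" if v.retained else "removed",
                 ";".join(map(str, v.failed_criteria)))
            )
            if v.retained:
                if v.site.pos_at != GAP:
                    retained_positions.add((pair.chrom_at, v.site.pos_at))
                if v.site.pos_dt != GAP:
                    retained_positions.add((pair.chrom_dt, v.site.pos_dt))
    pd.DataFrame(
        linked_rows,
        columns=["pair_id", "pos_at", "pos_dt", "opposite_strand", "status", "failed_criteria"],
    ).to_csv(out / "linked_sites.tsv", sep="\t", index=False)

    keep = np.array(
        [
            (c, int(q)) in retained_positions
            for c, q in zip(pol_df["chrom"], pol_df["pos"])
        ],
        dtype=bool,
    ) if len(pol_df) else np.zeros(0, dtype=bool)
    final_df = pol_df.loc[keep].reset_index(drop=True)
    final_p = p[keep]
    ledger.append(("snp_retention", len(pol_df), len(final_df)))

    # ------------------------------------------- annotations + load stats
    key = pd.MultiIndex.from_frame(final_df[["chrom", "pos"]])
    final_df["class"] = classes.reindex(key).to_numpy()
    final_df["deleterious"] = (
        pd.Series(flags.reindex(key).to_numpy()).fillna(False).astype(bool).to_numpy()
    )
    final_df["score"] = scores.reindex(key).to_numpy()
    known = final_df["class"].isin(["synonymous", "nonsynonymous"]).to_numpy()
    final_df = final_df.loc[known].reset_index(drop=True)
    final_p = final_p[known]

    pol_out = final_df.copy()
    for j, lineage in enumerate(lineages):
        pol_out[f"p_{lineage}"] = final_p[:, j]
    pol_out.to_csv(out / "polarized_variants.tsv", sep="\t", index=False)

    summary = load_summary(final_df, final_p, lineages)
    summary.to_csv(out / "load_by_depth.tsv", sep="\t", index=False)
    summary[["lineage", "depth_class", "proportion_deleterious"]].to_csv(
        out / "proportion_deleterious.tsv", sep="\t", index=False
    )

    loads = bin_loads_table(final_df, final_p, lineages, "since_prog")
    ri_rows = []
    for sub, diploid in model.progenitors.items():
        ratios = relative_increase_by_bin(loads, diploid)
        members = [diploid] + [f"{sp}_{sub}" for sp in model.polyploid_species]
        for lineage in members:
            for b in BINS:
                ri_rows.append((lineage, b, ratios[lineage][b]))
    pd.DataFrame(ri_rows, columns=["lineage", "bin", "relative_increase"]).to_csv(
        out / "relative_increase.tsv", sep="\t", index=False
    )

    diversity = _diversity_table(
        config, model, species_of, cds_variants, pairs_he, pair_site_rows, null_report
    )
    diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)

    led = filter_ledger(ledger)
    led.to_csv(out / "filter_ledger.tsv", sep="\t", index=False)
    manifest = {
        "config_digest": config_digest,
        "seed": config.seed,
        "n_pairs_input": n0,
        "n_pairs_analyzed": len(pairs_he),
        "n_linked_sites": n_links,
        "n_variants_analyzed": int(len(final_df)),
        "polarization": pol_report,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished: %s", manifest)
    return out


def dataclasses_replace_inputs(config: PipelineConfig, paths: dict[str, str]) -> PipelineConfig:
    import dataclasses

    return dataclasses.replace(config, inputs=dict(paths), simulate=None)


def _group_cols(lineages: list[str], model: SpeciesTreeModel, sub: str) -> list[int]:
    members = set(model.lineages(sub))
    return [i for i, l in enumerate(lineages) if l in members]


def _site_infos(
    pair, side, linked, cds_variants, gene_rows, anc_by_pos, pres_by_pos,
    groups, p, lineages, model,
):
    """Build SiteInfo for every linked position on one side of a pair."""
    chrom = pair.chrom_at if side == "at" else pair.chrom_dt
    intervals = pair.intervals_at if side == "at" else pair.intervals_dt
    strand = pair.strand_at if side == "at" else pair.strand_dt
    seq = pair.seq_at if side == "at" else pair.seq_dt
    sub = "At" if side == "at" else "Dt"
    df = cds_variants.df
    by_pos = {int(df["pos"].iat[r]): r for r in gene_rows}
    infos: dict[int, SiteInfo] = {}
    for site in linked:
        pos = site.pos_at if side == "at" else site.pos_dt
        if pos == GAP or pos in infos:
            continue
        row = by_pos.get(pos)
        if row is None:
            # monomorphic in the data: reference base, trivially ancestral
            off = genomic_to_cds(pos - 1, intervals, strand)
            base = seq[off]
            if strand == "-":
                from .coords import complement

                base = complement(base)
            infos[pos] = SiteInfo.monomorphic(base)
            continue
        ref = df["ref"].iat[row]
        alt = df["alt"].iat[row]
        anc = anc_by_pos.get((chrom, pos), UNRESOLVED)
        try:
            pres = bool(pres_by_pos.at[(chrom, pos), f"present_{sub}"])
        except KeyError:
            pres = False
        der = alt if anc == ref else (ref if anc == alt else None)
        present = {anc: True} if anc != UNRESOLVED else {}
        if der is not None:
            present[der] = pres
        dip = model.progenitors[sub]
        dip_freq = None
        sub_freqs: tuple[float, ...] = ()
        if der is not None and (chrom, pos) in pres_by_pos.index:
            j = lineages.index(dip)
            row_idx = pres_by_pos.index.get_loc((chrom, pos))
            dip_freq = float(p[row_idx, j]) if not np.isnan(p[row_idx, j]) else None
            sub_freqs = tuple(
                float(p[row_idx, lineages.index(l)])
                for l in model.lineages(sub)
                if l != dip and not np.isnan(p[row_idx, lineages.index(l)])
            )
        infos[pos] = SiteInfo(
            ref=ref, alleles=(ref, alt), anc=anc, present=present,
            diploid_freq=dip_freq, subgenome_freqs=sub_freqs,
        )
    return infos


def _diversity_table(
    config, model, species_of, table, pairs_he, pair_site_rows, null_report
):
    rows = []
    total_len = {
        "At": sum(pr.cds_length_at for pr in pairs_he),
        "Dt": sum(pr.cds_length_dt for pr in pairs_he),
    }
    cds_rows = {"At": [], "Dt": []}
    for pr in pairs_he:
        cds_rows["At"].extend(pair_site_rows[pr.pair_id]["at"])
        cds_rows["Dt"].extend(pair_site_rows[pr.pair_id]["dt"])
    null_by_group: dict[str, set[tuple[str, int]]] = {}
    for _, r in null_report.iterrows():
        null_by_group.setdefault(r["group"], set()).add((r["chrom"], int(r["pos"])))
    for sub in model.progenitors:
        tip_samples = model.tip_samples(sub, species_of)
        for lineage, samples in tip_samples.items():
            species = lineage if lineage == model.progenitors[sub] else lineage[: -len(sub) - 1]
            idx = table.sample_index(samples)
            rsel = np.array(sorted(set(cds_rows[sub])), dtype=int)
            g = table.G[np.ix_(rsel, idx)] if rsel.size else np.zeros((0, len(idx)), dtype=np.int8)
            n_excl = 0
            if config.pi_exclude_nullified:
                for group, sites in null_by_group.items():
                    if species in group.split("+"):
                        chrom_set = {table.df["chrom"].iat[r] for r in rsel} if rsel.size else set()
                        n_excl += sum(1 for c, _ in sites if c in chrom_set)
            res = nucleotide_diversity(g, total_len[sub], n_excl, lineage)
            rows.append((lineage, sub, res.pi, res.total_sites, res.n_variant_sites))
    return pd.DataFrame(
        rows, columns=["lineage", "subgenome", "pi", "total_sites", "n_variant_sites"]
    )
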