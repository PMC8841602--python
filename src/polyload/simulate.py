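"""Synthetic allopolyploid-clade data generator.

Generates a clade with the structure the load analysis assumes: two diploid
progenitor species (A1, D5), six allopolyploid species carrying At/Dt
subgenomes descended from a single polyploidization, and three outgroup
species used for polarization.  Mutation events are placed on the branches
of a species tree by Poisson sampling (branch lengths in substitutions per
site), classified as synonymous / nonsynonymous / deleterious, and retained
according to a two-component selection model:

* a fixation path — the classic diffusion (Kimura) probability that a new
  mutation with heterozygous selection coefficient s*h_eff fixes, relative
  to a neutral mutation, evaluated with the branch's effective population
  size.  h_eff = h * (1 - masking_m) on polyploid branches: the masking
  coefficient models the shielding of recessive deleterious alleles by the
  homoeologous gene copy.
* a segregating path — transient standing variation on terminal branches,
  retained with probability 1 / (1 + 2 * Ne_ref * s * h_eff), the
  mutation-selection-balance scaling of equilibrium frequency.  This path
  deliberately uses a fixed reference Ne, so a pure bottleneck (lower Ne on
  polyploid branches, no masking) changes fixation retention but not
  segregating retention, while masking rescales both.

Artifacts the QC stage must catch are planted explicitly: homoeologous
exchanges as non-2:2 copy-number depth signatures, collapsed reference
regions as all-heterozygote variant calls, and homoeologous gene conversion
as derived alleles copied across subgenomes at linked positions.

Everything is driven by a single master seed through independent named
substreams, so identical parameters give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import trees
from .coords import cds_to_genomic, complement
from .polarize import SpeciesTreeModel
from .qc import CopyState, HomoeologPair
from .variants import VariantTable

__all__ = [
    "SimulationParams",
    "SyntheticDataset",
    "simulate_clade",
    "retention_probability",
    "segregating_retention",
    "plant_homoeologous_exchange",
    "plant_collapsed_region",
    "write_dataset",
    "evolve_jc_alignment",
    "DEFAULT_SPECIES_TREE",
]

BASES = np.array(list("ACGT"))

# Time-scaled topology (substitutions/site at neutral sites, ~0.003 per My):
# outgroups split 7 Mya, progenitor genomes 5 Mya, sampled progenitor
# lineages 2 Mya, polyploid crown 1.3 Mya.
def _crown(sub: str) -> str:
    s = sub
    return (
        f"(AD4_{s}:0.0039,(AD5_{s}:0.003,(AD3_{s}:0.0024,(AD1_{s}:0.0015,"
        f"(AD6_{s}:0.0009,AD7_{s}:0.0009){s}67:0.0006){s}167:0.0009)"
        f"{s}c3:0.0006){s}c2:0.0009){s}_crown"
    )


DEFAULT_SPECIES_TREE = (
    "((K1:0.009,(K2:0.0045,K3:0.0045)K23:0.0045)KOG:0.012,"
    f"((A1:0.006,{_crown('At')}:0.0021)A_side:0.009,"
    f"(D5:0.006,{_crown('Dt')}:0.0021)D_side:0.009)AD_split:0.006)root;"
)

DEFAULT_OUTGROUPS = ["K1", "K2", "K3"]
DEFAULT_PROGENITORS = {"At": "A1", "Dt": "D5"}

_STREAMS = (
    "layout",
    "sequences",
    "mutations",
    "dfe",
    "retention",
    "freqs",
    "genotypes",
    "artifacts",
    "depths",
    "scores",
)


@dataclass
class SimulationParams:
    """All knobs of the generator; defaults are the package's study conditions."""

    species_tree: str = DEFAULT_SPECIES_TREE
    outgroups: tuple[str, ...] = tuple(DEFAULT_OUTGROUPS)
    progenitors: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PROGENITORS))
    n_individuals: int | dict[str, int] = 3
    n_gene_pairs: int = 200
    cds_length_bp: int = 300
    mu: float = 1.0  # rescales branch lengths (already substitutions/site)
    frac_synonymous: float = 0.3
    frac_deleterious: float = 0.45  # of nonsynonymous candidates
    dfe_shape: float = 0.5
    dfe_mean_s: float = 1e-3
    h: float = 0.25
    Ne: int | dict[str, int] = 25000
    ne_reference: int = 25000
    masking_m: float = 0.0
    seg_fraction: float = 0.4  # candidates on terminal branches taking the segregating path
    he_rate: float = 0.05
    collapse_rate: float = 0.001
    conversion_rate: float = 0.01
    depth_mean: float = 30.0
    depth_dispersion: float = 0.0005
    score_scale_a: float = 1.2
    score_noise: float = 0.25
    minus_strand_fraction: float = 0.3  # of Dt gene models
    cross_map_diploids: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "frac_synonymous": self.frac_synonymous,
            "frac_deleterious": self.frac_deleterious,
            "h": self.h,
            "masking_m": self.masking_m,
            "seg_fraction": self.seg_fraction,
            "he_rate": self.he_rate,
            "collapse_rate": self.collapse_rate,
            "conversion_rate": self.conversion_rate,
            "minus_strand_fraction": self.minus_strand_fraction,
        }
        for name, val in probs.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.cds_length_bp <= 0 or self.cds_length_bp % 3:
            raise ValueError("cds_length_bp must be a positive multiple of 3")
        if self.n_gene_pairs <= 0:
            raise ValueError("n_gene_pairs must be positive")
        if self.mu < 0 or self.dfe_mean_s < 0:
            raise ValueError("rates must be nonnegative")

    def ne_of(self, species: str) -> int:
        if isinstance(self.Ne, dict):
            return int(self.Ne[species])
        return int(self.Ne)

    def n_ind(self, species: str) -> int:
        if isinstance(self.n_individuals, dict):
            return int(self.n_individuals[species])
        return int(self.n_individuals)


def retention_probability(
    s: float, h: float, Ne: float, masking_m: float = 0.0, is_polyploid: bool = False
) -> float:
    """Relative fixation probability of a deleterious mutation (Kimura).

    Probability that a new mutation with heterozygous selection s * h_eff
    fixes, divided by the neutral fixation probability 1/(2Ne);
    h_eff = h * (1 - masking_m) when ``is_polyploid``.  Returns 1 in the
    neutral limit and decreases monotonically with s * h_eff.  Degenerate
    inputs are clamped rather than raised.
    """
    s = max(float(s), 0.0)
    h = min(max(float(h), 0.0), 1.0)
    masking_m = min(max(float(masking_m), 0.0), 1.0)
    Ne = max(float(Ne), 1.0)
    h_eff = h * (1.0 - masking_m) if is_polyploid else h
    return float(_kimura_retention(np.array([s * h_eff]), Ne)[0])


def _kimura_retention(sigma: np.ndarray, Ne: float | np.ndarray) -> np.ndarray:
    """Vectorized 2N * (1 - e^{2 sigma}) / (1 - e^{4 N sigma}), sigma >= 0."""
    sigma = np.asarray(sigma, dtype=float)
    Ne = np.asarray(Ne, dtype=float)
    S2 = 4.0 * Ne * sigma  # exponent of the denominator
    out = np.ones(np.broadcast(sigma, Ne).shape)
    nz = sigma > 0
    if np.any(nz):
        s_nz = np.broadcast_to(sigma, out.shape)[nz]
        n_nz = np.broadcast_to(Ne, out.shape)[nz]
        s2 = np.broadcast_to(S2, out.shape)[nz]
        with np.errstate(over="ignore"):
            num = np.expm1(2.0 * s_nz)
            den = np.expm1(np.minimum(s2, 700.0))
            vals = 2.0 * n_nz * num / den
        vals = np.where(s2 > 700.0, 0.0, vals)
        out[nz] = vals
    return out


def segregating_retention(
    s: np.ndarray | float, h_eff: np.ndarray | float, ne_reference: float
) -> np.ndarray | float:
    """Retention of transient standing variants: 1/(1 + 2 Ne_ref s h_eff).

    Mutation-selection-balance scaling; independent of the branch's own Ne,
    so demography alone does not move it.
    """
    return 1.0 / (1.0 + 2.0 * ne_reference * np.asarray(s, dtype=float) * h_eff)


# --------------------------------------------------------------------------
# branch bookkeeping


@dataclass
class _Branch:
    name: str
    length: float
    tipset: frozenset[str]
    side: str  # 'A', 'D', or 'shared' (above the progenitor split / outgroups)
    is_polyploid: bool
    terminal_species: str | None
    ne: float


def _branch_table(model: SpeciesTreeModel, params: SimulationParams) -> list[_Branch]:
    tree = model.tree
    below = trees.clade_tipsets(tree)
    at_tips = {f"{sp}_At" for sp in model.polyploid_species}
    dt_tips = {f"{sp}_Dt" for sp in model.polyploid_species}
    a_side = at_tips | {model.progenitors["At"]}
    d_side = dt_tips | {model.progenitors["Dt"]}
    out = []
    for node in tree.postorder():
        if node is tree:
            continue
        tipset = below[node.name]
        if tipset <= a_side:
            side = "A"
        elif tipset <= d_side:
            side = "D"
        else:
            side = "shared"
        species = None
        if node.is_tip:
            name = node.name
            species = name[:-3] if (name in at_tips or name in dt_tips) else name
        ingroup_species = {
            t[:-3] if t in at_tips | dt_tips else t
            for t in tipset
            if t not in model.outgroups
        }
        if ingroup_species:
            ne = float(np.mean([params.ne_of(sp) for sp in ingroup_species]))
        else:
            ne = float(params.ne_reference)
        out.append(
            _Branch(
                name=node.name,
                length=node.length,
                tipset=tipset,
                side=side,
                is_polyploid=tipset <= at_tips or tipset <= dt_tips,
                terminal_species=species,
                ne=ne,
            )
        )
    return out


# --------------------------------------------------------------------------
# dataset container


@dataclass
class SyntheticDataset:
    params: SimulationParams
    model: SpeciesTreeModel
    samples: list[str]
    species_of: dict[str, str]
    pairs: list[HomoeologPair]
    variants: VariantTable  # df carries truth columns alongside VCF fields
    depths: pd.DataFrame  # gene_id, individual, mean_depth
    he_truth: pd.DataFrame  # pair_id, he_planted, at_copies, dt_copies

    @property
    def chrom_subgenome(self) -> dict[str, str]:
        return {"chrA": "At", "chrD": "Dt"}

    @property
    def contigs(self) -> dict[str, int]:
        L, n = self.params.cds_length_bp, self.params.n_gene_pairs
        length = 100 + n * (L + 100)
        return {"chrA": length, "chrD": length}

    @property
    def truth(self) -> pd.DataFrame:
        cols = [
            "chrom", "pos", "id", "event", "pair_idx", "cds_offset", "true_branch",
            "cls", "s", "score", "fixed", "conversion", "collapse",
        ]
        return self.variants.df[cols]

    @property
    def polyploid_individuals(self) -> list[str]:
        return [
            s for s in self.samples if self.species_of[s] in self.model.polyploid_species
        ]


# --------------------------------------------------------------------------
# core simulation


def simulate_clade(params: SimulationParams) -> SyntheticDataset:
    """Run the generator; see the module docstring for the model."""
    model = SpeciesTreeModel(
        tree=trees.parse_newick(params.species_tree),
        outgroups=list(params.outgroups),
        progenitors=dict(params.progenitors),
    )
    tip_names = set(model.tree.tip_names())
    expected_tips = (
        set(params.outgroups)
        | set(params.progenitors.values())
        | {f"{sp}_{sub}" for sp in model.polyploid_species for sub in params.progenitors}
    )
    stray = tip_names - expected_tips
    if stray:
        raise ValueError(f"species tree contains unexpected tips: {sorted(stray)}")

    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(_STREAMS, np.random.SeedSequence(params.seed).spawn(len(_STREAMS)))
    }

    species_order = (
        [params.progenitors["At"], params.progenitors["Dt"]]
        + model.polyploid_species
        + list(params.outgroups)
    )
    samples: list[str] = []
    species_of: dict[str, str] = {}
    for sp in species_order:
        for i in range(params.n_ind(sp)):
            name = f"{sp}_i{i}"
            samples.append(name)
            species_of[name] = sp

    n_pairs, L = params.n_gene_pairs, params.cds_length_bp
    n_sites = n_pairs * L

    # gene models: one exon per gene; Dt genes may be minus strand
    rng_layout = streams["layout"]
    dt_minus = rng_layout.random(n_pairs) < params.minus_strand_fraction
    pairs = []
    for g in range(n_pairs):
        start = 100 + g * (L + 100)
        pairs.append(
            HomoeologPair(
                pair_id=f"p{g:05d}",
                gene_at=f"g{g:05d}_At",
                gene_dt=f"g{g:05d}_Dt",
                chrom_at="chrA",
                chrom_dt="chrD",
                intervals_at=[(start, start + L)],
                intervals_dt=[(start, start + L)],
                strand_at="+",
                strand_dt="-" if dt_minus[g] else "+",
            )
        )

    # ancestral CDS sequences (shared by the two homoeologs of a pair)
    anc_seq = streams["sequences"].integers(0, 4, size=n_sites).astype(np.int8)

    branches = _branch_table(model, params)
    events = _draw_events(params, model, branches, streams, n_sites)

    # genotype assembly per chromosome + artifact planting
    table, he_truth, depths = _assemble(
        params, model, branches, events, pairs, anc_seq, samples, species_of, streams
    )
    return SyntheticDataset(
        params=params,
        model=model,
        samples=samples,
        species_of=species_of,
        pairs=pairs,
        variants=table,
        depths=depths,
        he_truth=he_truth,
    )


def _draw_events(params, model, branches, streams, n_sites) -> pd.DataFrame:
    rng_mut = streams["mutations"]
    rng_dfe = streams["dfe"]
    rng_ret = streams["retention"]
    rng_frq = streams["freqs"]

    lam = np.array([params.mu * b.length * n_sites for b in branches])
    counts = rng_mut.poisson(lam)
    total = int(counts.sum())
    if total > n_sites:
        raise ValueError(
            f"mutation density too high: {total} candidate mutations for {n_sites} sites"
        )
    sites = rng_mut.choice(n_sites, size=total, replace=False)
    edge_idx = np.repeat(np.arange(len(branches)), counts)

    is_syn = rng_mut.random(total) < params.frac_synonymous
    is_del = (~is_syn) & (rng_dfe.random(total) < params.frac_deleterious)
    s = np.zeros(total)
    if params.dfe_mean_s > 0 and is_del.any():
        s[is_del] = rng_dfe.gamma(
            params.dfe_shape, params.dfe_mean_s / params.dfe_shape, size=int(is_del.sum())
        )

    poly = np.array([b.is_polyploid for b in branches])[edge_idx]
    h_eff = np.where(poly, params.h * (1.0 - params.masking_m), params.h)
    ne_branch = np.array([b.ne for b in branches])[edge_idx]
    terminal = np.array([b.terminal_species is not None for b in branches])[edge_idx]

    seg = terminal & (rng_ret.random(total) < params.seg_fraction)
    sigma = s * h_eff
    p_keep = np.where(
        seg,
        segregating_retention(s, h_eff, params.ne_reference),
        _kimura_retention(sigma, ne_branch),
    )
    keep = rng_ret.random(total) < p_keep

    q = np.ones(total)
    if seg.any():
        q[seg] = rng_frq.beta(0.5, 0.5, size=int(seg.sum()))

    # conservation score track values (truth): monotone in s for deleterious
    rng_sc = streams["scores"]
    eps = rng_sc.uniform(-params.score_noise, params.score_noise, size=total)
    score = np.where(
        is_del,
        np.minimum(6.0, params.score_scale_a * np.log1p(s * params.ne_reference) + eps),
        -rng_sc.uniform(0.0, 1.0, size=total),
    )

    # derived base: uniform over the three non-ancestral bases (index shift)
    base_shift = rng_mut.integers(1, 4, size=total).astype(np.int8)

    df = pd.DataFrame(
        {
            "site": sites,
            "edge": edge_idx,
            "cls": np.where(is_syn, "synonymous", "nonsynonymous"),
            "deleterious": is_del,
            "s": s,
            "score": score,
            "seg": seg,
            "q": q,
            "base_shift": base_shift,
        }
    )
    return df.loc[keep].reset_index(drop=True)


def plant_homoeologous_exchange(
    depth_expected: pd.DataFrame,
    pair: HomoeologPair,
    individuals: list[str],
    copy_state: CopyState,
    depth_mean: float,
) -> pd.DataFrame:
    """Overwrite a pair's expected depths with an HE copy-state signature.

    Before noise, the At-read fraction of the modified rows is exactly
    at_copies / 4 (e.g. 2:2 -> 50%, 4:0 -> 100%).
    """
    out = depth_expected
    sel_at = out["gene_id"].eq(pair.gene_at) & out["individual"].isin(individuals)
    sel_dt = out["gene_id"].eq(pair.gene_dt) & out["individual"].isin(individuals)
    if not sel_at.any() or not sel_dt.any():
        raise ValueError(f"pair {pair.pair_id} has no depth rows for these individuals")
    out.loc[sel_at, "expected_depth"] = depth_mean * copy_state.at_copies / 2.0
    out.loc[sel_dt, "expected_depth"] = depth_mean * copy_state.dt_copies / 2.0
    return out


def plant_collapsed_region(G: np.ndarray, row: int, sample_cols: np.ndarray) -> None:
    """Set every individual of a species group heterozygous at one site."""
    G[row, sample_cols] = 1


def _assemble(params, model, branches, events, pairs, anc_seq, samples, species_of, streams):
    n_samples = len(samples)
    col_of = {s: i for i, s in enumerate(samples)}
    at_tips = {f"{sp}_At" for sp in model.polyploid_species}
    dt_tips = {f"{sp}_Dt" for sp in model.polyploid_species}
    dip_at, dip_dt = params.progenitors["At"], params.progenitors["Dt"]

    def tip_of(species: str, chrom: str) -> str:
        if species in model.polyploid_species:
            return f"{species}_{'At' if chrom == 'chrA' else 'Dt'}"
        return species

    # per chromosome: columns of each species, carrier columns per branch
    sp_cols = {
        sp: np.array([col_of[s] for s in samples if species_of[s] == sp])
        for sp in set(species_of.values())
    }

    rng_gt = streams["genotypes"]
    rng_art = streams["artifacts"]

    records: dict[str, dict] = {}
    for chrom, sides, ref_tip, other_dip in (
        ("chrA", {"A", "shared"}, "AD1_At", dip_dt),
        ("chrD", {"D", "shared"}, "AD1_Dt", dip_at),
    ):
        sel = np.array([branches[e].side in sides for e in events["edge"]], dtype=bool)
        ev = events.loc[sel]  # keep the global event index
        n = len(ev)
        G = np.zeros((n, n_samples), dtype=np.int8)
        if not params.cross_map_diploids and len(sp_cols[other_dip]):
            G[:, sp_cols[other_dip]] = -1
        ref_carrier = np.zeros(n, dtype=bool)
        edges_here = ev["edge"].to_numpy()
        fixed = ~ev["seg"].to_numpy()
        for e in np.unique(edges_here):
            br = branches[e]
            rows = np.nonzero(edges_here == e)[0]
            carrier_species = sorted(
                {sp for sp in sp_cols if tip_of(sp, chrom) in br.tipset}
            )
            if not params.cross_map_diploids and other_dip in carrier_species:
                carrier_species.remove(other_dip)
            cols = np.concatenate([sp_cols[sp] for sp in carrier_species]) if carrier_species else np.array([], dtype=int)
            fx = rows[fixed[rows]]
            if fx.size and cols.size:
                G[np.ix_(fx, cols)] = 2
            sg = rows[~fixed[rows]]
            if sg.size:
                # segregating events live on terminal branches: one species
                assert br.terminal_species is not None
                sp = br.terminal_species
                if sp in carrier_species:
                    scols = sp_cols[sp]
                    qv = ev["q"].to_numpy()[sg]
                    draws = rng_gt.binomial(2, qv[:, None], size=(sg.size, scols.size)).astype(np.int8)
                    # never leave a species all-heterozygous by chance (the
                    # all-het signature is reserved for planted collapses),
                    # and never emit an all-absent variant
                    all_het = (draws == 1).all(axis=1)
                    draws[all_het, 0] = np.where(qv[all_het] < 0.5, 0, 2)
                    none = (draws == 0).all(axis=1)
                    draws[none, 0] = 1
                    het_fix = (draws == 1).all(axis=1)
                    draws[het_fix, 0] = 2
                    G[np.ix_(sg, scols)] = draws
            if ref_tip in br.tipset:
                ref_carrier[rows[fixed[rows]]] = True
        rec = {
            "chrom": chrom,
            "ev": ev,
            "G": G,
            "ref_carrier": ref_carrier,
            "conversion": np.zeros(n, dtype=bool),
            "collapse": np.zeros(n, dtype=bool),
            "event_id": ev.index.to_numpy() if n else np.array([], dtype=int),
        }
        records[chrom] = rec

    # ---- gene conversion: copy a derived allele across subgenomes.  Only a
    # polyploid lineage that actually carries the derived allele can donate
    # it to its other subgenome; the reference species (AD1) is excluded as a
    # target so the reference haplotypes stay free of conversion alleles.
    conv_rows: dict[str, list] = {"chrA": [], "chrD": []}
    for chrom, other in (("chrA", "chrD"), ("chrD", "chrA")):
        rec = records[chrom]
        ev = rec["ev"]
        side = "A" if chrom == "chrA" else "D"
        eligible = np.array(
            [branches[e].side == side for e in ev["edge"]], dtype=bool
        ) if len(ev) else np.array([], dtype=bool)
        pick = eligible & (rng_art.random(len(ev)) < params.conversion_rate)
        for i in np.nonzero(pick)[0]:
            tipset = branches[ev["edge"].iat[i]].tipset
            carriers = sorted(
                sp for sp in model.polyploid_species
                if sp != "AD1" and tip_of(sp, chrom) in tipset
            )
            if not carriers:
                continue
            target = carriers[rng_art.integers(len(carriers))]
            rec["conversion"][i] = True
            conv_rows[other].append((int(ev["site"].iat[i]), int(ev["base_shift"].iat[i]),
                                     float(ev["score"].iat[i]), ev["cls"].iat[i],
                                     bool(ev["deleterious"].iat[i]), float(ev["s"].iat[i]),
                                     target))

    # ---- optional diploid cross-mapping: a diploid's own variants surface
    # at the homoeologous coordinates when its reads are mapped against the
    # other subgenome's reference
    cross_rows: dict[str, list] = {"chrA": [], "chrD": []}
    if params.cross_map_diploids:
        for chrom, other, dip in (("chrA", "chrD", dip_at), ("chrD", "chrA", dip_dt)):
            rec = records[chrom]
            ev = rec["ev"]
            side = "A" if chrom == "chrA" else "D"
            for i in range(len(ev)):
                br = branches[ev["edge"].iat[i]]
                if br.side != side or dip not in br.tipset:
                    continue
                gt = rec["G"][i, sp_cols[dip]].copy()
                cross_rows[other].append(
                    (int(ev["site"].iat[i]), int(ev["base_shift"].iat[i]),
                     float(ev["score"].iat[i]), ev["cls"].iat[i],
                     bool(ev["deleterious"].iat[i]), float(ev["s"].iat[i]),
                     br.name, bool(~ev["seg"].iat[i]), dip, gt)
                )

    # ---- collapse artifacts on unused sites
    n_sites = params.n_gene_pairs * params.cds_length_bp
    used = set(int(x) for x in events["site"])
    collapse_groups = _collapse_groups(model)
    collapse_rows: dict[str, list] = {"chrA": [], "chrD": []}
    if params.collapse_rate > 0:
        unused = np.setdiff1d(np.arange(n_sites), np.fromiter(used, dtype=int, count=len(used)))
        for chrom in ("chrA", "chrD"):
            n_art = rng_art.binomial(len(unused), params.collapse_rate)
            if n_art == 0:
                continue
            chosen = rng_art.choice(len(unused), size=n_art, replace=False)
            for idx in chosen:
                site = int(unused[idx])
                grp = collapse_groups[rng_art.integers(len(collapse_groups))]
                collapse_rows[chrom].append((site, grp))
            unused = np.delete(unused, chosen)

    # ---- materialize genomic records
    frames = []
    gmats = []
    seqs: dict[str, np.ndarray] = {}
    for pair in pairs:
        seqs[pair.gene_at] = anc_seq[
            int(pair.pair_id[1:]) * params.cds_length_bp : (int(pair.pair_id[1:]) + 1) * params.cds_length_bp
        ].copy()
        seqs[pair.gene_dt] = seqs[pair.gene_at].copy()

    branch_names = np.array([b.name for b in branches])
    L = params.cds_length_bp
    for chrom in ("chrA", "chrD"):
        rec = records[chrom]
        ev = rec["ev"]
        rows = []
        gm = [rec["G"]]
        n = len(ev)
        sites = ev["site"].to_numpy() if n else np.array([], dtype=int)
        pair_idx = sites // L
        offsets = sites % L
        anc_codes = anc_seq[sites] if n else np.array([], dtype=np.int8)
        der_codes = (anc_codes + ev["base_shift"].to_numpy()) % 4 if n else anc_codes
        ev_edge = ev["edge"].to_numpy()
        ev_cls = ev["cls"].to_numpy()
        ev_del = ev["deleterious"].to_numpy()
        ev_s = ev["s"].to_numpy()
        ev_score = ev["score"].to_numpy()
        ev_fixed = ~ev["seg"].to_numpy()
        for i in range(n):
            rows.append(
                _genomic_row(
                    chrom, pairs[pair_idx[i]], int(offsets[i]), int(anc_codes[i]),
                    int(der_codes[i]), bool(rec["ref_carrier"][i]),
                    int(rec["event_id"][i]), branch_names[ev_edge[i]],
                    ev_cls[i], bool(ev_del[i]),
                    float(ev_s[i]), float(ev_score[i]),
                    bool(ev_fixed[i]), bool(rec["conversion"][i]), False,
                )
            )
            if rec["ref_carrier"][i]:
                gene = pairs[pair_idx[i]].gene_at if chrom == "chrA" else pairs[pair_idx[i]].gene_dt
                seqs[gene][offsets[i]] = der_codes[i]

        cross_flags = [False] * n
        # conversion twins
        for site, shift, score, cls, dele, s_val, target in conv_rows[chrom]:
            g = np.zeros(n_samples, dtype=np.int8)
            other_dip = dip_dt if chrom == "chrA" else dip_at
            if not params.cross_map_diploids:
                g[sp_cols[other_dip]] = -1
            g[sp_cols[target]] = 2
            gm.append(g[None, :])
            anc_c = int(anc_seq[site])
            der_c = (anc_c + shift) % 4
            rows.append(
                _genomic_row(
                    chrom, pairs[site // L], site % L, anc_c, der_c, False,
                    -1, "conversion", cls, dele, s_val, score, True, True, False,
                )
            )
            cross_flags.append(False)
        # collapse artifacts
        for site, grp in collapse_rows[chrom]:
            g = np.zeros(n_samples, dtype=np.int8)
            other_dip = dip_dt if chrom == "chrA" else dip_at
            if not params.cross_map_diploids:
                g[sp_cols[other_dip]] = -1
            cols = np.concatenate([sp_cols[sp] for sp in grp])
            plant_collapsed_region(g[None, :], 0, cols)
            gm.append(g[None, :])
            anc_c = int(anc_seq[site])
            shift = 1 + (site % 3)  # deterministic non-ancestral base
            rows.append(
                _genomic_row(
                    chrom, pairs[site // L], site % L, anc_c, (anc_c + shift) % 4,
                    False, -1, "artifact", "artifact", False, 0.0, float("nan"),
                    False, False, True,
                )
            )
            cross_flags.append(False)
        # diploid cross-mapped records
        for site, shift, score, cls, dele, s_val, branch, fixed_flag, dip, gt in cross_rows[chrom]:
            g = np.zeros(n_samples, dtype=np.int8)
            g[sp_cols[dip]] = gt
            gm.append(g[None, :])
            anc_c = int(anc_seq[site])
            rows.append(
                _genomic_row(
                    chrom, pairs[site // L], site % L, anc_c, (anc_c + shift) % 4,
                    False, -1, branch, cls, dele, s_val, score, fixed_flag, False, False,
                )
            )
            cross_flags.append(True)
        frame = pd.DataFrame(
            rows,
            columns=[
                "chrom", "pos", "id", "ref", "alt", "event", "pair_idx", "cds_offset",
                "true_branch", "cls", "deleterious", "s", "score", "fixed", "conversion",
                "collapse", "ref_is_derived",
            ],
        )
        frame["cross_map"] = cross_flags
        frames.append(frame)
        gmats.append(np.vstack(gm) if gm else np.zeros((0, n_samples), dtype=np.int8))

    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    G = np.vstack(gmats)
    # genotype matrices hold derived-allele counts; flip to ALT counts where
    # the reference haplotype carries the derived base
    flip = df["ref_is_derived"].to_numpy(dtype=bool)
    G[flip] = np.where(G[flip] >= 0, 2 - G[flip], -1).astype(np.int8)

    order = np.lexsort((df["pos"].to_numpy(), df["chrom"].to_numpy()))
    df = df.iloc[order].reset_index(drop=True)
    G = G[order]
    df["id"] = [f"v{i:06d}" for i in range(len(df))]
    df["pos"] = df["pos"].astype(int)
    table = VariantTable(df, G, samples)

    # ---- sequences onto pairs
    for pair in pairs:
        pair.seq_at = "".join(BASES[seqs[pair.gene_at]])
        pair.seq_dt = "".join(BASES[seqs[pair.gene_dt]])

    # ---- depths with planted HE states
    he_truth, depths = _depths(params, model, pairs, samples, species_of, streams)
    return table, he_truth, depths


def _genomic_row(chrom, pair, offset, anc_code, der_code, ref_is_derived, event_id,
                 branch, cls, deleterious, s_val, score, fixed, conversion, collapse):
    if chrom == "chrA":
        intervals, strand = pair.intervals_at, pair.strand_at
    else:
        intervals, strand = pair.intervals_dt, pair.strand_dt
    gpos = cds_to_genomic(offset, intervals, strand) + 1  # 1-based VCF
    anc_b, der_b = BASES[anc_code], BASES[der_code]
    if strand == "-":
        anc_b, der_b = complement(anc_b), complement(der_b)
    ref, alt = (der_b, anc_b) if ref_is_derived else (anc_b, der_b)
    return (
        chrom, gpos, ".", ref, alt, event_id, int(pair.pair_id[1:]), offset, branch,
        cls, deleterious, s_val, score, fixed, conversion, collapse, ref_is_derived,
    )


def _collapse_groups(model: SpeciesTreeModel) -> list[tuple[str, ...]]:
    """Species groups eligible for planted collapse artifacts.

    AD6 and AD7 are pooled, mirroring the analysis-side merge of species
    with too few sampled individuals.
    """
    groups: list[tuple[str, ...]] = [
        (model.progenitors["At"],),
        (model.progenitors["Dt"],),
    ]
    merged = {"AD6", "AD7"} & set(model.polyploid_species)
    for sp in model.polyploid_species:
        if sp in merged:
            continue
        groups.append((sp,))
    if merged:
        groups.append(tuple(sorted(merged)))
    return groups


def _depths(params, model, pairs, samples, species_of, streams):
    rng_art = streams["artifacts"]
    rng_dep = streams["depths"]
    he = rng_art.random(len(pairs)) < params.he_rate
    states = [CopyState(0, 4), CopyState(1, 3), CopyState(3, 1), CopyState(4, 0)]
    he_states = {}
    for i in np.nonzero(he)[0]:
        he_states[i] = states[rng_art.integers(len(states))]

    poly_inds = [s for s in samples if species_of[s] in model.polyploid_species]
    dip_at, dip_dt = params.progenitors["At"], params.progenitors["Dt"]
    rows = []
    for i, pair in enumerate(pairs):
        for ind in poly_inds:
            rows.append((pair.gene_at, ind, params.depth_mean))
            rows.append((pair.gene_dt, ind, params.depth_mean))
        for ind in (s for s in samples if species_of[s] == dip_at):
            rows.append((pair.gene_at, ind, params.depth_mean))
        for ind in (s for s in samples if species_of[s] == dip_dt):
            rows.append((pair.gene_dt, ind, params.depth_mean))
    depths = pd.DataFrame(rows, columns=["gene_id", "individual", "expected_depth"])
    for i, state in he_states.items():
        plant_homoeologous_exchange(depths, pairs[i], poly_inds, state, params.depth_mean)

    if params.depth_dispersion == 0:
        depths["mean_depth"] = depths["expected_depth"]
    else:
        # gene-mean depth = NB-distributed read total over the CDS / length
        m = depths["expected_depth"].to_numpy() * params.cds_length_bp
        r = 1.0 / params.depth_dispersion
        vals = np.where(
            m > 0, rng_dep.negative_binomial(r, r / (r + np.maximum(m, 1e-9))), 0
        )
        depths["mean_depth"] = vals / params.cds_length_bp
    depths = depths.drop(columns=["expected_depth"])

    he_truth = pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "he_planted": he,
            "at_copies": [he_states[i].at_copies if i in he_states else 2 for i in range(len(pairs))],
            "dt_copies": [he_states[i].dt_copies if i in he_states else 2 for i in range(len(pairs))],
        }
    )
    return he_truth, depths


# --------------------------------------------------------------------------
# neutral sequence evolution (for conservation-module calibration tests)


def evolve_jc_alignment(tree: trees.Node, n_sites: int, rng: np.random.Generator) -> dict[str, str]:
    """Evolve a random root sequence down a tree under Jukes-Cantor.

    Returns tip name -> sequence.  Substitution probability along a branch
    of length t is the JC69 transition probability 3/4 (1 - e^{-4t/3}).
    """
    root_seq = rng.integers(0, 4, size=n_sites).astype(np.int8)
    out: dict[str, str] = {}

    def walk(node: trees.Node, seq: np.ndarray) -> None:
        if node.length > 0:
            p_change = 0.75 * (1.0 - np.exp(-4.0 * node.length / 3.0))
            hits = rng.random(n_sites) < p_change
            if hits.any():
                seq = seq.copy()
                seq[hits] = (seq[hits] + rng.integers(1, 4, size=int(hits.sum()))) % 4
        if node.is_tip:
            out[node.name] = "".join(BASES[seq])
        for child in node.children:
            walk(child, seq)

    walk(tree, root_seq)
    return out


# --------------------------------------------------------------------------
# on-disk form


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the dataset as VCF/BED/FASTA/TSV/newick plus truth tables.

    Returns a name -> path map of everything written.  All files are plain
    text and re-readable by the pipeline's own readers.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["vcf"] = str(out / "variants.vcf")
    dataset.variants.write_vcf(paths["vcf"], contigs=dataset.contigs)

    paths["bed"] = str(out / "genes.bed")
    with open(paths["bed"], "w") as fh:
        for pair in dataset.pairs:
            for gene, chrom, ivs, strand, sub in (
                (pair.gene_at, pair.chrom_at, pair.intervals_at, pair.strand_at, "At"),
                (pair.gene_dt, pair.chrom_dt, pair.intervals_dt, pair.strand_dt, "Dt"),
            ):
                for s, e in ivs:
                    fh.write(f"{chrom}\t{s}\t{e}\t{gene}|{sub}|{pair.pair_id}\t0\t{strand}\n")

    paths["fasta"] = str(out / "cds.fasta")
    with open(paths["fasta"], "w") as fh:
        for pair in dataset.pairs:
            fh.write(f">{pair.gene_at}\n{pair.seq_at}\n>{pair.gene_dt}\n{pair.seq_dt}\n")

    paths["depths"] = str(out / "depths.tsv")
    dataset.depths.to_csv(paths["depths"], sep="\t", index=False)

    paths["species_tree"] = str(out / "species_tree.nwk")
    with open(paths["species_tree"], "w") as fh:
        fh.write(trees.to_newick(dataset.model.tree) + "\n")
    paths["neutral_tree"] = str(out / "neutral_tree.nwk")
    with open(paths["neutral_tree"], "w") as fh:
        fh.write(trees.to_newick(dataset.model.tree) + "\n")

    paths["samples"] = str(out / "samples.tsv")
    pd.DataFrame(
        {"individual": dataset.samples,
         "species": [dataset.species_of[s] for s in dataset.samples]}
    ).to_csv(paths["samples"], sep="\t", index=False)

    paths["truth_variants"] = str(out / "truth_variants.tsv")
    dataset.truth.to_csv(paths["truth_variants"], sep="\t", index=False)
    paths["truth_pairs"] = str(out / "truth_pairs.tsv")
    dataset.he_truth.to_csv(paths["truth_pairs"], sep="\t", index=False)

    paths["scores"] = str(out / "scores.tsv")
    dataset.variants.df[["chrom", "pos", "score"]].to_csv(paths["scores"], sep="\t", index=False)
    paths["deleterious_flags"] = str(out / "deleterious_flags.tsv")
    flags = dataset.variants.df[["chrom", "pos", "deleterious"]].copy()
    flags["deleterious"] = flags["deleterious"].astype(int)
    flags.to_csv(paths["deleterious_flags"], sep="\t", index=False)
    return paths
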