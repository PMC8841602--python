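"""Ancestral-allele polarization, derived frequencies, and branch mapping.

Mutations are polarized against a set of outgroup species: the ancestral
allele is the one carried homozygously and concordantly by at least
``min_outgroup_species`` outgroup species (heterozygous outgroup calls count
as missing — they are not "confidently called").  Each variant then gets a
per-lineage derived allele frequency (lineage = species x subgenome), a
branch assignment by parsimony (the stem branch of the clade of carriers,
or AMBIGUOUS when the carrier pattern is not a clade and would require more
than one gain), and membership in three nested phylogenetic depth classes:

* ``clade_wide``      — arose since the divergence of the two diploid
                        progenitors (anywhere on the ingroup side);
* ``since_prog``      — arose after the split of a subgenome lineage from
                        its sampled diploid progenitor (or on the diploid's
                        own terminal branch);
* ``within_poly``     — arose within the polyploid crown, i.e. after the
                        earliest divergence among the sampled polyploids.

The depth classes obey within_poly <= since_prog <= clade_wide by
construction of the branch flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import trees
from .trees import Node

__all__ = [
    "SpeciesTreeModel",
    "infer_ancestral",
    "derived_allele_frequency",
    "assign_branch_parsimony",
    "classify_depth",
    "polarize_table",
    "UNRESOLVED",
    "AMBIGUOUS",
]

UNRESOLVED = "UNRESOLVED"
AMBIGUOUS = "AMBIGUOUS"


@dataclass
class LineageView:
    """Per-subgenome view of the species tree: the outgroups, one diploid
    progenitor, and the polyploid tips of that subgenome, with unary paths
    merged."""

    subgenome: str
    tree: Node
    branch_map: dict[str, str]  # full-tree edge -> restricted edge
    ingroup_tips: list[str]
    clade_to_branch: dict[frozenset, str]
    flags: dict[str, dict[str, bool]]  # branch -> depth-class flags


@dataclass
class SpeciesTreeModel:
    """Rooted species tree plus the maps the pipeline needs.

    ``progenitors`` maps subgenome label -> diploid tip (e.g. ``{"At": "A1",
    "Dt": "D5"}``); polyploid subgenome tips are named ``<species>_<sub>``.
    """

    tree: Node
    outgroups: list[str]
    progenitors: dict[str, str]
    views: dict[str, LineageView] = field(init=False)
    polyploid_species: list[str] = field(init=False)

    def __post_init__(self) -> None:
        tip_names = set(self.tree.tip_names())
        for og in self.outgroups:
            if og not in tip_names:
                raise ValueError(f"outgroup tip {og!r} not in tree")
        poly: set[str] = set()
        for sub in self.progenitors:
            if self.progenitors[sub] not in tip_names:
                raise ValueError(f"progenitor tip {self.progenitors[sub]!r} not in tree")
            for t in tip_names:
                if t.endswith(f"_{sub}"):
                    poly.add(t[: -len(sub) - 1])
        self.polyploid_species = sorted(poly)
        self.views = {}
        for sub, diploid in self.progenitors.items():
            sub_tips = [f"{sp}_{sub}" for sp in self.polyploid_species]
            missing = [t for t in sub_tips if t not in tip_names]
            if missing:
                raise ValueError(f"tree lacks subgenome tips: {missing}")
            keep = set(self.outgroups) | {diploid} | set(sub_tips)
            rtree, mapping = trees.restrict(self.tree, keep)
            below = trees.clade_tipsets(rtree)
            side_tips = frozenset({diploid} | set(sub_tips))
            crown_tips = frozenset(sub_tips)
            clade_to_branch: dict[frozenset, str] = {}
            flags: dict[str, dict[str, bool]] = {}
            for node in rtree.postorder():
                if node is rtree:
                    continue
                tipset = below[node.name]
                if tipset & frozenset(self.outgroups):
                    continue  # outgroup-side branch
                clade_to_branch[tipset] = node.name
                flags[node.name] = {
                    "clade_wide": tipset <= side_tips,
                    "since_prog": tipset < side_tips,
                    "within_poly": tipset < crown_tips,
                }
            self.views[sub] = LineageView(
                subgenome=sub,
                tree=rtree,
                branch_map=mapping,
                ingroup_tips=sorted(side_tips),
                clade_to_branch=clade_to_branch,
                flags=flags,
            )

    def lineages(self, subgenome: str) -> list[str]:
        return list(self.views[subgenome].ingroup_tips)

    def tip_samples(
        self, subgenome: str, species_of: dict[str, str]
    ) -> dict[str, list[str]]:
        """Map each ingroup tip of a subgenome view to its sample names."""
        view = self.views[subgenome]
        diploid = self.progenitors[subgenome]
        out: dict[str, list[str]] = {}
        for tip in view.ingroup_tips:
            species = tip if tip == diploid else tip[: -len(subgenome) - 1]
            out[tip] = [s for s, sp in species_of.items() if sp == species]
        return out


def infer_ancestral(
    ref: str,
    alt: str,
    outgroup_genotypes: dict[str, list[int]],
    min_outgroup_species: int = 2,
) -> str:
    """Outgroup-consensus ancestral allele, or UNRESOLVED.

    ``outgroup_genotypes`` maps outgroup species -> list of ALT-allele counts
    (0/1/2, -1 missing) for its individuals.  A species votes only if every
    nonmissing individual is homozygous for the same allele; heterozygous
    calls are treated as missing.  The ancestral allele is returned when at
    least ``min_outgroup_species`` species vote and all votes agree.
    """
    votes = []
    for _species, gts in outgroup_genotypes.items():
        nonmissing = [g for g in gts if g >= 0]
        if not nonmissing:
            continue
        if all(g == 0 for g in nonmissing):
            votes.append(ref)
        elif all(g == 2 for g in nonmissing):
            votes.append(alt)
        # het or internally discordant species: no vote
    if len(votes) >= min_outgroup_species and len(set(votes)) == 1:
        return votes[0]
    return UNRESOLVED


def derived_allele_frequency(genotypes: list[int] | np.ndarray) -> float:
    """p = derived count / (2 x nonmissing samples); genotypes are derived counts."""
    g = np.asarray(genotypes)
    nonmissing = g >= 0
    n = int(nonmissing.sum())
    if n == 0:
        raise ValueError("all genotypes missing")
    return float(g[nonmissing].sum()) / (2.0 * n)


def assign_branch_parsimony(
    presence: dict[str, bool], view: LineageView
) -> str:
    """Stem branch of the carrier clade, or AMBIGUOUS.

    ``presence`` maps every non-outgroup tip of the view to whether the
    derived allele is present (frequency > 0).  A pattern that is exactly
    one clade needs a single gain and maps to that clade's stem branch; any
    other pattern needs more than one change under Fitch parsimony and is
    AMBIGUOUS.
    """
    carriers = frozenset(t for t, present in presence.items() if present)
    if not carriers:
        raise ValueError("derived allele absent from every ingroup tip")
    return view.clade_to_branch.get(carriers, AMBIGUOUS)


def classify_depth(branch: str, view: LineageView) -> set[str]:
    """Depth-class memberships for a branch assignment (nested sets)."""
    if branch == AMBIGUOUS:
        return {"clade_wide"}
    flags = view.flags[branch]
    out = {name for name, on in flags.items() if on}
    assert not ({"within_poly"} <= out and "since_prog" not in out)
    assert not ({"since_prog"} <= out and "clade_wide" not in out)
    return out


# --------------------------------------------------------------------------
# vectorized table driver


def polarize_table(
    table,
    species_of: dict[str, str],
    model: SpeciesTreeModel,
    chrom_subgenome: dict[str, str],
    min_outgroup_species: int = 2,
):
    """Polarize every variant of a :class:`~polyload.variants.VariantTable`.

    Returns ``(df, p, lineage_names, report)`` where ``df`` carries the
    site fields plus ``anc``, ``der``, ``subgenome``, ``branch`` and the
    three depth-class flags, and ``p`` is the (variants x lineages) derived
    allele frequency matrix (NaN where a lineage has no data or belongs to
    the other subgenome).  Sites with an unresolved ancestral allele, or
    where the derived allele is absent from every ingroup lineage, are
    dropped and counted in ``report``.
    """
    G = table.G
    n = table.n_variants
    # --- outgroup species votes, vectorized
    votes = []
    for og in model.outgroups:
        cols = table.sample_index([s for s, sp in species_of.items() if sp == og])
        if cols.size == 0:
            continue
        block = G[:, cols]
        nm = block >= 0
        any_nm = nm.any(axis=1)
        hom_ref = (((block == 0) | ~nm).all(axis=1)) & any_nm
        hom_alt = (((block == 2) | ~nm).all(axis=1)) & any_nm
        votes.append(np.select([hom_ref, hom_alt], [0, 1], default=-9))
    V = np.vstack(votes) if votes else np.full((0, n), -9)
    called = V >= 0
    n_called = called.sum(axis=0)
    first = np.where(called.any(axis=0), V.max(axis=0), -9)
    concordant = np.ones(n, dtype=bool)
    for row in V:
        concordant &= (row == -9) | (row == first)
    resolved = (n_called >= min_outgroup_species) & concordant
    anc_is_alt = resolved & (first == 1)

    # derived-allele counts: flip where ancestral == ALT
    D = np.where(G >= 0, np.where(anc_is_alt[:, None], 2 - G, G), -1)

    # --- per-lineage frequencies
    lineage_names: list[str] = []
    for sub in model.progenitors:
        lineage_names.extend(model.lineages(sub))
    p = np.full((n, len(lineage_names)), np.nan)
    chroms = table.df["chrom"].to_numpy()
    sub_of_row = np.array([chrom_subgenome[c] for c in chroms]) if n else np.array([])
    presence_mask = np.zeros((n, len(lineage_names)), dtype=bool)
    for sub in model.progenitors:
        rows = np.nonzero(sub_of_row == sub)[0] if n else np.array([], dtype=int)
        if rows.size == 0:
            continue
        tip_samples = model.tip_samples(sub, species_of)
        for tip, samples in tip_samples.items():
            j = lineage_names.index(tip)
            cols = table.sample_index(samples)
            block = D[np.ix_(rows, cols)]
            nm = block >= 0
            counts = np.where(nm, block, 0).sum(axis=1)
            denom = 2.0 * nm.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                freq = np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)
            p[rows, j] = freq
            presence_mask[rows, j] = freq > 0

    derived_somewhere = presence_mask.any(axis=1)
    keep = resolved & derived_somewhere
    ref_arr = table.df["ref"].to_numpy()
    alt_arr = table.df["alt"].to_numpy()
    anc_all = np.where(
        resolved, np.where(anc_is_alt, alt_arr, ref_arr), UNRESOLVED
    )
    report = {
        "n_input": int(n),
        "n_unresolved_ancestral": int((~resolved).sum()),
        "n_no_ingroup_derived": int((resolved & ~derived_somewhere).sum()),
        "n_polarized": int(keep.sum()),
        "site_ancestral": pd.DataFrame(
            {"chrom": table.df["chrom"], "pos": table.df["pos"], "anc": anc_all}
        ),
    }

    # --- branch assignment + depth flags
    branches = np.empty(n, dtype=object)
    flags = {k: np.zeros(n, dtype=bool) for k in ("clade_wide", "since_prog", "within_poly")}
    for sub in model.progenitors:
        view = model.views[sub]
        tips = view.ingroup_tips
        tip_cols = np.array([lineage_names.index(t) for t in tips])
        rows = np.nonzero((sub_of_row == sub) & keep)[0]
        weights = 1 << np.arange(len(tips))
        masks = presence_mask[np.ix_(rows, tip_cols)] @ weights
        clade_lookup = {}
        for tipset, branch in view.clade_to_branch.items():
            key = sum(1 << tips.index(t) for t in tipset)
            clade_lookup[key] = branch
        for r, m in zip(rows, masks):
            br = clade_lookup.get(int(m), AMBIGUOUS)
            branches[r] = br
            for name in flags:
                if br == AMBIGUOUS:
                    flags[name][r] = name == "clade_wide"
                else:
                    flags[name][r] = view.flags[br][name]

    df = table.df.copy()
    ref = df["ref"].to_numpy()
    alt = df["alt"].to_numpy()
    df["anc"] = np.where(anc_is_alt, alt, ref)
    df["der"] = np.where(anc_is_alt, ref, alt)
    df["subgenome"] = sub_of_row if n else []
    df["branch"] = branches
    for name, col in flags.items():
        df[name] = col
    df = df.loc[keep].reset_index(drop=True)
    p = p[keep]
    return df, p, lineage_names, report
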