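"""In-memory simulate -> polarize -> load drivers for replicate experiments.

These functions run the analytical core of the pipeline (polarization,
cross-subgenome SNP filtering, load statistics) directly on a simulated
dataset without touching disk, which makes replicate grids over the masking
coefficient or demography cheap.  The genotype-level machinery is exactly
the machinery the file-based pipeline uses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .load import (
    bin_loads_table,
    load_summary,
    proportion_deleterious,
    relative_increase_by_bin,
)
from .polarize import polarize_table
from .simulate import SimulationParams, SyntheticDataset, simulate_clade

__all__ = [
    "analyze_dataset",
    "scenario_statistics",
    "proportion_deleterious_gap",
    "bin_ratio_means",
    "masking_scenario",
    "bottleneck_scenario",
]


def drop_cross_subgenome(
    df: pd.DataFrame, p: np.ndarray, lineages: list[str], model
) -> tuple[pd.DataFrame, np.ndarray]:
    """Remove variants whose derived allele surfaces in both subgenome groups.

    This is retention criterion 3 evaluated through the homoeologous
    coordinate link (here the pair/offset key): a derived allele present in
    the A group (diploid A + At lineages) at one position *and* in the D
    group at the linked position marks gene conversion or a shared
    pre-divergence mutation, and the whole linked site is removed.
    """
    a_cols = [i for i, l in enumerate(lineages) if not l.endswith("_Dt") and l != model.progenitors["Dt"]]
    d_cols = [i for i, l in enumerate(lineages) if l.endswith("_Dt") or l == model.progenitors["Dt"]]
    with np.errstate(invalid="ignore"):
        in_a = np.nansum(np.nan_to_num(p[:, a_cols]), axis=1) > 0
        in_d = np.nansum(np.nan_to_num(p[:, d_cols]), axis=1) > 0
    key = df["pair_idx"].to_numpy() * 10_000_000 + df["cds_offset"].to_numpy()
    side_a = df["chrom"].to_numpy() == "chrA"
    hit_a = set(key[side_a & in_a])
    hit_d = set(key[~side_a & in_d])
    shared = hit_a & hit_d
    keep = ~np.isin(key, list(shared))
    return df.loc[keep].reset_index(drop=True), p[keep]


def analyze_dataset(
    ds: SyntheticDataset, min_outgroup_species: int = 2
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Polarize a simulated dataset and apply the cross-subgenome filter.

    Returns the polarized variant frame (with ``class``, ``deleterious`` and
    ``score`` columns), the per-lineage derived-frequency matrix, and the
    lineage names.
    """
    df, p, lineages, _report = polarize_table(
        ds.variants,
        ds.species_of,
        ds.model,
        ds.chrom_subgenome,
        min_outgroup_species=min_outgroup_species,
    )
    real = df["cls"].isin(["synonymous", "nonsynonymous"]).to_numpy()
    df, p = df.loc[real].reset_index(drop=True), p[real]
    df, p = drop_cross_subgenome(df, p, lineages, ds.model)
    df = df.rename(columns={"cls": "class"})
    return df, p, lineages


def _pairs_with_progenitor(model) -> list[tuple[str, str]]:
    out = []
    for sub, diploid in model.progenitors.items():
        for sp in model.polyploid_species:
            out.append((f"{sp}_{sub}", diploid))
    return out


def scenario_statistics(
    params: SimulationParams, depth_class: str = "since_prog"
) -> dict:
    """One simulation, both headline statistics.

    Returns ``{"gap": ..., "bins": {...}}`` where ``gap`` is the mean
    (polyploid - diploid) difference in proportion deleterious (deleterious
    count load over nonsynonymous count load) and ``bins`` is the mean
    relative GERP-load increase per deleteriousness bin, both at the
    requested phylogenetic depth and averaged over the twelve subgenome
    lineages against their respective progenitors.
    """
    ds = simulate_clade(params)
    df, p, lineages = analyze_dataset(ds)
    summary = load_summary(df, p, lineages)
    at_depth = summary.loc[summary["depth_class"] == depth_class].set_index("lineage")
    gaps = []
    for lineage, diploid in _pairs_with_progenitor(ds.model):
        gaps.append(
            at_depth.at[lineage, "proportion_deleterious"]
            - at_depth.at[diploid, "proportion_deleterious"]
        )
    loads = bin_loads_table(df, p, lineages, depth_class)
    sums: dict[str, list[float]] = {"mild": [], "moderate": [], "strong": []}
    for sub, diploid in ds.model.progenitors.items():
        ratios = relative_increase_by_bin(loads, diploid)
        for sp in ds.model.polyploid_species:
            for b in sums:
                sums[b].append(ratios[f"{sp}_{sub}"][b])
    return {
        "gap": float(np.nanmean(gaps)),
        "bins": {b: float(np.nanmean(v)) for b, v in sums.items()},
    }


def proportion_deleterious_gap(
    params: SimulationParams, depth_class: str = "since_prog"
) -> float:
    """Mean (polyploid - diploid) difference in proportion deleterious."""
    return scenario_statistics(params, depth_class)["gap"]


def bin_ratio_means(
    params: SimulationParams, depth_class: str = "since_prog"
) -> dict[str, float]:
    """Mean relative GERP-load increase per deleteriousness bin."""
    return scenario_statistics(params, depth_class)["bins"]


# --------------------------------------------------------------------------
# named scenarios (the study conditions for replicate experiments)


def masking_scenario(
    masking_m: float, seed: int, n_gene_pairs: int = 2000, **overrides
) -> SimulationParams:
    """Masking-only scenario: equal Ne everywhere, tunable masking."""
    kw = dict(
        n_gene_pairs=n_gene_pairs,
        masking_m=masking_m,
        he_rate=0.0,
        collapse_rate=0.0,
        conversion_rate=0.0,
        seed=seed,
    )
    kw.update(overrides)
    return SimulationParams(**kw)


def bottleneck_scenario(
    seed: int, ne_factor: float = 0.5, n_gene_pairs: int = 2000, **overrides
) -> SimulationParams:
    """Bottleneck-only scenario: reduced polyploid Ne, no masking."""
    base = SimulationParams()
    ne_dip = int(base.ne_reference)
    ne_map = {sp: ne_dip for sp in ("A1", "D5", "K1", "K2", "K3")}
    for sp in ("AD1", "AD3", "AD4", "AD5", "AD6", "AD7"):
        ne_map[sp] = int(ne_dip * ne_factor)
    kw = dict(
        n_gene_pairs=n_gene_pairs,
        masking_m=0.0,
        Ne=ne_map,
        he_rate=0.0,
        collapse_rate=0.0,
        conversion_rate=0.0,
        seed=seed,
    )
    kw.update(overrides)
    return SimulationParams(**kw)
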