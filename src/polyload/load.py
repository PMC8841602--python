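"""Load statistics: count loads, GERP load, proportions, and diversity.

All statistics operate on a "polarized table": a DataFrame with one row per
variant carrying ``class`` (synonymous|nonsynonymous), ``deleterious``
(boolean flag, externally supplied), ``score`` (rejected-substitutions
conservation score), the depth-class flags, and a per-lineage derived
allele frequency matrix ``p`` aligned row-wise.

Definitions:

* count load of a class     = sum of derived allele frequencies p over the
                              class's variants (the expected number of
                              derived mutations per individual);
* GERP load                 = sum of p x score over variants with score > 0;
* proportion deleterious    = deleterious count load / nonsynonymous count
                              load;
* relative increase per bin = lineage GERP-load in a deleteriousness bin
                              divided by the diploid reference's bin load
                              (the reference is 1 in every bin by
                              definition);
* nucleotide diversity pi   = sum of sitewise unbiased pairwise diversity
                              over the concatenated CDS length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conservation import gerp_bin

__all__ = [
    "category_load",
    "gerp_load",
    "proportion_deleterious",
    "relative_increase_by_bin",
    "nucleotide_diversity",
    "load_summary",
    "DiversityResult",
]

CLASSES = ("synonymous", "nonsynonymous")
DEPTHS = ("clade_wide", "since_prog", "within_poly")
BINS = ("mild", "moderate", "strong")


def _lineage_col(p: np.ndarray, lineages: list[str], lineage: str) -> np.ndarray:
    try:
        j = lineages.index(lineage)
    except ValueError:
        raise KeyError(f"unknown lineage {lineage!r}") from None
    return p[:, j]


def _depth_mask(df: pd.DataFrame, depth_class: str) -> np.ndarray:
    if depth_class not in DEPTHS:
        raise ValueError(f"unknown depth class {depth_class!r}")
    return df[depth_class].to_numpy(dtype=bool)


def category_load(
    df: pd.DataFrame,
    p: np.ndarray,
    lineages: list[str],
    lineage: str,
    mclass: str,
    depth_class: str,
) -> float:
    """Sum of derived allele frequencies for one class x depth x lineage."""
    if mclass not in CLASSES:
        raise ValueError(f"unknown mutation class {mclass!r}")
    col = _lineage_col(p, lineages, lineage)
    mask = (df["class"].to_numpy() == mclass) & _depth_mask(df, depth_class)
    vals = col[mask]
    return float(np.nansum(vals)) if vals.size else 0.0


def deleterious_load(
    df: pd.DataFrame,
    p: np.ndarray,
    lineages: list[str],
    lineage: str,
    depth_class: str,
) -> float:
    """Sum of p over externally flagged deleterious variants."""
    col = _lineage_col(p, lineages, lineage)
    mask = df["deleterious"].to_numpy(dtype=bool) & _depth_mask(df, depth_class)
    vals = col[mask]
    return float(np.nansum(vals)) if vals.size else 0.0


def gerp_load(
    df: pd.DataFrame,
    p: np.ndarray,
    lineages: list[str],
    lineage: str,
    depth_class: str,
    score_bin: str | None = None,
) -> float:
    """Sum of p x score over variants with score > 0 (optionally one bin)."""
    col = _lineage_col(p, lineages, lineage)
    score = df["score"].to_numpy(dtype=float)
    mask = _depth_mask(df, depth_class) & (score > 0) & ~np.isnan(score)
    if score_bin is not None:
        if score_bin not in BINS:
            raise ValueError(f"unknown bin {score_bin!r}")
        with np.errstate(invalid="ignore"):
            bins = np.select(
                [score <= 0, score <= 2, score <= 4], ["none", "mild", "moderate"],
                default="strong",
            )
        mask &= bins == score_bin
    vals = col[mask] * score[mask]
    return float(np.nansum(vals)) if vals.size else 0.0


def proportion_deleterious(deleterious: float, nonsynonymous: float) -> float:
    """Deleterious load over nonsynonymous load; NaN when undefined."""
    if deleterious < 0 or nonsynonymous < 0:
        raise ValueError("loads must be nonnegative")
    if deleterious > nonsynonymous:
        raise ValueError(
            "deleterious load exceeds nonsynonymous load; flags must be a "
            "subset of nonsynonymous variants"
        )
    if nonsynonymous == 0:
        return float("nan")
    return deleterious / nonsynonymous


def relative_increase_by_bin(
    bin_loads: dict[str, dict[str, float]], reference_lineage: str
) -> dict[str, dict[str, float]]:
    """Per-bin GERP-load ratios against a diploid reference lineage.

    ``bin_loads`` maps lineage -> {bin -> load}.  The reference lineage's
    ratio is exactly 1 in every bin; bins with a zero reference load give
    NaN for every lineage.
    """
    if reference_lineage not in bin_loads:
        raise KeyError(f"reference lineage {reference_lineage!r} missing")
    ref = bin_loads[reference_lineage]
    out: dict[str, dict[str, float]] = {}
    for lineage, loads in bin_loads.items():
        out[lineage] = {}
        for b in BINS:
            denom = ref.get(b, 0.0)
            if lineage == reference_lineage:
                out[lineage][b] = 1.0 if denom > 0 else float("nan")
            elif denom > 0:
                out[lineage][b] = loads.get(b, 0.0) / denom
            else:
                out[lineage][b] = float("nan")
    return out


@dataclass
class DiversityResult:
    lineage: str
    pi: float
    total_sites: int
    n_variant_sites: int


def nucleotide_diversity(
    genotypes: np.ndarray,
    total_cds_length: int,
    n_excluded_positions: int = 0,
    lineage: str = "",
) -> DiversityResult:
    """Concatenated-CDS nucleotide diversity for one lineage.

    ``genotypes`` is the (variants x individuals) matrix of allele counts
    (0/1/2, -1 missing) for the lineage's samples at its variant sites.
    Sitewise pi uses the unbiased pairwise estimator
    2 j (n - j) / (n (n - 1)) over the n = 2 x nonmissing haplotypes; sites
    with fewer than 2 haplotypes are skipped, and the summed sitewise values
    are divided by the usable concatenated CDS length.
    """
    if total_cds_length <= 0:
        raise ValueError("total_cds_length must be positive")
    denom_sites = total_cds_length - n_excluded_positions
    if denom_sites <= 0:
        raise ValueError("no sites left after exclusions")
    g = np.asarray(genotypes)
    if g.size == 0:
        return DiversityResult(lineage, 0.0, denom_sites, 0)
    nm = g >= 0
    n_hap = 2.0 * nm.sum(axis=1)
    j = np.where(nm, g, 0).sum(axis=1)
    ok = n_hap >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        site_pi = np.where(ok, 2.0 * j * (n_hap - j) / (n_hap * (n_hap - 1.0)), 0.0)
    pi = float(site_pi.sum()) / denom_sites
    return DiversityResult(lineage, pi, denom_sites, int((site_pi > 0).sum()))


def load_summary(
    df: pd.DataFrame, p: np.ndarray, lineages: list[str]
) -> pd.DataFrame:
    """Tidy per-lineage x depth summary of all load statistics."""
    rows = []
    for lineage in lineages:
        for depth in DEPTHS:
            syn = category_load(df, p, lineages, lineage, "synonymous", depth)
            nonsyn = category_load(df, p, lineages, lineage, "nonsynonymous", depth)
            dele = deleterious_load(df, p, lineages, lineage, depth)
            gl = gerp_load(df, p, lineages, lineage, depth)
            rows.append(
                {
                    "lineage": lineage,
                    "depth_class": depth,
                    "synonymous_load": syn,
                    "nonsynonymous_load": nonsyn,
                    "deleterious_load": dele,
                    "gerp_load": gl,
                    "proportion_deleterious": proportion_deleterious(dele, nonsyn),
                }
            )
    return pd.DataFrame(rows)


def bin_loads_table(
    df: pd.DataFrame,
    p: np.ndarray,
    lineages: list[str],
    depth_class: str = "since_prog",
) -> dict[str, dict[str, float]]:
    """GERP load per deleteriousness bin for every lineage at one depth."""
    return {
        lineage: {
            b: gerp_load(df, p, lineages, lineage, depth_class, score_bin=b)
            for b in BINS
        }
        for lineage in lineages
    }
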