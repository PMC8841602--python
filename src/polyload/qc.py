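"""Gene- and site-level quality filters for homoeologous pairs.

Three filters guard the load estimates against artifacts of mapping short
reads to an allopolyploid reference:

* a CDS-length parity filter on homoeologous pairs (gene models that differ
  substantially in annotated CDS length are likely mis-paired or partially
  lost);
* a homoeologous-exchange (HE) filter based on the per-individual fraction
  of reads hitting the At copy: a pair in the expected 2:2 copy state yields
  ~50% At reads, whereas HE copy states 0:4 / 1:3 / 3:1 / 4:0 yield
  0 / 25 / 75 / 100%.  Midpoints between the 2:2 expectation and the
  nearest HE states give the removal cutoffs (37.5 and 62.5); a pair is
  removed when *any* polyploid individual falls strictly outside them;
* nullification of variant calls at which every individual of a species
  group is heterozygous, the signature of a collapsed repeat in the
  reference or an unassembled paralog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import VariantTable

__all__ = [
    "HomoeologPair",
    "HEFilterConfig",
    "CopyState",
    "cds_length_filter",
    "at_read_fraction",
    "expected_fraction",
    "he_filter",
    "nullify_all_het",
]


@dataclass
class HomoeologPair:
    """A syntenic At/Dt gene pair with CDS models and (optionally) sequences."""

    pair_id: str
    gene_at: str
    gene_dt: str
    chrom_at: str
    chrom_dt: str
    intervals_at: list[tuple[int, int]]  # 0-based half-open, sorted
    intervals_dt: list[tuple[int, int]]
    strand_at: str = "+"
    strand_dt: str = "+"
    seq_at: str | None = None  # gene-oriented CDS sequence
    seq_dt: str | None = None

    def __post_init__(self) -> None:
        for name, ivs in (("At", self.intervals_at), ("Dt", self.intervals_dt)):
            last = None
            for s, e in ivs:
                if e <= s:
                    raise ValueError(f"{self.pair_id}/{name}: empty interval {s}-{e}")
                if last is not None and s < last:
                    raise ValueError(f"{self.pair_id}/{name}: intervals unsorted/overlapping")
                last = e

    @property
    def cds_length_at(self) -> int:
        return sum(e - s for s, e in self.intervals_at)

    @property
    def cds_length_dt(self) -> int:
        return sum(e - s for s, e in self.intervals_dt)


@dataclass
class HEFilterConfig:
    lower_pct: float = 37.5
    upper_pct: float = 62.5
    max_cds_rel_diff: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.lower_pct < self.upper_pct <= 100):
            raise ValueError("require 0 <= lower_pct < upper_pct <= 100")


@dataclass(frozen=True)
class CopyState:
    at_copies: int
    dt_copies: int

    def __post_init__(self) -> None:
        if self.at_copies not in range(5) or self.at_copies + self.dt_copies != 4:
            raise ValueError(f"invalid copy state {self.at_copies}:{self.dt_copies}")


def expected_fraction(state: CopyState) -> float:
    """Expected % At reads / total reads for a copy state (e.g. 2:2 -> 50)."""
    return 100.0 * state.at_copies / 4.0


def he_cutoffs(no_he: CopyState = CopyState(2, 2),
               low: CopyState = CopyState(1, 3),
               high: CopyState = CopyState(3, 1)) -> tuple[float, float]:
    """Removal cutoffs as midpoints between the no-HE and flanking HE states."""
    f = expected_fraction
    return ((f(no_he) + f(low)) / 2.0, (f(no_he) + f(high)) / 2.0)


def cds_length_filter(
    pairs: list[HomoeologPair], max_cds_rel_diff: float = 0.05
) -> list[HomoeologPair]:
    """Keep pairs whose CDS lengths differ by less than ``max_cds_rel_diff``.

    The relative difference is |lenAt - lenDt| / max(lenAt, lenDt); the
    comparison is strict, so a pair exactly at the threshold is removed.
    """
    kept = []
    for pair in pairs:
        la, ld = pair.cds_length_at, pair.cds_length_dt
        if la <= 0 or ld <= 0:
            raise ValueError(f"{pair.pair_id}: zero-length CDS")
        if abs(la - ld) / max(la, ld) < max_cds_rel_diff:
            kept.append(pair)
    return kept


def at_read_fraction(depth_at: float, depth_dt: float) -> float:
    """100 * depth_at / (depth_at + depth_dt); both-zero is undefined."""
    total = depth_at + depth_dt
    if total <= 0:
        raise ValueError("total depth is zero; no evidence for this pair")
    return 100.0 * depth_at / total


def he_filter(
    pairs: list[HomoeologPair],
    depth_table: pd.DataFrame,
    config: HEFilterConfig,
    polyploid_individuals: list[str],
) -> tuple[list[HomoeologPair], pd.DataFrame]:
    """Remove pairs with a homoeologous-exchange read-depth signature.

    ``depth_table`` has columns (gene_id, individual, mean_depth).  For every
    polyploid individual the At-read fraction is computed from the pair's two
    gene-level mean depths; the pair is removed iff the fraction falls
    strictly below ``config.lower_pct`` or strictly above ``config.upper_pct``
    in any individual (boundary values are retained).  Individuals with zero
    total depth for a pair contribute no evidence and are skipped.

    Returns the retained pairs and a per-pair report with the offending
    individual and fraction for removed pairs.
    """
    piv = depth_table.pivot_table(
        index="individual", columns="gene_id", values="mean_depth", aggfunc="first"
    )
    missing_rows: list[str] = []
    records = []
    retained = []
    for pair in pairs:
        status, offender, fraction = "retained", "", np.nan
        for ind in polyploid_individuals:
            try:
                da = piv.at[ind, pair.gene_at]
                dd = piv.at[ind, pair.gene_dt]
            except KeyError:
                da = dd = np.nan
            if np.isnan(da) or np.isnan(dd):
                missing_rows.append(f"{pair.pair_id}:{ind}")
                continue
            if da + dd <= 0:
                continue  # no evidence from this individual
            frac = at_read_fraction(da, dd)
            if frac < config.lower_pct or frac > config.upper_pct:
                status, offender, fraction = "removed_he", ind, frac
                break
        if status == "retained":
            retained.append(pair)
        records.append((pair.pair_id, status, offender, fraction))
    if missing_rows:
        raise ValueError(
            "missing depth rows for polyploid individuals: "
            + ", ".join(missing_rows[:10])
            + ("..." if len(missing_rows) > 10 else "")
        )
    report = pd.DataFrame(
        records, columns=["pair_id", "status", "offending_individual", "fraction"]
    )
    return retained, report


def nullify_all_het(
    variants: VariantTable,
    species_groups: dict[str, list[str]],
    merge_groups: list[set[str]] | None = None,
    outgroup_species: set[str] | frozenset[str] = frozenset(),
) -> tuple[VariantTable, pd.DataFrame]:
    """Set genotypes to missing where every individual of a group is het.

    ``species_groups`` maps species name -> its sample names.  Species in
    ``merge_groups`` are pooled and tested jointly (useful when a species has
    too few individuals for the test to be meaningful on its own); outgroup
    species are exempt.  Allele fields are never touched, only genotypes.

    Returns a new table plus a tidy report of nullified (group, site)
    combinations.
    """
    merge_groups = merge_groups or []
    for grp in merge_groups:
        unknown = grp - set(species_groups)
        if unknown:
            raise ValueError(f"merge group references unknown species: {sorted(unknown)}")
    merged_away: set[str] = set()
    groups: dict[str, list[str]] = {}
    for grp in merge_groups:
        label = "+".join(sorted(grp))
        samples: list[str] = []
        for sp in sorted(grp):
            if sp in outgroup_species:
                raise ValueError(f"outgroup species {sp} cannot be merged/nullified")
            samples.extend(species_groups[sp])
            merged_away.add(sp)
        groups[label] = samples
    for sp, samples in species_groups.items():
        if sp in merged_away or sp in outgroup_species:
            continue
        groups[sp] = samples

    out = variants.copy()
    records = []
    for label, samples in groups.items():
        idx = out.sample_index(samples)
        block = out.G[:, idx]
        nonmissing = block >= 0
        all_het = ((block == 1) | ~nonmissing).all(axis=1) & nonmissing.any(axis=1)
        sites = np.nonzero(all_het)[0]
        for i in sites:
            records.append((label, out.df["chrom"].iat[i], int(out.df["pos"].iat[i])))
        if len(sites):
            out.G[np.ix_(sites, idx)] = -1
    report = pd.DataFrame(records, columns=["group", "chrom", "pos"])
    return out, report
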