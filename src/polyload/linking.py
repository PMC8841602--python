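"""Homoeolog CDS alignment, coordinate liftover, and SNP-site linking.

Homoeologous gene pairs are aligned globally (affine gap penalties, default
match +2 / mismatch -3 / gap open -5 / gap extend -2 — standard DNA weights
for high-identity pairs), every alignment column is mapped back to genomic
coordinates through the exon structure and strand of each gene, and SNPs
are linked across subgenomes.  Linked SNP pairs then pass through four
retention criteria designed to exclude indel-adjacent sites, inconsistent
polarization, and homoeologous gene conversion:

1. the SNP does not link to an indel (gap column) in its homoeolog;
2. at most two alleles across the two linked positions (after strand
   reconciliation) and a consistently inferred ancestral state at both;
3. the derived allele occurs in only one of the two subgenome lineages
   (the subgenome plus its diploid progenitor) — a derived allele seen in
   both is the signature of gene conversion (or a shared pre-divergence
   mutation) and is removed;
4. (optional, off by default) the derived allele is fixed in the diploid
   and segregating in its subgenome, or vice versa.

For pairs encoded on opposite strands of the reference, allele comparison
uses the purine/pyrimidine complement (an ancestral "A" on the forward-
strand gene corresponds to an ancestral "T" on the reverse-strand gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .coords import GAP, complement, genomic_to_cds, cds_to_genomic
from .polarize import UNRESOLVED
from .qc import HomoeologPair

__all__ = [
    "PairwiseAlignment",
    "LinkedSitePair",
    "SiteInfo",
    "align_cds",
    "map_alignment_to_genome",
    "link_snp_sites",
    "retention_filter",
]

_DNA = set("ACGTN")


@dataclass
class PairwiseAlignment:
    aligned_at: str
    aligned_dt: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_at) != len(self.aligned_dt):
            raise ValueError("aligned sequences differ in length")

    @property
    def column_count(self) -> int:
        return len(self.aligned_at)


def align_cds(
    seq_at: str,
    seq_dt: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (end gaps penalized).

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  The first
    optimal alignment in the aligner's deterministic traceback order is
    returned, so results are reproducible across runs and platforms.
    """
    for name, seq in (("seq_at", seq_at), ("seq_dt", seq_dt)):
        if not seq:
            raise ValueError(f"{name} is empty")
        bad = set(seq.upper()) - _DNA
        if bad:
            raise ValueError(f"{name} contains non-DNA characters: {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(seq_at.upper(), seq_dt.upper())[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def map_alignment_to_genome(
    aln: PairwiseAlignment, pair: HomoeologPair
) -> list[tuple[int, int]]:
    """Per-column (pos_at, pos_dt) 1-based genomic positions; GAP at indels.

    Minus-strand genes walk genomic coordinates in decreasing order, so
    alignment column order always follows the genes' reading direction.
    """
    la = len(aln.aligned_at.replace("-", ""))
    ld = len(aln.aligned_dt.replace("-", ""))
    if la != pair.cds_length_at or ld != pair.cds_length_dt:
        raise ValueError(
            f"{pair.pair_id}: aligned sequence lengths ({la}, {ld}) do not match "
            f"CDS lengths ({pair.cds_length_at}, {pair.cds_length_dt})"
        )
    out = []
    off_at = off_dt = 0
    for ca, cd in zip(aln.aligned_at, aln.aligned_dt):
        if ca != "-":
            pa = cds_to_genomic(off_at, pair.intervals_at, pair.strand_at) + 1
            off_at += 1
        else:
            pa = GAP
        if cd != "-":
            pd_ = cds_to_genomic(off_dt, pair.intervals_dt, pair.strand_dt) + 1
            off_dt += 1
        else:
            pd_ = GAP
        out.append((pa, pd_))
    return out


@dataclass
class LinkedSitePair:
    pair_id: str
    pos_at: int  # 1-based genomic, or GAP
    pos_dt: int
    column: int
    opposite_strand: bool


def link_snp_sites(
    snp_positions_at: list[int],
    snp_positions_dt: list[int],
    column_map: list[tuple[int, int]],
    pair: HomoeologPair,
) -> list[LinkedSitePair]:
    """Link SNP positions (1-based) across the two homoeologs.

    Every SNP in either gene yields one linked pair; two SNPs aligned to
    each other collapse into a single pair.  SNPs outside the CDS are
    skipped.
    """
    opposite = pair.strand_at != pair.strand_dt
    col_of_at = {pa: c for c, (pa, _) in enumerate(column_map) if pa != GAP}
    col_of_dt = {pd_: c for c, (_, pd_) in enumerate(column_map) if pd_ != GAP}
    seen: dict[int, LinkedSitePair] = {}
    for pos in snp_positions_at:
        col = col_of_at.get(pos)
        if col is None:
            continue
        pa, pd_ = column_map[col]
        seen[col] = LinkedSitePair(pair.pair_id, pa, pd_, col, opposite)
    for pos in snp_positions_dt:
        col = col_of_dt.get(pos)
        if col is None:
            continue
        if col not in seen:
            pa, pd_ = column_map[col]
            seen[col] = LinkedSitePair(pair.pair_id, pa, pd_, col, opposite)
    return [seen[c] for c in sorted(seen)]


@dataclass
class SiteInfo:
    """Everything the retention criteria need to know about one position."""

    ref: str  # reference base (genomic strand)
    alleles: tuple[str, ...]  # observed alleles, genomic strand
    anc: str  # ancestral base or UNRESOLVED
    present: dict[str, bool] = field(default_factory=dict)  # allele -> seen in this side's lineage group
    diploid_freq: float | None = None  # derived freq in the diploid progenitor
    subgenome_freqs: tuple[float, ...] = ()  # derived freq per polyploid subgenome

    @classmethod
    def monomorphic(cls, base: str) -> "SiteInfo":
        return cls(ref=base, alleles=(base,), anc=base, present={base: True})


@dataclass
class RetentionVerdict:
    site: LinkedSitePair
    retained: bool
    failed_criteria: tuple[int, ...]


def retention_filter(
    linked: list[LinkedSitePair],
    info_at: dict[int, SiteInfo],
    info_dt: dict[int, SiteInfo],
    criterion4: bool = False,
) -> list[RetentionVerdict]:
    """Apply the SNP retention criteria to linked site pairs.

    ``info_at`` / ``info_dt`` map 1-based genomic positions to
    :class:`SiteInfo` (monomorphic linked positions included).  Criterion 4
    is off by default; it additionally requires a fixed-vs-segregating
    contrast between a diploid and its subgenome.
    """
    out = []
    for site in linked:
        failed: list[int] = []
        if site.pos_at == GAP or site.pos_dt == GAP:
            failed.append(1)
            out.append(RetentionVerdict(site, False, (1,)))
            continue
        ia = info_at.get(site.pos_at)
        id_ = info_dt.get(site.pos_dt)
        if ia is None or id_ is None:
            raise KeyError(
                f"missing site info at {site.pos_at}/{site.pos_dt} for {site.pair_id}"
            )

        def rec(base: str) -> str:
            return complement(base) if site.opposite_strand else base

        union = set(ia.alleles) | {rec(b) for b in id_.alleles}
        anc_ok = (
            ia.anc != UNRESOLVED
            and id_.anc != UNRESOLVED
            and ia.anc == rec(id_.anc)
        )
        if len(union) > 2 or not anc_ok:
            failed.append(2)
        derived = None
        if anc_ok and len(union) == 2:
            derived = next(iter(union - {ia.anc}))
        if derived is not None:
            in_a = ia.present.get(derived, False)
            in_d = id_.present.get(rec(derived), False)
            if in_a and in_d:
                failed.append(3)
            if criterion4:
                side = ia if in_a else id_
                if not _fixed_segregating_contrast(side):
                    failed.append(4)
        elif not failed:
            # no derived allele at all: nothing to retain
            failed.append(2)
        out.append(RetentionVerdict(site, not failed, tuple(failed)))
    return out


def _fixed_segregating_contrast(info: SiteInfo) -> bool:
    if info.diploid_freq is None or not info.subgenome_freqs:
        return False
    dip = info.diploid_freq
    fixed_dip = dip == 1.0
    seg_dip = 0.0 < dip < 1.0
    fixed_sub = any(f == 1.0 for f in info.subgenome_freqs)
    seg_sub = any(0.0 < f < 1.0 for f in info.subgenome_freqs)
    return (fixed_dip and seg_sub) or (fixed_sub and seg_dip)
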