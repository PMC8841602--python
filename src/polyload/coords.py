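"""Coordinate conventions, centralized.

Internally everything is 0-based half-open (BED convention).  VCF positions
are 1-based and converted exactly once, at the I/O boundary, through the two
helpers here.  CDS coordinates are gene-oriented offsets (0 = first coding
base of the gene, reading 5'->3' of the *gene*), so minus-strand genes walk
genomic coordinates in decreasing order.
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}

GAP = -1  # sentinel genomic position for alignment columns inside an indel


def vcf_pos(zero_based: int) -> int:
    """0-based genomic coordinate -> 1-based VCF POS."""
    return zero_based + 1


def zero_based(vcf_position: int) -> int:
    """1-based VCF POS -> 0-based genomic coordinate."""
    return vcf_position - 1


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def complement(base: str) -> str:
    return COMPLEMENT[base]


def cds_to_genomic(offset: int, intervals: list[tuple[int, int]], strand: str) -> int:
    """Map a gene-oriented CDS offset to a 0-based genomic position.

    ``intervals`` are 0-based half-open exon intervals sorted by genomic
    start.  For minus-strand genes offset 0 is the *last* genomic base of
    the last interval.
    """
    total = sum(e - s for s, e in intervals)
    if not 0 <= offset < total:
        raise ValueError(f"CDS offset {offset} outside CDS of length {total}")
    if strand == "+":
        walk = offset
        for s, e in intervals:
            if walk < e - s:
                return s + walk
            walk -= e - s
    elif strand == "-":
        walk = offset
        for s, e in reversed(intervals):
            if walk < e - s:
                return e - 1 - walk
            walk -= e - s
    else:
        raise ValueError(f"bad strand {strand!r}")
    raise AssertionError("unreachable")


def genomic_to_cds(pos: int, intervals: list[tuple[int, int]], strand: str) -> int:
    """Inverse of :func:`cds_to_genomic`; raises if ``pos`` is not coding."""
    if strand == "+":
        walk = 0
        for s, e in intervals:
            if s <= pos < e:
                return walk + (pos - s)
            walk += e - s
    elif strand == "-":
        walk = 0
        for s, e in reversed(intervals):
            if s <= pos < e:
                return walk + (e - 1 - pos)
            walk += e - s
    else:
        raise ValueError(f"bad strand {strand!r}")
    raise ValueError(f"position {pos} not inside CDS intervals")
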