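"""Readers for the pipeline's on-disk inputs (BED, FASTA, TSV, newick).

VCF I/O lives with the :class:`~polyload.variants.VariantTable`.  BED
records follow BED6 with ``name=geneID|subgenome|pairID``; homoeologous
pairs are reassembled from the shared pairID.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import trees
from .qc import HomoeologPair

__all__ = [
    "read_bed_pairs",
    "read_cds_fasta",
    "read_depths",
    "read_samples",
    "read_score_track",
    "read_deleterious_flags",
    "read_newick",
]


def read_bed_pairs(path) -> list[HomoeologPair]:
    """Parse a BED6 gene-model file into homoeologous pairs."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{line_no}: BED6 record expected")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                gene_id, subgenome, pair_id = name.split("|")
            except ValueError:
                raise ValueError(
                    f"{path}:{line_no}: name must be geneID|subgenome|pairID, got {name!r}"
                ) from None
            rec = genes.setdefault(
                gene_id,
                {"chrom": chrom, "strand": strand, "sub": subgenome,
                 "pair": pair_id, "intervals": []},
            )
            rec["intervals"].append((int(start), int(end)))

    by_pair: dict[str, dict[str, tuple[str, dict]]] = {}
    for gene_id, rec in genes.items():
        by_pair.setdefault(rec["pair"], {})[rec["sub"]] = (gene_id, rec)
    pairs = []
    for pair_id in sorted(by_pair):
        members = by_pair[pair_id]
        if set(members) != {"At", "Dt"}:
            raise ValueError(f"pair {pair_id} lacks an At/Dt member: has {sorted(members)}")
        (gat, rat), (gdt, rdt) = members["At"], members["Dt"]
        pairs.append(
            HomoeologPair(
                pair_id=pair_id,
                gene_at=gat,
                gene_dt=gdt,
                chrom_at=rat["chrom"],
                chrom_dt=rdt["chrom"],
                intervals_at=sorted(rat["intervals"]),
                intervals_dt=sorted(rdt["intervals"]),
                strand_at=rat["strand"],
                strand_dt=rdt["strand"],
            )
        )
    return pairs


def read_cds_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def attach_sequences(pairs: list[HomoeologPair], seqs: dict[str, str]) -> None:
    for pair in pairs:
        try:
            pair.seq_at = seqs[pair.gene_at]
            pair.seq_dt = seqs[pair.gene_dt]
        except KeyError as err:
            raise KeyError(f"FASTA lacks CDS sequence for gene {err}") from None


def read_depths(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "individual", "mean_depth"}
    if not required <= set(df.columns):
        raise ValueError(f"depth table needs columns {sorted(required)}")
    return df


def read_samples(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["individual"], df["species"]))


def read_score_track(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "pos", "score"} <= set(df.columns):
        raise ValueError("score track needs columns chrom, pos, score")
    return df


def read_deleterious_flags(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "pos", "deleterious"} <= set(df.columns):
        raise ValueError("flag table needs columns chrom, pos, deleterious")
    df["deleterious"] = df["deleterious"].astype(bool)
    return df


def read_newick(path) -> trees.Node:
    return trees.parse_newick(Path(path).read_text())
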