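"""Biallelic SNP container and VCF I/O.

The central in-memory object is :class:`VariantTable`: a pandas DataFrame of
site-level fields (``chrom``, ``pos`` 1-based, ``id``, ``ref``, ``alt``, plus
any annotation columns downstream stages attach) and an aligned int8 genotype
matrix of ALT-allele counts per diploid sample (0, 1, 2; -1 for missing).
VCFs are read with cyvcf2 and written as plain VCF v4.2 text so that small
synthetic datasets round-trip byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


@dataclass
class VariantTable:
    df: pd.DataFrame
    G: np.ndarray  # (n_variants, n_samples) int8 ALT counts, -1 missing
    samples: list[str]

    def __post_init__(self) -> None:
        if len(self.df) != self.G.shape[0]:
            raise ValueError("df and genotype matrix disagree on variant count")
        if self.G.ndim != 2 or self.G.shape[1] != len(self.samples):
            raise ValueError("genotype matrix and sample list disagree")

    @property
    def n_variants(self) -> int:
        return len(self.df)

    def sample_index(self, names: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return np.array([lookup[n] for n in names], dtype=int)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(
            self.df.loc[mask].reset_index(drop=True),
            self.G[np.asarray(mask)],
            list(self.samples),
        )

    def copy(self) -> "VariantTable":
        return VariantTable(self.df.copy(), self.G.copy(), list(self.samples))

    # ------------------------------------------------------------------ I/O

    def write_vcf(self, path, contigs: dict[str, int] | None = None) -> None:
        df = self.df
        order = np.lexsort((df["pos"].to_numpy(), df["chrom"].to_numpy()))
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=polyload\n")
            if contigs:
                for name, length in contigs.items():
                    fh.write(f"##contig=<ID={name},length={length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            chrom = df["chrom"].to_numpy()
            pos = df["pos"].to_numpy()
            vid = df["id"].to_numpy() if "id" in df else np.full(len(df), ".")
            ref = df["ref"].to_numpy()
            alt = df["alt"].to_numpy()
            for i in order:
                gts = "\t".join(_GT_STRINGS[int(g)] for g in self.G[i])
                fh.write(
                    f"{chrom[i]}\t{pos[i]}\t{vid[i]}\t{ref[i]}\t{alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
                )

    @classmethod
    def read_vcf(cls, path) -> "VariantTable":
        reader = VCF(str(path))
        samples = list(reader.samples)
        rows = []
        gmat = []
        for v in reader:
            alt = v.ALT[0] if v.ALT else "."
            rows.append((v.CHROM, v.POS, v.ID or ".", v.REF, alt))
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt = np.asarray(v.gt_types)
            counts = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1)
            gmat.append(counts.astype(np.int8))
        reader.close()
        df = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
        G = (
            np.vstack(gmat)
            if gmat
            else np.zeros((0, len(samples)), dtype=np.int8)
        )
        return cls(df, G, samples)


def empty_table(samples: list[str]) -> VariantTable:
    df = pd.DataFrame(columns=["chrom", "pos", "id", "ref", "alt"])
    return VariantTable(df, np.zeros((0, len(samples)), dtype=np.int8), samples)
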