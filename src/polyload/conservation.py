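"""Rejected-substitutions conservation scoring.

The score of a site is RS = E - O: the neutral substitution expectation E
(total branch length of the neutral tree spanning the species present at the
site) minus the observed number of substitutions O (minimum changes under
Fitch parsimony on that spanning subtree).  Positive RS means the site has
tolerated fewer substitutions than neutrality predicts, i.e. it is
constrained; mutations at constrained sites are binned into mildly
(0 < RS <= 2), moderately (2 < RS <= 4) and strongly (4 < RS <= 6)
deleterious categories, with RS > 6 clamped into the strong bin.

The neutral tree is calibrated at 4-fold degenerate third-codon positions:
JC69-corrected pairwise distances at those sites are fit to the fixed
topology by nonnegative least squares.  Fitch parsimony is a lower bound on
the true substitution count, so RS here is an upper-bound-flavored score —
adequate for ranking and binning, and swappable for an externally computed
per-site score track.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.optimize import nnls

from . import trees
from .trees import Node

__all__ = [
    "NeutralTree",
    "SiteScore",
    "fourfold_sites",
    "estimate_neutral_tree",
    "site_expected_subs",
    "site_observed_subs",
    "rs_score",
    "gerp_bin",
    "score_alignment",
    "jc69_distance",
]

_DNA = set("ACGT")
GAP_CHARS = set("-NX?.")


def _fourfold_prefixes(table_id: int = 1) -> frozenset[str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    prefixes = []
    for first in "TCAG":
        for second in "TCAG":
            codons = [first + second + third for third in "TCAG"]
            if any(c in table.stop_codons for c in codons):
                continue
            aas = {table.forward_table[c] for c in codons}
            if len(aas) == 1:
                prefixes.append(first + second)
    return frozenset(prefixes)


FOURFOLD_PREFIXES = _fourfold_prefixes()


def fourfold_sites(cds_alignment: dict[str, str], reference: str | None = None) -> list[int]:
    """Indices of 4-fold degenerate third-codon positions in an alignment.

    The reading frame is taken from the reference row (first row if not
    named), which must be gap-free and a multiple of 3.  A column qualifies
    when, for every sequence without gaps in that codon, the codon belongs
    to a 4-fold degenerate family.
    """
    if not cds_alignment:
        raise ValueError("empty alignment")
    names = list(cds_alignment)
    ref_name = reference if reference is not None else names[0]
    ref = cds_alignment[ref_name]
    if any(c in GAP_CHARS for c in ref):
        raise ValueError("reference row must be ungapped to define the frame")
    if len(ref) % 3 != 0:
        raise ValueError("reference row length is not a multiple of 3")
    lengths = {len(s) for s in cds_alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")

    out = []
    for codon_start in range(0, len(ref), 3):
        ok = True
        for seq in cds_alignment.values():
            codon = seq[codon_start : codon_start + 3].upper()
            if any(c in GAP_CHARS for c in codon):
                continue  # species with a gap in the codon is ignored here
            if any(c not in _DNA for c in codon):
                ok = False
                break
            if codon[:2] not in FOURFOLD_PREFIXES:
                ok = False
                break
        if ok:
            out.append(codon_start + 2)
    return out


def jc69_distance(p: float) -> float:
    """Jukes-Cantor distance from a proportion of differing sites."""
    if p < 0:
        raise ValueError("negative mismatch proportion")
    if p >= 0.75:
        raise ValueError(f"saturated distance (p={p:.3f} >= 0.75)")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


@dataclass
class NeutralTree:
    """Fixed topology with branch lengths in expected substitutions/site."""

    root: Node

    @property
    def total_length(self) -> float:
        return sum(n.length for n in self.root.postorder() if n is not self.root)

    def newick(self) -> str:
        return trees.to_newick(self.root)


def estimate_neutral_tree(
    fourfold_alignment: dict[str, str], topology: Node
) -> NeutralTree:
    """Least-squares branch lengths on a fixed topology from 4-fold sites.

    Pairwise JC69-corrected distances are computed over columns where both
    sequences are ungapped, then fit by nonnegative least squares to the
    path-indicator system of the topology.  Saturated pairs (raw mismatch
    >= 0.75) raise, naming the pair.
    """
    species = topology.tip_names()
    if len(species) < 3:
        raise ValueError("need at least 3 species")
    missing = [s for s in species if s not in fourfold_alignment]
    if missing:
        raise ValueError(f"alignment lacks species: {missing}")

    pairs = list(itertools.combinations(species, 2))
    dists = []
    for a, b in pairs:
        sa, sb = fourfold_alignment[a].upper(), fourfold_alignment[b].upper()
        both = [
            (x, y)
            for x, y in zip(sa, sb)
            if x not in GAP_CHARS and y not in GAP_CHARS
        ]
        if not both:
            raise ValueError(f"no comparable sites for pair ({a},{b})")
        p = sum(x != y for x, y in both) / len(both)
        try:
            dists.append(jc69_distance(p))
        except ValueError as err:
            raise ValueError(f"pair ({a},{b}): {err}") from None

    below = trees.clade_tipsets(topology)
    edges = [n for n in topology.postorder() if n is not topology]
    A = np.zeros((len(pairs), len(edges)))
    for i, (a, b) in enumerate(pairs):
        for j, edge in enumerate(edges):
            inside = below[edge.name]
            if (a in inside) != (b in inside):
                A[i, j] = 1.0
    lengths, _ = nnls(A, np.asarray(dists))

    fitted = trees.parse_newick(trees.to_newick(topology))
    for edge, val in zip(edges, lengths):
        fitted.find(edge.name).length = float(val)
    return NeutralTree(fitted)


def site_expected_subs(tree: NeutralTree, present_species: set[str]) -> float:
    """Neutral expectation: spanning-subtree length over the present species."""
    if len(present_species) < 2:
        return 0.0
    return trees.spanning_length(tree.root, present_species)


def site_observed_subs(column: dict[str, str], tree: NeutralTree) -> int:
    """Minimum substitutions explaining an alignment column (Fitch parsimony).

    ``column`` maps species -> base; species with gaps should be omitted by
    the caller (they are excluded from both E and O).
    """
    states = {sp: b.upper() for sp, b in column.items() if b.upper() in _DNA}
    if len(states) < 2:
        return 0
    return trees.fitch_count(tree.root, states)


def rs_score(expected: float, observed: float) -> float:
    """Rejected substitutions: expected - observed (may be negative)."""
    if expected < 0 or observed < 0:
        raise ValueError("expected and observed must be nonnegative")
    return expected - observed


@dataclass
class SiteScore:
    position: int
    expected_subs: float
    observed_subs: int
    rs: float
    bin: str


def gerp_bin(rs: float) -> str:
    """Deleteriousness bin; RS above 6 is clamped into ``strong``."""
    if rs <= 0:
        return "none"
    if rs <= 2:
        return "mild"
    if rs <= 4:
        return "moderate"
    return "strong"


def score_alignment(
    alignment: dict[str, str],
    tree: NeutralTree,
    positions: list[int] | None = None,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> list[SiteScore]:
    """Score alignment columns; ``exclude`` drops rows (e.g. the focal genome).

    The focal genome is excluded so that derived states in the very lineage
    being assayed do not depress its own conservation scores.
    """
    rows = {sp: seq.upper() for sp, seq in alignment.items() if sp not in exclude}
    if not rows:
        raise ValueError("no alignment rows left after exclusion")
    length = len(next(iter(rows.values())))
    if positions is None:
        positions = list(range(length))
    out = []
    for pos in positions:
        column = {
            sp: seq[pos] for sp, seq in rows.items() if seq[pos] in _DNA
        }
        present = set(column)
        exp = site_expected_subs(tree, present)
        obs = site_observed_subs(column, tree) if len(present) >= 2 else 0
        rs = rs_score(exp, obs)
        out.append(SiteScore(pos, exp, obs, rs, gerp_bin(rs)))
    return out


def scores_to_frame(scores: list[SiteScore], chrom: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": [s.position + 1 for s in scores],  # 1-based in the track
            "expected": [s.expected_subs for s in scores],
            "observed": [s.observed_subs for s in scores],
            "score": [s.rs for s in scores],
            "bin": [s.bin for s in scores],
        }
    )
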