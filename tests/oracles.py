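"""Independent brute-force oracles used to validate the package's algorithms.

Everything here is deliberately naive (exhaustive enumeration) and shares no
code with the implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from polyload.trees import Node

DNA = "ACGT"


# ---------------------------------------------------------------- parsimony


def exhaustive_parsimony(root: Node, states: dict[str, str]) -> int:
    """Minimum changes over all assignments of internal-node states."""
    internals = [n for n in root.postorder() if not n.is_tip]
    tips = [n for n in root.postorder() if n.is_tip and n.name in states]
    if len(tips) < 2:
        return 0

    def prune(node: Node) -> Node | None:
        if node.is_tip:
            return Node(node.name) if node.name in states else None
        kept = [c for c in (prune(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        return Node(node.name, children=kept)

    pruned = prune(root)
    assert pruned is not None
    internals = [n for n in pruned.postorder() if not n.is_tip]
    best = None
    for combo in itertools.product(DNA, repeat=len(internals)):
        assign = {n.name: s for n, s in zip(internals, combo)}
        assign.update(states)
        changes = 0
        for node in pruned.postorder():
            for child in node.children:
                if assign[node.name] != assign[child.name]:
                    changes += 1
        best = changes if best is None else min(best, changes)
    return int(best)


# ------------------------------------------------------- spanning subtree


def path_union_length(root: Node, present: set[str]) -> float:
    """Sum of edges on the union of paths between all pairs of present tips."""
    if len(present) < 2:
        return 0.0
    parents: dict[str, Node | None] = {root.name: None}
    lengths: dict[str, float] = {}
    for node in root.preorder():
        lengths[node.name] = node.length
        for child in node.children:
            parents[child.name] = node

    def root_path(tip: str) -> list[str]:
        out = []
        node_name = tip
        while parents[node_name] is not None:
            out.append(node_name)
            node_name = parents[node_name].name
        return out

    union: set[str] = set()
    for a, b in itertools.combinations(sorted(present), 2):
        pa, pb = set(root_path(a)), set(root_path(b))
        union |= pa ^ pb
    return sum(lengths[e] for e in union)


# ------------------------------------------------------------- alignment


def brute_force_global_alignment(
    a: str, b: str, match: float, mismatch: float, gap_open: float, gap_extend: float
) -> float:
    """Maximum score over every global alignment of ``a`` and ``b``.

    Alignments are monotone move sequences (diagonal / up / down); a gap run
    of length k scores gap_open + (k - 1) * gap_extend.
    """
    best = [-np.inf]

    def walk(i: int, j: int, score: float, last: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            walk(i + 1, j + 1, score + s, "d")
        if i < len(a):
            s = gap_extend if last == "u" else gap_open
            walk(i + 1, j, score + s, "u")
        if j < len(b):
            s = gap_extend if last == "l" else gap_open
            walk(i, j + 1, score + s, "l")

    walk(0, 0, 0.0, "d")
    return float(best[0])


# ---------------------------------------------------------- random trees


def random_tree(n_tips: int, rng: np.random.Generator, prefix: str = "t") -> Node:
    """Random binary topology with uniform-random branch lengths."""
    nodes = [Node(f"{prefix}{i}", float(rng.uniform(0.05, 1.0))) for i in range(n_tips)]
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        counter += 1
        nodes.append(
            Node(f"{prefix}_n{counter}", float(rng.uniform(0.05, 1.0)), [left, right])
        )
    root = nodes[0]
    root.length = 0.0
    return root
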