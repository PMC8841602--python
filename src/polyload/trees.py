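"""Rooted-tree utilities shared by the polarization and conservation modules.

A deliberately small tree representation: nodes are plain objects with a
name, a branch length (length of the edge *above* the node) and children.
Every node carries a unique name, so an edge can be identified by the name
of its child node.  Newick parsing is delegated to dendropy; everything the
hot loops need (clade bitsets, Fitch parsimony, spanning-subtree lengths)
runs on this lightweight structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import dendropy

__all__ = [
    "Node",
    "parse_newick",
    "to_newick",
    "clade_tipsets",
    "fitch_count",
    "spanning_length",
    "restrict",
]


@dataclass
class Node:
    """One node of a rooted tree; ``length`` is the edge above the node."""

    name: str
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()

    def tips(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def find(self, name: str) -> "Node":
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(f"no node named {name!r}")


def parse_newick(newick: str) -> Node:
    """Parse a rooted newick string into a :class:`Node` tree.

    Unlabeled internal nodes receive synthetic names ``_n1``, ``_n2``, ...
    (preorder).  Duplicate names raise ``ValueError`` because edges are
    addressed by child-node name throughout the package.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
        )
    except dendropy.utility.error.DataParseError as err:
        raise ValueError(f"invalid newick: {err}") from None
    counter = [0]

    def convert(dnode) -> Node:
        if dnode.taxon is not None:
            name = dnode.taxon.label
        elif dnode.label:
            name = dnode.label
        else:
            counter[0] += 1
            name = f"_n{counter[0]}"
        node = Node(name=name, length=dnode.edge.length or 0.0)
        for child in dnode.child_nodes():
            node.children.append(convert(child))
        return node

    root = convert(dtree.seed_node)
    names = [n.name for n in root.postorder()]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate node names in tree: {dupes}")
    return root


def to_newick(root: Node, include_internal_labels: bool = True) -> str:
    buf = StringIO()

    def write(node: Node, top: bool) -> None:
        if node.children:
            buf.write("(")
            for i, child in enumerate(node.children):
                if i:
                    buf.write(",")
                write(child, False)
            buf.write(")")
            if include_internal_labels and not node.name.startswith("_n"):
                buf.write(node.name)
        else:
            buf.write(node.name)
        if not top:
            buf.write(f":{node.length:g}")

    write(root, True)
    buf.write(";")
    return buf.getvalue()


def clade_tipsets(root: Node) -> dict[str, frozenset[str]]:
    """Map each node name to the frozenset of tip names below it."""
    out: dict[str, frozenset[str]] = {}
    for node in root.postorder():
        if node.is_tip:
            out[node.name] = frozenset([node.name])
        else:
            acc: set[str] = set()
            for child in node.children:
                acc |= out[child.name]
            out[node.name] = frozenset(acc)
    return out


def fitch_count(root: Node, states: dict[str, str]) -> int:
    """Minimum number of state changes on ``root`` explaining tip ``states``.

    Tips missing from ``states`` are pruned: a node with observed tips below
    only one child inherits that child's state set at zero cost, which is
    exactly Fitch parsimony on the induced subtree.  Returns 0 when fewer
    than two tips carry data.
    """

    def walk(node: Node) -> tuple[frozenset[str] | None, int]:
        if node.is_tip:
            s = states.get(node.name)
            return (frozenset([s]), 0) if s is not None else (None, 0)
        acc: frozenset[str] | None = None
        cost = 0
        for child in node.children:
            cset, ccost = walk(child)
            cost += ccost
            if cset is None:
                continue
            if acc is None:
                acc = cset
            else:
                inter = acc & cset
                if inter:
                    acc = inter
                else:
                    acc = acc | cset
                    cost += 1
        return acc, cost

    _, total = walk(root)
    return total


def spanning_length(root: Node, present: set[str] | frozenset[str]) -> float:
    """Total branch length of the subtree spanning the ``present`` tips.

    An edge contributes iff present tips occur both below it and elsewhere
    in the tree; fewer than two present tips give 0.
    """
    present = set(present)
    tips = set(root.tip_names())
    unknown = present - tips
    if unknown:
        raise ValueError(f"tips not in tree: {sorted(unknown)}")
    if len(present) < 2:
        return 0.0
    below = clade_tipsets(root)
    total = 0.0
    for node in root.postorder():
        if node is root:
            continue
        inside = len(below[node.name] & present)
        if 0 < inside < len(present):
            total += node.length
    return total


def restrict(root: Node, keep_tips: set[str]) -> tuple[Node, dict[str, str]]:
    """Restrict the tree to ``keep_tips``, merging unary paths.

    Returns the restricted tree and a mapping from every original edge
    (child-node name) with surviving descendants to the edge of the
    restricted tree it became part of.  A merged path is named after its
    lowest (most tipward) node, so e.g. a stem edge plus the edge to a clade
    both map onto the clade's edge.
    """
    mapping: dict[str, str] = {}

    def build(node: Node) -> Node | None:
        if node.is_tip:
            return Node(node.name, node.length) if node.name in keep_tips else None
        kept = [c for c in ((build(ch), ch.name) for ch in node.children)]
        kept_nodes = [(n, orig) for n, orig in kept if n is not None]
        if not kept_nodes:
            return None
        if len(kept_nodes) == 1:
            child, _orig = kept_nodes[0]
            merged = Node(child.name, child.length + node.length, child.children)
            mapping[node.name] = child.name
            return merged
        new = Node(node.name, node.length, [n for n, _ in kept_nodes])
        return new

    new_root = build(root)
    if new_root is None:
        raise ValueError("no tips survive restriction")
    # root's own edge length is irrelevant; pin it at 0 for cleanliness
    new_root.length = 0.0
    for node in new_root.postorder():
        mapping.setdefault(node.name, node.name)
    return new_root, mapping
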