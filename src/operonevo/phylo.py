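"""A minimal rooted binary phylogeny.

The inference algorithm is parsimony-based: branch lengths are ignored and
only the topology, leaf names and a deterministic traversal order matter.
Internal nodes without a name are auto-named ``anc_<postorder_index>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["PhyloNode", "Phylogeny", "cherry_tree", "triplet_tree"]


@dataclass(eq=False)
class PhyloNode:
    name: str | None
    children: list["PhyloNode"] = field(default_factory=list)
    parent: "PhyloNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()

    def __repr__(self) -> str:
        return f"PhyloNode({self.name})"


class Phylogeny:
    """Rooted binary tree with unique leaf names."""

    def __init__(self, root: PhyloNode):
        self.root = root
        self._autoname()
        self.validate()

    def _autoname(self) -> None:
        for i, node in enumerate(self.root.postorder()):
            if not node.name:
                node.name = f"anc_{i}"
            for c in node.children:
                c.parent = node

    def validate(self) -> None:
        names = [n.name for n in self.leaves()]
        if len(set(names)) != len(names):
            raise ValueError("leaf names must be unique")
        for node in self.root.postorder():
            if node.children and len(node.children) != 2:
                raise ValueError(
                    f"node {node.name!r} has {len(node.children)} children; "
                    "the algorithm requires a binary tree"
                )

    def leaves(self) -> list[PhyloNode]:
        return [n for n in self.root.postorder() if n.is_leaf]

    def internals(self) -> list[PhyloNode]:
        return [n for n in self.root.postorder() if not n.is_leaf]

    def postorder(self):
        return self.root.postorder()

    def node(self, name: str) -> PhyloNode:
        for n in self.root.postorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def sibling(self, node: PhyloNode) -> PhyloNode | None:
        if node.parent is None:
            return None
        a, b = node.parent.children
        return b if a is node else a

    def cherries(self) -> list[PhyloNode]:
        """Internal nodes whose two children are both leaves."""
        return [n for n in self.internals() if all(c.is_leaf for c in n.children)]

    def branches(self) -> list[tuple[PhyloNode, PhyloNode]]:
        """(parent, child) pairs, preorder."""
        out = []
        for node in self.root.preorder():
            for c in node.children:
                out.append((node, c))
        return out


def cherry_tree(x: str = "X", y: str = "Y") -> Phylogeny:
    root = PhyloNode("root", [PhyloNode(x), PhyloNode(y)])
    return Phylogeny(root)


def triplet_tree(x: str = "X", y: str = "Y", n: str = "N") -> Phylogeny:
    cherry = PhyloNode("P", [PhyloNode(x), PhyloNode(y)])
    root = PhyloNode("root", [cherry, PhyloNode(n)])
    return Phylogeny(root)
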