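"""Minimal unrooted-tree container shared by the NJ builder and the Newick writer.

The tree is stored rooted at the final join of the neighbor-joining pass:
a trifurcation for three or more taxa, a bifurcation for the two-taxon
convention. Per-edge bootstrap supports live on the child node of each
internal edge.
"""
from __future__ import annotations

from typing import Iterator, Optional


class TreeNode:
    __slots__ = ("name", "length", "support", "children")

    def __init__(
        self,
        name: Optional[str] = None,
        length: float = 0.0,
        support: Optional[int] = None,
        children: Optional[list["TreeNode"]] = None,
    ) -> None:
        self.name = name
        self.length = length
        self.support = support
        self.children: list[TreeNode] = children if children is not None else []

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name] if self.name is not None else [None]
        names: list[str] = []
        for child in self.children:
            names.extend(child.leaf_names())
        return names


class Tree:
    """Unrooted phylogeny with branch lengths and optional split supports."""

    def __init__(self, root: TreeNode) -> None:
        self.root = root

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def n_leaves(self) -> int:
        return len(self.leaf_names())

    def splits(self) -> dict[frozenset, TreeNode]:
        """Canonical internal-edge splits, mapped to the child node of the edge.

        A split is the frozenset of leaf names on the side of the edge that
        does NOT contain the lexicographically smallest leaf, so the key is
        independent of rooting and leaf order.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset, TreeNode] = {}
        for node in self.root.postorder():
            if node is self.root or node.is_leaf():
                continue
            side = frozenset(node.leaf_names())
            key = frozenset(all_leaves - side) if anchor in side else side
            out[key] = node
        return out

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                if not node.name:
                    raise ValueError("tree contains an unnamed leaf")
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else str(int(node.support))
            return f"({inner}){label}:{node.length:.6f}"

        root = self.root
        inner = ",".join(fmt(c) for c in root.children)
        return f"({inner});"
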