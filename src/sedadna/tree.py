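"""Minimal rooted tree used for mitochondrial panels and placement.

Placement works on explicit parent/child ids and clade bitsets, which a
thin dedicated structure serves better than a general phylogenetics object;
Newick I/O goes through dendropy so files interoperate with standard tools.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable

import dendropy
import numpy as np


@dataclasses.dataclass
class TreeNode:
    node_id: str
    parent_id: str | None
    children: list[str] = dataclasses.field(default_factory=list)


class RootedTree:
    """Rooted tree over string node ids; tips are nodes without children."""

    def __init__(self, nodes: Iterable[TreeNode]):
        self.nodes: dict[str, TreeNode] = {}
        for n in nodes:
            if n.node_id in self.nodes:
                raise ValueError(f"duplicate node id {n.node_id}")
            self.nodes[n.node_id] = n
        roots = [n.node_id for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"expected one root, found {len(roots)}")
        self.root_id = roots[0]
        for n in self.nodes.values():
            if n.parent_id is not None and n.parent_id not in self.nodes:
                raise ValueError(f"node {n.node_id}: unknown parent {n.parent_id}")

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def is_tip(self, node_id: str) -> bool:
        return not self.nodes[node_id].children

    def tips(self) -> list[str]:
        return [nid for nid in self.preorder() if self.is_tip(nid)]

    def preorder(self) -> list[str]:
        out: list[str] = []
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            # reversed keeps child order stable in the output
            stack.extend(reversed(self.nodes[nid].children))
        return out

    def path_to_root(self, node_id: str) -> list[str]:
        if node_id not in self.nodes:
            raise KeyError(f"unknown node id {node_id}")
        path = [node_id]
        while self.nodes[path[-1]].parent_id is not None:
            path.append(self.nodes[path[-1]].parent_id)
        return path

    def depth(self, node_id: str) -> int:
        return len(self.path_to_root(node_id)) - 1

    def branch_path(self, node_id: str) -> list[str]:
        """Branches (child-node ids) on the root-to-node path, root side first."""
        return [nid for nid in reversed(self.path_to_root(node_id)) if nid != self.root_id]

    def clade_tips(self, node_id: str) -> frozenset[str]:
        """Tip ids of the clade subtended by ``node_id`` (itself if a tip)."""
        out = []
        stack = [node_id]
        while stack:
            nid = stack.pop()
            if self.is_tip(nid):
                out.append(nid)
            stack.extend(self.nodes[nid].children)
        return frozenset(out)

    def lca(self, node_ids: Iterable[str]) -> str:
        paths = [self.path_to_root(n)[::-1] for n in node_ids]
        if not paths:
            raise ValueError("lca of empty node set")
        result = self.root_id
        for level in zip(*paths):
            if len(set(level)) == 1:
                result = level[0]
            else:
                break
        return result

    def is_ancestor_or_self(self, ancestor: str, descendant: str) -> bool:
        return ancestor in self.path_to_root(descendant)

    # -- Newick I/O ------------------------------------------------------

    def to_newick(self) -> str:
        def render(nid: str) -> str:
            node = self.nodes[nid]
            if not node.children:
                return nid
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){nid}"

        return render(self.root_id) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "RootedTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        nodes: list[TreeNode] = []
        counter = [0]

        def label_of(dnode) -> str:
            if dnode.taxon is not None and dnode.taxon.label:
                return dnode.taxon.label.replace(" ", "_")
            if dnode.label:
                return dnode.label
            counter[0] += 1
            return f"_anon{counter[0]}"

        ids: dict[int, str] = {}
        for dnode in dt.preorder_node_iter():
            nid = label_of(dnode)
            ids[id(dnode)] = nid
            parent = ids[id(dnode.parent_node)] if dnode.parent_node is not None else None
            nodes.append(TreeNode(nid, parent))
        tree = cls(nodes)
        for dnode in dt.preorder_node_iter():
            for child in dnode.child_nodes():
                tree.nodes[ids[id(dnode)]].children.append(ids[id(child)])
        return tree


def random_bifurcating_tree(
    n_tips: int, rng: np.random.Generator, outgroup: str = "OUT"
) -> RootedTree:
    """Random rooted bifurcating ingroup of ``n_tips`` tips plus an outgroup.

    The outgroup attaches at the root as sister to the whole ingroup; the
    ingroup topology is built by random sequential joining.  Internal nodes
    are labelled N1, N2, ... in construction order; the ingroup stem node is
    always "ING".
    """
    if n_tips < 3:
        raise ValueError(f"n_tips must be >= 3, got {n_tips}")
    tips = [f"T{i + 1}" for i in range(n_tips)]
    nodes: dict[str, TreeNode] = {t: TreeNode(t, None) for t in tips}
    subtrees = list(tips)
    counter = 0
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        counter += 1
        parent = "ING" if len(subtrees) == 2 else f"N{counter}"
        a, b = subtrees[i], subtrees[j]
        nodes[parent] = TreeNode(parent, None, [a, b])
        nodes[a].parent_id = parent
        nodes[b].parent_id = parent
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)] + [parent]
    ing = subtrees[0]
    nodes["ROOT"] = TreeNode("ROOT", None, [outgroup, ing])
    nodes[outgroup] = TreeNode(outgroup, "ROOT")
    nodes[ing].parent_id = "ROOT"
    return RootedTree(nodes.values())
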