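"""Taxonomy trees: parsing (Newick or parent-table TSV) and LCA queries."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy

__all__ = ["TaxonomyTree", "parse_taxonomy", "lca"]


@dataclass
class TaxonomyTree:
    """Rooted tree as parent pointers, with genome-to-leaf mapping.

    ``parent`` maps every node id to its parent (the root maps to itself);
    ``leaf_of_doc`` maps the 0-based genome index to its leaf node.
    """

    parent: dict[str, str]
    leaf_of_name: dict[str, str]
    doc_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        roots = [n for n, p in self.parent.items() if p == n]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self.depth: dict[str, int] = {}
        for node in self.parent:
            self._depth(node)

    def _depth(self, node: str) -> int:
        if node in self.depth:
            return self.depth[node]
        chain = []
        while node not in self.depth and self.parent[node] != node:
            chain.append(node)
            node = self.parent[node]
            if len(chain) > len(self.parent):
                raise ValueError("cycle in parent pointers")
        base = self.depth.get(node, 0)
        self.depth.setdefault(node, 0)
        for i, n in enumerate(reversed(chain), start=1):
            self.depth[n] = base + i
        return self.depth[chain[0]] if chain else base

    @property
    def node_ids(self) -> list[str]:
        return list(self.parent)

    def leaf_of_doc(self, doc: int) -> str:
        return self.leaf_of_name[self.doc_names[doc]]

    def lca(self, a: str, b: str) -> str:
        """Deepest common ancestor by depth-aligned pointer walking."""
        if a not in self.parent or b not in self.parent:
            raise KeyError(f"unknown node: {a if a not in self.parent else b}")
        while self.depth[a] > self.depth[b]:
            a = self.parent[a]
        while self.depth[b] > self.depth[a]:
            b = self.parent[b]
        while a != b:
            a, b = self.parent[a], self.parent[b]
        return a

    def subtree_for_mem(self, first_doc: int, last_doc: int) -> str:
        """LCA of the leaves of the first and last documents of a MEM."""
        return self.lca(self.leaf_of_doc(first_doc), self.leaf_of_doc(last_doc))

    def to_newick(self) -> str:
        children: dict[str, list[str]] = {}
        for n, p in self.parent.items():
            if n != p:
                children.setdefault(p, []).append(n)
        for v in children.values():
            v.sort()

        def fmt(node: str) -> str:
            kids = children.get(node, [])
            if not kids:
                return node
            return "(" + ",".join(fmt(k) for k in kids) + ")" + node
        return fmt(self.root) + ";"


def _from_dendropy(tree: dendropy.Tree, names: Sequence[str]) -> TaxonomyTree:
    parent: dict[str, str] = {}
    leaf_of_name: dict[str, str] = {}
    counter = 0
    labels: dict[int, str] = {}
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            label = node.taxon.label
        elif node.label:
            label = node.label
        else:
            label = f"_n{counter}"
            counter += 1
        labels[id(node)] = label
        parent[label] = labels[id(node.parent_node)] if node.parent_node else label
        if node.is_leaf():
            leaf_of_name[label] = label
    missing = [n for n in names if n not in leaf_of_name]
    if missing:
        raise ValueError(f"genomes missing from taxonomy: {missing}")
    return TaxonomyTree(parent=parent, leaf_of_name=leaf_of_name, doc_names=list(names))


def parse_taxonomy(
    path: str | Path, names: Sequence[str], format: str | None = None
) -> TaxonomyTree:
    """Parse a taxonomy covering the genome ``names`` (in collection order).

    ``format`` is ``"newick"`` or ``"tsv"`` (two columns: child, parent);
    when omitted it is inferred from the file suffix.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in {".tsv", ".txt"} else "newick"
    if format == "newick":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return _from_dendropy(tree, names)
    if format != "tsv":
        raise ValueError(f"unknown taxonomy format {format!r}")
    parent: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            child, par = line.split("\t")[:2]
            parent[child] = par
    for par in list(parent.values()):
        if par not in parent:
            parent[par] = par  # implicit root
    leaf_set = set(parent) - set(p for n, p in parent.items() if n != p)
    leaf_of_name = {n: n for n in leaf_set}
    missing = [n for n in names if n not in leaf_of_name]
    if missing:
        raise ValueError(f"genomes missing from taxonomy: {missing}")
    return TaxonomyTree(parent=parent, leaf_of_name=leaf_of_name, doc_names=list(names))


def lca(tree: TaxonomyTree, a: str, b: str) -> str:
    return tree.lca(a, b)
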