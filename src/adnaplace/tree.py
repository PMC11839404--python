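"""Reference trees with numbered edges.

Phylogenetic placement interchange files (jplace) annotate every branch of
the reference tree with an integer in braces, e.g. ``(A:0.1{0},B:0.2{1}){2};``.
Placements refer to branches through these numbers, so the tree container
here keeps an explicit ``edge_num -> branch`` map on top of a dendropy tree.

When a plain Newick string without brace annotations is given, edges are
numbered ``0..E-1`` in post-order of the tree as parsed (the root's own edge,
if any, is left unnumbered).  Truth tables and placement files produced by
this package follow the same convention, so they always agree.
"""

from __future__ import annotations

import io
import re
from typing import Iterator

import dendropy
import networkx as nx

__all__ = ["ReferenceTree", "NewickParseError", "parse_newick_edges"]

_BRACE_RE = re.compile(r"\{(\d+)\}")


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class ReferenceTree:
    """A phylogeny whose branches carry jplace-style integer edge numbers.

    Wraps a :class:`dendropy.Tree`; every non-root branch (plus the root
    branch when the input annotated it) has an integer ``edge_num`` stored
    as an attribute on the dendropy edge object.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._by_num: dict[int, dendropy.Edge] = {}
        for node in tree.preorder_node_iter():
            num = getattr(node.edge, "edge_num", None)
            if num is not None:
                if num in self._by_num:
                    raise ValueError(f"duplicate edge number {num}")
                self._by_num[int(num)] = node.edge
        self._graph: nx.Graph | None = None

    # ------------------------------------------------------------------ #
    # construction

    @classmethod
    def from_newick(cls, text: str) -> "ReferenceTree":
        """Parse Newick, honouring ``{N}`` edge annotations when present.

        Without annotations, edges are numbered 0..E-1 in post-order of the
        parsed tree (root edge unnumbered).
        """
        has_braces = _BRACE_RE.search(text) is not None
        # jplace braces are not Newick; smuggle them through the parser as
        # BEAST-style comments, which dendropy attaches to the right node.
        prepared = _BRACE_RE.sub(r"[&edge_num=\1]", text)
        try:
            tree = dendropy.Tree.get(
                data=prepared,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        if has_braces:
            for node in tree.preorder_node_iter():
                value = node.annotations.get_value("edge_num")
                if value is not None:
                    node.edge.edge_num = int(value)
            for node in tree.preorder_node_iter():
                if node.parent_node is not None and not hasattr(node.edge, "edge_num"):
                    raise NewickParseError(
                        f"edge above node {cls._node_label(node)!r} lacks an "
                        "{N} edge number while other edges carry one"
                    )
        else:
            _number_edges_postorder(tree)
        return cls(tree)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, renumber: bool = False) -> "ReferenceTree":
        if renumber:
            _number_edges_postorder(tree)
        return cls(tree)

    # ------------------------------------------------------------------ #
    # basic accessors

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_count(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def edge_nums(self) -> list[int]:
        return sorted(self._by_num)

    def edge(self, edge_num: int) -> dendropy.Edge:
        try:
            return self._by_num[edge_num]
        except KeyError:
            raise KeyError(f"edge number {edge_num} not present in tree") from None

    def has_edge(self, edge_num: int) -> bool:
        return edge_num in self._by_num

    @property
    def leaf_labels(self) -> list[str]:
        return [self._node_label(leaf) for leaf in self._tree.leaf_node_iter()]

    def pendant_edge_num(self, leaf_label: str) -> int:
        for leaf in self._tree.leaf_node_iter():
            if self._node_label(leaf) == leaf_label:
                num = getattr(leaf.edge, "edge_num", None)
                if num is None:
                    raise KeyError(f"pendant edge of {leaf_label!r} is unnumbered")
                return num
        raise KeyError(f"no leaf labelled {leaf_label!r}")

    @staticmethod
    def _node_label(node: dendropy.Node) -> str | None:
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    # ------------------------------------------------------------------ #
    # topological distance

    def edge_graph(self) -> nx.Graph:
        """Adjacency graph over numbered edges: two branches that share a
        tree node are neighbours.  Built lazily and cached."""
        if self._graph is None:
            graph = nx.Graph()
            graph.add_nodes_from(self._by_num)
            for node in self._tree.preorder_node_iter():
                incident = [
                    getattr(child.edge, "edge_num", None)
                    for child in node.child_nodes()
                ]
                incident.append(getattr(node.edge, "edge_num", None))
                incident = [e for e in incident if e is not None]
                for i, a in enumerate(incident):
                    for b in incident[i + 1:]:
                        graph.add_edge(a, b)
            self._graph = graph
        return self._graph

    def node_distance(self, edge_a: int, edge_b: int) -> int:
        """Topological distance between two branches.

        Zero for the same branch; branches sharing a node are at distance 1;
        otherwise the shortest-path length in the edge-adjacency graph.
        """
        for e in (edge_a, edge_b):
            if e not in self._by_num:
                raise KeyError(f"edge number {e} not present in tree")
        if edge_a == edge_b:
            return 0
        return nx.shortest_path_length(self.edge_graph(), edge_a, edge_b)

    # ------------------------------------------------------------------ #
    # serialisation

    def to_newick(self, include_edge_numbers: bool = True) -> str:
        """Serialise to Newick with ``{N}`` annotations preserved."""
        out = io.StringIO()
        self._write_node(self._tree.seed_node, out, include_edge_numbers)
        out.write(";")
        return out.getvalue()

    def _write_node(self, node, out, numbers: bool) -> None:
        children = node.child_nodes()
        if children:
            out.write("(")
            for i, child in enumerate(children):
                if i:
                    out.write(",")
                self._write_node(child, out, numbers)
            out.write(")")
        label = self._node_label(node)
        if label is not None:
            out.write(_escape_label(label))
        if node.edge.length is not None:
            out.write(f":{node.edge.length:.10g}")
        num = getattr(node.edge, "edge_num", None)
        if numbers and num is not None:
            out.write(f"{{{num}}}")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<ReferenceTree tips={self.tip_count} edges={len(self._by_num)}>"


def _number_edges_postorder(tree: dendropy.Tree) -> None:
    counter = 0
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            if hasattr(node.edge, "edge_num"):
                del node.edge.edge_num
            continue
        node.edge.edge_num = counter
        counter += 1


_SAFE_LABEL_RE = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _escape_label(label: str) -> str:
    if _SAFE_LABEL_RE.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def parse_newick_edges(text: str) -> ReferenceTree:
    """Parse a Newick string (optionally with ``{N}`` edge numbers)."""
    return ReferenceTree.from_newick(text)
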