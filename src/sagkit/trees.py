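"""Rooted trees with optional per-node gene-family presence states.

Newick parsing is delegated to dendropy; the parsed topology is frozen
into a small immutable node table that makes preorder traversal, MRCA
queries and root-to-node paths cheap and deterministic.  Internal nodes
without a label are auto-named ``n<preorder index>`` so that every node
has a stable, unique identifier; branch lengths default to 1.0 where the
Newick string omits them.

Ancestral presence states are a mapping ``node_id -> frozenset`` of the
families present at that node, together with the family universe over
which the states are defined (a family in the universe but not in a
node's set is explicitly absent there, not unknown).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import dendropy

__all__ = ["AnnotatedTree", "TreeError"]


class TreeError(ValueError):
    """Raised for malformed Newick input or invalid tree queries."""


@dataclass(frozen=True)
class _Node:
    id: str
    parent: int | None  # index into the node table, None for the root
    branch_length: float
    is_leaf: bool


class AnnotatedTree:
    """A rooted tree plus optional per-node family presence sets."""

    def __init__(
        self,
        nodes: list[_Node],
        states: Mapping[str, frozenset] | None = None,
        family_universe: frozenset | None = None,
    ):
        self._nodes = nodes
        self._index = {n.id: i for i, n in enumerate(nodes)}
        if len(self._index) != len(nodes):
            raise TreeError("node ids are not unique")
        self._children: list[list[int]] = [[] for _ in nodes]
        for i, n in enumerate(nodes):
            if n.parent is not None:
                self._children[n.parent].append(i)
        self.states = dict(states) if states is not None else None
        if self.states is not None and family_universe is None:
            family_universe = frozenset().union(*self.states.values()) if self.states else frozenset()
        self.family_universe = family_universe

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "AnnotatedTree":
        """Parse a rooted tree from a Newick string."""
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"malformed Newick: {exc}") from exc
        nodes: list[_Node] = []
        index_of: dict[int, int] = {}
        seen: set[str] = set()
        auto = 0
        for dnode in dtree.preorder_node_iter():
            if dnode.is_leaf():
                if dnode.taxon is None or not dnode.taxon.label:
                    raise TreeError("leaf without a name")
                name = dnode.taxon.label
            else:
                name = dnode.label
                if not name:
                    name = f"n{auto}"
                    while name in seen:
                        auto += 1
                        name = f"n{auto}"
            if name in seen:
                raise TreeError(f"duplicate node name {name!r}")
            seen.add(name)
            auto += 1
            parent = index_of[id(dnode.parent_node)] if dnode.parent_node is not None else None
            bl = dnode.edge.length if dnode.edge.length is not None else 1.0
            index_of[id(dnode)] = len(nodes)
            nodes.append(_Node(id=name, parent=parent, branch_length=float(bl), is_leaf=dnode.is_leaf()))
        if not nodes:
            raise TreeError("empty tree")
        return cls(nodes)

    def with_states(
        self,
        states: Mapping[str, Iterable],
        family_universe: Iterable | None = None,
    ) -> "AnnotatedTree":
        """Return a copy of this tree annotated with presence states."""
        frozen = {node: frozenset(fams) for node, fams in states.items()}
        for node in frozen:
            if node not in self._index:
                raise TreeError(f"state refers to unknown node {node!r}")
        universe = frozenset(family_universe) if family_universe is not None else None
        return AnnotatedTree(self._nodes, states=frozen, family_universe=universe)

    # -- queries -------------------------------------------------------

    def node_ids(self) -> list[str]:
        return [n.id for n in self._nodes]

    def root_id(self) -> str:
        return self._nodes[0].id

    def leaf_names(self) -> list[str]:
        return [n.id for n in self._nodes if n.is_leaf]

    def is_leaf(self, node_id: str) -> bool:
        return self._nodes[self._index[node_id]].is_leaf

    def parent(self, node_id: str) -> str | None:
        p = self._nodes[self._index[node_id]].parent
        return None if p is None else self._nodes[p].id

    def children(self, node_id: str) -> list[str]:
        return [self._nodes[c].id for c in self._children[self._index[node_id]]]

    def branch_length(self, node_id: str) -> float:
        return self._nodes[self._index[node_id]].branch_length

    def preorder_edges(self) -> Iterator[tuple[str, str, float]]:
        """Yield (node_id, parent_id, branch_length) for every non-root node."""
        for n in self._nodes[1:]:
            yield n.id, self._nodes[n.parent].id, n.branch_length

    def path_to_root(self, node_id: str) -> list[str]:
        """Node ids from ``node_id`` (inclusive) up to and including the root."""
        if node_id not in self._index:
            raise TreeError(f"unknown node {node_id!r}")
        path = [node_id]
        i = self._index[node_id]
        while self._nodes[i].parent is not None:
            i = self._nodes[i].parent
            path.append(self._nodes[i].id)
        return path

    def mrca(self, node_ids: Iterable[str]) -> str:
        """Most recent common ancestor of a nonempty set of nodes."""
        ids = list(node_ids)
        if not ids:
            raise TreeError("mrca of an empty node set")
        common = None
        for node in ids:
            ancestors = self.path_to_root(node)
            if common is None:
                common = ancestors
            else:
                anc_set = set(ancestors)
                common = [a for a in common if a in anc_set]
        return common[0]

    def presence(self, node_id: str) -> frozenset:
        """Presence set at a node; requires states to be annotated."""
        if self.states is None:
            raise TreeError("tree carries no ancestral states")
        if node_id not in self._index:
            raise TreeError(f"unknown node {node_id!r}")
        if node_id not in self.states:
            raise TreeError(f"no ancestral state recorded for node {node_id!r}")
        return self.states[node_id]

    def to_newick(self) -> str:
        def render(i: int) -> str:
            n = self._nodes[i]
            if n.is_leaf:
                body = n.id
            else:
                body = "(" + ",".join(render(c) for c in self._children[i]) + ")" + n.id
            if n.parent is not None:
                body += f":{n.branch_length:g}"
            return body

        return render(0) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"AnnotatedTree({len(self.leaf_names())} leaves, "
            f"{len(self._nodes)} nodes, states={'yes' if self.states else 'no'})"
        )
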