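"""Rooted phylogenetic trees and patristic distance matrices.

Trees are thin wrappers around :class:`dendropy.Tree`. The canonical OTU
order used everywhere downstream (distance-matrix rows, embedding rows,
convolution input order) is the post-order traversal of the rooted tree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "patristic_distance_matrix",
    "read_newick",
    "write_newick",
]


class TreeError(ValueError):
    """Raised for structurally invalid trees (duplicate labels, bad lengths)."""


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths and uniquely labeled leaves.

    Parameters
    ----------
    tree:
        The underlying dendropy tree. Ownership is transferred; callers
        should not mutate it afterwards.

    Attributes
    ----------
    leaf_labels:
        Leaf labels in canonical post-order. This order is the contract for
        every matrix whose rows correspond to OTUs.
    """

    tree: dendropy.Tree
    leaf_labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.leaf_labels = self._collect_leaf_labels()

    def _collect_leaf_labels(self) -> list[str]:
        labels: list[str] = []
        seen: set[str] = set()
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                label = _leaf_label(node)
                if label is None:
                    raise TreeError("leaf without a label encountered")
                if label in seen:
                    raise TreeError(f"duplicate leaf label: {label!r}")
                seen.add(label)
                labels.append(label)
        return labels

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        """Parse a Newick string (quoted labels and branch lengths supported)."""
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            if "Duplicate taxon labels" in str(exc):
                raise TreeError(f"duplicate leaf label: {exc}") from exc
            raise TreeError(f"Newick parse error: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        out = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        return out if out.endswith(";") else out + ";"

    def validate_branch_lengths(self) -> None:
        """Reject negative or missing (non-root) branch lengths."""
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:  # root "edge" carries no length
                continue
            if edge.length is None:
                head = _node_descr(edge.head_node)
                raise TreeError(f"missing branch length on edge above {head}")
            if not np.isfinite(edge.length):
                head = _node_descr(edge.head_node)
                raise TreeError(f"non-finite branch length on edge above {head}")
            if edge.length < 0:
                head = _node_descr(edge.head_node)
                raise TreeError(f"negative branch length on edge above {head}")


def _leaf_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None and node.taxon.label is not None:
        return node.taxon.label
    return node.label


def _node_descr(node: dendropy.Node) -> str:
    label = _leaf_label(node)
    if label is not None:
        return f"node {label!r}"
    leaves = [_leaf_label(lf) for lf in node.leaf_iter()]
    return f"internal node subtending {leaves[:3]}"


def patristic_distance_matrix(tree: PhyloTree) -> "DistanceMatrix":
    """Pairwise path-length distances between all leaves.

    D[i, j] is the sum of branch lengths on the unique path between leaves
    i and j; labels follow the canonical post-order of ``tree``.

    A single bottom-up sweep is used: each node carries the distances from
    itself to the leaves below it, and distances between leaves in different
    child subtrees are emitted when the subtrees join.
    """
    from deepphylo.embed import DistanceMatrix  # local import to avoid cycle

    tree.validate_branch_lengths()
    labels = tree.leaf_labels
    m = len(labels)
    if m == 0:
        raise TreeError("tree has no leaves")
    index = {label: i for i, label in enumerate(labels)}
    D = np.zeros((m, m), dtype=float)

    # node -> (leaf indices below, distances from node to those leaves)
    below: dict[dendropy.Node, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            i = index[_leaf_label(node)]
            below[node] = (np.array([i], dtype=np.intp), np.zeros(1))
            continue
        child_entries = []
        for child in node.child_nodes():
            idx, dist = below.pop(child)
            child_entries.append((idx, dist + child.edge.length))
        idx0, d0 = child_entries[0]
        for idx1, d1 in child_entries[1:]:
            # cross-pair distances between already-joined leaves and the
            # next child subtree
            cross = d0[:, None] + d1[None, :]
            D[np.ix_(idx0, idx1)] = cross
            D[np.ix_(idx1, idx0)] = cross.T
            idx0 = np.concatenate([idx0, idx1])
            d0 = np.concatenate([d0, d1])
        below[node] = (idx0, d0)

    return DistanceMatrix(D=D, labels=list(labels))


def read_newick(path: str) -> PhyloTree:
    with open(path, "r") as fh:
        return PhyloTree.from_newick(fh.read())


def write_newick(tree: PhyloTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
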