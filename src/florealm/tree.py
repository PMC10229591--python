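"""Dated phylogeny container.

A :class:`DatedTree` wraps a rooted :class:`dendropy.Tree` whose branch
lengths are in millions of years (Ma). The pipeline consumes dated trees; it
never infers or re-dates them. Tips are genera; internal nodes receive stable
generated identifiers (``node0001`` in preorder) unless the newick supplies
labels.
"""

from __future__ import annotations

from typing import Iterator

import dendropy
import numpy as np

from .errors import FormatError

__all__ = ["DatedTree", "read_tree", "write_tree"]


class DatedTree:
    """Rooted, dated tree with unique tip labels and nonnegative branch lengths.

    Parameters
    ----------
    tree:
        A rooted dendropy tree. Edge lengths must be present on every non-seed
        edge and nonnegative. Tip labels must be unique.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate_and_annotate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "DatedTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parser errors
            raise FormatError(f"unparsable newick: {exc}") from exc
        return cls(tree)

    def _validate_and_annotate(self) -> None:
        seen: set[str] = set()
        n_internal = 0
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise FormatError("leaf without a label")
                label = node.taxon.label
                if label in seen:
                    raise FormatError(f"duplicate tip label: {label!r}")
                seen.add(label)
                node.florealm_id = label
            else:
                n_internal += 1
                node.florealm_id = node.label or f"node{n_internal:04d}"
            if node is not self._tree.seed_node:
                if node.edge.length is None:
                    raise FormatError(
                        f"missing branch length above {node.florealm_id!r}"
                    )
                if node.edge.length < 0:
                    raise FormatError(
                        f"negative branch length above {node.florealm_id!r}"
                    )
        if len(seen) < 2:
            raise FormatError("a dated tree needs at least 2 tips")
        self._annotate_depths()

    def _annotate_depths(self) -> None:
        root = self._tree.seed_node
        root.florealm_depth = 0.0
        for node in self._tree.preorder_node_iter():
            if node is not root:
                node.florealm_depth = (
                    node.parent_node.florealm_depth + node.edge.length
                )
        height = max(
            leaf.florealm_depth for leaf in self._tree.leaf_node_iter()
        )
        self._crown_age = float(height)
        for node in self._tree.preorder_node_iter():
            # age = time before present; leaves are pinned to the present
            node.florealm_age = (
                0.0 if node.is_leaf() else float(height - node.florealm_depth)
            )

    # -- basic accessors ---------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def crown_age(self) -> float:
        """Maximum root-to-tip distance, in Ma."""
        return self._crown_age

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in lexicographic order."""
        return sorted(
            leaf.taxon.label for leaf in self._tree.leaf_node_iter()
        )

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def node_age(self, node) -> float:
        return node.florealm_age

    def internal_nodes(self) -> Iterator:
        """Internal nodes in preorder (root first)."""
        for node in self._tree.preorder_node_iter():
            if not node.is_leaf():
                yield node

    def find_node(self, node_id: str):
        for node in self._tree.preorder_node_iter():
            if node.florealm_id == node_id:
                return node
        raise KeyError(f"no node with id {node_id!r}")

    def clade_tip_labels(self, node) -> list[str]:
        return sorted(leaf.taxon.label for leaf in node.leaf_iter())

    # -- transforms --------------------------------------------------------

    def scaled(self, factor: float) -> "DatedTree":
        """A copy with every branch length multiplied by ``factor``."""
        clone = self._tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return DatedTree(clone)

    def branch_incidence(
        self, genus_index: dict[str, int]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Branch lengths and tip-descendancy indicators for branch-based beta.

        Returns ``(lengths, desc)`` where ``lengths`` has one entry per
        non-root branch and ``desc[e, j]`` is True iff genus ``j`` (column
        index per ``genus_index``) descends from branch ``e``. The root
        carries no stem branch and is excluded. Genera absent from
        ``genus_index`` are ignored.
        """
        lengths: list[float] = []
        rows: list[np.ndarray] = []
        n_gen = len(genus_index)
        root = self._tree.seed_node
        # postorder so each node's tip set is the union of its children's
        tipset: dict[int, np.ndarray] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                vec = np.zeros(n_gen, dtype=bool)
                col = genus_index.get(node.taxon.label)
                if col is not None:
                    vec[col] = True
            else:
                vec = np.zeros(n_gen, dtype=bool)
                for child in node.child_nodes():
                    vec |= tipset[id(child)]
            tipset[id(node)] = vec
            if node is not root:
                lengths.append(node.edge.length)
                rows.append(vec)
        return np.asarray(lengths, dtype=float), np.vstack(rows)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True
        ).strip() + "\n"

    def __repr__(self) -> str:  # pragma: no cover
        return f"DatedTree(n_tips={self.n_tips}, crown_age={self.crown_age:.4g})"


def read_tree(path) -> DatedTree:
    """Read a dated newick tree; reject duplicate tips and missing lengths."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise FormatError(f"empty tree file: {path}")
    return DatedTree.from_newick(text)


def write_tree(tree: DatedTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick())
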