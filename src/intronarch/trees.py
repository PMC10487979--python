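"""Rooted species tree wrapper.

Thin layer over dendropy providing the guarantees the reconstruction code
relies on: a genuinely rooted (bifurcating-root) tree, unique labels on
every node, and stable parent/child lookups by label.
"""

from __future__ import annotations

import dendropy

from .models import ValidationError


class SpeciesTree:
    """A rooted tree with uniquely labeled leaves and internal nodes."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        root = tree.seed_node
        if len(root.child_nodes()) != 2:
            raise ValidationError(
                "tree root is not bifurcating; supply a rooted tree "
                "(e.g. root it on an outgroup before running)"
            )
        self._autolabel()
        self._by_label: dict[str, dendropy.Node] = {}
        for node in tree.preorder_node_iter():
            lab = self.label(node)
            if lab in self._by_label:
                raise ValidationError(f"duplicate node label {lab!r}")
            self._by_label[lab] = node

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
            preserve_underscores=True,
        )
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @classmethod
    def balanced(cls, n_leaves: int, prefix: str = "t") -> "SpeciesTree":
        """Nearly balanced binary tree with leaves ``t1..tn`` (any n >= 2)."""
        if n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        labels = [f"{prefix}{i + 1}" for i in range(n_leaves)]

        def build(labs):
            if len(labs) == 1:
                return labs[0]
            h = len(labs) // 2
            return f"({build(labs[:h])},{build(labs[h:])})"

        return cls.from_newick(build(labels) + ";")

    def _autolabel(self) -> None:
        # deterministic post-order labels for unlabeled internal nodes
        i = 0
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                continue
            if not node.label:
                node.label = f"N{i}"
            i += 1

    # -- accessors -----------------------------------------------------

    @staticmethod
    def label(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label if node.taxon else node.label
        return node.label

    @property
    def root_label(self) -> str:
        return self.label(self._tree.seed_node)

    @property
    def leaf_labels(self) -> list[str]:
        return [self.label(n) for n in self._tree.leaf_node_iter()]

    def node(self, label: str) -> dendropy.Node:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"no node labeled {label!r} in tree") from None

    def parent_label(self, label: str) -> str | None:
        p = self.node(label).parent_node
        return self.label(p) if p is not None else None

    def children_labels(self, label: str) -> list[str]:
        return [self.label(c) for c in self.node(label).child_nodes()]

    def postorder_labels(self) -> list[str]:
        return [self.label(n) for n in self._tree.postorder_node_iter()]

    def preorder_labels(self) -> list[str]:
        return [self.label(n) for n in self._tree.preorder_node_iter()]

    def branch_labels(self) -> list[str]:
        """Labels of all non-root nodes; a branch is named by its child node."""
        return [lab for lab in self.preorder_labels() if lab != self.root_label]

    def mrca_label(self, leaf_labels) -> str:
        leaf_labels = list(leaf_labels)
        if len(leaf_labels) == 1:
            return leaf_labels[0]
        node = self._tree.mrca(taxon_labels=leaf_labels)
        return self.label(node)

    def leaves_under(self, label: str) -> list[str]:
        return [self.label(n) for n in self.node(label).leaf_iter()]

    def is_leaf(self, label: str) -> bool:
        return self.node(label).is_leaf()

    def to_newick(self, node_comments: dict[str, str] | None = None) -> str:
        """Newick string; optional per-node bracket comments (e.g. intron counts)."""
        def render(node) -> str:
            lab = self.label(node)
            comment = f"[{node_comments[lab]}]" if node_comments and lab in node_comments else ""
            if node.is_leaf():
                return f"{lab}{comment}"
            inner = ",".join(render(c) for c in node.child_nodes())
            return f"({inner}){lab}{comment}"

        return render(self._tree.seed_node) + ";"
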