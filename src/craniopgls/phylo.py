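"""Phylogenies for comparative analysis.

A rooted tree with branch lengths implies, under Brownian motion, an
expected trait covariance between any two tips equal to the summed branch
length they share on the path from the root to their most recent common
ancestor.  This module reads and prunes Newick trees, builds that N x N
covariance matrix C, and provides its (pseudo-)inverse square root, the
transform that whitens phylogenetic correlation in GLS-type models.

Newick dialect is deliberately strict: every non-root edge must carry a
branch length, and quoted labels / bracket comments are rejected rather
than silently interpreted, because silently mangled taxon names corrupt
comparative datasets.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np


class NewickError(ValueError):
    """Raised for malformed or unsupported Newick input."""


def _validate_newick_text(text: str) -> None:
    if "'" in text or '"' in text:
        pos = min(i for i in (text.find("'"), text.find('"')) if i >= 0)
        raise NewickError(
            f"quoted labels are not supported (quote at character {pos})"
        )
    if "[" in text:
        raise NewickError(
            f"Newick comments are not supported (bracket at character {text.find('[')})"
        )


class PhyloTree:
    """A rooted phylogeny with branch lengths on every non-root edge.

    Tip order is canonical: the order in which taxa appear in the Newick
    string.  All downstream matrices and tables are re-indexed to it.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(tips) < 2:
            raise NewickError("a phylogeny needs at least 2 tips")
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise NewickError(f"duplicate tip labels: {dup}")
        self.tips: list[str] = tips
        self._validate_lengths()

    def _validate_lengths(self) -> None:
        zero_terminals = []
        for edge in self._tree.preorder_edge_iter():
            node = edge.head_node
            if node is self._tree.seed_node:
                continue  # the root has no subtending edge in our model
            if edge.length is None:
                where = (
                    f"tip '{node.taxon.label}'" if node.is_leaf() else "an internal edge"
                )
                raise NewickError(f"missing branch length on {where}")
            if edge.length < 0:
                raise NewickError(f"negative branch length {edge.length}")
            if node.is_leaf() and edge.length == 0:
                zero_terminals.append(node.taxon.label)
        if zero_terminals:
            warnings.warn(
                "zero-length terminal branches on "
                f"{zero_terminals}: the Brownian covariance matrix will be "
                "singular; the inverse-square-root tolerance handles this",
                stacklevel=3,
            )

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a Newick string (strict dialect, branch lengths required)."""
        _validate_newick_text(text)
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy error classes carry line/col
            line = getattr(exc, "line_num", None)
            col = getattr(exc, "col_num", None)
            loc = f" (line {line}, column {col})" if col is not None else ""
            raise NewickError(f"malformed Newick{loc}: {exc}") from exc
        # the root edge length, if any, carries no comparative information
        tree.seed_node.edge.length = None
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path, encoding="utf-8") as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        """Newick string with >= 10 significant digits on branch lengths."""
        out = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".12g",
        )
        return out.strip() + "\n"

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick())

    # -- topology operations ------------------------------------------

    def prune_to_taxa(self, keep) -> "PhyloTree":
        """Restrict the tree to `keep`, preserving all pairwise path lengths.

        Degree-2 nodes created by pruning are collapsed by summing the two
        incident edge lengths, so root-to-tip distances and shared path
        lengths among surviving taxa are unchanged.
        """
        keep = list(dict.fromkeys(keep))
        missing = [k for k in keep if k not in self.tips]
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
        if len(keep) < 2:
            raise ValueError("prune requires at least 2 taxa to keep")
        sub = self._tree.extract_tree_with_taxa_labels(
            keep, suppress_unifurcations=True
        )
        sub.seed_node.edge.length = None
        return PhyloTree(sub)

    def root_to_tip_depths(self) -> dict[str, float]:
        depths = {}
        for leaf in self._tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node is not self._tree.seed_node:
                d += node.edge.length
                node = node.parent_node
            depths[leaf.taxon.label] = d
        return depths

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        d = np.array(list(self.root_to_tip_depths().values()))
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1.0))

    def scale_to_unit_height(self) -> "PhyloTree":
        """Rescale all branch lengths so the maximum root-to-tip depth is 1."""
        h = max(self.root_to_tip_depths().values())
        if h <= 0:
            raise ValueError("tree has zero height")
        clone = self._tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length / h
        return PhyloTree(clone)

    # -- Brownian-motion covariance ------------------------------------

    def vcv(self) -> "PhyloCovariance":
        """Expected tip covariance matrix under Brownian motion.

        C[i, j] is the root-to-MRCA path length of tips i and j; the
        diagonal holds each tip's root-to-tip depth.  Computed in one
        preorder pass: each internal node at depth d contributes d as the
        covariance of every tip pair split between its child subtrees.
        """
        n = len(self.tips)
        idx = {t: i for i, t in enumerate(self.tips)}
        C = np.zeros((n, n))
        depth = {self._tree.seed_node: 0.0}
        leafsets: dict = {}
        for node in self._tree.preorder_node_iter():
            if node is not self._tree.seed_node:
                depth[node] = depth[node.parent_node] + node.edge.length
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = idx[node.taxon.label]
                C[i, i] = depth[node]
                leafsets[node] = [i]
            else:
                children = [leafsets.pop(c) for c in node.child_nodes()]
                d = depth[node]
                for a in range(len(children)):
                    for b in range(a + 1, len(children)):
                        for i in children[a]:
                            for j in children[b]:
                                C[i, j] = C[j, i] = d
                leafsets[node] = [i for ch in children for i in ch]
        return PhyloCovariance(taxa=list(self.tips), matrix=C)

    def __repr__(self) -> str:
        return f"PhyloTree({len(self.tips)} tips)"


@dataclass
class PhyloCovariance:
    """N x N Brownian-motion trait covariance implied by a tree."""

    taxa: list[str]
    matrix: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        C = np.asarray(self.matrix, dtype=float)
        if C.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("covariance matrix must be symmetric")
        self.matrix = C

    @property
    def n(self) -> int:
        return len(self.taxa)

    def reindex(self, taxa) -> "PhyloCovariance":
        """Submatrix / reorder for the given taxa (exact path-length entries)."""
        missing = [t for t in taxa if t not in self.taxa]
        if missing:
            raise KeyError(f"taxa not in covariance: {missing}")
        pos = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(list(taxa), self.matrix[np.ix_(pos, pos)])

    def inv_sqrt(self, tol: float | None = None) -> np.ndarray:
        """Symmetric P with P @ C @ P = I on the span of eigenvalues > tol.

        Eigendecomposition-based; eigenvalues below tol (default
        1e-10 * largest) are excluded (pseudo-inverse behaviour), so
        singular C from zero-length branches is handled gracefully.
        """
        key = ("P", tol)
        if key not in self._cache:
            w, V = np.linalg.eigh(self.matrix)
            cut = (1e-10 * w.max()) if tol is None else tol
            if np.any(w < -cut):
                raise ValueError("matrix not PSD")
            inv_root = np.where(w > cut, 1.0 / np.sqrt(np.clip(w, cut, None)), 0.0)
            self._cache[key] = (V * inv_root) @ V.T
        return self._cache[key]


def parse_newick(text: str) -> PhyloTree:
    """Functional alias for :meth:`PhyloTree.from_newick`."""
    return PhyloTree.from_newick(text)


def vcv_from_tree(tree: PhyloTree) -> PhyloCovariance:
    """Functional alias for :meth:`PhyloTree.vcv`."""
    return tree.vcv()
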