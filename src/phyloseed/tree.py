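"""Time-calibrated phylogenetic trees (chronograms) and phylogenetic covariance.

A :class:`Chronogram` is a rooted, ultrametric tree whose branch lengths are
durations in millions of years (Mya).  Node *ages* are depths measured from the
tips (tips at age 0, the root at the root age).  It is the backbone shared by
every downstream analysis: trait-model fitting, ancestral-state estimation,
ancestral range estimation and the threshold regression.

Newick parsing and writing are delegated to dendropy; this module adds the
chronogram-specific invariants (ultrametricity, unique tip labels, non-negative
edge lengths), derived quantities (node ages, the Brownian-motion covariance
matrix of shared path lengths) and species-level pruning.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "PhyloCovariance",
    "TreeError",
    "parse_newick",
    "write_newick",
    "phylo_covariance",
    "prune_to_species",
]


class TreeError(ValueError):
    """Raised for malformed or invalid chronogram input."""


#: relative tolerance (times root age) for the ultrametricity check
ULTRAMETRIC_RTOL = 1e-6


@dataclass(frozen=True)
class PhyloCovariance:
    """Brownian-motion covariance structure of a chronogram.

    ``matrix[i, j]`` is the shared path length (Mya) from the root to the most
    recent common ancestor of taxa ``i`` and ``j``; the diagonal holds each
    tip's root-to-tip depth.  For an ultrametric tree the diagonal is constant
    and equal to the root age, and the matrix is positive semi-definite.
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise TreeError("covariance matrix shape does not match taxa")
        object.__setattr__(self, "matrix", m)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=list(self.taxa), columns=list(self.taxa))


class Chronogram:
    """Rooted ultrametric tree with branch lengths in Mya.

    Parameters
    ----------
    tree:
        A rooted dendropy tree with branch lengths.  The tree is deep-copied;
        the chronogram is immutable afterwards.
    resolve_polytomies:
        Resolve multifurcations into an arbitrary binary shape using
        zero-length internal edges.  All likelihoods computed by this package
        are invariant to the resolution chosen.  Default True.
    force_ultrametric:
        If the input fails the ultrametricity check, adjust each terminal edge
        so every tip sits exactly at age 0 instead of rejecting the tree.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        *,
        resolve_polytomies: bool = True,
        force_ultrametric: bool = False,
    ) -> None:
        tree = tree.clone(depth=1)
        tree.is_rooted = True
        if resolve_polytomies:
            _resolve_polytomies(tree)
        self._validate_and_index(tree, force_ultrametric)

    # ------------------------------------------------------------------ #
    # construction
    # ------------------------------------------------------------------ #
    @classmethod
    def from_newick(
        cls,
        text: str,
        *,
        resolve_polytomies: bool = True,
        force_ultrametric: bool = False,
    ) -> "Chronogram":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                rooting="force-rooted",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy reports line/column in the message
            raise TreeError(f"malformed Newick: {exc}") from exc
        return cls(
            tree,
            resolve_polytomies=resolve_polytomies,
            force_ultrametric=force_ultrametric,
        )

    @classmethod
    def from_file(cls, path, **kwargs) -> "Chronogram":
        with open(path) as fh:
            return cls.from_newick(fh.read(), **kwargs)

    def _validate_and_index(self, tree: dendropy.Tree, force_ultrametric: bool) -> None:
        root = tree.seed_node
        if root.edge.length is None:
            root.edge.length = 0.0
        for nd in tree.preorder_node_iter():
            if nd is root:
                continue
            if nd.edge.length is None:
                raise TreeError("every non-root edge must carry a branch length")
            if nd.edge.length < 0:
                raise TreeError(f"negative edge length {nd.edge.length!r}")
        labels = [
            (lf.taxon.label if lf.taxon is not None else lf.label)
            for lf in tree.leaf_node_iter()
        ]
        if any(lbl is None for lbl in labels):
            raise TreeError("every tip must be labelled")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")

        # depths from root, then ages from tips
        depth = {root: 0.0}
        for nd in tree.preorder_node_iter():
            if nd is root:
                continue
            depth[nd] = depth[nd.parent_node] + nd.edge.length
        tip_depths = np.array([depth[lf] for lf in tree.leaf_node_iter()])
        root_age = float(tip_depths.max())
        tol = ULTRAMETRIC_RTOL * max(root_age, 1.0)
        if np.ptp(tip_depths) > tol:
            if not force_ultrametric:
                raise TreeError(
                    "tree is not ultrametric (tip depth spread "
                    f"{np.ptp(tip_depths):.3g} exceeds tolerance {tol:.3g}); "
                    "pass force_ultrametric=True to smooth terminal edges"
                )
            for lf in tree.leaf_node_iter():
                lf.edge.length += root_age - depth[lf]
                depth[lf] = root_age

        self._tree = tree
        # postorder index: tips first in leaf iteration order is NOT guaranteed,
        # so build explicit arrays.
        self._nodes: list[dendropy.Node] = list(tree.postorder_node_iter())
        self._index = {nd: i for i, nd in enumerate(self._nodes)}
        n = len(self._nodes)
        self._parent = np.full(n, -1, dtype=int)
        self._edge_length = np.zeros(n)
        self._age = np.zeros(n)
        for nd, i in self._index.items():
            if nd.parent_node is not None:
                self._parent[i] = self._index[nd.parent_node]
                self._edge_length[i] = float(nd.edge.length)
            self._age[i] = root_age - depth[nd]
        self._tip_ids = np.array(
            [self._index[lf] for lf in tree.leaf_node_iter()], dtype=int
        )
        self._tip_labels = tuple(
            (lf.taxon.label if lf.taxon is not None else lf.label)
            for lf in tree.leaf_node_iter()
        )
        self._root_age = root_age

    # ------------------------------------------------------------------ #
    # basic queries
    # ------------------------------------------------------------------ #
    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def root_age(self) -> float:
        """Age of the root in Mya (tips are at age 0)."""
        return self._root_age

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    def postorder(self) -> Sequence[int]:
        """Node ids in postorder (children before parents; root last)."""
        return range(len(self._nodes))

    def parent(self, node_id: int) -> int:
        return int(self._parent[node_id])

    def children(self, node_id: int) -> list[int]:
        return [self._index[c] for c in self._nodes[node_id].child_nodes()]

    def is_tip(self, node_id: int) -> bool:
        return self._nodes[node_id].is_leaf()

    def node_age(self, node_id: int) -> float:
        return float(self._age[node_id])

    @property
    def ages(self) -> np.ndarray:
        return self._age.copy()

    @property
    def edge_lengths(self) -> np.ndarray:
        """Edge length above each node (0 for the root), indexed by node id."""
        return self._edge_length.copy()

    @property
    def tip_ids(self) -> np.ndarray:
        """Node ids of the tips, in ``tip_labels`` order."""
        return self._tip_ids.copy()

    def node_label(self, node_id: int) -> str | None:
        nd = self._nodes[node_id]
        if nd.is_leaf():
            return nd.taxon.label if nd.taxon is not None else nd.label
        return nd.label

    def mrca_age(self, a: str, b: str) -> float:
        """Age (Mya) of the most recent common ancestor of two tips."""
        ids = {lbl: i for lbl, i in zip(self._tip_labels, self._tip_ids)}
        for t in (a, b):
            if t not in ids:
                raise TreeError(f"unknown taxon {t!r}")
        if a == b:
            return 0.0
        anc_a = set()
        i = ids[a]
        while i != -1:
            anc_a.add(i)
            i = self._parent[i]
        i = ids[b]
        while i not in anc_a:
            i = self._parent[i]
        return float(self._age[i])

    # ------------------------------------------------------------------ #
    # output
    # ------------------------------------------------------------------ #
    def to_newick(self) -> str:
        """Newick string with branch lengths (durations, Mya)."""
        buf = _io.StringIO()

        def rec(nd: dendropy.Node) -> None:
            if nd.is_leaf():
                buf.write(_quote(nd.taxon.label if nd.taxon else nd.label))
            else:
                buf.write("(")
                for k, ch in enumerate(nd.child_nodes()):
                    if k:
                        buf.write(",")
                    rec(ch)
                buf.write(")")
                if nd.label:
                    buf.write(_quote(nd.label))
            if nd.parent_node is not None:
                buf.write(f":{nd.edge.length:.12g}")

        rec(self._tree.seed_node)
        buf.write(";")
        return buf.getvalue()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Chronogram n_tips={self.n_tips} root_age={self.root_age:.4g} Mya>"

    # ------------------------------------------------------------------ #
    # derived structures
    # ------------------------------------------------------------------ #
    def covariance(self, taxa: Iterable[str] | None = None) -> PhyloCovariance:
        """Shared-path-length (BM) covariance for ``taxa`` (default: all tips)."""
        taxa = tuple(taxa) if taxa is not None else self._tip_labels
        known = set(self._tip_labels)
        missing = [t for t in taxa if t not in known]
        if missing:
            raise TreeError(f"unknown taxa: {missing}")
        pos = {t: k for k, t in enumerate(taxa)}
        n = len(taxa)
        mat = np.zeros((n, n))
        # tips below each node, accumulated in postorder
        below: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in self.postorder():
            nd = self._nodes[i]
            if nd.is_leaf():
                lbl = nd.taxon.label if nd.taxon else nd.label
                if lbl in pos:
                    below[i] = [pos[lbl]]
                    # root-to-tip depth; equals the root age for ultrametric trees
                    mat[pos[lbl], pos[lbl]] = self._root_age - self._age[i]
            else:
                shared = self._root_age - self._age[i]
                kids = [below[self._index[c]] for c in nd.child_nodes()]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for x in kids[a]:
                            for y in kids[b]:
                                mat[x, y] = mat[y, x] = shared
                below[i] = [x for k in kids for x in k]
        return PhyloCovariance(taxa=taxa, matrix=mat)

    def prune_to_species(
        self, keep: Mapping[str, str], *, force: bool = False
    ) -> "Chronogram":
        """Prune to one designated accession per species and relabel.

        ``keep`` maps retained accession (tip) labels to species names; all
        other tips are dropped.  Traversed edges are summed, so the result is
        still ultrametric with the same root age.  This also serves as the
        relabel map for placeholder tips.
        """
        if not keep:
            raise TreeError("empty accession->species mapping")
        present = set(self._tip_labels)
        missing = [a for a in keep if a not in present]
        if missing:
            raise TreeError(f"accessions not in tree: {missing}")
        species = list(keep.values())
        if len(set(species)) != len(species):
            dup = sorted({s for s in species if species.count(s) > 1})
            raise TreeError(f"species kept by more than one accession: {dup}")
        t = self._tree.clone(depth=1)
        t.retain_taxa_with_labels(list(keep))
        for lf in t.leaf_node_iter():
            lf.taxon.label = keep[lf.taxon.label]
        return Chronogram(t, resolve_polytomies=False, force_ultrametric=force)


def _quote(label: str) -> str:
    if any(c in label for c in " ():,;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _resolve_polytomies(tree: dendropy.Tree) -> None:
    """Binarize multifurcations with zero-length internal edges (deterministic:
    successive pairing of the first two children)."""
    for nd in list(tree.preorder_node_iter()):
        while len(nd.child_nodes()) > 2:
            kids = nd.child_nodes()
            a, b = kids[0], kids[1]
            nd.remove_child(a)
            nd.remove_child(b)
            new = dendropy.Node(edge_length=0.0)
            new.add_child(a)
            new.add_child(b)
            nd.insert_child(0, new)


# ---------------------------------------------------------------------- #
# functional surface
# ---------------------------------------------------------------------- #
def parse_newick(text: str, **kwargs) -> Chronogram:
    return Chronogram.from_newick(text, **kwargs)


def write_newick(tree: Chronogram) -> str:
    return tree.to_newick()


def phylo_covariance(tree: Chronogram, taxa: Iterable[str] | None = None) -> PhyloCovariance:
    return tree.covariance(taxa)


def prune_to_species(tree: Chronogram, keep: Mapping[str, str]) -> Chronogram:
    return tree.prune_to_species(keep)
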