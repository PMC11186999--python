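"""Phylogenies and phylogenetic covariance matrices.

Rooted, branch-length trees (Newick; TimeTree-style, branch lengths in Myr) are
parsed and pruned with :mod:`dendropy` behind a thin validating wrapper. The
phylogenetic covariance matrix V has V[i, i] equal to the root-to-tip path
length of species i and V[i, j] equal to the depth of the most recent common
ancestor of i and j; Pagel's lambda rescales the off-diagonal entries only.
Species are always ordered lexicographically so matrices are reproducible.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import InsufficientOverlapError, NewickParseError

logger = logging.getLogger("karyomorph.phylo")

_WS = re.compile(r"[\s_]+")


def normalize_name(name: str) -> str:
    """Canonical species label: underscores -> spaces, whitespace collapsed."""
    return _WS.sub(" ", name.strip())


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths and unique, normalized tip labels."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) < 2:
            raise NewickParseError("tree must have at least 2 tips")
        seen: set[str] = set()
        for lab in labels:
            if lab in seen:
                raise NewickParseError(f"duplicate tip label: {lab!r}")
            seen.add(lab)
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue  # a root ("stem") edge may legitimately lack a length
            if edge.length is None:
                node = edge.head_node
                token = node.taxon.label if node.taxon else "internal node"
                raise NewickParseError(f"missing branch length on edge to {token!r}")
            if edge.length < 0:
                raise NewickParseError(f"negative branch length: {edge.length}")

    @property
    def tip_labels(self) -> list[str]:
        return [normalize_name(leaf.taxon.label) for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        out: dict[str, float] = {}
        for node in self.tree.preorder_node_iter():
            parent_depth = 0.0 if node.parent_node is None else node.parent_node._km_depth
            node._km_depth = parent_depth + (node.edge.length or 0.0)
            if node.is_leaf():
                out[normalize_name(node.taxon.label)] = node._km_depth
        return out

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = np.array(list(self.depths().values()))
        span = d.max() - d.min()
        return bool(span <= rel_tol * max(d.max(), 1.0))

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class PhyloCovariance:
    """Species-ordered phylogenetic covariance matrix.

    ``matrix[i, j]`` is the shared root-to-MRCA path length of species i and j
    (the diagonal holds root-to-tip depths). ``lambda_applied`` records whether
    a Pagel's-lambda transform has been applied (``None`` = untransformed).
    """

    matrix: np.ndarray
    species: list[str]
    lambda_applied: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.species)
        if self.matrix.shape != (n, n):
            raise ValueError("covariance matrix shape does not match species list")

    @property
    def n(self) -> int:
        return len(self.species)

    def reorder(self, species: Sequence[str]) -> "PhyloCovariance":
        """Row/column selection of V for a subset (or reordering) of species."""
        idx = [self.species.index(normalize_name(s)) for s in species]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)],
                               [self.species[i] for i in idx],
                               self.lambda_applied)


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted Newick statement with branch lengths.

    Underscores in unquoted labels follow the Newick convention and become
    spaces; square-bracket comments are ignored; polytomies are preserved.
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several unrelated classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def read_newick(path: str) -> Phylogeny:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def prune_to(phy: Phylogeny, species: Iterable[str]) -> tuple[Phylogeny, list[str]]:
    """Prune the tree to the given species, preserving tip-to-tip path lengths.

    Returns the pruned tree and the (sorted) list of requested species absent
    from the tree. Raises if fewer than two requested species are present.
    """
    wanted = {normalize_name(s) for s in species}
    present = set(phy.tip_labels)
    keep = sorted(wanted & present)
    dropped = sorted(wanted - present)
    for name in dropped:
        logger.warning("species %r not found in tree; dropped", name)
    if len(keep) < 2:
        raise InsufficientOverlapError(
            f"only {len(keep)} of {len(wanted)} species found in tree; need >= 2")
    taxa = [leaf.taxon for leaf in phy.tree.leaf_node_iter()
            if normalize_name(leaf.taxon.label) in keep]
    sub = phy.tree.extract_tree_with_taxa(taxa=taxa)
    return Phylogeny(sub), dropped


def vcv(phy: Phylogeny) -> PhyloCovariance:
    """Phylogenetic covariance matrix of a tree, species sorted lexicographically.

    Computed in one postorder pass: each internal node of depth d contributes d
    as the covariance of every tip pair split between two of its child subtrees.
    """
    species = sorted(phy.tip_labels)
    index = {name: i for i, name in enumerate(species)}
    n = len(species)
    V = np.zeros((n, n))

    depth: dict[int, float] = {}
    below: dict[int, list[int]] = {}
    for node in phy.tree.preorder_node_iter():
        parent = node.parent_node
        depth[id(node)] = (depth[id(parent)] if parent is not None else 0.0) + \
            (node.edge.length or 0.0)
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            i = index[normalize_name(node.taxon.label)]
            V[i, i] = depth[id(node)]
            below[id(node)] = [i]
        else:
            kids = [below[id(c)] for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            V[i, j] = V[j, i] = d
            below[id(node)] = [i for k in kids for i in k]

    if not phy.is_ultrametric():
        logger.warning("tree is not ultrametric; tip depths vary")
    return PhyloCovariance(V, species)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda: multiply off-diagonal entries by lam, diagonal unchanged.

    lam = 0 removes all phylogenetic covariance; lam = 1 is full Brownian
    structure. Values outside [0, 1] are a domain error.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    V = cov.matrix * lam
    np.fill_diagonal(V, np.diag(cov.matrix))
    return PhyloCovariance(V, list(cov.species), lambda_applied=lam)
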