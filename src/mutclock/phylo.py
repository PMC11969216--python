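"""Phylogeny handling: Newick I/O, pruning, and the Brownian-motion
expected trait covariance matrix.

Trees are represented as :class:`dendropy.Tree` objects throughout.  The
covariance construction follows the standard Brownian expectation for a
trait evolving on a rooted tree with branch lengths in time units: the
covariance of tip *i* and tip *j* equals the root-to-MRCA path length, and
the variance of tip *i* equals its root-to-tip distance.

Convention for the root edge: if the seed node carries an edge length
(which happens when a pruned tree retains the stem lineage of the kept
clade), that length counts toward every tip depth and toward every
pairwise covariance.  This makes pruning commute exactly with taking a
submatrix of the covariance matrix.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "parse_newick",
    "read_newick",
    "write_newick",
    "leaf_names",
    "prune_to",
    "brownian_vcv",
    "is_ultrametric",
    "PhyloCovariance",
]


@dataclass(frozen=True)
class PhyloCovariance:
    """Brownian expected covariance among tips.

    matrix
        (n, n) symmetric matrix; entry (i, j) is the shared root-to-MRCA
        path length of species i and j, in the tree's time units.
    species_order
        Tip labels in the row/column order of ``matrix``.
    """

    matrix: np.ndarray
    species_order: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def submatrix(self, names: list[str]) -> "PhyloCovariance":
        idx = [self.species_order.index(nm) for nm in names]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], tuple(names))


_COMMENT_RE = re.compile(r"\[[^\]]*\]")


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree.

    Square-bracket comments are stripped.  Quoted and underscore labels are
    preserved literally.  Edges without a length (other than the root edge)
    are rejected; a missing root-edge length is treated as 0.
    """
    stripped = _COMMENT_RE.sub("", text).strip()
    if not stripped.endswith(";"):
        raise ValidationError(
            f"Newick parse error: missing terminating ';' (near offset {len(stripped)})"
        )
    depth = 0
    for off, ch in enumerate(stripped):
        depth += {"(": 1, ")": -1}.get(ch, 0)
        if depth < 0:
            raise ValidationError(f"Newick parse error: unbalanced ')' at offset {off}")
    if depth != 0:
        raise ValidationError(
            f"Newick parse error: {depth} unclosed '(' at offset {len(stripped)}"
        )
    try:
        tree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"Newick parse error: {exc}") from None
    _validate_tree(tree)
    return tree


def _validate_tree(tree: dendropy.Tree) -> None:
    labels = leaf_names(tree)
    seen: set[str] = set()
    dupes = sorted({lb for lb in labels if lb in seen or seen.add(lb)})
    if dupes:
        raise ValidationError(f"duplicate leaf labels: {dupes}")
    if tree.seed_node.edge.length is None:
        tree.seed_node.edge.length = 0.0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            who = node.taxon.label if node.taxon else "an internal node"
            raise ValidationError(f"missing branch length on edge above {who}")
        if node.edge.length < 0:
            raise ValidationError("negative branch length in tree")


def read_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
        )


def leaf_names(tree: dendropy.Tree) -> list[str]:
    """Tip labels in tree traversal order (the canonical species order)."""
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def prune_to(tree: dendropy.Tree, keep) -> dendropy.Tree:
    """Return a copy of ``tree`` restricted to the tips in ``keep``.

    Unary internal nodes created by the pruning are collapsed with their
    branch lengths summed; if the retained clade hangs below the original
    root, the shared stem is kept as a root-edge length so that tip depths
    (and hence Brownian covariances) are unchanged.
    """
    keep = set(keep)
    present = set(leaf_names(tree))
    missing = sorted(keep - present)
    if missing:
        raise ValidationError(f"names not present in tree: {missing}")
    if len(keep) < 2:
        raise ValidationError("pruning requires at least 2 tips to keep")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(keep))
    if pruned.seed_node.edge.length is None:
        pruned.seed_node.edge.length = 0.0
    return pruned


def _leaf_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    root = tree.seed_node
    depths[root] = root.edge.length or 0.0
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def brownian_vcv(tree: dendropy.Tree) -> PhyloCovariance:
    """Brownian expected covariance matrix of the tree's tips.

    Entry (i, j) is the depth of MRCA(i, j) from the origin of the root
    edge; the diagonal holds root-to-tip distances.  Polytomies are handled
    directly (the matrix is well defined on any rooted topology).
    """
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValidationError("covariance requires at least 2 tips")
    names = [lf.taxon.label for lf in leaves]
    index = {lf: i for i, lf in enumerate(leaves)}
    depths = _leaf_depths(tree)
    n = len(leaves)
    C = np.zeros((n, n))
    # postorder sweep: at each internal node, leaf pairs whose paths first
    # meet there lie in different child subtrees
    subtree_leaves: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node]
            C[i, i] = depths[node]
            subtree_leaves[node] = [i]
            continue
        blocks = [subtree_leaves.pop(ch) for ch in node.child_nodes()]
        d = depths[node]
        for a in range(len(blocks)):
            for b in range(a + 1, len(blocks)):
                for i in blocks[a]:
                    for j in blocks[b]:
                        C[i, j] = C[j, i] = d
        subtree_leaves[node] = [i for blk in blocks for i in blk]
    if any(depths[lf] == 0 for lf in leaves):
        log.warning("tree has zero-length root-to-tip path(s); covariance may be singular")
    return PhyloCovariance(C, tuple(names))


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    """True if all root-to-tip distances agree to within ``rel_tol`` (relative)."""
    depths = _leaf_depths(tree)
    tip_depths = [depths[lf] for lf in tree.leaf_node_iter()]
    if len(tip_depths) < 2:
        raise ValidationError("ultrametricity is undefined for < 2 tips")
    dmax = max(tip_depths)
    if dmax == 0:
        return True
    return (dmax - min(tip_depths)) <= rel_tol * dmax
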