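"""Phylogeny I/O and tree-derived matrices.

Parses rooted Newick trees with branch lengths and turns them into the two
matrix objects every comparative statistic downstream consumes:

* the phylogenetic covariance ``C`` (shared root-to-MRCA path lengths, the
  trait covariance under Brownian motion up to a rate constant), and
* the patristic distance matrix ``D`` (tip-to-tip path lengths).

All matrices are aligned to a single canonical taxon ordering: tip labels
sorted lexicographically.  Polytomies are handled natively; no random
resolution is ever performed.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Tree",
    "PhyloCovariance",
    "PatristicDistances",
    "NewickError",
    "parse_newick",
    "phylo_covariance",
    "patristic_distances",
    "prune_to",
    "check_ultrametric",
]


class NewickError(ValueError):
    """Raised for malformed Newick input (syntax, duplicates, bad lengths)."""


@dataclass
class Tree:
    """A rooted phylogeny with branch lengths.

    Thin wrapper around a :class:`dendropy.Tree` that enforces the
    invariants the statistics need: nonnegative branch lengths, unique tip
    labels, a single root.  ``taxa`` is the canonical (sorted) tip ordering
    used by every matrix and vector in the package.
    """

    _dtree: dendropy.Tree
    taxa: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self._dtree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate tip labels: {dupes}")
        for edge in self._dtree.preorder_edge_iter():
            if edge.head_node is self._dtree.seed_node:
                continue
            if edge.length is None:
                raise NewickError(
                    f"missing branch length above node {edge.head_node!r}"
                )
            if edge.length < 0:
                raise NewickError(
                    f"negative branch length {edge.length} above "
                    f"{_node_name(edge.head_node)}"
                )
            if edge.length == 0 and edge.head_node.is_leaf():
                warnings.warn(
                    f"zero-length terminal branch at {_node_name(edge.head_node)}; "
                    "duplicate rows make the phylogenetic covariance singular",
                    stacklevel=3,
                )
        self.taxa = tuple(sorted(labels))

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    def write_newick(self) -> str:
        s = self._dtree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def copy(self) -> "Tree":
        return Tree(self._dtree.clone(depth=1))

    # -- internal helpers ---------------------------------------------------

    def _root_to_node_depths(self) -> dict:
        depths = {self._dtree.seed_node: 0.0}
        for node in self._dtree.preorder_node_iter():
            if node is self._dtree.seed_node:
                continue
            depths[node] = depths[node.parent_node] + node.edge.length
        return depths


def _node_name(node) -> str:
    if node.taxon is not None:
        return f"tip '{node.taxon.label}'"
    return f"internal node '{node.label or '<unnamed>'}'"


@dataclass(frozen=True)
class PhyloCovariance:
    """Shared-path-length matrix C: C_ij = root-to-MRCA(i,j) distance."""

    taxa: tuple[str, ...]
    matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.taxa), columns=list(self.taxa))


@dataclass(frozen=True)
class PatristicDistances:
    """Tip-to-tip path length matrix D with zero diagonal."""

    taxa: tuple[str, ...]
    matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.taxa), columns=list(self.taxa))


def parse_newick(text: str, *, impute_missing_lengths: bool = False) -> Tree:
    """Parse a Newick string into a validated :class:`Tree`.

    Parameters
    ----------
    text
        Newick with branch lengths on all non-root edges.
    impute_missing_lengths
        If True, edges without a length are assigned 1.0 instead of raising.
        Off by default: silently imputed unit lengths would distort every
        depth-sensitive statistic (K, OU covariances, preseason windows are
        unaffected but model fits are not).
    """
    if text.count("(") != text.count(")"):
        raise NewickError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"Newick parse failure: {exc}") from exc
    if impute_missing_lengths:
        for edge in dtree.preorder_edge_iter():
            if edge.head_node is not dtree.seed_node and edge.length is None:
                edge.length = 1.0
    if sum(1 for _ in dtree.leaf_node_iter()) < 2:
        raise NewickError("a tree needs at least 2 tips")
    return Tree(dtree)


def _require_n(tree: Tree, n: int, op: str) -> None:
    if tree.n_tips < n:
        raise ValueError(f"{op} requires at least {n} tips, got {tree.n_tips}")


def phylo_covariance(tree: Tree) -> PhyloCovariance:
    """Phylogenetic covariance C under Brownian motion (rate 1).

    C_ij is the path length from the root to the most recent common
    ancestor of tips i and j; C_ii is the root-to-tip depth.  Computed in a
    single postorder sweep: an internal node at depth d contributes d as
    C_ij for every tip pair split between two of its child subtrees.
    """
    _require_n(tree, 3, "phylo_covariance")
    taxa = tree.taxa
    idx = {label: i for i, label in enumerate(taxa)}
    n = len(taxa)
    C = np.zeros((n, n))
    depths = tree._root_to_node_depths()

    tips_below: dict = {}
    for node in tree._dtree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            tips_below[node] = [i]
            C[i, i] = depths[node]
        else:
            groups = [tips_below.pop(ch) for ch in node.child_nodes()]
            d = depths[node]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            C[i, j] = C[j, i] = d
            tips_below[node] = [i for g in groups for i in g]
    return PhyloCovariance(taxa, C)


def patristic_distances(tree: Tree) -> PatristicDistances:
    """Pairwise tip-to-tip path lengths, D_ij = C_ii + C_jj - 2 C_ij."""
    _require_n(tree, 3, "patristic_distances")
    cov = phylo_covariance(tree)
    diag = np.diag(cov.matrix)
    D = diag[:, None] + diag[None, :] - 2.0 * cov.matrix
    np.fill_diagonal(D, 0.0)
    return PatristicDistances(cov.taxa, D)


def prune_to(tree: Tree, keep) -> Tree:
    """Induced subtree on ``keep``, unifurcations suppressed.

    Patristic distances among kept taxa are preserved exactly: degree-two
    nodes created by pruning are removed with their incident branch lengths
    summed.
    """
    keep = set(keep)
    missing = keep - set(tree.taxa)
    if missing:
        raise KeyError(f"taxa not in tree: {sorted(missing)}")
    if len(keep) < 3:
        raise ValueError(f"prune_to requires at least 3 kept taxa, got {len(keep)}")
    if keep == set(tree.taxa):
        return tree.copy()
    dtree = tree._dtree.clone(depth=1)
    taxa_to_keep = [t for t in dtree.taxon_namespace if t.label in keep]
    dtree.retain_taxa(taxa_to_keep)
    # retain_taxa can leave a unifurcate root edge; fold it away.
    root = dtree.seed_node
    while len(root.child_nodes()) == 1:
        child = root.child_nodes()[0]
        child.edge.length = None
        dtree.seed_node = child
        child.parent_node = None
        root = child
    return Tree(dtree)


def check_ultrametric(tree: Tree, rel_tol: float = 1e-6) -> tuple[bool, float]:
    """Whether all root-to-tip depths agree within ``rel_tol`` of their mean.

    Returns ``(flag, mean_height)``.
    """
    depths = tree._root_to_node_depths()
    tip_depths = np.array(
        [depths[leaf] for leaf in tree._dtree.leaf_node_iter()]
    )
    height = float(tip_depths.mean())
    if height == 0:
        return True, 0.0
    ok = bool(np.all(np.abs(tip_depths - height) <= rel_tol * height))
    return ok, height


def matrix_to_csv(obj, path_or_buf) -> None:
    """Write C or D as CSV with taxa as header row and index column."""
    obj.to_frame().to_csv(path_or_buf, index_label="taxon")


def matrix_from_csv(path_or_buf, cls):
    df = pd.read_csv(path_or_buf, index_col=0)
    return cls(tuple(df.index), df.to_numpy(dtype=float))
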