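"""Faith's Phylogenetic Diversity and Phylogenetic Species Clustering.

Both metrics are presence-based: a community contributes the *set* of ASVs it
contains, abundances play no role.

Faith's PD of a taxon set is the total branch length of the minimal subtree
connecting the set, by default extended to the root (the convention under
which PD of a single tip is its root-to-tip distance).

PSC rests on the phylogenetic covariance of root-to-tip paths: for tips i, j
the shared path length V_ij is the depth of their most recent common
ancestor, V_ii the root-to-tip distance, and the correlation
C_ij = V_ij / sqrt(V_ii V_jj).  PSC = 1 - mean_i max_{j != i} C_ij: values
near 0 mean every taxon has a close relative in the set (phylogenetic
clustering), values near 1 mean a star-like, overdispersed set.  The
correlation form makes no ultrametricity assumption, which matters because
amplicon trees are not ultrametric.

:class:`TreeIndex` caches the per-tree quantities (edge incidence, shared
path matrix) so that the null model can re-evaluate the metrics thousands of
times at array-indexing cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = ["TreeIndex", "faith_pd", "phylo_correlation", "psc", "PhyloMetricResult"]


@dataclass
class PhyloMetricResult:
    sample_id: str
    subset_label: str  # all | rare | abundant
    metric: str        # PD | PSC
    value: float


class TreeIndex:
    """Precomputed arrays for fast subset PD / PSC on one rooted tree.

    Parameters
    ----------
    tree
        Rooted ``skbio.TreeNode`` with branch lengths (``None`` treated as 0).

    Attributes
    ----------
    tip_names : list of str
        Tip labels in index order.
    edge_lengths : (n_edges,) float array
        One entry per non-root node (the edge above it).
    edge_below : (n_edges, n_tips) bool array
        ``edge_below[e, t]`` is True when tip ``t`` lies below edge ``e``.
    shared_path : (n_tips, n_tips) float array
        V matrix: shared root-to-tip path length; diagonal is root-to-tip
        distance.
    """

    def __init__(self, tree: TreeNode):
        tips = list(tree.tips())
        self.tip_names: list[str] = [t.name for t in tips]
        if len(set(self.tip_names)) != len(self.tip_names):
            raise ValueError("tree has duplicate tip labels")
        self.tip_index: dict[str, int] = {n: i for i, n in enumerate(self.tip_names)}
        n = len(tips)

        # postorder pass: tip sets below each node, edge arrays, V matrix
        edge_lengths: list[float] = []
        edge_tip_sets: list[np.ndarray] = []
        V = np.zeros((n, n))
        depth: dict[int, float] = {id(tree): 0.0}
        for node in tree.preorder(include_self=False):
            depth[id(node)] = depth[id(node.parent)] + float(node.length or 0.0)

        below: dict[int, np.ndarray] = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                below[id(node)] = np.array([self.tip_index[node.name]])
            else:
                child_sets = [below[id(c)] for c in node.children]
                # tips whose MRCA is this node share path length depth(node)
                d = depth[id(node)]
                if d != 0.0:
                    for a in range(len(child_sets)):
                        for b in range(a + 1, len(child_sets)):
                            V[np.ix_(child_sets[a], child_sets[b])] = d
                            V[np.ix_(child_sets[b], child_sets[a])] = d
                below[id(node)] = np.concatenate(child_sets)
            if node.parent is not None:
                edge_lengths.append(float(node.length or 0.0))
                edge_tip_sets.append(below[id(node)])

        np.fill_diagonal(V, [depth[id(t)] for t in tips])
        self.shared_path = V
        self.edge_lengths = np.array(edge_lengths)
        self.edge_below = np.zeros((len(edge_lengths), n), dtype=bool)
        for e, tipset in enumerate(edge_tip_sets):
            self.edge_below[e, tipset] = True

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def indices_of(self, taxa: Iterable[str], strict: bool = False) -> np.ndarray:
        """Tip indices for *taxa*; unknown names dropped with a logged count."""
        taxa = list(taxa)
        known = [t for t in taxa if t in self.tip_index]
        if len(known) < len(taxa):
            msg = f"{len(taxa) - len(known)} taxa absent from the tree were dropped"
            if strict:
                raise KeyError(msg)
            logger.warning(msg)
        return np.array(sorted(self.tip_index[t] for t in known), dtype=np.intp)

    # -- metrics on index arrays (hot path) --------------------------------
    def pd_of(self, idx: np.ndarray, include_root: bool = True) -> float:
        if idx.size == 0:
            raise ValueError("empty taxon set")
        hits = self.edge_below[:, idx].sum(axis=1)
        if include_root:
            used = hits > 0
        else:
            used = (hits > 0) & (hits < idx.size)
        return float(self.edge_lengths[used].sum())

    def correlation_of(self, idx: np.ndarray) -> np.ndarray:
        if idx.size < 2:
            raise ValueError("phylogenetic correlation needs at least 2 taxa")
        V = self.shared_path[np.ix_(idx, idx)]
        d = np.diag(V)
        if (d <= 0).any():
            raise ValueError("a taxon sits at zero distance from the root")
        return V / np.sqrt(np.outer(d, d))

    def psc_of(self, idx: np.ndarray) -> float:
        C = self.correlation_of(idx).copy()
        np.fill_diagonal(C, -np.inf)
        return float(1.0 - C.max(axis=1).mean())


def _as_index(tree: TreeNode | TreeIndex) -> TreeIndex:
    return tree if isinstance(tree, TreeIndex) else TreeIndex(tree)


def faith_pd(tree: TreeNode | TreeIndex, taxa: Iterable[str], include_root: bool = True) -> float:
    """Total branch length of the minimal subtree connecting *taxa*.

    With ``include_root`` (default) the subtree is extended to the root, the
    convention of the standard community-phylogenetics toolchains.
    """
    ti = _as_index(tree)
    idx = ti.indices_of(taxa)
    if idx.size == 0:
        raise ValueError("no taxa from the set occur in the tree")
    return ti.pd_of(idx, include_root=include_root)


def phylo_correlation(tree: TreeNode | TreeIndex, taxa: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Pairwise phylogenetic correlation matrix over *taxa*.

    Returns ``(C, labels)`` where ``C[i, j] = V_ij / sqrt(V_ii V_jj)`` with
    V the shared root-to-tip path length; C is symmetric with unit diagonal
    and entries in [0, 1].
    """
    ti = _as_index(tree)
    idx = ti.indices_of(taxa)
    C = ti.correlation_of(idx)
    return C, [ti.tip_names[i] for i in idx]


def psc(tree: TreeNode | TreeIndex, taxa: Iterable[str]) -> float:
    """Phylogenetic Species Clustering of *taxa*: 1 - mean max inter-taxon correlation.

    0 when every taxon has a perfectly correlated partner (clustered);
    approaches 1 on a star phylogeny (overdispersed).
    """
    ti = _as_index(tree)
    idx = ti.indices_of(taxa)
    if idx.size < 2:
        raise ValueError("PSC needs at least 2 taxa present in the tree")
    return ti.psc_of(idx)
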