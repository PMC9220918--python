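"""Rarefaction, alpha/beta diversity, UPGMA clustering and the Mantel test.

Rarefaction is exact subsampling without replacement (one multivariate-
hypergeometric draw per sample), the standard reading of "rarefied to N
reads per sample".  Shannon entropy takes an explicit log base because the
two amplicon libraries the pipeline models were processed by toolchains with
different conventions (base 2 vs base e); the base is recorded on the output.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity as _skbio_beta

from .io import CommunityTable, SampleMetadata

__all__ = [
    "rarefy",
    "alpha_diversity",
    "beta_diversity",
    "upgma",
    "geographic_distances",
    "mantel",
    "AlphaResult",
    "MantelResult",
]


@dataclass
class AlphaResult:
    sample_id: str
    observed: int
    shannon: float
    log_base: str  # "e" or "2"


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    method: str = "pearson"
    exhaustive: bool = False


def rarefy(
    table: CommunityTable,
    depth: int,
    seed: int | np.random.Generator = 0,
    drop_empty_asvs: bool = False,
    on_small: str = "error",
) -> CommunityTable:
    """Subsample every sample to exactly *depth* reads without replacement.

    Each sample is one multivariate-hypergeometric draw: a uniform random
    subset of its physical reads.  Columns that end up all-zero are retained
    unless ``drop_empty_asvs`` is set.

    ``on_small`` controls samples whose total is below *depth*: ``"error"``
    (default) or ``"drop"`` (with a warning).
    """
    rng = np.random.default_rng(seed)
    depth = int(depth)
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = table.sample_totals()
    small = np.flatnonzero(totals < depth)
    keep = np.arange(table.n_samples)
    if small.size:
        names = [table.sample_ids[i] for i in small]
        if on_small == "drop":
            import warnings

            warnings.warn(f"dropping samples below depth {depth}: {names}")
            keep = np.setdiff1d(keep, small)
            if keep.size == 0:
                raise ValueError("all samples fall below the rarefaction depth")
        else:
            raise ValueError(
                f"sample(s) {names} have fewer than {depth} reads; "
                "lower the depth or pass on_small='drop'"
            )
    out = np.empty((keep.size, table.n_asvs), dtype=np.int64)
    for r, i in enumerate(keep):
        row = table.counts[i]
        if totals[i] == depth:
            out[r] = row
        else:
            out[r] = rng.multivariate_hypergeometric(row, depth)
    sample_ids = [table.sample_ids[i] for i in keep]
    result = CommunityTable(out, sample_ids, list(table.asv_ids))
    if drop_empty_asvs:
        nonzero = np.flatnonzero(result.counts.sum(axis=0) > 0)
        result = CommunityTable(
            result.counts[:, nonzero], sample_ids, [table.asv_ids[j] for j in nonzero]
        )
    return result


def alpha_diversity(table: CommunityTable, log_base: str = "e") -> list[AlphaResult]:
    """Observed ASV richness and Shannon index H = -sum p_i log p_i per sample."""
    if log_base not in {"e", "2"}:
        raise ValueError("log_base must be 'e' or '2'")
    log = np.log if log_base == "e" else np.log2
    results = []
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        total = row.sum()
        if total == 0:
            raise ValueError(f"sample {sid!r} has zero reads")
        p = row[row > 0] / total
        results.append(
            AlphaResult(sid, int((row > 0).sum()), float(-(p * log(p)).sum()), log_base)
        )
    return results


def beta_diversity(table: CommunityTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise Bray-Curtis (abundance) or Jaccard-1 (presence/absence) distances."""
    if table.n_samples < 2:
        raise ValueError("beta diversity needs at least 2 samples")
    if (table.sample_totals() == 0).sum() >= 2:
        raise ValueError("more than one all-zero sample: distances undefined")
    name = {"bray_curtis": "braycurtis", "jaccard": "jaccard"}.get(metric)
    if name is None:
        raise ValueError(f"unknown metric {metric!r}")
    counts = table.counts if metric == "bray_curtis" else (table.counts > 0)
    return _skbio_beta(name, counts, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class Dendrogram:
    """Ultrametric average-linkage merge tree of samples."""

    tree: TreeNode
    merge_heights: list[float]

    def newick(self) -> str:
        return str(self.tree)


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration with a deterministic tie-break.

    Among all pairs at the minimal distance the lexicographically smallest
    (by current cluster creation order) is merged first.  Node heights are
    half the merge distance, so cophenetic distances reproduce the average
    linkage distances.
    """
    n = dm.shape[0]
    if n < 2:
        raise ValueError("UPGMA needs at least 2 samples")
    if not np.isfinite(dm.data).all():
        raise ValueError("distance matrix contains non-finite values")
    d = {}
    sizes = {}
    nodes = {}
    heights = {}
    for i, label in enumerate(dm.ids):
        nodes[i] = TreeNode(name=str(label))
        sizes[i] = 1
        heights[i] = 0.0
    for i, j in itertools.combinations(range(n), 2):
        d[(i, j)] = float(dm.data[i, j])
    active = list(range(n))
    next_id = n
    merge_heights = []
    while len(active) > 1:
        best = min(
            ((d[(min(a, b), max(a, b))], a, b) for a, b in itertools.combinations(active, 2)),
            key=lambda t: (t[0], t[1], t[2]),
        )
        dist, a, b = best
        h = dist / 2.0
        parent = TreeNode(children=[nodes[a], nodes[b]])
        nodes[a].length = h - heights[a]
        nodes[b].length = h - heights[b]
        nodes[next_id] = parent
        heights[next_id] = h
        merge_heights.append(h)
        sizes[next_id] = sizes[a] + sizes[b]
        for c in active:
            if c in (a, b):
                continue
            da = d[(min(a, c), max(a, c))]
            db = d[(min(b, c), max(b, c))]
            d[(min(c, next_id), max(c, next_id))] = (
                sizes[a] * da + sizes[b] * db
            ) / (sizes[a] + sizes[b])
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    root = nodes[active[0]]
    root.length = None
    return Dendrogram(root, merge_heights)


# ---------------------------------------------------------------------------
# transect geography & Mantel


def geographic_distances(meta: SampleMetadata, sample_ids: list[str] | None = None) -> DistanceMatrix:
    """Pairwise |position_i - position_j| in metres along the transect."""
    ids = sample_ids if sample_ids is not None else sorted(meta.positions)
    pos = np.array([meta.position(s) for s in ids], dtype=float)
    return DistanceMatrix(np.abs(pos[:, None] - pos[None, :]), ids=ids)


def _triangle(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices_from(m, k=1)]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        from scipy.stats import rankdata

        x, y = rankdata(x), rankdata(y)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in a distance triangle: Mantel r undefined")
    return float(np.corrcoef(x, y)[0, 1])


def mantel(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
    method: str = "pearson",
) -> MantelResult:
    """One-sided (greater) Mantel test between two distance matrices.

    r is the Pearson (or Spearman) correlation of the strictly-lower-triangle
    vectors; the null permutes rows/columns of *dm_b* jointly and
    p = (1 + #{r_perm >= r_obs}) / (n_permutations + 1).  When the number of
    objects is small enough that every permutation can be enumerated
    (n! <= n_permutations) the exact p over all n! relabellings is returned
    instead.
    """
    if list(dm_a.ids) != list(dm_b.ids):
        raise ValueError("distance matrices must share labels in the same order")
    a, b = dm_a.data, dm_b.data
    n = a.shape[0]
    xa = _triangle(a)
    r_obs = _corr(xa, _triangle(b), method)

    if math.factorial(n) <= n_permutations:
        count, total = 0, 0
        for perm in itertools.permutations(range(n)):
            bp = b[np.ix_(perm, perm)]
            if _corr(xa, _triangle(bp), method) >= r_obs - 1e-12:
                count += 1
            total += 1
        return MantelResult(r_obs, count / total, total, method, exhaustive=True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        if _corr(xa, _triangle(bp), method) >= r_obs - 1e-12:
            count += 1
    return MantelResult(r_obs, (1 + count) / (n_permutations + 1), n_permutations, method)
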