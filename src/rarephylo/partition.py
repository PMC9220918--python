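"""Rare / abundant subcommunity partitioning and shared-core analysis.

Two complementary definitions of "rare" are implemented:

* the per-site quartile rule — within one sample, rank the nonzero ASV
  counts and call ASVs at or below the first quartile rare and at or above
  the third quartile abundant (nearest-rank quartiles, so thresholds are
  integer read counts);
* the whole-table relative-abundance rule — units (ASVs or genera) above a
  relative-abundance threshold (default 1 %) are abundant, the rest form
  the rare biosphere.

Shared-core analysis assigns every ASV to the exact subset of samples where
it occurs, the table behind an UpSet plot; the core is the all-samples
subset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import CommunityTable, TaxonomyTable

__all__ = [
    "SubcommunityPartition",
    "IntersectionSummary",
    "quartile_partition",
    "balance_partition",
    "relabund_partition",
    "shared_intersections",
    "nearest_rank_quartiles",
]


@dataclass
class SubcommunityPartition:
    sample_id: str
    q1_threshold: int
    q3_threshold: int
    rare_asvs: frozenset[str]
    abundant_asvs: frozenset[str]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.q1_threshold > self.q3_threshold:
            raise ValueError("Q1 threshold exceeds Q3 threshold")
        if not self.degenerate and self.rare_asvs & self.abundant_asvs:
            raise ValueError("rare and abundant sets overlap in a non-degenerate partition")


@dataclass
class IntersectionSummary:
    """ASV counts per exact sample subset, plus the all-samples core."""

    subset_counts: dict[frozenset[str], int]
    core_count: int
    core_read_fraction: float
    core_asvs: frozenset[str] = field(default_factory=frozenset)


def nearest_rank_quartiles(values: np.ndarray) -> tuple[int, int]:
    """Nearest-rank Q1/Q3 of an array of counts (returned as integers)."""
    v = np.sort(np.asarray(values))
    n = v.size
    q1 = v[math.ceil(0.25 * n) - 1]
    q3 = v[math.ceil(0.75 * n) - 1]
    return int(q1), int(q3)


def quartile_partition(
    table: CommunityTable, sample_id: str, method: str = "nearest_rank"
) -> SubcommunityPartition:
    """Partition one sample's ASVs into rare (<= Q1) and abundant (>= Q3).

    Quartiles are taken over the sample's *nonzero* counts, ascending.  The
    default nearest-rank estimator yields integer thresholds; ``method``
    accepts any numpy interpolation name (e.g. ``"linear"``) for sensitivity
    checks.  Equal quartiles raise the ``degenerate`` flag and both sets are
    returned with a warning.
    """
    row = table.sample_counts(sample_id)
    nz = np.flatnonzero(row)
    if nz.size < 4:
        raise ValueError(f"sample {sample_id!r} has fewer than 4 nonzero ASVs")
    counts = row[nz]
    if method == "nearest_rank":
        q1, q3 = nearest_rank_quartiles(counts)
    else:
        q1 = float(np.quantile(counts, 0.25, method=method))
        q3 = float(np.quantile(counts, 0.75, method=method))
    rare = frozenset(table.asv_ids[j] for j in nz[counts <= q1])
    abundant = frozenset(table.asv_ids[j] for j in nz[counts >= q3])
    degenerate = q1 == q3
    if degenerate:
        warnings.warn(
            f"sample {sample_id!r}: Q1 == Q3 == {q1}; rare/abundant sets overlap"
        )
    return SubcommunityPartition(sample_id, int(q1), int(q3), rare, abundant, degenerate)


def balance_partition(
    p: SubcommunityPartition, seed: int | np.random.Generator = 0
) -> SubcommunityPartition:
    """Equalise rare/abundant set sizes by subsampling the larger set (seeded)."""
    if p.degenerate:
        raise ValueError("cannot balance a degenerate partition")
    n_r, n_a = len(p.rare_asvs), len(p.abundant_asvs)
    if n_r == n_a:
        return p
    rng = np.random.default_rng(seed)
    k = min(n_r, n_a)
    rare, abundant = p.rare_asvs, p.abundant_asvs
    if n_r > n_a:
        rare = frozenset(rng.choice(sorted(rare), size=k, replace=False))
    else:
        abundant = frozenset(rng.choice(sorted(abundant), size=k, replace=False))
    return SubcommunityPartition(p.sample_id, p.q1_threshold, p.q3_threshold, rare, abundant)


def relabund_partition(
    table: CommunityTable,
    threshold_pct: float = 1.0,
    level: str = "asv",
    taxonomy: TaxonomyTable | None = None,
) -> tuple[set[str], set[str], dict[str, float]]:
    """Whole-table relative-abundance split into abundant (> threshold) and rare.

    At ``level="genus"`` counts are aggregated over samples by the genus of
    each ASV (taxonomy required).  Returns ``(abundant, rare, fractions)``
    where ``fractions`` maps each class to its share of total reads.
    """
    totals = table.counts.sum(axis=0).astype(float)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("empty table")
    if level == "asv":
        units = dict(zip(table.asv_ids, totals))
    elif level == "genus":
        if taxonomy is None:
            raise ValueError("genus-level partition requires a taxonomy table")
        gmap = taxonomy.genus_map()
        units: dict[str, float] = {}
        for asv, t in zip(table.asv_ids, totals):
            units[gmap.get(asv, "unclassified")] = units.get(gmap.get(asv, "unclassified"), 0.0) + t
    else:
        raise ValueError(f"unknown level {level!r}")
    thr = threshold_pct / 100.0
    abundant = {u for u, t in units.items() if t / grand > thr}
    rare = {u for u in units if u not in abundant}
    fractions = {
        "abundant": sum(units[u] for u in abundant) / grand,
        "rare": sum(units[u] for u in rare) / grand,
    }
    return abundant, rare, fractions


def shared_intersections(table: CommunityTable) -> IntersectionSummary:
    """Assign every ASV to the exact subset of samples where it occurs.

    The core is the subset containing all samples; ``core_read_fraction`` is
    the share of all reads carried by core ASVs.
    """
    if table.n_samples < 2:
        raise ValueError("intersections need at least 2 samples")
    presence = table.counts > 0
    subset_counts: dict[frozenset[str], int] = {}
    core_asvs = []
    for j, asv in enumerate(table.asv_ids):
        members = frozenset(
            table.sample_ids[i] for i in np.flatnonzero(presence[:, j])
        )
        if not members:
            continue
        subset_counts[members] = subset_counts.get(members, 0) + 1
        if len(members) == table.n_samples:
            core_asvs.append(asv)
    total = table.counts.sum()
    core_idx = [table.asv_ids.index(a) for a in core_asvs]
    core_reads = table.counts[:, core_idx].sum() if core_idx else 0
    return IntersectionSummary(
        subset_counts,
        len(core_asvs),
        float(core_reads / total) if total else 0.0,
        frozenset(core_asvs),
    )
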