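"""Richness null model, standardized effect sizes, and the clustered /
null / overdispersed classification.

The null model randomizes a community matrix sample by sample: each sample's
multiset of nonzero counts is reassigned to a uniformly random subset of the
full ASV pool of the same size, so per-sample richness and per-sample read
totals are both conserved while taxon identities are scrambled.  The
standardized effect size of a metric is

    SES = (observed - mean(null)) / sd(null)

over ``n_replicates`` randomized matrices (sd with one delta degree of
freedom, the convention of the community-phylogenetics toolchains).  SES
below -2 is classified as phylogenetically clustered, above +2 as
overdispersed, and anything in between (boundaries included) as consistent
with the null.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .io import CommunityTable
from .partition import nearest_rank_quartiles
from .phylo import TreeIndex

logger = logging.getLogger(__name__)

__all__ = ["SESResult", "richness_null", "ses_metric", "classify_ses"]

SES_THRESHOLD = 2.0


@dataclass
class SESResult:
    sample_id: str
    subset_label: str           # all | rare | abundant
    metric: str                 # PD | PSC
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    n_replicates: int
    label: str
    degenerate: bool = False
    null_values: np.ndarray | None = field(default=None, repr=False, compare=False)


def classify_ses(ses: float, threshold: float = SES_THRESHOLD) -> str:
    """Map an SES value to clustered (< -t), overdispersed (> +t) or null."""
    if math.isnan(ses):
        raise ValueError("SES is NaN")
    if ses < -threshold:
        return "clustered"
    if ses > threshold:
        return "overdispersed"
    return "null"


def richness_null(
    table: CommunityTable, seed: int | np.random.Generator = 0
) -> CommunityTable:
    """One draw from the richness null model.

    For each sample independently, its nonzero counts are placed (in random
    order) on a uniformly random subset of the full ASV pool of the same
    size.  Per-sample richness, per-sample totals and the multiset of
    nonzero counts are all conserved.
    """
    rng = np.random.default_rng(seed)
    out = np.zeros_like(table.counts)
    n_asvs = table.n_asvs
    for i in range(table.n_samples):
        row = table.counts[i]
        nz = row[row > 0]
        pos = rng.choice(n_asvs, size=nz.size, replace=False)
        out[i, pos] = rng.permutation(nz)
    return CommunityTable(out, list(table.sample_ids), list(table.asv_ids))


def _subset_indices(
    counts_row: np.ndarray, col_to_tip: np.ndarray
) -> dict[str, np.ndarray]:
    """Tip-index sets for all / rare / abundant ASVs of one sample row.

    Quartile thresholds are re-derived from the row itself (nearest-rank on
    the nonzero counts); columns without a tree tip carry index -1 and are
    excluded from the phylogenetic sets.
    """
    nz = np.flatnonzero(counts_row)
    tips_all = col_to_tip[nz]
    out = {"all": np.sort(tips_all[tips_all >= 0])}
    if nz.size >= 4:
        vals = counts_row[nz]
        q1, q3 = nearest_rank_quartiles(vals)
        rare = nz[vals <= q1]
        abundant = nz[vals >= q3]
        for label, cols in (("rare", rare), ("abundant", abundant)):
            t = col_to_tip[cols]
            out[label] = np.sort(t[t >= 0])
    return out


def ses_metric(
    table: CommunityTable,
    tree: TreeNode | TreeIndex,
    metric: str = "PSC",
    subset: str | None = None,
    n_replicates: int = 1000,
    seed: int | np.random.Generator = 0,
    freeze_subsets: bool = False,
    include_root: bool = True,
    keep_null: bool = False,
) -> list[SESResult]:
    """Standardized effect size of PD or PSC per sample (and per subcommunity).

    Parameters
    ----------
    metric
        ``"PD"`` (Faith's phylogenetic diversity) or ``"PSC"``.
    subset
        ``None`` evaluates each sample's full ASV set; ``"quartile"``
        additionally evaluates the rare (<= Q1) and abundant (>= Q3)
        subcommunities.
    freeze_subsets
        With the quartile subset, reuse the *observed* rare/abundant ASV sets
        inside every null replicate instead of re-deriving them from the
        randomized counts (sensitivity variant; re-deriving is the default and
        keeps the null internally consistent).
    keep_null
        Attach the replicate metric vector to each result for inspection.
    """
    if metric not in {"PD", "PSC"}:
        raise ValueError("metric must be 'PD' or 'PSC'")
    if n_replicates < 2:
        raise ValueError("need at least 2 null replicates")
    ti = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    col_to_tip = np.array(
        [ti.tip_index.get(a, -1) for a in table.asv_ids], dtype=np.intp
    )
    n_missing = int((col_to_tip < 0).sum())
    if n_missing:
        logger.warning("%d table ASVs absent from the tree are excluded", n_missing)

    def evaluate(idx: np.ndarray) -> float:
        if metric == "PD":
            if idx.size == 0:
                return np.nan
            return ti.pd_of(idx, include_root=include_root)
        if idx.size < 2:
            return np.nan
        return ti.psc_of(idx)

    labels = ["all"] if subset is None else ["all", "rare", "abundant"]
    observed: dict[tuple[str, str], float] = {}
    frozen_cols: dict[str, dict[str, np.ndarray]] = {}
    for i, sid in enumerate(table.sample_ids):
        sets = _subset_indices(table.counts[i], col_to_tip)
        frozen_cols[sid] = sets
        for lab in labels:
            observed[(sid, lab)] = evaluate(sets.get(lab, np.array([], dtype=np.intp)))

    rng = np.random.default_rng(seed)
    nulls: dict[tuple[str, str], list[float]] = {k: [] for k in observed}
    n_asvs = table.n_asvs
    for _ in range(n_replicates):
        for i, sid in enumerate(table.sample_ids):
            row = table.counts[i]
            nz = row[row > 0]
            pos = rng.choice(n_asvs, size=nz.size, replace=False)
            null_row = np.zeros(n_asvs, dtype=np.int64)
            null_row[pos] = rng.permutation(nz)
            if freeze_subsets and subset is not None:
                # frozen variant: subset *sizes* stay as observed; membership
                # taken from the randomized counts by rank
                sets = _frozen_sets(null_row, frozen_cols[sid], col_to_tip)
            else:
                sets = _subset_indices(null_row, col_to_tip)
            for lab in labels:
                nulls[(sid, lab)].append(
                    evaluate(sets.get(lab, np.array([], dtype=np.intp)))
                )

    results: list[SESResult] = []
    for sid in table.sample_ids:
        for lab in labels:
            obs = observed[(sid, lab)]
            nv = np.array(nulls[(sid, lab)], dtype=float)
            nv_ok = nv[~np.isnan(nv)]
            degenerate = False
            if math.isnan(obs) or nv_ok.size < 2:
                mean, sd, ses, label = np.nan, np.nan, np.nan, "null"
                degenerate = True
                warnings.warn(
                    f"{sid}/{lab}/{metric}: metric undefined (too few taxa); "
                    "flagged degenerate"
                )
            else:
                mean = float(nv_ok.mean())
                sd = float(nv_ok.std(ddof=1))
                if np.ptp(nv_ok) == 0:  # constant null: sd is pure round-off
                    sd = 0.0
                if sd == 0:
                    ses = np.nan
                    label = "null"
                    degenerate = True
                    warnings.warn(
                        f"{sid}/{lab}/{metric}: null distribution is constant; "
                        "SES undefined, labelled null"
                    )
                else:
                    ses = (obs - mean) / sd
                    label = classify_ses(ses)
            results.append(
                SESResult(
                    sid, lab, metric, float(obs), mean, sd, float(ses),
                    n_replicates, label, degenerate,
                    nv if keep_null else None,
                )
            )
    return results


def _frozen_sets(
    null_row: np.ndarray,
    observed_sets: dict[str, np.ndarray],
    col_to_tip: np.ndarray,
) -> dict[str, np.ndarray]:
    """Frozen-subset variant: keep the observed subset sizes, fill them with
    the randomized sample's taxa by count rank (smallest counts -> rare,
    largest -> abundant)."""
    nz = np.flatnonzero(null_row)
    order = nz[np.argsort(null_row[nz], kind="stable")]
    tips_all = col_to_tip[nz]
    out = {"all": np.sort(tips_all[tips_all >= 0])}
    for lab in ("rare", "abundant"):
        if lab not in observed_sets:
            continue
        k = observed_sets[lab].size
        cols = order[:k] if lab == "rare" else order[-k:] if k else order[:0]
        t = col_to_tip[cols]
        out[lab] = np.sort(t[t >= 0])
    return out
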