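"""Synthetic communities with the structure of a hypersaline mat transect.

The generator emulates the community architecture the pipeline is built to
analyse: around ten samples along a short transect, thousands of ASVs, a
very small abundant core (a few percent of taxa) present in every sample and
carrying most of the reads, and a long rare tail of low-count,
patchily-occurring taxa.

Mechanism (the simplest one reproducing that architecture):

* a pure-birth (Yule) tree over the taxon pool;
* the core is either a uniform random taxon set or the tips of a single
  clade (``abundant_placement="clade"``), the knob that makes the abundant
  subcommunity phylogenetically clustered so null-model recovery can be
  tested in both directions;
* lognormal relative abundances for core and tail; each rare taxon occurs in
  each sample independently with probability ``occupancy_rare``;
* per sample, the core is rescaled to an expected read share of
  ``core_read_fraction`` and counts are one multinomial draw at ``depth``
  reads, so per-sample totals are exact.

One global seed feeds a ``numpy.random.SeedSequence`` substream per stage
(tree, core choice, abundances, occupancy, counts), so the dataset is
bit-reproducible and stages can be varied independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from skbio import TreeNode

from .io import CommunityTable

__all__ = ["SimulationParams", "SyntheticDataset", "simulate_tree", "simulate_communities"]


@dataclass
class SimulationParams:
    """Generator knobs; defaults are the mat-transect study conditions."""

    n_samples: int = 10
    n_taxa: int = 2000
    depth: int = 250_000
    core_size: int = 60                 # 3 % of the taxon pool
    core_read_fraction: float = 0.725
    abundance_shape: float = 2.0        # lognormal sigma of the rare tail
    abundant_placement: str = "random"  # random | clade
    occupancy_rare: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.core_size < self.n_taxa:
            raise ValueError("need 2 <= core_size < n_taxa")
        if not 0 < self.core_read_fraction < 1:
            raise ValueError("core_read_fraction must be in (0, 1)")
        if not 0 <= self.occupancy_rare <= 1:
            raise ValueError("occupancy_rare must be in [0, 1]")
        if self.abundant_placement not in {"random", "clade"}:
            raise ValueError("abundant_placement must be 'random' or 'clade'")


@dataclass
class SyntheticDataset:
    table: CommunityTable
    tree: TreeNode
    truth: SimulationParams
    core_asvs: frozenset[str] = field(default_factory=frozenset)
    rare_asvs: frozenset[str] = field(default_factory=frozenset)

    def truth_dict(self) -> dict:
        d = asdict(self.truth)
        d["core_asvs"] = sorted(self.core_asvs)
        return d


def _tip_name(i: int) -> str:
    return f"ASV{i:05d}"


def simulate_tree(
    n_tips: int, seed: int | np.random.Generator = 0, model: str = "yule", birth_rate: float = 1.0
) -> TreeNode:
    """Simulate a rooted binary pure-birth tree with exponential waiting times.

    Starting from a single lineage, after an Exp(k*birth_rate) wait one of the
    k extant lineages (uniform) splits; the process stops when ``n_tips``
    lineages exist, plus one final waiting time so tips have pendant length.
    The same seed yields a byte-identical Newick string.
    """
    if model != "yule":
        raise ValueError("only the 'yule' model is implemented")
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)

    root = TreeNode()
    birth_time = {id(root): 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = active.pop(rng.integers(k))
        node.length = t - birth_time[id(node)] if node.parent is not None else None
        left, right = TreeNode(), TreeNode()
        birth_time[id(left)] = birth_time[id(right)] = t
        node.extend([left, right])
        active.extend([left, right])
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for i, node in enumerate(sorted(active, key=lambda nd: id(nd))):
        node.length = t - birth_time[id(node)]
    # label tips left-to-right for a stable, readable naming
    for i, tip in enumerate(root.tips()):
        tip.name = _tip_name(i)
    root.length = None
    return root


def _pick_clade(tree: TreeNode, size: int, rng: np.random.Generator) -> list[str]:
    """Tips of the smallest clade holding at least *size* tips (never the root)."""
    best = None
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            continue
        tips = [t.name for t in node.tips()]
        if len(tips) >= size and (best is None or len(tips) < len(best)):
            best = tips
    if best is None:
        raise ValueError(
            f"no internal clade with >= {size} tips exists; use a smaller core_size"
        )
    if len(best) > size:
        best = list(rng.choice(best, size=size, replace=False))
    return best


def simulate_communities(tree: TreeNode, params: SimulationParams) -> SyntheticDataset:
    """Draw a multi-sample community table over the tips of *tree*.

    See the module docstring for the generative mechanism.  Core taxa occur
    in every sample; the expected per-sample core read share equals
    ``core_read_fraction`` exactly by construction.
    """
    tip_names = sorted(t.name for t in tree.tips())
    if len(tip_names) < params.n_taxa:
        raise ValueError("tree has fewer tips than n_taxa")

    streams = np.random.SeedSequence(params.seed).spawn(5)
    rng_taxa = np.random.default_rng(streams[0])
    rng_core = np.random.default_rng(streams[1])
    rng_abund = np.random.default_rng(streams[2])
    rng_occ = np.random.default_rng(streams[3])
    rng_counts = np.random.default_rng(streams[4])

    if len(tip_names) > params.n_taxa:
        taxa = sorted(rng_taxa.choice(tip_names, size=params.n_taxa, replace=False))
    else:
        taxa = tip_names
    taxa_set = set(taxa)

    if params.abundant_placement == "clade":
        clade_tips = [t for t in _pick_clade(tree, params.core_size, rng_core) if t in taxa_set]
        # the clade was chosen on the full tree; top up from inside it if the
        # taxon subsample clipped some members
        if len(clade_tips) < params.core_size:
            raise ValueError(
                "clade-based core lost members to the taxon subsample; "
                "use n_taxa equal to the tree size or a smaller core_size"
            )
        core = sorted(clade_tips[: params.core_size])
    else:
        core = sorted(rng_core.choice(taxa, size=params.core_size, replace=False))
    core_set = set(core)
    rare = sorted(taxa_set - core_set)

    # static relative-abundance profiles
    w_core = rng_abund.lognormal(mean=0.0, sigma=1.0, size=len(core))
    w_rare = rng_abund.lognormal(mean=0.0, sigma=params.abundance_shape, size=len(rare))

    col = {a: j for j, a in enumerate(taxa)}
    counts = np.zeros((params.n_samples, len(taxa)), dtype=np.int64)
    f = params.core_read_fraction
    for i in range(params.n_samples):
        occ = rng_occ.random(len(rare)) < params.occupancy_rare
        p = np.zeros(len(taxa))
        core_p = w_core / w_core.sum() * f
        for a, v in zip(core, core_p):
            p[col[a]] = v
        wr = w_rare * occ
        if wr.sum() > 0:
            rare_p = wr / wr.sum() * (1.0 - f)
            for a, v in zip(rare, rare_p):
                p[col[a]] = v
        else:
            p[[col[a] for a in core]] /= f  # no rare taxa occur: core takes all
        counts[i] = rng_counts.multinomial(params.depth, p / p.sum())

    sample_ids = [f"S{i + 1}" for i in range(params.n_samples)]
    table = CommunityTable(counts, sample_ids, list(taxa))
    return SyntheticDataset(table, tree, params, frozenset(core), frozenset(rare))
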