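# rarephylo

Diversity analysis of amplicon (ASV) community tables sampled along a short
spatial transect — rarefaction, alpha/beta diversity, shared-core
quantification, rare/abundant subcommunity partitioning, Faith's
Phylogenetic Diversity (PD), Phylogenetic Species Clustering (PSC), and a
randomization null model that classifies each sample–subcommunity as
phylogenetically **clustered**, **null**, or **overdispersed**.

The motivating system is a hypersaline elastic microbial mat sampled at ten
points over 1.5 m, whose community is dominated by a tiny core of abundant
ASVs shared by every site (a few percent of taxa carrying most of the reads)
above a long, patchy rare tail. The package answers, with explicit seeds and
reproducible bundles: how much of the community is that core, where do the
rare and abundant subcommunities sit on the phylogeny, and is their placement
more extreme than chance?

## The statistics at the core

- **Faith's PD** of a taxon set S on a rooted tree: the total branch length
  of the minimal subtree connecting S, extended to the root by default.
- **PSC**: from the phylogenetic correlation matrix
  C_ij = V_ij / √(V_ii·V_jj), with V_ij the shared root-to-tip path length
  of tips i and j, PSC(S) = 1 − meanᵢ maxⱼ≠ᵢ C_ij. Near 0 ⇒ every taxon has
  a close relative in S (clustered); a star phylogeny gives 1.
- **Richness null model**: each sample's multiset of nonzero counts is
  reassigned to a uniformly random same-size subset of the ASV pool,
  conserving per-sample richness and reads. The standardized effect size
  SES = (obs − mean_null)/sd_null over 1,000 replicates; SES < −2 clustered,
  > +2 overdispersed, else null.
- **Rare/abundant partition**: per sample, nearest-rank quartiles of the
  nonzero counts; rare = counts ≤ Q1, abundant = counts ≥ Q3. A whole-table
  rule (> 1 % relative abundance) covers the "rare biosphere" sense.
- Supporting stages: exact multivariate-hypergeometric rarefaction, Shannon
  entropy with an explicit log base, Bray–Curtis and Jaccard-1 distances,
  UPGMA with a deterministic tie-break, and a one-sided permutation Mantel
  test (exact enumeration when n! is small enough).

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Simulate a mat-like dataset (10 samples, 400 taxa, a 12-taxon clade core
targeted at 72.5 % of reads), then quantify the core, partition sample S1 and
test both subcommunities against the null model:

```python
from rarephylo import (SimulationParams, simulate_communities, simulate_tree,
                       shared_intersections, quartile_partition, faith_pd,
                       ses_metric)
from rarephylo.phylo import TreeIndex

tree = simulate_tree(400, seed=42)
params = SimulationParams(n_samples=10, n_taxa=400, depth=40_000, core_size=12,
                          abundant_placement="clade", seed=42)
ds = simulate_communities(tree, params)

core = shared_intersections(ds.table)
print(f"core: {core.core_count} ASVs shared by all 10 samples, "
      f"{100 * core.core_read_fraction:.1f}% of reads")

ti = TreeIndex(tree)
p = quartile_partition(ds.table, "S1")
print(f"S1 thresholds: Q1={p.q1_threshold}, Q3={p.q3_threshold} reads; "
      f"{len(p.rare_asvs)} rare, {len(p.abundant_asvs)} abundant ASVs")
print(f"S1 Faith PD: rare={faith_pd(ti, p.rare_asvs):.1f}, "
      f"abundant={faith_pd(ti, p.abundant_asvs):.1f}")

for r in ses_metric(ds.table, ti, metric="PSC", subset="quartile",
                    n_replicates=1000, seed=7):
    if r.sample_id == "S1":
        print(f"S1 {r.subset_label:>8s} PSC={r.observed:.3f} "
              f"SES={r.ses:+.2f} -> {r.label}")
```

prints

```
core: 12 ASVs shared by all 10 samples, 72.4% of reads
S1 thresholds: Q1=10, Q3=435 reads; 18 rare, 18 abundant ASVs
S1 Faith PD: rare=58.2, abundant=39.2
S1      all PSC=0.253 SES=+0.31 -> null
S1     rare PSC=0.412 SES=-0.04 -> null
S1 abundant PSC=0.248 SES=-3.51 -> clustered
```

Reading: the 12 core ASVs dominate the reads (72.4 %); the rare
subcommunity is the more phylogenetically diverse one (PD 58.2 vs 39.2
despite equal set sizes); and the null model flags the abundant
subcommunity — planted in one clade by the generator — as significantly
clustered (SES −3.51 < −2) while the rare one is indistinguishable from
chance. That is the qualitative fingerprint of a filtered/competitive
abundant core over a stochastic rare biosphere.

The same analysis runs from the shell:

```sh
rarephylo simulate --n-taxa 400 --core-size 12 --abundant-placement clade \
    --seed 42 --out-table table.tsv --out-tree tree.nwk
rarephylo core table.tsv --out intersections.tsv
rarephylo nmdpsc table.tsv tree.nwk --replicates 1000 --seed 7 --out ses.tsv
rarephylo run --config config.toml     # full pipeline, manifest, presets 16s/its
```

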