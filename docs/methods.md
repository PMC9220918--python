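# Methods

`rarephylo` analyses the diversity of an amplicon (ASV) community sampled at
several points along a short spatial transect — the motivating system is a
hypersaline elastic microbial mat sampled at ten points over 1.5 m — and asks
two questions: how is diversity distributed between a small abundant core and
a long rare tail, and is either subcommunity more phylogenetically clustered
than chance would produce?

## The analysis pipeline

Stages, in order, each exposed as a library function and a CLI subcommand:

1. **Rarefaction.** Every sample is subsampled without replacement to a common
   depth (one multivariate-hypergeometric draw per sample, seeded). This is
   the exact meaning of "rarefied to N reads": the output is a uniformly
   random subset of the sample's physical reads. Depth is a free parameter;
   the two presets (760,000 reads for a 16S-style library, 164,820 for an
   ITS-style library) mirror the depths used for the mat libraries. Samples
   below the target depth either abort the run (default) or are dropped with
   a warning.
2. **Alpha diversity.** Observed richness (ASVs with count > 0) and Shannon
   entropy H = −Σ pᵢ log pᵢ. The log base is an explicit, recorded parameter
   because the two library presets were historically processed by toolchains
   with different conventions (base 2 vs base e); mixing bases silently makes
   Shannon values incomparable.
3. **Beta diversity.** Bray–Curtis (abundance-weighted) and Jaccard-1
   (presence/absence) distances, both in [0, 1], followed by a UPGMA
   dendrogram. UPGMA uses the textbook average-linkage agglomeration with a
   deterministic tie-break (among minimal-distance pairs, the pair whose
   clusters were created first); node heights are half the merge distance so
   cophenetic distances reproduce the linkage distances.
4. **Transect geography and Mantel.** Geographic distance is |xᵢ − xⱼ| along
   the transect. The Mantel statistic is the Pearson (optionally Spearman)
   correlation of the two strictly-upper-triangle vectors; significance is
   one-sided (greater), p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1) over
   seeded joint row/column permutations of the second matrix. When n! does
   not exceed the requested permutation count the test switches to exact
   enumeration of all n! relabellings.
5. **Shared core.** Every ASV is assigned to the exact subset of samples in
   which it occurs (the table behind an UpSet plot); the core is the
   all-samples subset, summarised as a count and a fraction of total reads.
6. **Rare/abundant partitioning.** Two rules. The per-site quartile rule
   ranks each sample's nonzero counts and takes rare = counts ≤ Q1,
   abundant = counts ≥ Q3, with nearest-rank quartiles so thresholds are
   integer read counts (zero-count ASVs are not part of a site's
   distribution). Interpolating quantile estimators are available behind a
   flag for sensitivity analysis; at integer counts the differences are at
   the level of single ties. An optional balancing step subsamples the larger
   set to the smaller one's size (seeded) when exactly equal set sizes are
   wanted. The whole-table relative-abundance rule calls a unit (ASV or
   genus) abundant when its share of all reads exceeds a threshold, 1 % by
   default; "rare biosphere" is the complement.
7. **Phylogenetic diversity.** Faith's PD of a taxon set is the total branch
   length of the minimal subtree connecting the set, extended to the root by
   default (under that convention the PD of a single taxon is its root-to-tip
   distance; the flag is recorded in the output since PD magnitudes are only
   comparable within one convention). Phylogenetic Species Clustering is
   computed from the phylogenetic correlation matrix: for tips i, j the
   shared root-to-tip path length V_ij (the depth of their most recent common
   ancestor), normalised to C_ij = V_ij/√(V_ii·V_jj), and
   PSC = 1 − meanᵢ maxⱼ≠ᵢ C_ij. PSC near 0 means every taxon in the set has
   a close relative in the set (clustering); a star phylogeny gives 1. The
   correlation form assumes nothing about ultrametricity, which matters
   because amplicon trees are not ultrametric. Both metrics are
   presence-based; a sample's taxon set is its ASVs with count > 0. ASVs
   absent from the tree are excluded from the phylogenetic metrics only,
   with a logged count.
8. **Null model and SES.** The richness null model randomizes each sample
   independently: its multiset of nonzero counts is reassigned to a uniformly
   random same-size subset of the full ASV pool, conserving per-sample
   richness and totals ("total sample diversity") while scrambling taxon
   identities. For each sample × subcommunity × metric, the standardized
   effect size is (observed − null mean)/null sd over 1,000 replicates by
   default (sd with ddof = 1). SES < −2 is labelled clustered, > +2
   overdispersed, anything in between — boundaries included — null. The
   rare/abundant subsets are re-derived inside every replicate from the
   randomized counts, keeping the null internally consistent; a
   `freeze_subsets` flag instead holds the observed subset sizes fixed and
   fills them by count rank, for sensitivity analysis. A constant null
   distribution (possible for tiny or saturated communities) yields a
   flagged, non-fatal degenerate result labelled null.

Orchestration (`rarephylo run --config cfg.toml`) executes all stages from a
TOML config, derives every stage's random stream from one seed via
`numpy.random.SeedSequence` substreams, and writes a manifest that reproduces
the run bit for bit.

## The synthetic-data generator

The generator produces the community architecture the pipeline assumes so
that every stage can be exercised without any download. Mechanism: a Yule
(pure-birth) tree with exponential waiting times; a small core of taxa chosen
either uniformly at random or as one clade (`abundant_placement="clade"`,
the knob that makes the abundant subcommunity phylogenetically clustered);
lognormal relative-abundance profiles for core (σ = 1) and tail
(σ = `abundance_shape`); independent per-sample Bernoulli occupancy for rare
taxa; and one multinomial draw per sample at the stated depth, with the core
rescaled so its expected read share equals `core_read_fraction` exactly.

Defaults are the mat study conditions: 10 samples; 2,000 taxa (the real 16S
library held ~6,000; two thousand keeps every desk-scale experiment fast
while staying in the "thousands" regime); depth 250,000 reads (preserving the
~125 reads-per-ASV ratio of the real rarefaction depth at the scaled taxon
count, which is what the integer quartile thresholds are sensitive to); core
size 60 (3 % of taxa) at `core_read_fraction` 0.725; `occupancy_rare` 0.2
(most rare ASVs occur at one to three of ten sites); tail σ = 2.0, a
canonical long-tailed species-abundance shape. `abundant_placement` defaults
to `random` — the neutral setting — because recovery experiments must be able
to generate both clustered and unclustered truth; mat-emulating runs set
`clade`, since the mat's abundant subcommunity is observed to be clustered.

What the generator does **not** emulate: sequencing error and chimeras,
taxon–taxon interactions, spatial autocorrelation of occupancy along the
transect (occupancy is i.i.d. across samples, so Mantel tests on synthetic
data are expected to be null), compositional coupling between core and tail
beyond the fixed read-share split, and taxonomy. Passing tests therefore
demonstrate the correctness and calibration of the estimators under a
known-truth community of realistic shape — not robustness to denoising
artifacts or real spatial structure.

## Numerical choices

- Counts are exact integers end to end; ratios appear only where a metric
  demands them. Quartile thresholds are reported as integers (nearest-rank).
- `TreeIndex` precomputes, once per tree, the edge-incidence matrix and the
  shared-path (MRCA-depth) matrix; PD and PSC for any subset then cost an
  array slice, which is what makes 1,000-replicate nulls over thousands of
  taxa practical on one CPU.
- Rarefaction uses `numpy`'s exact multivariate-hypergeometric sampler, one
  draw per sample.
- A null metric distribution with zero range is treated as sd = 0 (the
  floating-point sd of bit-identical values is round-off, ~1e-17) and flagged
  degenerate rather than producing a huge spurious SES.
- Mantel tie handling: permuted r counts as ≥ observed within 1e-12, so
  automorphic relabellings are counted exactly once each in the exhaustive
  mode.
- UPGMA and the tree simulator break all ties deterministically, and every
  random stage takes a seed or `Generator`, so identical configs reproduce
  identical bytes.

## Problem sizes in the shipped experiments

The test suite and the acceptance script run desk-scale versions of the
study: metric oracles on 8-tip trees against brute-force path enumeration;
null calibration on 200 samples × 300 taxa × 1,000 replicates; recovery on
25 (tests) or 10 (script) replicate datasets of 10 samples × 500 taxa with a
15-taxon clade core; and the study-condition snapshot at the full generator
defaults. These sizes are the package's chosen trade-off between Monte-Carlo
resolution and a comfortable single-CPU run; all of them are parameters, not
constants.

## Known limitations

- The quartile rule needs ≥ 4 nonzero ASVs per sample and degenerates when
  Q1 = Q3 (flagged, not fatal).
- PSC requires ≥ 2 taxa and a nonzero root-to-tip distance for every taxon.
- The published mat values that depend on the deposited supplementary tables
  (e.g. the 183-ASV core, the 6,063-ASV total, Mantel r = 0.3224) can only be
  reproduced after downloading those tables; the repository ships no real
  data. The corresponding checks live in `tests/test_acceptance.py` and fail
  with a clear message until the files are placed under `data/supplementary/`.
- The null model is the richness null only; swap/frequency-preserving nulls
  and phylogeny-shuffling nulls are out of scope, as are ordination, UniFrac,
  MPD/MNTD-family metrics and any figure rendering.
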