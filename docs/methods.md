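# Methods

## Model and pipeline

`phylopd` treats a metagenomic sample as a set of fragmentary amino-acid
reads, each pre-assigned to one single-copy marker gene family and already
aligned to that family's columns. The stages are:

1. **Scaffold.** Per-family reference alignments over a shared genome set
   are concatenated into one matrix with half-open, contiguous column
   partitions (one per family; 0-based coordinates). A read is *tiled* into
   this coordinate system: its family's columns carry the read, every other
   column is missing data. Taxa absent from a family get all-gap columns
   there. Reads with fewer than 50 unmasked amino acids are dropped
   (`length_filter`); gaps, `X` and lowercase letters all count as masked —
   both common masking conventions are treated identically, and all three
   are missing data in the likelihood.

2. **Likelihood.** A reversible amino-acid CTMC with the published WAG
   exchangeabilities and stationary frequencies (no empirical `+F`
   re-estimation), rate variation across sites by K = 4 discrete gamma
   categories (equal-probability bins, category rate = bin mean, mean one),
   and rate variation across families by per-partition gamma shapes and
   rate multipliers constrained to mean one. The total log-likelihood is
   the sum of per-partition Felsenstein-pruning log-likelihoods on the
   fixed reference tree; per-column rescaling guards against underflow on
   large trees. Missing data contributes a partial-likelihood vector of
   ones, so an all-missing column contributes exactly zero.

   Shapes and multipliers are fitted on the fixed tree by bounded 1-D
   optimisation per coordinate. The partitioned optimum is searched
   starting from the single-shape (unpartitioned) fit, with multiplier
   updates restricted to the mean-one simplex via a feasible line search;
   the partitioned log-likelihood therefore can never fall below the
   unpartitioned one, as required for the nested likelihood-ratio test
   (statistic 2·ΔlogL, χ² with 2(P−1) degrees of freedom for P families:
   P shapes plus P−1 free multipliers vs one global shape).

3. **Placement.** Each query is attached in turn at the *midpoint* of every
   reference edge; only the pendant branch length is optimised (bounded
   Brent search in [1e−8, 5] substitutions/site). Reference branch lengths
   are never re-estimated. Ties in edge likelihood go to the smallest edge
   number, so results are deterministic. The engine precomputes downward
   and outward conditional-likelihood vectors per partition, which makes
   one candidate attachment cost only the pendant transition term; the
   insertion likelihood equals a full pruning pass on the physically
   grafted tree (checked against a grid-search oracle in the tests).
   Columns the query does not cover contribute a placement-independent
   constant, so reported placement log-likelihoods are full-alignment
   log-likelihoods of the grafted tree.

   Uncertainty: a phylogenetic bootstrap resamples, with replacement, the
   query's non-missing columns only (resampling the full concatenated row
   would mostly redraw missing data for a single-family fragment) and
   re-places each resample; the per-edge selection frequencies form the
   placement distribution. Replicate grafted trees draw each read's edge
   independently from its distribution (100 replicates by default), using
   the ML pendant length for the drawn edge. Every random stream is keyed
   by (global seed, read id), so results are independent of query order
   and parallelisation.

4. **Query trees and diversity.** Reference leaves are pruned; degree-2
   nodes are collapsed with branch lengths summed, so query–query patristic
   distances are preserved exactly. Per sample, MPD is the mean pairwise
   patristic distance among its reads; SES_MPD standardizes it against
   999 (default) random draws of the same number of reads from the pool of
   all reads present in the analysed tree, drawn without replacement. Each
   bootstrap replicate tree is standardized against its own leaf set. A
   degenerate null (sd = 0, e.g. a star tree) is reported as SES = 0 with
   an explicit flag rather than NaN. Null streams are keyed by (seed,
   sample, tree index). Reads enter as individuals, so relative abundance
   affects SES_MPD with no explicit weighting.

5. **Filters.** Besides the 50-residue length filter, reads whose pendant
   branch exceeds the 95th percentile (linear interpolation) of all pendant
   lengths can be dropped (`long_branch_filter`) as likely rogue or highly
   divergent sequences.

6. **OTUs and phylotyping.** OTU binning is agglomerative complete linkage
   on the tree-derived distances: clusters merge while their maximum
   pairwise distance stays within the cutoff; a similarity cutoff s maps to
   distance 1 − s (95% → 0.05, 99% → 0.01). Richness is the number of OTUs
   represented in a sample. Phylotyping gives each reference edge the
   longest ranked-lineage prefix shared by the reference leaves distal to
   it (distal relative to the fixed canonical root); a read's support at a
   rank is the total bootstrap frequency over edges agreeing with its
   ML-edge lineage at that rank, its assignment is the deepest rank with
   support strictly above 0.70 (exactly 0.70 does not qualify), and
   assignments that resolve no deeper than the root rank are flagged
   unusable and excluded from composition tables, with the excluded
   fraction reported. The nearest reference genome is the leaf at minimal
   patristic distance from the ML attachment point, ties broken
   lexicographically.

7. **Gradient statistics.** Linear and quadratic OLS regressions of a
   per-sample diversity value on log10(depth/m), compared by AIC under the
   Gaussian maximum-likelihood convention with the residual variance
   counted as a parameter (k = 3 and 4); ΔAIC = AIC_linear −
   AIC_quadratic, so positive values favour the unimodal model. SES values
   across bootstrap trees are tested against zero with a two-sided
   one-sample t-test; zero-variance inputs return a degenerate flag.

## Tree representation

Trees are canonicalized on construction: a degree-2 seed node (an artifact
of rooted serialization) is collapsed, the tree is rooted at the internal
node adjacent to the lexicographically smallest leaf, children are ordered
by smallest descendant label, and edges are numbered in preorder. The model
is reversible, so the likelihood does not depend on this choice; what it
buys is a unique canonical form per unrooted topology and edge numbers that
are stable across runs and serialisation round-trips — the bootstrap
aggregation and jplace output rely on that. Newick files carry the edge
numbers as jplace-style `{n}` annotations; branch lengths are required
(zero allowed), duplicate leaf labels rejected.

## Synthetic data generator

`simdata` emulates the pipeline's inputs at configurable scale: a
birth–death reference tree (pure birth by default), per-family alignments
evolved under WAG+Γ (root states from the stationary distribution,
per-site rates drawn from the discrete gamma categories and shared between
reference and query simulation), a ranked taxonomy derived from tree
clades, and fragmentary reads of known origin. Because the simulator stops
at the n-th speciation, the newest cherry would carry zero-length pendants
(identical genomes); the present is instead sampled uniformly within the
waiting interval to the next event. Branch lengths are rescaled so the mean
root-to-tip path equals a configured depth (0.6 substitutions/site by
default, a realistic breadth for a bacterial marker phylogeny).

Reads are contiguous windows (100 residues by default, matching short
fragment data) of a fresh tip evolved off a known source taxon (pendant
0.05 substitutions/site by default), so every read has a recorded true
placement edge. Sample composition is controlled by a clustering parameter
c ∈ [−1, 1]: with probability c a clustered sample draws its read from its
focal clade; overdispersed samples (c < 0) pick, with probability |c|, the
taxon maximizing the minimum distance to the taxa already drawn; c = 0 is
uniform. Focal clades are mutually disjoint minority clades (between 1/8
and 1/4 of the taxa) assigned to samples without replacement — distinct
habitats select distinct clades; if clustered samples shared one clade the
pooled null itself would be clustered and the SES signal would vanish by
construction rather than by biology. Depths are log-spaced over 10–4000 m
with 7 samples by default, mirroring an oceanic water-column study design;
the default 71 reads per sample matches the scale of marker-gene yields
from early shotgun datasets.

The generator simulates aligned data without indels (the method consumes
pre-aligned reads) and without sequencing error or copy-number variation;
passing tests therefore demonstrate correctness of the statistical
machinery on data matching the model, not robustness to alignment error,
contamination, or HGT in real metagenomes.

## Validation experiment sizes

The acceptance experiments use desk-scale study conditions chosen once:
placement accuracy on a 32-leaf reference with 100-residue reads
(100 reads); self-placement on 8-leaf references with 250 informative
columns (20 trials, source rows required to be unique so the true pendant
edge is well defined); null calibration over 200 random subsets of a
40-leaf pool with 199 null draws; sign recovery over 40 end-to-end runs
(24 taxa, 2 families × 150 columns, 3 samples × 12 reads, c = ±0.9,
199 null draws). Likelihood and placement kernels are checked against
exhaustive-enumeration and grid-search oracles on ≤5-leaf fixtures.

## Numerical choices and limitations

- Transition matrices come from a symmetrized eigendecomposition computed
  once per model; tiny negative entries from round-off are clipped at zero.
- Pendant optimisation tolerance is 1e−6; placement ties are resolved by
  edge number, which matters only for exactly symmetric data.
- The attachment point is fixed at the edge midpoint; only the pendant
  length is free. This mirrors the single-sequence insertion heuristic the
  placement literature describes; optimising the attachment position along
  the edge is out of scope.
- Only MPD-based SES is implemented (no MNTD/NRI/NTI, no UniFrac), OTU
  binning is complete linkage only, and the reference tree is always taken
  as given — there is no tree search.
- `fit_gamma_shapes` is a profile/coordinate scheme, not a joint Newton
  optimisation; with strongly correlated shape and multiplier it can stop
  within ~1e−3 log-likelihood units of the constrained optimum (always on
  the feasible side of the nesting inequality).
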