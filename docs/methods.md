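# Methods

This note documents the models and procedures implemented in `orthodyn`,
the defaults they run with, and what the synthetic benchmark does and does
not establish.

## Data model

The central object is the copy-number matrix: nonnegative integer counts,
gene families × species, read from an OrthoFinder-style `GeneCount` table
(the trailing `Total` column is dropped). Species must also appear as
tips of a rooted tree with branch lengths and carry exactly one
taxonomic-order label. Mismatches between matrix and tree species are an
error by default; an explicit `intersect` policy prunes both, because
silent intersection hides upstream data bugs.

## Coverage and family filtering

Coverage of a family in an order is the fraction of the order's species
with at least one copy; overall coverage is the unweighted mean over
orders, so small orders count as much as large ones (a deliberate guard
against a single species-rich order dominating). Thresholds are
inclusive: average coverage ≥ 0.1 retains a family for the weighted-size
and fold-change stages, ≥ 0.5 defines the conserved set used by the
presence PCA, and ≥ 0.98 within a single order (with zero coverage
elsewhere) defines an orphan candidate. The two analysis thresholds
correspond to the two modes typically seen in the bimodal density of
average coverage in clade-scale datasets.

## Weighted average gene family size

For species *s* over the *n* retained families,
`WAS(s) = (Σ_i copy_is · w_i / n) · mean_max` with `w_i = 1/max_i`.
`max_i` is the maximum copy number of family *i* over **all species in
the matrix** — weights are global constants, never recomputed for a
species subset, so per-species values remain comparable. `mean_max` is
the mean of the per-family denominators actually used. Alternative
weightings: `inv_p95_max` drops the top ⌈5%⌉ of a family's copy values
and uses the next highest; `inv_mean` and `inv_median` use the mean and
median over all species including zeros. Families with an all-zero row
are a hard error (they should have been coverage-filtered); a nonzero
family whose p95/median denominator is zero is dropped with a warning.
Species with zero copies in every retained family are reported as 0 with
a warning rather than dropped.

## Dip test and lineage splitting

The dip statistic is the sup-norm distance from the empirical CDF to the
nearest unimodal CDF (convex, then concave, with an atom allowed at the
mode). It is computed by the classical greatest-convex-minorant /
least-concave-majorant fixed-point algorithm; the test suite checks it to
1e-9 against a linear-programming oracle that minimizes the fitting band
directly over all mode positions.

P-values are Monte-Carlo: the observed dip is ranked among the dips of
`n_boot = 2000` uniform(0,1) samples of the same size,
`p = (1 + #{null ≥ obs}) / (n_boot + 1)`. Uniform samples are the
canonical least-favourable unimodal null; Monte-Carlo calibration (under
a fixed internal seed) was chosen over interpolated tables for exact
reproducibility across platforms. Null tables are cached per sample size.

Per order, the splitting gate is dip p ≤ α (default 0.05) on the
root-to-tip rates; the dip p on weighted sizes is recorded alongside, and
a `force_split` override exists for orders where the analyst wants a
split despite a non-significant dip (small orders lack power). Orders
whose rate range is below 1e-9 relative are treated as clock-like and
never split: the dip is scale-invariant, so spacing-level floating-point
noise in an ultrametric clade would otherwise masquerade as
multimodality.

DBSCAN runs on the 1-D rates with `min_pts = 3` and
`eps = 3 × median k-NN distance` (k = min_pts), falling back to 5% of the
data range when the k-NN distances collapse to zero (exactly repeated
rates). The highest-mean cluster is the FEL; remaining clustered tips are
SEL; unclustered tips are noise. The split is invariant to tip
relabelling and to adding a constant to all rates.

## Fold change

Categories are functions of the two lineage means only: loss (FEL mean
0), contraction (fc < 0.67), stable, expansion (fc > 1.5), gain (SEL mean
0), undefined (both 0). Boundary values 0.67 and 1.5 are stable — the
conventional cutoffs are strict, and note they are not exact reciprocals
(1/1.5 = 0.6667), so label-swapping has a narrow legitimate asymmetry
band. Significance is a two-sample KS test between the family's
per-species copy numbers in the FEL and SEL samples — the only two
per-family samples available, which fixes an ambiguity in how "the
significance of expansions" can be tested. Exact KS p-values are used
when min(n, m) ≤ 12, the asymptotic form otherwise. Bonferroni uses m =
families actually tested (at least one nonzero mean), and `significant`
additionally requires a directional category.

## Presence PCA and drivers

Counts are binarized (> 0 → 1), family columns centered, no variance
scaling (scaling binary columns upweights rare families; a `scale` flag
exists). The SVD sign is fixed by making the largest-|entry| loading
coordinate positive, so outputs are platform-stable. PCoA on Jaccard or
Hamming distances is provided as a cross-check; on block-structured data
both separate the blocks on their first axis.

Driver identification ranks families by loading (both directions), takes
prefix means of the presence rows via running sums, and Spearman-
correlates each prefix's per-species mean presence with the component
coordinates. Prefixes with zero variance (tie-constant presence) are
skipped. The optimum maximizes |rho|; ties prefer the smaller prefix,
then the descending direction. The signed rho is reported: a negative
value means high-coordinate species carry fewer of the driver families.

## Orphans and their origins

Gene-level calls: duplication/speciation if any in-dataset hit to a
species outside the host order passes e-value < 1e-5, bit score > 50,
and identity > 40%; otherwise horizontal transfer if any external-
database hit passes the first two thresholds (the identity cutoff applies
only to the in-dataset comparison); otherwise de novo. Family-level
origin is the majority vote over the family's genes with ties resolved to
de novo — the most conservative label — and the per-gene calls are kept
so other aggregation rules can be applied downstream.

## Trees, contrasts, rates

Phylogenetically independent contrasts follow the standard pruning
recursion with branch-length adjustment `b' = b + b_l·b_r/(b_l+b_r)`;
polytomies and zero-length cherries are errors. The contrast correlation
uses Spearman's rho (large-sample p by default; full permutation
enumeration available for ≤ 10 contrast pairs) and a through-origin
slope `Σc_x c_y / Σc_x²`, since contrasts have arbitrary sign.

DR follows the inverse equal-splits construction. Group comparisons use
the unpaired two-sided Mann–Whitney rank-sum test — chosen over the
signed-rank test because FEL/SEL groups have unequal sizes — exact when
both samples are tie-free and no larger than 20, normal approximation
with tie correction otherwise; a `paired` flag provides the signed-rank
variant. ANI divides by intron-containing genes (an `all_genes` variant
exists); species with no intron-containing genes report ANI as missing.

Fitch parsimony returns bottom-up state sets (intersection else union),
so a node's set depends on its subtree only; the ambiguous set {0, 1}
counts as "present" for the inclusion filter — conservative retention —
with a flag to flip the policy.

## Synthetic benchmark

`simulate_tree` grafts per-order pure-birth (Yule) clades onto a short
pectinate backbone (total depth 1, backbone step 0.02, stem 0.05), which
guarantees monophyletic orders without rejection sampling and an
ultrametric tree when the rate multiplier is 1. The planted FEL clade is
the internal node of the designated order whose tip count is closest to
`fel_fraction × tips_per_order` (ties to the first in preorder); all its
edges including the stem are scaled by `rate_multiplier` (default 2).
Because only edges inside the clade are scaled, the FEL/SEL root-to-tip
ratio is below the multiplier — about 1.7 on average under defaults.

Default study conditions: 12 orders × 32 tips, 1000 families in blocks
(core 500, contracted 60, lost 40, gained 30, driver 100, orphan 20, rare
250); Poisson counts (negative binomial with mean/dispersion
parameterization available; a `fixed` noiseless mode supports exact
planted-block checks); block means 2 / 5 / 3 / 2 / 1 / 2 / 1; contraction
factor 0.4 (so contracted families sit at fc ≈ 0.4, clearly below the
0.67 cutoff but not degenerate); driver families present with
probability 0.95 in the first ⌈60%⌉ of orders and 0.02 elsewhere (so
their average coverage clears the 0.5 conserved threshold); rare
families in a fixed 6% of species (below the 0.1 threshold by
construction); orphans in every tip of the last order. Intron counts are
Poisson with mean 0.2 in FEL tips vs 0.5 elsewhere at 100 genes/species —
intron-poor genomes with further streamlining in the FEL. All draws flow
from one seed through named substreams, so datasets are reproducible
byte for byte.

What the generator does **not** emulate: phylogenetic autocorrelation of
counts along the tree (counts are drawn per block, not evolved by a
birth–death process), annotation noise, order-size imbalance, incomplete
genomes, and gradual rate variation (rates are clock-like outside the
planted clade). Passing the planted-truth suite therefore shows the
detectors are correct and calibrated under their stated assumptions, not
that they are robust to every artefact of real genome data.

## Numerical and scale choices

Exact enumeration is used wherever cheap (KS and rank-sum at small n,
permutation Spearman at ≤ 10 pairs, hypergeometric tails); asymptotic
forms elsewhere. Output tables are written with `%.10g` floats and
canonical row order, and the pipeline report rounds to 10 decimals, so
repeated runs are byte-identical. Test and acceptance runs use reduced
problem sizes (6 orders × 12 tips, ~250 families for most checks; the
full 12 × 32 defaults for recovery metrics; 20–100 replicate seeds for
rates), which keeps the whole suite in the tens of seconds while leaving
every statistical property measurable.

## Known limitations

The per-branch change tables consumed by `net_change_tally` must come
from an external ancestral-reconstruction tool; the package does not fit
birth–death models. The dip test's Monte-Carlo p is conditional on the
uniform null; for very small orders (< ~8 tips) it has little power and
the `force_split` escape hatch is the intended workflow. Driver
identification assumes the component of interest reflects a presence
gradient; components dominated by a single aberrant species will yield
small, uninformative prefixes.
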