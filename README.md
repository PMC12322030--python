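# orthodyn

Analysis of gene-family (orthogroup) copy-number evolution across a
phylogeny: which lineages are shedding or gaining gene families, which
families drive the differences, and how that relates to lineage-level
rates of molecular evolution and speciation.

The package is aimed at comparative genomicists working with an
OrthoFinder-style gene-count table (families × species), a rooted species
tree with branch lengths, and a species → taxonomic-order map — the
typical output of a large clade-scale genome project.

## What it computes

**Coverage filtering.** Coverage of family *i* in order *g* is the
fraction of *g*'s species with ≥ 1 copy; the family's overall coverage is
the unweighted mean over orders. Families below a threshold (0.1 relaxed,
0.5 conserved) are species-specific and handled separately.

**Weighted average gene family size.** For species *s* over *n* families,

```
WAS(s) = ( Σ_i copy_is · w_i / n ) · mean_max ,   w_i = 1 / max_i
```

where `max_i` is family *i*'s maximum copy number over all species and
`mean_max` the mean of those maxima. Each family counts equally no matter
how large it can get; the `mean_max` factor restores the scale of a plain
average (if all maxima are equal, WAS is exactly the species' mean copy
number). Alternative weightings (95th-percentile max, mean, median) are
provided.

**Faster/slower-evolving lineages (FEL/SEL).** Root-to-tip branch-length
sums are the per-tip evolutionary rates. Orders whose rate distribution
rejects unimodality (Hartigan–Hartigan dip test; Monte-Carlo p against
uniform null samples) are split by one-dimensional DBSCAN; the cluster
with the higher mean rate is the FEL.

**Fold-change dynamics.** Per family, fc = mean FEL copies / mean SEL
copies: loss (0), contraction (< 0.67), stable, expansion (> 1.5), gain
(SEL mean 0). Significance is a per-family two-sample Kolmogorov–Smirnov
test (exact for small lineages) with Bonferroni correction.

**Presence/absence structure.** PCA of the column-centered binary
presence matrix (PCoA on Jaccard/Hamming distances as a cross-check);
DBSCAN clustering of the score plane; and driver-family identification:
rank families by component loading, and find the prefix whose cumulative
mean presence best correlates (Spearman) with the species' component
coordinates.

**Orphan families.** Families in ≥ 98% of one order's species and absent
elsewhere, classified from staged homology-hit thresholds into
duplication/speciation (in-dataset hit outside the host order: e-value
< 1e-5, bit score > 50, identity > 40%), putative horizontal transfer
(external-database hit: two thresholds), or putative de novo origin.

**Rates and introns.** DR tip speciation rates (inverse equal-splits:
`ES_i = Σ_j l_j / 2^(j-1)`, `DR_i = 1/ES_i`), phylogenetically
independent contrasts with Spearman correlation and through-origin
slope, rank-sum group comparisons, per-species intron summaries
(TNI/ANI), Fitch-parsimony ancestral presence, and birth–death-input
inclusion filters.

**Synthetic data with planted truth.** A first-class generator simulates
an ultrametric pure-birth species tree with monophyletic orders, one
planted FEL clade at an elevated rate, and a count matrix of labelled
family blocks (core / contracted / lost / gained / driver / orphan /
rare), plus homology-hit and intron tables realizing planted orphan
origins. Every detector is validated by recovering this ground truth.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/03_detect_lineages.py` prints:

```
O01: dip p(rates) = 0.0005  SPLIT  fel=15 sel=17
O02: dip p(rates) = 1.0000
...
O12: dip p(rates) = 1.0000
planted FEL tips recovered exactly: True
```

Only the order carrying the planted 2× rate shift rejects unimodality,
and its high-rate cluster coincides exactly with the planted clade.
`examples/04_fold_change.py` then classifies the family dynamics of that
order:

```
planted        lost_in_fel recovered as        loss: recall = 1.00
planted  contracted_in_fel recovered as contraction: recall = 1.00
planted      gained_in_fel recovered as        gain: recall = 1.00
88 families significant after Bonferroni (KS, alpha = 0.05)
```

and `examples/05_presence_pca_drivers.py` identifies the families that
drive the species' positions on PC1:

```
driver scan: k = 100 families (descending loadings), rho = 0.984
Jaccard overlap with the planted driver block: 1.00
```

A |rho| near 1 means PC1 placement is almost fully explained by how many
driver families a species carries. The whole analysis also runs from one
config: `python examples/08_full_pipeline.py`, or from the shell:

```
orthodyn simulate --seed 1 --out-dir data/
orthodyn run --config pipeline.yaml --seed 1
```

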