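# Methods

## Scope and model

`copynorm` treats 16S rRNA gene copy number (GCN) as a continuous trait
evolving on a rooted phylogeny under Brownian motion. Three layers build on
that model:

1. **Curation** of the empirical trait values attached to sequenced
   genomes (catalog records cross-checked against independent rRNA gene
   predictors, assembly contiguity and within-species strain variation).
2. **Estimation** of the trait for every internal node, unsequenced tip and
   named taxon of the tree (independent contrasts plus rerooting).
3. **Correction** of amplicon community profiles and qPCR template counts
   using the estimated copy numbers, with a count-level mock community
   simulator and distance/rank statistics to validate the correction.

## Curation rules

A catalog GCN is *suspicious* when any of four criteria fire: value outside
[1, 15]; average contig length < 200 kbp; disagreement with either of two
independent rRNA gene predictors; or deviation from the species mean x̄
beyond 1.2·f(x̄), where f(x) = 0.105x + 0.720 is the empirical upper bound
on within-species strain deviation. Resolution ignores the catalog value
and tries, in order: (1) a predictor value consistent with the strain
database (consistency reuses the same 1.2·f(x̄) bound — the source text
does not define it, and keeping one notion of agreement avoids a second
tunable); (2) the predictors' shared value when the species is absent from
the strain database but the scaffold exceeds 200 kbp; (3) the 5S/23S count
when the 16S record is zero and the other count matches the strain-database
mean. If nothing fires, genes shorter than 1,220 bp (potentially truncated
calls) are dropped from the predicted gene set and the rules rerun once;
one pass suffices because the removal is idempotent. Unresolvable records
are removed, never guessed. The outlier criterion applies to the catalog
value only, not to predictor values, since the bound anchors on the
catalog/strain-database average.

## Trait estimation

**PIC recursion.** Post-order over the tree; daughters are combined by
inverse-branch-length weights and the parent branch is lengthened by
1/Σ(1/v_i). Multifurcations use the generalized weighted mean directly
rather than an arbitrary binary resolution, which keeps the estimate
invariant to child order. Zero-length or missing branch lengths are
replaced by ε = 10⁻⁶ × (mean positive branch length) so the weights stay
finite; collapsing such edges into polytopies would instead change the
topology. At the root the recursion returns the Brownian-motion
maximum-likelihood root state — the property the test suite checks against
an independent GLS oracle on random trees.

**Tip prediction by rerooting.** For each trait-less tip the tree is pruned
to the empirical tips plus the query, rerooted at the query's attachment
node, the query removed, and the PIC root estimate taken as the prediction.
Because Brownian motion is reversible, this equals the GLS conditional
expectation of the tip value, and is insensitive to degree-2 nodes created
or removed along the way; the query's pendant branch length adds only
zero-mean noise and does not affect the prediction. Prediction iterates
per tip on the pruned backbone — simple and adequate at the problem sizes
the package targets; incremental rerooting would only matter for trees with
millions of tips.

**Weights and taxon aggregation.** Every estimate carries a weight equal to
the number of empirical tip values underlying it (a tip that averaged k
genomes contributes k). When several nodes map to one taxon, reconstructed
estimates are discarded if any empirical value is present, and the
survivors are combined by weighted mean. The full lookup computes ancestral
states on the complete tree using empirical plus predicted tip values, so
taxa whose nodes lose all empirical descendants during pruning still
receive an estimate. Estimates stay fractional; no rounding.

## Pagel's lambda

The Brownian tip covariance C (C_ij = root-to-MRCA path length) has its
off-diagonal entries scaled by λ; the root state and rate σ² are profiled
out analytically by GLS, leaving a one-dimensional likelihood maximized on
[0, 1] by bounded scalar optimization (tolerance 10⁻⁶), with both endpoints
checked explicitly. λ beyond 1 is admissible in principle but not used. On
a star phylogeny λ has no effect on the likelihood; the fit flags this
degeneracy (`degenerate=True`) and reports λ̂ = 0 by convention. The
likelihood-ratio statistic 2Δℓ is referred to χ²(1); at the λ = 0 boundary
this is conservative. A helper builds a uniform-branch-length (1.0) tree
from taxonomic strings so the statistic can also be computed on a taxonomy.
λ is fitted to empirical tip values only, never to reconstructed estimates.

## Correction

The corrected relative abundance is r_i = (c_i/g_i)·100/Σ_j(c_j/g_j). The
community-average GCN is defined as the read-weighted mean
ḡ = Σc_i/Σ(c_i/g_i): this is the unique definition for which (templates)/ḡ
equals the genome count exactly when reads ∝ genomes × GCN, which is the
stated purpose of the qPCR division — an exactly testable identity rather
than a convention. Unassigned OTUs (and OTUs whose taxonomy misses the
lookup, logged with a warning) receive g_i = ḡ, computed in a single pass
over the assigned OTUs; assigning any constant preserves the assigned OTUs'
pairwise ratios, and with this particular constant the reported per-sample
average is unchanged by the imputation. Taxonomic-string lookups fall back
by stripping the deepest rank until a prefix matches, mirroring the
phylogeny's nesting. Rarefaction draws multivariate-hypergeometric
subsamples (without replacement) at the requested depth and averages the
repetitions; shallower samples pass through unchanged with a warning.

Formats: plain tabular, JSON BIOM v1.0 (sparse and dense) and QIIME
classic, autodetected from leading bytes; output reuses the input dialect.
Legacy GAAS/UniFrac dialects are out of scope.

## Mock community simulator

Communities follow a power-law rank-abundance curve p(r) ∝ r^(−a); the
exponent is solved by bisection on a ∈ [0, 50] so that the top rank holds a
chosen fraction (default 20%, the design the validation study uses), to
|Σr^(−a)·top − 1| < 10⁻¹⁰. Member genomes are drawn without replacement
from a seeded pool whose GCNs span the empirical range 1–15 and genome
lengths 1.5–9 Mbp. Sequencing is simulated at the count level: one
multinomial draw per sample with probabilities ∝ cells × GCN (amplicon) or
∝ cells × genome length (shotgun). Read-level artifacts — sequencing
errors, chimeras, primer mismatch, OTU-picking noise — are deliberately not
modelled: the correction acts on counts, so passing the mock benchmark
shows the estimator and formula remove the copy-number bias, not that the
pipeline is robust to upstream read-processing errors on real data. The
default validation grid uses 10 replicates per richness group (10, 100,
1000 species) at depth 10⁴ reads per sample, and 30 replicates for the
amplicon-vs-shotgun comparison — sizes chosen so the whole benchmark runs
in seconds while the rank tests remain decisive.

## Validation statistics

Profile distances follow the transform order: square root of the percent
abundances, renormalize to 100%, Euclidean distance. (Classic Hellinger
omits the renormalization; the literal order is kept and documented since
all comparisons happen within one convention.) Observed and expected
profiles are aligned on the union of taxa with zero fill. Mann–Whitney
tests are exact (scipy's permutation distribution) when n_x + n_y ≤ 20 and
there are no ties, otherwise the tie-corrected normal approximation; an
exact request with ties falls back with a warning. The Berger–Parker index
is the maximum relative abundance. The incremental procedure sorts sample
pairs by the absolute difference of their uncorrected/corrected
Berger–Parker values and grows a two-sided Mann–Whitney comparison one pair
at a time, reporting the largest prefix fraction that stays non-significant.

## Known limitations

- Estimates inherit the reference tree's errors: taxa with no sequenced
  relatives get predictions dominated by distant lineages.
- Brownian motion is an approximation for a bounded integer trait; the
  model can return fractional values below 1 on extreme trees (not
  clamped, by design — the lookup stores what the model says).
- The simulator validates the correction under its own generative model;
  agreement there does not bound errors from chimeras, primer bias or
  taxonomy misassignment in real surveys.
- The λ likelihood uses dense covariance algebra (O(n³) per evaluation),
  fine for trees up to a few thousand tips, not for full reference trees.
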