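# Methods notes

This note records what each stage computes, the defaults and why, the
choices made where the underlying literature leaves the procedure open,
and what the synthetic-data tests do and do not establish.

## Input handling and rarefaction

The canonical in-memory orientation is samples x taxa; readers transpose
only on an explicit flag, never by guessing. Counts must be integers
before rarefaction — relative-abundance tables are rejected outright,
because subsampling them is meaningless.

Rarefaction draws a single exact multivariate-hypergeometric subsample per
sample (numpy's `multivariate_hypergeometric`), i.e. sampling reads without
replacement, reproducible under the recorded seed. A single draw (rather
than an average over draws) keeps every downstream statistic deterministic
given the manifest. Samples below the requested depth are dropped only on
an explicit flag; with the default depth = minimum row sum nothing is
dropped. Rarefaction precedes abundance-class partitioning by default; the
order is configurable because the literature is not uniform on it.

## Abundance-class partitioning

Abundant: dataset-wide relative abundance strictly above 0.1 %; rare:
strictly below 0.01 %; intermediate: the closed band between, so boundary
values land in the intermediate class. The default basis is a taxon's
summed reads over all reads — the basis under which the headline
percentages of this kind of survey recompute exactly — with mean
per-sample relative abundance available because part of the rare-biosphere
literature uses it. Outputs label the basis used.

At desk scale the published thresholds need care: 0.01 % of a 10⁴–10⁵-read
fixture is less than one read, so the rare class would hold only all-zero
taxa. The pipeline tests and the acceptance self-check therefore configure
desk-scale cutoffs (2 % / 0.2 %); the package defaults remain the
published 0.1 % / 0.01 %.

Subcommunity tables are column subsets of one shared rarefied parent
table — never re-rarefied — so class read totals stay additive. Samples
with zero reads in a class are retained in the subset (the sample set must
stay aligned with the metadata) but are excluded from per-subcommunity
diversity and assembly statistics by the pipeline, with a manifest note.

## Diversity

Shannon entropy is reported in nats (natural log; base configurable).
Richness — the count of observed taxa — stands in for the species pool.
Beta diversity is Bray–Curtis on counts; PERMANOVA follows Anderson's
pseudo-F with free whole-sample permutation of labels and reports
r² = SS_between / SS_total alongside the permutation p. The study design
(sites crossed with seasons) could justify restricted permutations; these
are not implemented, which makes the reported p-values marginally liberal
for strongly structured designs.

The regressions and the path model need a per-sample "beta diversity"
number, which pairwise dissimilarities do not directly provide. The
default reduction is the first principal-coordinate (PCoA) score of the
Bray–Curtis matrix, sign-fixed to correlate positively with salinity when
available; the alternative — each sample's mean dissimilarity to its group
members — is selectable. Output metadata records which reduction was used.
Negative PCoA eigenvalues are reported, not corrected.

## Assembly null models

βMNTD is abundance-weighted by default and symmetric by construction
(each direction's abundance-weighted nearest-taxon distance, averaged).
The βNTI null shuffles taxa labels across the tips of the pruned
phylogeny — the standard richness-, abundance- and occupancy-preserving
randomization. One shuffle per iteration is shared across all sample pairs;
marginally each pair still sees independent uniform relabelings, and the
vectorized form is orders of magnitude cheaper than per-pair shuffles.
Default 999 iterations (minimum 99 enforced). Pairs whose null standard
deviation is below 10⁻¹² (identical taxon support, star-like trees) have no
usable standardization; their βNTI is reported missing and the pair is
classified "undetermined" rather than forced into a category.

RC_bray assembles each sample's null community independently per
iteration: draw the observed richness many taxa without replacement with
probability proportional to regional occupancy (Gumbel top-k, which is
exactly successive weighted sampling), seed each drawn taxon with one
read, and allocate the remaining reads multinomially by regional relative
abundance. The one-read seeding preserves the observed richness in every
null community, following the cited null-model framework; a plain
multinomial allocation could silently drop drawn taxa. RC is the doubly
scaled tie-corrected rank of the observed Bray–Curtis within its null
distribution, in [−1, 1]. The regional pool is the full analyzed table —
the per-subcommunity pool when run on a subcommunity.

Classification uses strict inequalities throughout (±2 for βNTI, ±0.95 for
RC); exact ties fall through to the next rule. The published description of
the RC-to-process mapping is internally garbled; the implementation follows
the standard framework: RC > +0.95 dispersal limitation, RC < −0.95
homogenizing dispersal, |RC| ≤ 0.95 drift. Process fractions are
percentages of classified pairs (undetermined reported separately), per
salinity group (pairs with both members inside the group) and overall,
plus the deterministic share (% of pairs with |βNTI| > 2).

## Multi-nutrient cycling index

MNI is the per-sample mean of the eight standardized nutrient factors.
The published recipe applies a Z-score and then min–max standardization;
min–max is invariant to positive affine maps, so the Z-score stage is
provably inert — it is retained for fidelity and its inertness is asserted
to 10⁻¹² in tests. Consequences worth knowing: MNI is unit-free (rescaling
a factor changes nothing) and every factor has one sample at 0 and one at
1. Standardization runs over the full sample set (a single comparable
index), not per group. Samples missing any factor are dropped entirely
rather than per-factor deleted, so all retained samples are scored on the
identical factor set.

## Association statistics

Mantel and partial Mantel use Spearman correlation of lower-triangle
entries; significance permutes one matrix's sample order jointly in rows
and columns, two-sided on |r|. The partial statistic correlates the rank
residuals after regressing out the control matrix's ranks. Permutation
p-values are (1 + hits) / (1 + n_perm) and can never be zero. The
environmental distance is Euclidean on per-variable Z-scores. No
multiplicity correction is applied by default (matching how such panels
are usually reported); Benjamini–Hochberg is available by flag.

## PLS-PM

Lohmöller-style alternating estimation: indicators standardized, outer
weights initialized equal, inner approximation by the path scheme
(predecessors weighted by OLS coefficients, successors by correlation;
centroid and factorial schemes selectable), mode-A outer update, scores
rescaled to unit variance each pass; convergence when the largest outer
weight change is below 10⁻⁷ (non-convergence at 300 iterations is an
error, not a silent acceptance). Sign indeterminacy is resolved by
aligning every latent score positively with its block's first indicator —
which also keeps bootstrap replicates sign-consistent. Inner path
coefficients are OLS on scores; effects decompose by exhaustive path
enumeration over the (acyclic, validated) structural model, so
total = direct + Σ products over directed chains by construction. With
single-indicator blocks the whole machinery degenerates exactly to
classical path analysis — the tests assert this to 10⁻⁶. Bootstrap
resamples samples with replacement; degenerate resamples count as failures
and more than 5 % failures aborts. R² per endogenous latent is the fit
surface; no global goodness-of-fit index is computed.

The default structural model has water properties (temperature, salinity,
pH, Chl-a) and nutrients (TOC, COD, NO3-N, NO2-N, NH4-N, DIN, TN, DIP, TP)
exogenous; alpha diversity (Shannon), beta diversity (PCoA score) and
species pool (richness) endogenous on both; EMF (MNI) endogenous on all
five.

## Synthetic data: what it emulates, and what a green test proves

The generator produces the statistical structure the analysis assumes,
not a literal estuary: a pure-birth (Yule) ultrametric phylogeny; niche
optima evolved along it by Brownian motion (default rate 20 PSU² per unit
branch length, giving tip-niche spread comparable to the 0–33 PSU
gradient); a lognormal regional abundance pool (σ = 2, heavy-tailed enough
that the abundance classes are non-empty at 200 taxa); Gaussian
environmental filtering exp(−(env − niche)² / 2σ_f²) of the pool at each
sample's gradient position; multinomial read sampling at fixed depth
(default 5,000); and nutrient covariates that load linearly on a latent
multifunctionality signal increasing along the gradient, with relative
noise of 0.3. Default scale: 200 taxa, 20 samples. Salinity groups are
fixed thirds of the gradient (LS < 11 ≤ MS < 22 ≤ HS); season and year
labels are cyclic, with no temporal autocorrelation simulated.

Brownian niches are the essential ingredient: they make composition carry
genuine phylogenetic signal, so βNTI (not merely taxonomic turnover) can
detect selection. The strong-selection preset sets σ_f = 3 PSU with
samples split across the gradient extremes — strong filtering relative to
a 33 PSU span; the neutral preset removes filtering entirely (the
σ_f → ∞ limit, requested by flag; σ_f = 0 is rejected as it means
infinitely strong filtering, not neutrality).

A green parameter-recovery test establishes that the implementation ranks
deterministic against stochastic regimes correctly on data satisfying its
own assumptions. It does not establish performance on real communities,
which add dispersal limitation, temporal structure, uneven sampling
depths, compositional noise and phylogenetic uncertainty — none of which
are simulated.

## Numerical choices

- Permutation p-values: (1 + hits) / (1 + n_perm), two-sided where a sign
  is meaningful.
- βNTI degenerate-null tolerance: sd < 10⁻¹²; RC Bray–Curtis tie
  tolerance: 10⁻⁹ (counts are integers, so true ties are exact rationals).
- Round-trip fidelity targets: matrices exact, branch lengths to 10⁻¹⁰.
- Percentages are reported at 2 decimals with full precision retained in
  `*_exact` columns.
- Reported tables are written with `%.10g` so reruns are byte-identical.

## Known limitations

- PERMANOVA offers no restricted/stratified permutations.
- No UniFrac or other phylogenetic beta-diversity metrics.
- RC_bray cost grows with n_null × samples × pool size; the defaults are
  desk-scale. For hundreds of samples, expect minutes.
- PLS-PM needs more samples than indicators (18+ for the default model)
  and bootstrap stability realistically needs several dozen.
- BIOM input is not supported (no biom-format dependency); use TSV.
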