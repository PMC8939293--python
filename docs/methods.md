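# Methods

## Data model and filtering

The unit of observation is one collected flower-visiting insect: visitor
taxon, sex, the plant it was netted on, and the collection site and year.
Records missing any of those labels are discarded (reasons are counted in a
filter report), as are records whose sex is not female or male. Taxon
identity is the verbatim label string — genus-level "sp." morphospecies are
kept as distinct labels and no taxonomic normalization is attempted, so
labels are assumed pre-cleaned and are matched per network only. A network
origin is a (site, year) pair; each origin yields a species network (both
sexes pooled — only sexed specimens exist after filtering) and female and
male subnetworks. Matrices store plants on rows and visitors on columns,
ordered lexicographically; every metric is invariant to row/column
permutation (tested), so the ordering is presentation only. By
construction the female and male matrices sum cell-wise to the species
matrix and every retained species has margin ≥ 1.

## Weighted NODF

The quantitative nestedness index ranks rows and columns by decreasing
marginal totals (stable sort) and scores ordered pairs within each guild.
A pair (i, j) contributes only when j's marginal total is *strictly* smaller
than i's — ties contribute zero — and then contributes `100·k_ij/N_j`,
where `N_j` is the number of non-empty cells of j and `k_ij` the number of
non-empty cells of j strictly below i's value in the same position (cells
where j is non-empty but i is empty count as not-lower). The total is
normalized by `m(m−1) + n(n−1)` over twice the pair counts, giving 100 on a
strictly nested matrix. Note that some implementations in circulation
condition pairs on decreasing *binary fill* (number of non-empty cells)
with totals only as a tie-breaker; this package conditions on the weighted
marginal totals, which follows the quantitative definition and makes the
maximum attainable. The implementation is vectorized (O(m·n²+n·m²) with
broadcasting) and is verified in the tests against a naive pair-enumeration
oracle coded directly from the formula.

## Chao niche overlap

Each species' "community" is its vector of partner counts (a visitor's
column of plants, a plant's row of visitors). For a pair (A, B) the
abundance-based estimate of the total relative abundance in A of shared
species is

    Û_A = Σ_shared X_iA/n_A + ((n_B−1)/n_B) · f_+1/(2 f_+2) · Σ_shared (X_iA/n_A)·I(X_iB = 1)

where `f_+1` and `f_+2` count shared species that are singletons and
doubletons in the other community. When `f_+2 = 0` the denominator uses 1
in its place (the index's standard bias-correction practice) and Û is
truncated at 1. Overlap of a guild is the mean over all unordered pairs of
`J = Û_AÛ_B/(Û_A+Û_B−Û_AÛ_B)`, i.e. overlap is the *similarity* — 1 when
diets match, 0 for disjoint diets. (The index is often presented as a
dissimilarity `1 − J`; this package reports the similarity orientation so
that "higher overlap = more similar diets".) The pairwise computation is
vectorized over all pairs and cross-checked against the scalar per-pair
function in the tests.

## Partner diversity and the z-unification identity

Partner diversity at one guild level is the abundance-weighted mean Shannon
entropy `H′_0 = (1/S) Σ_j n_j H′_j` with natural logarithms, weights
`n_j` the species' interaction totals and `S` their sum; species with a
single partner (including singleton-margin species) contribute zero entropy
with weight `n_j`. The two guild levels obey the exact identity

    S·H′_0(visitor) − S·H′_0(plant) = Σ_j c_j ln c_j − Σ_i r_i ln r_i

a function of the margins alone. Fixed-margin nulls hold the right-hand
side constant, so the two levels' z-scores coincide exactly whenever they
share a null set; the pipeline therefore evaluates all metrics of one
network on a single null set and reports a single unified partner-diversity
z-score.

## Null models and standardization

The null universe for a network is the set of non-negative integer tables
with the observed row and column sums, under the multiple hypergeometric
(uniform pairing) distribution — the expectation if every individual chose
partners by encounter probability alone. Tables are drawn with the
Patefield (r2d) algorithm (delegated to `scipy.stats.random_table`;
degenerate single-row/column margins are returned directly as the forced
table). An independently implemented sampler — writing S row labels against
a permuted multiset of S column labels and tabulating — is distributionally
identical and serves as the oracle in the tests, which also compare both
samplers against the exactly enumerated conditional distribution on small
margins. Standardization uses `z = (obs − mean)/sd` with the sample
standard deviation (n−1); 1000 nulls by default. Null draws on which a
metric is undefined are excluded with a count; when the null sd is zero the
z-score is reported as NaN (flagged) rather than ±∞. Child seeds for each
(site, year, network type) are derived from the master seed through
`numpy.random.SeedSequence` with a stable string digest, so any single
standardization is reproducible in isolation.

## Comparative statistics

z-score responses are compared across the three network types with a
Gaussian linear mixed model (statsmodels `MixedLM`, REML) with a random
intercept per origin. Omnibus and contrast tests are Wald F tests; the
denominator degrees of freedom use the containment approximation
`(k−1)(g−1)` for the type factor in the g-origins × k-types crossed design
(which matches classical repeated-measures df in the balanced case) and
`n − p − (g−1)` in covariate models. Under a null simulation with 11
origins this calibrates the omnibus test to the nominal 5% level (checked
in the acceptance tests at 1000 replicates). When the omnibus test is
significant at 0.05, each pair of types is refit and tested against the
Bonferroni threshold 0.05/3 ≈ 0.0167. If a mixed fit fails or is singular,
the comparison falls back to a seeded within-origin permutation test
(between-type sum of squares of origin-centered values; sign-flip test on
origin-matched differences for pairs) and records which route produced the
result.

Sex-composition counts (all-female / all-male / both-sex species per
network) are modelled as Poisson with a log link and the network's visitor
richness as log-offset. Grouping by origin is handled with generalized
estimating equations (exchangeable working correlation) using the
Mancl–DeRouen bias-reduced covariance, because the plain sandwich estimator
is strongly anticonservative with ~11 clusters; a Poisson GLM absorbing
origins as fixed effects is the documented fallback for degenerate fits.
Exact replication of any particular published F statistic is out of scope
by design — denominator-df conventions and software differ — and only
direction and significance patterns are meaningful comparison surfaces.

Covariate models (`z ~ covariate × type` with origin random intercept)
internally center and scale the covariate, so the reported main effect is
the slope at the mean covariate value. Standardized modularity is never
computed here; the Pearson correlation between standardized nestedness and
externally supplied modularity z-scores is provided as a separate
operation.

## Synthetic specimen generator

The generator emulates a museum collection with the structure the analysis
assumes: log-normal relative abundances for plants (σ = 1.5) and visitor
species (σ = 2.0, 250-species pool), 11 origins of 474 specimens (the
empirical totals of ~5212 specimens over 11 site-year datasets), and a
female specimen fraction of 0.625 (the empirical 3256:1956 split). Each
visitor species draws a symmetric Dirichlet preference vector over plants
(concentration 0.1 per plant — essentially one or two preferred species);
each sex's realized choice distribution is the convex mixture
`λ·abundance + (1−λ)·preference` with the sex's *neutrality* λ. The default
mechanism scenario sets λ_male = 1 and λ_female = 0: a male specimen's
plant is drawn from relative plant abundance — exactly the process the
fixed-margin null embodies, so male subnetworks have z ≈ 0 by construction
— while female specimens concentrate on their species' preferred plants,
producing significantly negative nestedness z-scores. Setting
λ_male = λ_female with a 1:1 sex ratio is the matched-null scenario in
which no sex difference should be detected (tested).

What the generator deliberately does not emulate: per-species preferences
are drawn independently across species, so there is no inter-species niche
complementarity (no coordinated partitioning of the flora), no phenology,
no spatial structure, and sex is i.i.d. per specimen (no species-level
sex-ratio biases). One consequence is documented as a limitation: under
the i.i.d.-preference mechanism the female under-nestedness signal requires
a moderate number of multi-specimen species to express diet concentration.
If richness is pushed to the point where singletons dominate the species
pool (as in the most extreme empirical collections), independent
specialists concentrate onto popular plants and the observed matrix becomes
*more* nested than its fixed-margin nulls — reproducing the empirical
singleton profile together with under-nested female networks would require
complementary (negatively correlated) preferences across species, which
this mechanism intentionally omits. The default richness (≈ 90 observed
visitor species per 474-specimen origin, ~40% singletons, a majority of
species observed in one sex only) keeps many rare species while remaining
inside the regime where the encoded mechanism drives the pattern. Passing
tests therefore demonstrate that the pipeline recovers the sex-dependent
pattern from data generated by this mechanism, not that the mechanism is
the only explanation of such patterns in field data.

## Problem sizes and numerical choices

The test suite and the acceptance script scale the stochastic layers to
what the checks need: 200 null networks per standardization in the
mechanism study (1000 is the production default), 20,000 draws for the
exact-distribution checks, 1000 replicates for the type-I-error
calibration. The exhaustive weighted-NODF oracle comparison samples
matrices with cells in {0, 1, 2} across all shapes up to 4×4 rather than
enumerating the full space. Determinism is end-to-end: every stochastic
stage takes an explicit seed, child seeds are derived (never reused), and
rerunning a pipeline configuration reproduces output files byte-identically.
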