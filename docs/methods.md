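# Methods

This note documents the statistical procedures, the assumptions behind them,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions used
throughout. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Site classification

Columns of an alignment are classified using only the four unambiguous bases.
Any column containing a gap or an IUPAC ambiguity code is counted as
`excluded` and takes no part in the conserved/variable tallies; among the
remaining columns, one observed state is conserved, and a variable column is
parsimony-informative when at least two states each occur in at least two
sequences (otherwise it is a singleton site). Two identities therefore hold
by construction and are asserted on every computation:
`variable = parsimony_informative + singletons` and
`conserved + variable + excluded = length`. Published per-locus tables of
this kind usually show conserved + variable summing to slightly less than the
alignment length without stating the exclusion rule; the gap/ambiguity rule
here is one deterministic mechanism that produces such a shortfall, but exact
agreement with any particular published table is not guaranteed, since the
original rule is unknown.

Concatenation requires an identical strain set in every locus and sorts
strains by id. A strain present in only some loci is an error, never an
implicit intersection: sequencing panels routinely amplify different gene
sets per strain, and silently dropping strains would change the sample
without the caller noticing.

## Distances

**p-distance.** Proportion of differing sites among columns where both
sequences carry an unambiguous base (pairwise deletion, the default).
Complete deletion is available as a flag; pairwise deletion was chosen as the
default because it preserves pairs with uneven coverage. A pair with no
comparable column raises an error naming the pair.

**TN93.** The closed-form Tamura–Nei (1993) distance, computed per pair from
the purine-transition proportion P₁, pyrimidine-transition proportion P₂ and
transversion proportion Q, with base frequencies pooled over the whole
alignment rather than estimated per pair - pooling stabilises the estimates
at the short locus lengths typical of MLSA. A non-positive logarithm argument
(substitution saturation) flags the pair as undefined (NaN, reported in
`undefined_pairs`) instead of erroring, so one saturated pair does not block
a matrix. An optional gamma-rate variant takes a user-supplied shape α
(published analyses often use "+G" without reporting α; plain TN93 is the
default). The correction is never smaller than the p-distance; the test suite
asserts this Jensen-type inequality at 1e-12.

**Haplotypes and allele sharing.** Within each locus, strains with
byte-identical aligned sequences (uppercase, gaps significant) share a dense
integer haplotype label. Treating gaps as characters keeps haplotype identity
deterministic and matches allele semantics for pre-aligned loci. The
allele-sharing distance is the fraction of loci at which two strains carry
different haplotypes, so its values lie on the grid {0, 1/L, ..., 1}.

**Species, geography, scalars.** Species-level distance is the 0/1
same/different-genospecies indicator. Geographic distances are haversine
great-circle distances on a sphere of radius 6371.0088 km (the IUGG mean
radius, fixed for bit-reproducibility). Elevation and trait distances are
absolute scalar differences.

## Genospecies assignment

Each query is assigned the genospecies of its nearest reference by ANI
(1 − p-distance on shared unambiguous columns of the concatenated alignment),
provided the ANI reaches `min_similarity` (default 0.95). The floor mirrors
reported within-genospecies ANI ranges for chickpea mesorhizobia, whose
lowest within-cluster values sit just above 95%. Below the floor a strain is
explicitly "unassigned" - raising the floor can only unassign, never assign.
Exact ties are broken by reference input order with a warning. De novo
cluster discovery is out of scope: genospecies here are anchored to named
references.

Composition differences are tested with Pearson's chi-squared on the
sample-by-genospecies table, df = (r−1)(c−1), no continuity correction.
Expected counts below 5 warn rather than error, since small genospecies are
the rule in such collections.

## Diversity and the bootstrap comparison

Shannon (natural log) and Gini–Simpson indices are computed over genospecies
counts; zero-count categories are ignored rather than rejected because
resampled draws routinely miss rare categories. Nucleotide- and
haplotype-level diversity are mean off-diagonal distances within a strain
subset.

The bootstrap comparison asks whether an observed collection is *less*
diverse than a reference population: B draws (default 10,000) of the observed
sample size (default 39) with replacement from the reference labels, indices
computed per draw, and `p = (1 + #{resample ≤ observed}) / (B + 1)`. The
lower tail is the default because the scientific question is reduced
diversity; a two-sided option doubles the smaller tail. The +1 correction
bounds p at 1/(B+1) and makes the null distribution conservative
(stochastically ≥ uniform at the lower tail), which the calibration tests
verify. The generator seed is stored in the result.

## Spatial inference

**Mantel.** r is the Pearson correlation of the strict lower triangles; the
null permutes rows and columns of the focal matrix simultaneously;
`p = (1 + #{|r_perm| ≥ |r|}) / (n_perm + 1)` two-sided by default (one-sided
tails available - published tables showing negative r with large p are
consistent with either convention). Default `n_perm = 9999`.

**Partial Mantel.** First-order partial correlation
r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)), with significance from
permuting x and recomputing the partial statistic while r_yz stays fixed
(Smouse–Long–Sokal-style; the permutation scheme for partial Mantel tests is
genuinely open, and this one is documented and seedable). A covariate
collinear with x is a degenerate error; a covariate carrying all of y's
signal (r_yz = ±1) returns the analytic limit 0.

**PCoA.** Gower double-centering of −½ D∘D followed by eigendecomposition;
axes with positive eigenvalues are retained and scaled by √eigenvalue.
Negative eigenvalues (non-Euclidean input, e.g. allele-sharing matrices) are
reported, not corrected - a Cailliez-style correction would change the
variance decomposition silently. On Euclidean-embeddable input the
coordinates reproduce the distances exactly (asserted at 1e-8).

**PCoA regression.** Each genetic principal coordinate is regressed by OLS on
the first two geographic principal coordinates (standing in for
latitude/longitude when sampling follows a transect) and altitude; terms are
tested with sequential (type-I) F-tests in the order geo1, geo2, altitude, so
the altitude term is adjusted for geography. Saturated fits (R² = 1 within
1e-10) report F = ∞ for the explaining term and F = 0 for the rest rather
than forming 0/0 ratios.

**Sliding-window distance decay.** Windows [k·step, k·step + width) with
width 40 km and step 10 km slide to the maximum observed pair distance. Per
window one eligible pair is sampled uniformly and its nucleotide and
haplotype distances recorded; the baseline draws the same number of pairs
irrespective of distance. One pair per window keeps the profile an unbiased
(if noisy) resample as specified; an `exhaustive` mode averaging all eligible
pairs is provided for variance reduction but is not the default. Empty
windows are kept as explicit NaN rows, never dropped silently.

## Greenhouse analysis

Two outcomes are deliberately distinct: *symbiotic performance* is shoot dry
weight (plant dry matter), while *symbiotic response* is the first principal
component of the four standardized traits (nodule number, nodule dry weight,
shoot dry weight, root dry weight) - a nodulation-plus-biomass score. PC1 is
taken from the trait correlation matrix, so the score is invariant to affine
rescaling of any trait; its sign is fixed by a positive loading on nodule dry
weight (response should increase with nodulation). Zero-variance traits are
dropped with a warning.

Variance components use the balanced-RCBD closed form: two-way ANOVA without
interaction, σ²_strain = (MS_strain − MS_error)/r, exact
F = MS_strain/MS_error with (s−1, (s−1)(r−1)) df. The closed form is exact
for the balanced three-replicate design this analysis targets, and fully
testable; unbalanced layouts are rejected rather than approximated with REML,
which would trade auditability for generality. Negative method-of-moments
estimates truncate to zero and are flagged.

Dunnett-style many-to-one comparisons estimate the max-t null by seeded Monte
Carlo (default n_mc = 100,000; the adjusted-p error is O(1/√n_mc) ≈ 0.003),
one-sided "greater" by default since the question is whether a strain
outperforms the uninoculated control. The test suite cross-checks the
adjusted p-values against an independent multivariate-t implementation.

Genospecies contrasts report group means, percent difference
(mean_A − mean_B)/mean_A × 100, a two-sided Welch t-test, and a one-sided
Wilcoxon rank-sum test - exact when both groups have ≤ 15 strains and no
ties, else the tie-corrected normal approximation.

## The synthetic-data generator

The generator emulates the structure such a survey assumes, with a truth
record sufficient to score every estimated quantity:

* 39 strains in four genospecies of sizes 26/8/2/3; three housekeeping loci
  of 1045/390/307 aligned bp.
* Sequences evolve by per-site independent substitutions under a
  TN93-consistent model: GC-rich base frequencies (0.19/0.31/0.31/0.19,
  matching rhizobial genomes) and transition bias κ = 4. Cluster ancestors
  diverge from a common root at 0.03 expected substitutions/site; members
  acquire within-cluster variation at 0.005 - values chosen so the
  within-genospecies mean pairwise distances land in the few-per-mille range
  reported for such collections. The high-elevation cluster's ancestor
  diverges at twice the between-cluster rate, reflecting that in real
  collections the high-altitude genospecies belongs to a distant clade and is
  the most divergent group.
* Geography: ~16 sites on a noisy 400-km south-west to north-east transect.
  Two small clusters are restricted to the south-western quarter; the
  three-strain high-elevation cluster occupies two sites above 2400 m; other
  sites draw elevations around 1800 ± 200 m.
* Isolation by distance: within each cluster, a stepping-stone chain along
  the transect contributes a fraction `ibd_strength` of the within-cluster
  divergence (normalized so the mean pairwise divergence is independent of
  `ibd_strength`), and private mutations contribute the rest. `ibd_strength`
  defaults to 0.5 - moderate IBD, strong enough to be detectable at the
  haplotype level without dominating the cluster structure; 0 removes all
  spatial signal (used for null calibration), 0.9 is used as the "strong IBD"
  condition in power checks. Strains at one site share the chain state, which
  reproduces the local haplotype homogenization such surveys report.
* Traits: balanced r = 3 RCBD; each trait is
  μ_t + λ_t(a_i + b_j) + ε with latent strain effectiveness a_i ~ N(0, 1),
  block effects, and trait-specific loadings; the uninoculated control has
  latent effect 0, zero nodulation and a 25% biomass deficit.
* A star phylogeny within clusters (plus the chain layer) rather than a full
  coalescent keeps every generated quantity auditable; optional uniform gap
  injection exercises pairwise deletion. Identical seeds give byte-identical
  datasets.

**What passing tests do and do not show.** The generator has no
recombination or horizontal gene transfer, no indels, no rate variation
across sites, no unbalanced greenhouse data and no measurement error in
coordinates. Tests passing on it demonstrate that the estimators recover
known structure under the model's assumptions - cluster recovery, calibrated
type-I error, detectable IBD - not that real surveys satisfy those
assumptions. In particular, real allele-sharing matrices can be strongly
non-Euclidean, and real trait data are rarely perfectly balanced; the
pipeline surfaces both situations (negative-eigenvalue reports, balanced
design errors) rather than hiding them.

## Problem sizes used in the checked runs

Calibration suites use 1000 null simulations with 99 permutations each for
the Mantel, partial Mantel, PCoA-regression and variance-component tests, and
200 replicates at n_mc = 2000 for the Dunnett familywise check; recovery
suites use 200 seeded generator runs for the distance-decay properties and
500 replicates for variance-component bias. These sizes give binomial 99%
confidence intervals tight enough to detect miscalibration of a 5% test at
roughly ±2 percentage points while keeping the default test run fast.

## Known limitations

* TN93 requires all four bases present in the pooled alignment; degenerate
  compositions error out.
* The sliding-window profile with one pair per window is noisy by design;
  use `exhaustive=True` for smooth profiles.
* The Monte-Carlo Dunnett assumes equal within-group variances (pooled s);
  heteroscedastic designs need a different procedure.
* Assignment is nearest-reference only; a query equidistant from two
  references of different genospecies is resolved by input order, which is
  reported but arbitrary.
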