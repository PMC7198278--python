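# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not emulate. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The problem

Cooperative variety-trial networks phenotype a few hundred inbred entries
across many locations and years, but almost never in a balanced design: an
entry is typically grown in only one or two years, the set of entries turns
over continually as breeders advance material, and the number of entries and
locations varies from year to year. The package extracts stable genetic
signal from such records in five stages: phenotype standardization,
kinship-conditioned BLUPs with narrow-sense heritability, mixed-linear-model
GWAS with FDR control, empirical-Bayes multivariate shrinkage across
phenotypes, and a cross-study association-overlap analysis.

## Phenotype standardization (`metgwas.phenostd`)

Trait scores arrive on heterogeneous scales (percent, 1–5, 0–9, 1–9).
Harmonization is the endpoint-preserving affine map
`to.lo + (to.hi − to.lo)·(v − from.lo)/(from.hi − from.lo)`; harmonized
ordinal values are deliberately not rounded because the downstream mixed
models treat them as continuous. Duplicate (entry, location, year, trait)
records are averaged first — plot means are the unit of record in trial
reports.

Outlier removal is cell-wise: for each trait, the mean of every
location × year cell is computed, Tukey fences at 1.5 × IQR are placed on
the distribution of those *cell means*, and every record of an offending
cell is dropped. The reference distribution had to be chosen (raw records
vs. cell means); cell means match the cell-wise removal semantics — a cell
either survives whole or is removed whole. With fewer than 4 cells the
fences are not estimable and nothing is filtered (with a warning).

## Kinship, REML and BLUP (`metgwas.genotypes`, `metgwas.reml`, `metgwas.blup`)

Relatedness is the VanRaden genomic relationship matrix
`K = ZZ′ / (2Σ p_j(1−p_j))` with `Z` the dosage matrix column-centered by
twice the alternate-allele frequency. In a highly selfing crop the diagonal
of `K` sits near `1 + f` rather than 1; variance components are therefore
estimated on the scale of this `K`, and `h² = Va/(Va+Ve)` is reported on
that same scale, as is conventional for trial analyses.

The mixed model is `y = Xb + Zg + e`, `g ~ N(0, Va·K)`, `e ~ N(0, Ve·I)`.
The restricted likelihood is profiled over `λ = Va/Ve`: one
eigendecomposition reduces every evaluation to diagonal arithmetic. For
entry-level data this is the classic spectral trick on `eig(K)`; for
record-level trial data with incidence `Z` the same reduction runs on the
q × q matrix `K^{1/2} Z′Z K^{1/2}` (q = number of entries), so tens of
thousands of plot records cost no more than an entries-sized
eigendecomposition. `λ` is maximized on a 41-point log grid over
[1e−5, 1e5] followed by bounded refinement; the `Va = 0` boundary is always
compared explicitly, so null traits land exactly on the boundary instead of
at a spurious interior optimum. The spectral likelihood is tested against a
naive dense-matrix oracle to 1e−6, and the BLUPs against a Henderson
mixed-model-equations solve to 1e−8.

BLUPs are fitted on record-level data with location and location:year as
fixed effects. Unbalanced designs alias fixed-effect columns (a cell
observed once, a location present in one year); columns are scanned left to
right with modified Gram–Schmidt and dependent columns dropped, so the
intercept and main effects always survive. Genetic values are reported as
deviations (centered), for entries phenotyped at least once.

## Mixed-model GWAS (`metgwas.gwas`)

Scans run on entry-level genetic values (BLUPs). Variance components are
estimated once under the null model and held fixed for every SNP test — the
standard P3D/EMMAX shortcut — with each SNP tested by GLS in the kinship
eigenbasis and a two-sided t test on `n − p − 1` degrees of freedom. An
exact mode refits the variance components per SNP; the shortcut tracks it
closely for the bulk of SNPs, while the odd marker most correlated with the
kinship axis can deviate more — the known cost of the approximation, which
the test suite quantifies rather than hides.

The number of leading genotype principal components carried as covariates
is chosen by BIC on the null mixed model (`−2·llf + p·log n`, ties toward
fewer PCs). Optional kinship compression clusters entries by average
linkage on `max(K) − K` and replaces `K` by block means, selecting the
group count by null restricted likelihood; at group count = n it reproduces
the uncompressed model exactly.

Multiple testing uses the Benjamini–Hochberg step-up at q = 0.1. Candidate
windows are 20-kb intervals centered on peaks; top-SNP lists are thinned to
one SNP per 20-kb region. The earliest trial year per entry serves as a
proxy phenotype for entry age, scanning for allele-frequency change over
the trial's history.

## Multivariate shrinkage (`metgwas.mash`)

Effect vectors across R phenotypes are modelled as draws from
`b_j ~ π₀·δ₀ + Σ_{k,l} π_{k,l}·N(0, ω_l·U_k)` with canonical components
(identity, per-phenotype singletons, equal-effects) plus data-driven ones
(the empirical second-moment matrix of the strong effects and its rank-5
eigen-truncation, normalized to unit maximum diagonal). The scale grid is
geometric with √2 spacing on the SD scale, spanning
`[(min ŝ)²/4, 4·(max b̂)²]`.

Bridge conventions: each phenotype's effects are centered and divided by
the maximum absolute centered effect so they span [−1, 1] with mean 0; SEs
are divided by the same factor (they are scales, not locations), so
z-scores of centered effects are preserved. When a scan yields usable SEs
for ≤ 95% of SNPs for a phenotype, the Hedges' G standard error
`√((n₀+n₁)/(n₀n₁) + g²/(2(n₀+n₁)))` with bias correction
`J = 1 − 3/(4·df − 1)` substitutes, using alt-carrier vs. reference group
sizes. Measurement errors are taken as independent across phenotypes given
the SEs (diagonal `S_j`); error correlations from the shared panel are a
known simplification.

The mixture weights are fitted by EM on a random LD-pruned SNP set; the
per-slice likelihoods `N(b̂_j; 0, S_j + ω_l U_k)` do not depend on the
weights, so they are computed once (batched Cholesky over SNPs) and the EM
iterations are pure matrix re-weighting. A Dirichlet pseudo-count of 10 on
the exact-null slice (the usual null-biased prior) regularizes the split
between the point mass and statistically indistinguishable tiny-scale
slices; with the prior at 1 the plain EM is exactly monotone in
log-likelihood, which the tests verify. "Near-null weight" pools the point
mass with slices at the bottom of the scale grid.

Posteriors on the strong set use the conjugate forms
`μ = U(U+S)⁻¹b̂`, `Σ = U − U(U+S)⁻¹U` per slice, computed via solves so
singular components are never inverted. The local false sign rate of each
entry is `min{P(b ≤ 0 | data), P(b ≥ 0 | data)}`, both sides including the
point mass at zero. The per-SNP Bayes factor is the fitted non-null mixture
likelihood over the null likelihood, with 10² as the conventional
"decisive" threshold. Pairwise sharing between two phenotypes is the
fraction of SNPs significant (lfsr ≤ 0.05) in at least one of the two whose
posterior means agree in sign with magnitude ratio within a factor of 2.

## Association-overlap analysis (`metgwas.overlap`)

The bundled catalog (`data/association_catalog.tsv`, 114 rows) transcribes
a published cross-study table of common-bean GWAS associations: 80
literature associations from 11 balanced-panel studies plus the
sparse-trial associations they were compared to, with positions printed to
2 d.p. in Mb and candidate genes where reported. Associations cluster by
single-linkage within a chromosome; two entries link when their distance is
strictly below the threshold and, under the same-gene criterion, when both
name the same candidate gene. Positions printed as ranges are represented
by their midpoints. Strict (rather than inclusive) thresholding is
deliberate: at the table's 10-kb print resolution an inclusive 200-kb rule
would link one pair whose printed distance is exactly 200 kb, changing the
region count; the strict rule reproduces the published counts at 200 kb
exactly. At 20 kb + same gene the printed table is internally inconsistent
(its third marked region lists two different gene identifiers for the two
rows it contains), so the rule as stated yields 6 associations in 2 regions
rather than the published 9 in 3; the implementation applies the stated
rule and reports what it finds.

Overlap rates between two study sets are compared with a 2×2 Pearson
chi-square without continuity correction. `percent_yield_change` expresses
an allele-substitution effect as a percentage of a subpopulation median.

## Synthetic trial data (`metgwas.simulate`)

The generator's defaults are the study conditions: 327 inbred entries in 3
subpopulations (two gene pools' worth of divergence, F_ST = 0.3,
inbreeding 0.95), biallelic SNPs in 10-SNP LD blocks, 16–61 entries and
10–28 locations per year, and a median of 2 distinct trial years per
tested entry. Sub-population allele frequencies follow the Balding–Nichols
construction (ancestral frequency Uniform(0.1, 0.9), Beta divergence at
F_ST); genotypes are drawn under inbreeding-deflated Hardy–Weinberg. LD
blocks copy the previous SNP column with a 2% per-entry perturbation
probability, giving r² ≈ 1 within blocks and ≈ 0 between (population
structure still induces background LD between unlinked SNPs, as in real
panels). The trial design is a turnover process: yearly entry and location
counts are drawn uniformly within the configured ranges, entries enter
service with geometric participation durations (success probability
`1 − 0.5^(1/median)` so the realized median matches the target) and retire
when they expire. The default of 20 trial years makes the demand for
distinct entries roughly match the 327-entry pool.

Phenotypes are `y = μ + g + L + LY + e` at the record level, with
`g` combining planted QTL and a kinship-structured polygenic term scaled so
that `Var(g)/(Var(g)+Ve)` hits each trait's target h² (defaults span 0.067
to 0.733, the range seen in real trial data; location and location×year
variances default to 0.5 and 0.3 against a unit error variance). Planted
QTL come in two trait groups with sign-coherent effect vectors within a
group; their magnitudes are scaled so the QTL jointly explain ~35% of each
trait's additive variance, the polygenic term supplying the rest. Ordinal
and percent traits are produced by thresholding/clipping a latent normal.

What the generator does not emulate: the real location/year incidence
pattern (only its summary sparsity statistics), pedigree structure and
selection over time, genotype-by-environment interaction, missing
genotypes, and multi-allelic or structural variation. Passing tests
therefore demonstrate the statistical machinery under the stated
assumptions, not robustness to these real-data features.

## Numerical conventions and degenerate inputs

- PSD is enforced to −1e−8 on kinship and mixture components; symmetric
  matrices are symmetrized before eigendecomposition.
- PCA signs follow the largest-magnitude-loading-positive convention, so
  scores are deterministic across LAPACK builds.
- Monomorphic SNPs in a scan are reported with `beta = 0, p = 1` and a
  missing SE rather than dropped, keeping row alignment.
- Constant phenotypes, empty designs, h² = 1 with positive error variance,
  all-monomorphic panels, and rank-deficient fixed designs raise
  immediately with named errors.
- All randomness flows from seeded `numpy` generators; the simulation
  derives per-stage streams from `(seed, stage)` so stages can re-run
  independently and identical configurations are byte-identical.

## Problem sizes

The shipped analyses run at desk scale by choice: simulations use 300
entries and 2 000–5 000 SNPs (the full pipeline at 300 × 5 000 × 8 traits
completes in well under a minute), the random/strong sets default to
5 000/400 with the larger published-scale settings (45 000/4 000) available
by configuration, and Monte-Carlo checks use 10–30 replicates. These sizes
are large enough for every calibration and recovery check in the suite
while keeping a full run interactive.

## Known limitations

- `h²` from the record-level model is reported on the scale of the VanRaden
  `K`; with strong inbreeding its absolute level is conservative relative
  to the generator's entry-variance definition (rank order is preserved,
  which the tests check).
- The P3D shortcut's worst-case per-SNP deviation from an exact refit grows
  as n shrinks (see the GWAS section).
- Extreme-deconvolution refinement of data-driven covariances and
  correlated measurement errors across phenotypes are out of scope.
- Kinship compression is available but off by default at desk scale.
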