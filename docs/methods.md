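# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of the `myxphen` pipeline. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Study design being emulated

A library of 180 single-gene disruption strains plus the DK1622 wild type,
scored on eight phenotypes: swarm expansion on soft (0.4%) and hard (1.5%)
agar (mm), sporulation efficiency (% of wild type), developmental timing
(an ordinal score recorded at five discrete observation intervals, mapped
to 24/48/72/96/120 h), and four traits extracted from brightfield images of
developing fruiting bodies — aggregate count, mean area (px), mean grayness
(8-bit intensity, higher = lighter), and mean circularity. Six traits carry
replicate structure (3 replicates per mutant; a pooled 24-replicate
reference set for wild type); count is a single non-negative integer per
strain and timing a single ordinal level, so neither enters the per-strain
test.

Wild-type replicates: the 24-replicate pool applies to *all six* replicated
traits, not only the image-derived ones. With a 3-vs-3 comparison the exact
permutation null has only C(6,3) = 20 reassignments and the smallest
achievable two-sided p is 2/20 = 0.1, so no strain could ever be called at
α = 0.05 on a 3-replicate reference; a large pooled wild-type set is the
design that makes the test usable. The count is configurable
(`SimulationConfig.n_replicates_wildtype`).

## Synthetic trait generator

Replicate values are drawn as

    value(s, t, r) = m_t + shift(s, t) + N(0, sd_t),   sd_t = cv_t * m_t

with wild-type baselines `m_t` and replicate-level coefficients of variation
`cv_t` chosen to reproduce the qualitative ranges reported for the assays
(sporulation spanning roughly 0–270% of wild type, expansion varying by
tens of percent, and every trait continuous across the library):

| trait        | baseline | CV   | unit               |
|--------------|----------|------|--------------------|
| area         | 5000     | 0.30 | px                 |
| circularity  | 0.72     | 0.08 | —                  |
| grayness     | 140      | 0.08 | 8-bit intensity    |
| count        | 30       | 0.25 | aggregates (Poisson) |
| timing       | 3        | 0.27 | ordinal level 1–5  |
| soft         | 11       | 0.12 | mm                 |
| hard         | 9        | 0.10 | mm                 |
| sporulation  | 100      | 0.35 | % of wild type     |

Sporulation is floored at 0; count is emitted as Poisson(max(m+shift, 0));
timing as round(m + shift + noise) clipped to 1–5. The replicate-noise
magnitudes are not published for the original assays, so these CVs are the
package's own realistic choices; downstream conclusions are properties of
the method, not of these constants.

**Planted effects (pleiotropy model).** Each mutant draws a latent vector
`z ~ MVN(0, C)` over the 8 traits, where `C` is a positive-semidefinite
trait–trait correlation built from a three-factor loading model (a
swarm/shape factor over soft, hard, area, circularity; a development/opacity
factor over timing and grayness, negatively coupled to the first; and a
count/sporulation factor). Trait *t* of strain *s* is *affected* when
|z_st| exceeds a two-sided cut, and affected pairs are shifted by
`effect_size_sd * sd_t * z_st` — shifts inherit the copula's correlation,
which is precisely what planted pleiotropy means. The cut is calibrated by
Monte Carlo on the copula itself (fixed internal seed, so it is a
deterministic function of the configuration) such that the fraction of
mutants with ≥1 affected trait equals `effect_fraction`; an independence
approximation undershoots badly under positive correlation.
`per_trait_effect_prob` bypasses the calibration and fixes the marginal
per-(strain, trait) effect rate instead — the natural parameterization for
FDR/power experiments. The default `effect_fraction = 0.86` matches the
fraction of strains the study design is meant to distinguish; at that
prevalence the per-trait significant counts land in the reported range.

**Planted strain groups.** `n_groups = 4` severity classes with ±1 sign
patterns on each group's characteristic traits (severe: all eight traits;
moderate: shape/swarming/timing; wild-type-like: none — the wild type is
assigned here; mildly enhanced: circularity/swarming up, count down),
scaled by `group_separation_sd` replicate SDs per trait (the same unit as
`effect_size_sd`). The default separation is **0**: with
`effect_fraction = 0` the generator must produce a pure null table (every
strain drawn from the wild-type distribution), so group structure is opt-in
for the clustering analyses. `GroundTruth.affected` covers both copula
effects and group shifts; it is false for wild type everywhere and
`planted_shifts` is zero wherever `affected` is false.

**Images.** 8-bit grayscale fields (512×512 by default) of elliptical
aggregates darker than background (80–110 vs 200), with additive Gaussian
noise; specifications are rejected unless every blob's intensity differs
from background by more than 2·noise_sd (separability guarantee). Ground
truth (area, perimeter, centroid, mean intensity, edge flag) is measured on
the *rasterized* mask with the same crack-boundary perimeter estimator the
extraction stage uses, so noise-free recovery can be checked exactly.

**Expression.** Four temporal archetypes over a 0–24 h post-starvation
course: induced after hour ~14 (logistic step), silent (low, slowly
decaying), early-activated (Gaussian bump at 6 h), and nearly constitutive
(high, gently rising); each gene is its archetype plus i.i.d. N(0, 0.3)
log-scale noise.

## Statistical stages

**Randomization test.** Two-sided, statistic |mean(mutant) − mean(wild
type)|, permutation of pooled replicate labels between groups of the
original sizes. When the number of distinct reassignments is at most the
iteration budget the null is enumerated exactly (p = #{T* ≥ T}/total, the
identity reassignment included, so p > 0); otherwise B Monte-Carlo
reassignments with the add-one rule p = (1 + #{T* ≥ T})/(1 + B). Null
statistics within a relative 1e-12 of the observed value count as extreme.
A practical note: with 3-vs-24 groups and B = 1000 the Monte-Carlo p-floor
is a lottery between 1/1001 and 2/1001 (the identity reassignment is
re-drawn with probability ≈ 0.29), which caps post-adjustment power at
m = 180 regardless of effect size; a budget of 3000 crosses the
C(27,3) = 2925 enumeration threshold and removes the artifact, which is why
the analysis drivers default to 3000 iterations while the pipeline default
remains the classical 1000.

**FDR.** Benjamini–Yekutieli step-up (valid under arbitrary dependence) via
statsmodels, applied within each trait across strains by default (a joint
`family="all"` option exists). The per-test type-I level is exact by
construction; note that the realized rejection *rate* over one library has
extra variance because all strains of a trait share the same wild-type
draw.

**Pleiotropy correlations.** Eleven variables: the 8 per-strain summaries
plus within-swarm variability of area, grayness and circularity expressed
as CV = sd/|mean| (normalizing by the mean prevents large averages from
masquerading as large variability; the absolute value keeps CVs
non-negative in degenerate cases, and zero means are flagged missing).
Zero-order: pairwise-complete Spearman with average-rank ties and the
two-sided t-approximation. Partial: listwise-complete, rank-transform, then
ρ_ij·rest = −q_ij/√(q_ii q_jj) from the precision matrix of the rank
correlations — every pair is conditioned on all 9 remaining variables
(full conditioning, the convention of the standard partial-correlation
packages); p-values use df = n − 2 − 9. Perfectly collinear variables raise
an error naming the pair; near-singular matrices retry once with a 1e-8
ridge.

**Multivariate.** z-scores use the sample SD (ddof = 1); constant columns
are dropped with a warning. Ward linkage on Euclidean distances of
z-scores, groups by cutting at fixed k (k = 4 for strains, k = 2 for
traits — the group counts the library analysis resolves, rather than a
height threshold). PCA is an eigendecomposition of the covariance of the
z-scores (= correlation-matrix PCA); eigenvalues are clipped at zero for
rank-deficient input, variance percentages sum to exactly 100, and each
component's largest-magnitude loading is oriented positive (loadings signs
are otherwise arbitrary). Dendrograms export to Newick with branch lengths
derived from merge heights.

**Image traits.** 25%-area corner crop (floor division on odd dimensions).
The Rényi-entropy threshold follows the three-order combination rule of the
classic auto-threshold implementation: partial thresholds maximizing the
summed background/foreground Rényi entropies at α = 0.5, α → 1 (Shannon)
and α = 2 are blended with weights depending on their mutual distances
(≤ 5 bins). One deliberate deviation: on criterion plateaus the *midpoint*
candidate is returned rather than the first, so a two-level histogram
thresholds strictly between the levels. Foreground is `image ≤ threshold`
for dark aggregates (polarity configurable); components use
8-connectivity; aggregates under 200 px or touching any border are
excluded; grayness is measured on the original (pre-threshold)
intensities; circularity = 4πA/P² with the scikit-image crack-boundary
perimeter, capped at 1.0 because rasterization can push the raw ratio above
the continuous bound (a rasterized disk of radius 30 measures ≈ 0.95–1.0);
single-pixel components (possible only when the size filter is disabled)
are treated as fully compact. "Manual correction" of thresholded masks is
replaced by an optional `mask_override` argument — no interactive step.

**Expression co-clustering.** Normalization is a self-contained two-step
substitute for the study's web-service pipeline: per-gene median centering
followed by per-array (column) z-scaling; gene-centering first makes the
result invariant to per-gene offsets. Average linkage on correlation
distance (1 − Pearson), the convention of the classic expression-clustering
tools, cut at k = 4; constant profiles are excluded (their correlation
distance is undefined). Development-phenotype groups (dev1–4) come from
Ward on the six development traits only (soft/hard excluded). Enrichment:
per-cell one-sided hypergeometric p for over-representation given the
contingency marginals, BY-adjusted across cells; each gene maps to its
disruption strain (identity mapping by default).

**Pipeline.** One master seed spawns per-stage substreams up front in a
fixed order, so disabling a stage never shifts another stage's draws; the
RunReport JSON records version, seed, parameters and summaries, and a rerun
with the same configuration reproduces the report bit-identically (within
platform floating-point caveats). Stage failures abort with the stage name
and leave a `FAILED` marker beside any partial outputs.

## Problem sizes

Simulation-heavy checks run at the study's natural scale, chosen once:
type-I calibration on 200 mutants × 6 traits at 1000 iterations; FDR/power
over 20 replicate libraries of 181 strains; cluster recovery on 181 strains;
image recovery on 50 fields of 5–15 aggregates; correlation-convergence
checks at 2000 strains; chain-decoupling at n = 5000; enrichment
calibration over 100 null replicates of 180 genes.

## Known limitations

* The generator emulates the *statistical* structure of the assays, not
  their biology: no swarm dynamics, no cell-level development, Gaussian
  replicate noise with trait-wise constant CV, and trait values (other than
  sporulation/count) are not range-constrained. Passing tests demonstrate
  correctness of the analysis machinery on data of this structure, not
  fidelity to any particular real library.
* Timing enters clustering/PCA as a z-scored 5-level ordinal and count as a
  z-scored Poisson draw; both are noisier per strain than the replicated
  traits, which z-scoring does not equalize.
* Under correlation distance, "nearly constitutive" expression profiles
  carry little shape information, so their cluster is recovered imperfectly
  at the default noise (the planted-archetype tests use low noise to check
  the mechanism; the enrichment stage does not depend on archetype
  recovery).
* The realized fraction of mutants with ≥1 planted effect tracks
  `effect_fraction` to within a few percent (Monte-Carlo calibration), not
  exactly.
* Exact permutation p-values are granular (multiples of 1/total); the BY
  step-up interacts with that granularity, so significant-call counts can
  shift discretely with the iteration budget.
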