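# Methods

This note records the statistical models, the conventions adopted where the
design was genuinely open, and what the synthetic-data experiments do and do
not demonstrate.

## Filtering

A locus passes when (i) its mean read depth over non-missing calls is
strictly greater than `min_locus_depth` (default 5), (ii) its overall minor
allele frequency is strictly greater than `min_maf` (default 0.05), and
(iii) its call rate is at least `min_call_rate` (default 0.72). The depth
rule is interpreted per locus (mean over calls) because it is a property of
the locus's read support; a per-call variant — masking individual calls with
depth ≤ 5 — is available via `FilterSpec(per_call_depth=True)`. Excluded
samples (e.g. reiteratively misplaced individuals) are removed before any
rule, as an explicit list rather than by automatic detection. The minor
allele is defined once over all samples after exclusion and frozen for all
downstream subsets, so effect signs cannot silently flip between dataset
partitions; exact 50/50 ties break toward the alphabetically smaller allele.
Missing dosage is a first-class state and is never imputed at this stage.

When population subsets are re-filtered for the partition series, only the
MAF and call-rate rules are reapplied: read depth is a property of the
sequencing run, not of the subset.

## Population structure

PCoA is classical metric scaling: double-center −½·D², eigendecompose, scale
eigenvectors by √λ. The default genetic distance is 1 − IBS allele sharing,
chosen to match the kinship currency used by the mixed models (the source
analyses do not state their PCoA metric). Negative eigenvalues —
non-Euclidean input — are excluded from the explained-variance normalization
and reported separately. Axis signs follow a fixed convention (the
largest-magnitude loading is positive) so runs are bit-reproducible.

AMOVA partitions squared Euclidean distances between dosage vectors
(pairwise-complete, normalized by shared-locus count) into among-locality,
among-population-within-locality and within-population components, using the
standard nested sums-of-squares with unequal-group-size coefficients.
Components may be negative and are reported raw; percentages truncate
negatives at zero by default. Permutation significance is deliberately not
implemented — only the percentage decomposition is used downstream.

Evanno's ΔK consumes a plain table of (K, run, log-likelihood) rows from an
external clustering program: ΔK = |mean L(K+1) − 2·mean L(K) + mean L(K−1)| /
sd(K), defined for interior K with at least two runs and positive run
standard deviation. Degenerate runs (sd = 0) are flagged rather than
dropped.

## Association scans

The model is dosage-on-factor: y_j = Xβ + ε per locus j, with X holding an
intercept, an optional phylogenetic covariate, and the factor block (one-hot
locality contrasts, or a single ordinal regressor of the habitat rank). The
factor is tested by the partial F comparing nested least-squares fits. This
orientation accommodates a categorical factor with many levels in one test
and reduces to the usual correlation test in the two-level case. A
categorical-habitat variant can be had by ranking habitats
non-monotonically; the default is the single linear rank regressor.

The mixed model adds a random effect u ~ N(0, σ²_g K) with K the IBS
allele-sharing matrix. Following EMMA, K is eigendecomposed once and the
REML profile in δ = σ²ₑ/σ²_g is maximized on a 61-point grid over
log δ ∈ [−5, 5] with bounded refinement to 10⁻⁶. `emma_full` re-estimates δ
at every locus on that locus's non-missing samples; `p3d` maximizes the
summed REML objective of the factor-free null model (over up to 500 evenly
spaced loci, mean-imputing missing dosages for this step only) and reuses
the single δ̂ for every locus test via Cholesky whitening of K + δI. Per
locus both families drop samples with missing dosage, so an identity K
collapses the mixed model exactly onto the GLM.

Pairwise-complete IBS matrices estimated from data with missing calls are
routinely slightly indefinite; eigenvalues down to −5% of the leading
eigenvalue are clipped to zero and anything worse is rejected as a malformed
kinship. P-values are floored at 10⁻³⁰⁰ to keep −log₁₀ finite. The genomic
inflation factor is λ_GC = median(χ²₁(p)) / 0.4549.

The phylogenetic covariate is the first principal coordinate of the
population-level distance matrix (patristic distances when a newick tree is
supplied), assigned to each sample through its population and centered. One
axis is the default because the source design specifies only "the
phylogenetic distance as a covariate"; `n_axes` exposes more.

Marker selection uses the GLM scans: on structured data the mixed models
over-control (the kinship absorbs the locality signal being tested), so MLMs
serve as diagnostics. Thresholds are always α/n_markers computed at run
time, never hard-coded printed values.

## Divergence and migration

Pairwise F_ST is the two-population Weir–Cockerham (1984) estimator: per
locus the a (among-population), b (among-individual) and c
(within-individual) components are computed from sample sizes, allele
frequencies and observed heterozygote frequencies, and the multi-locus
estimate is θ̂ = Σa / Σ(a+b+c) over loci where the denominator is non-zero.
Negative per-locus components are retained; loci monomorphic across both
populations are excluded and counted.

Migrants per generation are obtained from the island-model equilibrium: the
default closed-form moment estimator Nm = (1 − θ̂)/(4θ̂), plus a grid
pseudo-maximum-likelihood variant that fits per-locus θ̂ values to
θ(Nm) = 1/(1 + 4Nm) over log-spaced Nm ∈ [10⁻², 10²]. Full coalescent
migration inference is out of scope; network weights and group means depend
only on relative magnitudes. Non-positive θ̂ (undifferentiated pairs) maps
to a finite ceiling (default 20 migrants, logged) so summaries stay finite.
Group summaries report mean ± SE and the empirical 2.5–97.5 percentile
interval per category; the among-habitat-within-locality versus
within-habitat-across-localities contrast uses a two-sided Mann–Whitney U
(the source tables report p-values without naming a test). Edges carry a
panmixia flag at Nm > 1, the conventional one-migrant rule.

## IBD/IBE testing

Geographic distances are great-circle arcs on a sphere of radius
6371.0087714 km between population centroids (mean member coordinates).
Ecological distances are absolute differences of habitat ranks — frost
exposure F=1 < W=2 < D=3 and soil moisture D=1 < F=2 < W=3 by default, both
configurable, since the original rank codes live in supplementary material
not reproduced here; the directions follow the described habitat gradient
(frost most severe on exposed dry slopes, moisture highest in wet
depressions).

The Mantel test correlates strict upper triangles, permutes rows and columns
of the second matrix jointly, and reports the one-sided add-one p-value
(IBD/IBE predict positive correlation). Per-test seeds derive
deterministically from (master seed, dataset name, distance name). With
1,000 permutations the smallest attainable p is 1/1001 ≈ 0.001, which is
*larger* than the Bonferroni threshold α/N_PW for datasets with many pairs
(0.05/171 ≈ 0.0003); the significance flag therefore uses
max(α/N_PW, 1/(n_perm + 1)), i.e. a correlation that no permutation reaches
counts as significant, with raw p-values and thresholds reported alongside.
A second discreteness arises from exact matrix symmetries: habitat ranks
take three values, so on a 7-population habitat-contrast set only 24 of
5,040 relabelings change the frost matrix and the tie-aware p cannot fall
below ≈ 1/210 — below no sensible per-table threshold. The end-to-end
pattern check therefore evaluates its two prespecified hypotheses (frost
correlation present, geographic correlation absent, on the habitat-contrast
partition restricted to frost-associated markers) at α = 0.05 rather than at
the per-table Bonferroni level.

## Synthetic data

`simulate_dataset` emulates the sampling design: six localities at
approximately the real Andean centroids, habitats F/W/D in each, the
dry-slope cell of one locality split into two co-occurring taxa (19
populations), 162 samples, 1,273 loci. Ancestral frequencies are uniform on
[0.1, 0.9]. Locality frequencies drift along a greedy nearest-neighbour
chain starting from the northernmost locality (matching the genus's
north-to-south colonization), each step a Balding–Nichols draw with
F_pair(d) = d/(d + d₀), d₀ = 300 km. Within a locality, populations take a
further small Balding–Nichols step (f_within = 0.02) so within-locality
pairs are differentiated but weakly. Habitat loci (60 by default) get a
logit shift of δ_hab = 1.2 per frost-rank unit, centered; frequencies pushed
outside (0,1) are clamped to [0.001, 0.999] and counted. A small class of
loci (28) is private to the habitat-contrast localities, mirroring marker
panels that lose all polymorphism in the remaining localities — this is what
makes exactly one partition combination drop out in the design fixture.
Populations occupy distinct sampling sites ~3 km apart within a locality
(random direction per population): real habitat stands are distinct sites,
and exactly coincident coordinates would make the geographic matrix
degenerate under permutation. Missingness is uniform at 15%; depths are
negative binomial (mean 12, dispersion 3). Everything is reproducible from
the seed.

What the generator does *not* emulate: linkage between loci, genotyping
error, taxon-specific divergence beyond the population split, selection
dynamics through time, and — importantly — strong habitat differentiation at
neutral loci within localities. Because within-locality divergence is
limited to the planted loci plus the small f_within step, the AMOVA
habitat-within-locality component on synthetic data (a few percent) is much
smaller than the real study's, and within-locality migration estimates
often hit the Nm ceiling. Passing tests therefore validate estimator
correctness and the qualitative IBD/IBE logic, not the real data's variance
decomposition.

Single-locus GEA power on these defaults is materially attenuated by drift:
at realistic inter-locality distances the chain pushes many planted loci
near fixation in several localities, where a logit shift changes absolute
frequencies very little. Measured recall of planted loci at δ_hab = 1.2 is
≈ 0.45 (≈ 0.6 with the phylogenetic covariate), well short of the 0.8 one
might hope for — an honest property of GEA at this drift level, documented
rather than tuned away; recall does increase monotonically with δ_hab, and
the recovered marker sets are ample for the downstream partition analyses.

`simulate_island_model` is a discrete-generation Wright–Fisher model of two
demes of N diploids. By default migrants are drawn from the across-deme
mean frequency (Wright's migrant-pool convention), under which the
equilibrium Weir–Cockerham F_ST matches 1/(1 + 4Nm) — the convention the
moment estimator inverts. Literal exchange with the other deme
(`migration="exchange"`) is also available; because the source deme itself
drifts, it equilibrates near 1/(1 + 8Nm) and is not what the estimator
assumes. Final genotypes are drawn without replacement (hypergeometric) from
the 2N gene copies.

## Problem sizes

Simulation-based checks use sizes chosen to make the statistics stable while
keeping the suite quick on one CPU: 2,000 loci for equilibrium F_ST and null
calibration, 500 loci × 20 seeds for migration-rate recovery, 500 replicates
for Mantel null uniformity, and 20 seeded datasets at full design size
(1,273 loci, 162 samples) for the end-to-end pattern-recovery rate.
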