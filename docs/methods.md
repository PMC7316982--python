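# Methods

This note documents the statistical models implemented in `gutmwas`, the
defaults and why they were chosen, what the synthetic-cohort generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Synthetic cohorts

All stages consume feature-by-sample abundance tables; the generator
(`gutmwas.simulate`) produces them with planted, recoverable structure.
Every output is a deterministic function of `(CohortDesign, seed)`; the
global seed is expanded into independent per-stage substreams
(genes / taxa / metabolites / mice) so any stage regenerates identically on
its own.

**Gene catalog.** Each of `n_clusters` co-abundance clusters shares a
log-normal base trajectory across samples; a member gene's depth is the
base times `exp(Normal(0, noise_sd))`. Heavy-tailed log-normal depth is the
standard generative stand-in for metagenomic gene abundance. Differential
clusters shift the case-group mean by `effect_log2fc` on the log2 scale.
Annotations place 95% of a cluster's genes on its true species with DNA
identity drawn from 95–99%, query overlap 0.7–1.0; background genes carry
sub-threshold decoy hits so the taxonomy-voting thresholds are actually
exercised.

**Taxon tables.** Log-normal abundances with a taxon-specific location
(SD 1.5) giving the usual steep rank-abundance profile; planted
differential taxa (default 5) shift by `effect_log2fc` with alternating
sign; each sample is then closed to unit sum.

**Metabolites.** A linked metabolite is an exponential (hence monotone)
transform of a latent Gaussian coupled to its driver species'
log-abundance. The latent correlation r is set from the target Spearman ρ
through the Gaussian-copula identity ρ = (6/π)·arcsin(r/2), so the
empirical Spearman lands near the target without tuning.

**Mouse arms.** Per animal: Bernoulli aneurysm, Bernoulli rupture
conditional on aneurysm (rupture-rate denominators are aneurysm-positive
animals, matching how such experiments are reported), and for symptomatic
animals an onset day from a geometric distribution (p = 0.15) truncated to
the 21-day observation window — the simplest discrete event-time law on
that support. All other animals are censored at day 21. The default arm
parameters (85%/82% vs 45%/22%) are the printed incidence/rupture rates of
the fecal-transplant experiment, used as design parameters.

**What passing tests do and do not show.** The generator produces clean
log-normal compositions: no zero inflation, no sequencing noise, no batch
or covariate structure, no phylogenetic correlation, equal group sizes.
Recovery results (sensitivity ≈ 1 at log2FC = 2 with n = 100+100; MLG
ARI ≈ 1 at noise SD 0.2) are therefore upper bounds on real-data behavior;
they validate the *implementations*, not effect sizes in any real cohort.
One deliberate realism: because tables are closed, strong planted effects
induce genuine compensatory shifts in all other taxa, so discovery counts
on effect-bearing synthetic tables exceed the planted count — that is
compositionality, not a false-positive pathology (the zero-effect null
yields ≈ 0 discoveries at q < 0.05).

## Diversity and ordination

- Rarefaction draws `n_repeats = 100` subsamples without replacement
  (multivariate hypergeometric) per depth; the Monte-Carlo mean is checked
  against the closed form E[S] = Σᵢ (1 − C(N−Nᵢ, m)/C(N, m)).
- Shannon index defaults to base 2 (QIIME v1 convention); the base is a
  parameter because natural log (vegan) is the other common dialect.
- PCoA: Gower double-centering of −d²/2, symmetric eigendecomposition,
  axes scaled by √eigenvalue. Negative eigenvalues are reported in the
  spectrum but contribute no axes (no Cailliez/Lingoes correction,
  matching default vegan behavior).
- ANOSIM ranks all pairwise distances jointly;
  R = (r̄_between − r̄_within)/(M/2), M = n(n−1)/2. Sampled permutation
  p-values use the add-one correction p = (k+1)/(B+1), which can never
  return 0 — appropriate for a sampled null. Default B = 999.

## Differential abundance

Per-feature two-sided Wilcoxon rank-sum with midranks. The normal
approximation uses the tie-corrected variance and **no continuity
correction** — the large-sample `wilcox.test(correct=FALSE)` path common in
metagenomics pipelines; exact enumeration over all C(n₁+n₂, n₁) assignments
is available for tie-free data and is the oracle for small samples.
Benjamini–Hochberg is the step-up rule q₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j capped at
1. Direction comes from group arithmetic means of relative abundance
(medians available). No prevalence pre-filter by default.

## Metagenomic linkage groups

Marker genes are clustered by canopy/centroid iteration on the Pearson
correlation of log-transformed abundance: a seed gene opens a canopy;
genes whose correlation to the running centroid reaches the threshold
(default 0.9) are absorbed; the centroid is recomputed to convergence;
canopies whose centroids correlate at or above the threshold merge.
Iteration order is the input marker order, making the partition
deterministic. The log pseudocount is half the smallest nonzero abundance —
avoids −∞ while preserving ranks. Only clusters with **more than 50 genes**
qualify as MLGs (strict threshold).

MLG abundance is the gene-length-weighted mean of member depths,
a_s = Σ_g L_g·d_{g,s} / Σ_g L_g, i.e. a length-weighted mean of
length-normalized abundance; under per-gene length normalization upstream
this choice differs from an unweighted mean only in scale, not ordering.

Taxonomy voting (inclusive thresholds throughout): species if ≥90% of
members hit one species at ≥95% DNA identity and ≥70% query overlap; else
genus if ≥80% hit one genus at ≥85% DNA **and** protein identity; else
unclassified. Ties break by higher qualifying fraction, then lexicographic
name. Missing annotation is simply non-qualifying.

## SparCC

Fractions only constrain ratios, so Pearson correlations of closed data
carry closure artifacts. SparCC works from log-ratio variances
t_ij = Var(log xᵢ/xⱼ): assuming most pairs are uncorrelated, basis
variances ω solve the linear system with row sums of t and matrix
(D−2)I + J, and ρ_ij = (ωᵢ+ωⱼ−t_ij)/(2√(ωᵢωⱼ)), clipped to [−1,1].
The strongest pair above the exclusion threshold is iteratively removed
*from the solve* (its t_ij still enters the final correlation formula) for
up to 20 iterations. Defaults follow the original SparCC release: 20
exclusion iterations, exclusion threshold 0.1, 20 Dirichlet draws, 100
permutations.

Dirichlet resampling integrates out sampling noise: counts map to
per-sample Dirichlet(α = counts + 1) draws, and the estimate is the median
over draws. Closed fractions are first scaled to pseudo-counts at depth
10⁴ per sample; this default reflects that real shotgun per-sample read
counts are far larger than the +1 prior, which would otherwise inject
artificial noise into small fractions and attenuate strong correlations.

Pseudo-p-values: each permutation shuffles every feature's values across
samples independently and recomputes the matrix; two-sided extremity on
|ρ| with the add-one correction (an exact-zero p would break BH).
A calibration caveat: permuting features *of a closed composition* adds
per-sample total-depth variance to every log-ratio, so the permuted null
is slightly wider than the observed one and p-values lean conservative in
the signal direction; calibration is exact when features are independent
counts, which is what the null-calibration tests use.

Network edges: BH over the upper-triangle pseudo-p grid; keep pairs with
ρ > 0.5 or ρ < −0.5 (strict) and q < 0.01; written as TSV and GraphML.

## PLS-DA and Monte-Carlo stability selection

`PLSDAClassifier` is single-response NIPALS PLS against a centered 0/1
response. Columns are centered and, by default, autoscaled to unit
variance, with the composite coefficient β = W(PᵀW)⁻¹q mapped back to the
original axis; prediction thresholds the centered score at 0. Autoscaling
is the chemometrics default and makes the stability statistic below
exactly invariant to positive rescaling of any column (centered-only PLS
is not scale-equivariant); `scale=False` recovers the raw-covariance
variant. `n_components` defaults to 2. Zero-variance columns get
coefficient 0 with a warning.

Stability selection fits the model on N resamples of size M = ⌊n/2⌋ drawn
without replacement, stratified by class so every resample contains both
groups. Per variable, c_j = β̄_j / s(β_j) with the N−1 denominator; β̄_j is
the resample mean (the only reading under which s is a standard
deviation). N defaults to min(n², 2000): the n² schedule is statistically
comfortable but quadratic in cohort size, and the cap is configurable up
to n². A constant variable has s(β_j) = 0; its c_j is NaN and excluded
from selection. The selected set comes from scanning ascending |c_j|
cutoffs and taking the cutoff with the best k-fold (default 4)
cross-validated PLS-DA accuracy; ties resolve to the larger cutoff (fewer
variables). `MonteCarloStabilitySelector` wraps the whole procedure as an
sklearn transformer (`fit` → `support_`, `c_`; `transform` filters
columns).

## Classifier evaluation

30 random trials of stratified 4-fold cross-validation; out-of-fold
continuous scores are averaged over trials per sample; ROC by threshold
sweep with trapezoidal AUC (equal, including under ties, to the
Mann–Whitney concordance U/(n₁n₂)); AUC interval by stratified percentile
bootstrap (1000 resamples, 95%). BCa was not used because a percentile
interval is the plainest reading of "bootstrap confidence interval". The
learner is pluggable (`fit` + `predict_proba`/`decision_function`); the
default is a 200-tree random forest, and `PLSDAClassifier` satisfies the
same contract — the evaluation protocol, not the learner, is the point of
this module.

## Microbe–metabolite association

Spearman ρ is the Pearson correlation of midranks. For n ≤ 9 the two-sided
p comes from the full n! permutation distribution; above that, the
t-approximation with n−2 df. The heatmap computes the full species ×
metabolite grid, BH-adjusts across the *whole grid*, hides cells with
|ρ| < 0.4 (strict — a cell at exactly 0.4 is shown), and marks
significance at the 0.05/0.01 levels on BH-adjusted values by default
(raw-p marking via `mark_on="p"`). Rows and columns are ordered by
agglomerative clustering on 1 − Pearson distance, average linkage by
default (single/complete/ward available); a constant row's undefined
correlations become distance 1 with a warning.

## Preclinical statistics

- Fisher's exact test: hypergeometric over all tables with the observed
  margins; the two-sided p sums point probabilities ≤ that of the observed
  table (the R `fisher.test` rule; a small relative tolerance absorbs
  floating-point ties). The routine asserts internally that the point
  probabilities sum to 1.
- Kaplan–Meier: product-limit S(t) = Π(1 − dᵢ/nᵢ) over event days,
  censoring at day 21, restricted to aneurysm-positive animals (the
  denominator convention of symptom-free curves).
- Log-rank (Mantel–Cox), k arms: at each event time, observed minus
  hypergeometric-expected events per arm with the matching covariance;
  quadratic form over k−1 arms, χ² with k−1 df.
- Group comparisons: Student's t, exact Mann–Whitney (shared machinery
  with the differential-abundance module), one-way ANOVA with Bonferroni
  post-hoc pairwise t-tests (p × number of pairs, capped at 1).
- Hypergeometric enrichment: upper-tail P[X ≥ overlap] per term, BH across
  terms, significance at q < 0.05.
- DEG set exclusion is plain set difference, A \ (A ∩ B).

One reconstructed table deserves note: the rupture comparison printed as
44% vs 83% with n = 9 vs 18 and P = 0.026 does not reproduce under the
point-probability two-sided Fisher test on the implied counts
[[4,5],[15,3]] (which gives ≈ 0.07); the test variant behind that printed
value is unclear, and the package does not report it.

## Pipeline and I/O

Stages hand off through flat TSV/JSON files (features in rows, samples in
columns, first column the feature id), so any stage can be inspected or
re-run from its persisted inputs; `run_report.json` records per-stage
status, parameters, manifest, and headline statistics. Outputs are pure
functions of (inputs, parameters, seed); identical runs are byte-identical.

## Problem sizes and defaults in the test suite

The suite exercises the study-scale conditions where they are cheap
(n = 100+100 cohorts for differential abundance and stability selection;
SparCC at 50 features × 200 samples) and smaller cohorts (40+40, a few
hundred genes) where a full-scale run would add nothing but time. Null
calibrations use 1000 replicates with permutation counts of 199; stability
recovery uses N = 2000 resamples over 20 seeds. The full suite runs in
about a minute on one CPU.

## Known limitations

- SparCC assumes a sparse correlation network; dense strong correlations
  bias basis variances (the exclusion heuristic mitigates, not removes,
  this).
- The permutation null for SparCC pseudo-p is exact only for unclosed
  (count-like) inputs; see above.
- The canopy clustering is order-deterministic but, like all canopy
  variants, not invariant to input order in adversarial geometries.
- Exact Wilcoxon enumeration is exponential; it is intended for n ≤ ~20
  pooled observations and falls back to the normal approximation on ties.
- The synthetic generator omits zeros, batch effects, and covariates, so
  it cannot benchmark methods' robustness to those features of real data.
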