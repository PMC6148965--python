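# Methods

## Model

Counts are modeled per gene and group as i.i.d. negative binomial,
Y ~ NB(μ, φ) with Var(Y) = μ + φμ², so φ = 0 is the Poisson limit. Group 1
is the normal group, group 2 the disease group. The joint null is equality
of both mean and dispersion across groups; the alternative frees both per
group. This targets syndromes, where disease replicates are heterogeneous:
a gene aberrant in only some disease replicates shifts the disease-group
*dispersion* much more than its mean.

Normalized counts (TMM-scaled to the mean library size) are rounded to the
nearest integer before likelihood evaluation, keeping the NB pmf exact. The
offset-based alternative (continuous extension of the likelihood) was
considered and rejected in favor of evaluating the stated count model
directly; at typical depths the rounding perturbation is far below the
sampling noise.

## Estimation

For fixed φ the NB score in μ vanishes at the sample mean, so all fits use
the profile likelihood: μ̂ is the sample mean and the dispersion is found by
a coarse log-spaced scan over [0, 50] followed by golden-section refinement
(absolute tolerance ~1e-9, deterministic, no random starts). φ̂ = 0
(underdispersed samples) and φ̂ = 50 are boundary solutions and flagged.
All-zero observation vectors have likelihood 1 in the μ → 0 limit; such
fits are marked failed for hyperprior purposes but do not abort a run.

The sampling variance τ²_g of φ̂ enters the shrinkage weights. The inverse
expected Fisher information gives the asymptotic form 2(φ + 1/μ)²/n; direct
simulation across the count regimes exercised here shows the realized
finite-sample variance is smaller by almost exactly (n−1)/n (the φ ≥ 0
boundary truncates the estimator), so τ²_g = 2(φ̂ + 1/μ̂)²(n−1)/n² is used,
floored at 1e−6. The observed (curvature-based) information was evaluated
and rejected: with 4 replicates it is numerically erratic — near-flat
profiles produce unbounded variances while boundary fits produce spuriously
tiny ones — and those heavy tails make the genome-wide moment estimates of
the prior meaningless.

## Empirical-Bayes shrinkage

Each pooling context (pooled, group 1, group 2) carries a normal prior
φ_g ~ N(φ₀, τ₀²) with φ̂_g | φ_g ~ N(φ_g, τ²_g). Hyperpriors are estimated
from all genes by method of moments: φ₀ is the mean of the per-gene MLEs and
τ₀² = max(0, var(φ̂) − mean(τ²)), with failed fits excluded. The shrunken
dispersion is the precision-weighted posterior mean, floored at 0 because
the NB dispersion cannot be negative; τ₀² = 0 collapses every gene to φ₀.
Fewer than 10 usable genes is an error — the prior would be meaningless.

The shrunken dispersions are plugged into the likelihood-ratio statistic
with only the means re-profiled (they remain the sample means). Because
plug-in dispersions break the nesting of the two models, the resulting
statistic can be negative; it is deliberately not clipped — the permutation
null absorbs the negative tail.

## Permutation null and FDR

The shrunken-dispersion statistic has no analytic reference distribution.
Its null is built by relabeling: genes with chi-square p ≥ 0.1 under the
asymptotic screen are "null-like" (0.1 is a configurable cutoff); for every
distinct relabeling of the samples into the two group sizes — excluding the
observed labeling, collapsing label swaps in balanced designs since the
statistic is label-symmetric, and capped at 200 seeded-subsampled
relabelings (exhaustive for 4–6 per group, 34–461) — all per-gene fits and
all three hyperpriors are re-estimated under the permuted labels and the
null-like genes' statistics are pooled. The pooled-context fit does not
depend on the labels, so it is computed once and reused; the result is
identical to recomputing it per permutation. Pooling across genes assumes
exchangeability of null-like statistics across genes; this is a modeling
assumption, not a checked property.

Permutation p-values use the add-one convention (1 + #{null ≥ stat})/(N+1),
guaranteeing valid, strictly positive p-values. Storey's q-value procedure
with a single λ = 0.5 converts them to FDR estimates; genes whose fits
failed carry q = NA and are excluded from the multiple-testing denominator.
Permutations are processed serially; they are independent work units, so
results cannot depend on scheduling.

## Replicate classification

For each declared DE gene an equal-tailed interval for a *single new
observation* from NB(μ̂_g1, φ̂ᴮ_g1) is computed by pmf summation: the
largest lo with P(Y < lo) ≤ α/2 and smallest hi with P(Y > hi) ≤ α/2. A
prediction interval (not a confidence interval for the mean) is the only
construction under which comparing individual disease observations to the
bounds is coherent. α is the family-wise level divided by the number of
disease replicates — the Bonferroni family is the within-gene comparisons,
applied after DE selection; a global genes × replicates family is available
behind a flag. Counts above hi are aberrant_high, below lo aberrant_low.
A declared DE gene may legitimately have zero aberrant replicates (borderline
dispersion evidence); it is reported as such, never suppressed. Subset
summaries count genes by their exact aberrant-replicate set and partition
the DE list.

## Normalization and filtering

Genes with total count ≤ 10 across all samples are discarded first; TMM
factors are then computed on the filtered matrix (the alternative — factors
from unfiltered counts — changes factors negligibly because TMM already
trims extreme log-ratios). TMM uses the published defaults: reference =
sample whose upper-quartile of scaled counts is closest to the mean
upper-quartile, 30% two-sided trim on M-values, 5% on A-values,
inverse-asymptotic-variance weights, factors centered to geometric mean 1.
Normalized counts are scaled to the mean library size to stay count-like.
The implementation reproduces edgeR's `calcNormFactors(method="TMM")` to
1e-6 on random matrices (cross-checked in the test suite).

## Simulation framework

The generator draws per-gene (μ, φ) from a parameter pool. The synthetic
default pool — log₁₀ μ ~ N(2, 0.5²) truncated to μ ≥ 1, φ ~ Gamma(shape 2,
mean 0.15) — is a documented stand-in for pools fitted from real data; an
empirical (gene, μ, φ) table can be supplied instead. Disease-group DE
genes follow three scenarios: (1) φ_g2 = φ_g1 + X_φ·δ_φ with
δ_φ ~ Beta(2, 2) in every disease replicate; (2) the same shift in only the
last k_g replicates, k_g ~ U{1, 2, 3, 4}; (3) a dispersion shift plus a
mean shift μ_g2 = μ_g1 + X_μ·δ_μ·σ_g1 with δ_μ ~ Beta(2, 4) and σ_g1 the NB
standard deviation computed from the pool parameters (not sample moments).
Studies 1–2 use X_φ = 0.4; study 3 uses X_φ = 0.3 and X_μ = 2; study 4
mixes 79% EE with 7% of each scenario. At full scale that is 4000 EE + 1000
DE genes (3950/350/350/350 for study 4); the suite and the acceptance
script run the same designs at 1000 genes with the proportions preserved.

Simulated counts share a common library size by construction and are
treated as already normalized (TMM is skipped inside simulation studies; a
flag re-enables it). What the generator does *not* emulate: library-size
variation, batch effects, gene–gene correlation, and the trended
mean–dispersion relationship of real RNA-seq — so passing simulations
demonstrate correctness of the machinery and qualitative power behavior,
not real-data operating characteristics.

Under the synthetic pool's dispersion level (mean φ ≈ 0.15) the
dispersion-only alternative at 4 replicates per group is intrinsically hard:
the joint test ranks DE genes consistently above the mean-only baseline, but
realized power at q ≤ 0.05 is near zero at desk scale. With lower baseline
dispersions (as in pools fitted to real overdispersion-poor tissue data) the
same code shows the large ranking advantage expected of the method; the
mean-only baseline stays near chance in both regimes. Evaluation metrics
(TPr at nominal FDR, realized FDR with the empty-set convention FDR = 0,
trapezoidal ROC/AUC) come from scikit-learn's ROC utilities, cross-checked
against a brute-force threshold enumeration in the tests.

## Numerical conventions and limitations

- Chi-square p-values for the 2-df joint LRT are exp(−LR/2) exactly.
- Repetition seeds are base_seed + repetition index; every stochastic
  component accepts an explicit seed and repeated runs are bit-identical.
- The mean-only NB LRT baseline (common profiled dispersion, 1 df) exists
  for comparison only; it is not a supported analysis path.
- Designs below 2 replicates per group are rejected (no permutations
  exist); covariates, multi-group designs and quasi-likelihood are out of
  scope.
- The permutation null pools across genes; strong gene–gene dependence or
  highly heterogeneous statistic scales across genes would weaken its
  calibration. The global-null calibration checks in the suite bound this
  at desk scale only.
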