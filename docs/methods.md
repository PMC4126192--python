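# Methods

## Genotype model

Genotypes are binary parental types x ∈ {0, 1} on a genetic map
(cM positions per chromosome). Meiosis induces an approximately Markov
dependence along a chromosome, so the conditional law of a marker given
everything else reduces to its flanking markers.

**Interior model.** We use the bridge of a stationary two-state Markov
(telegraph) process with agreement probability (1 + e^{−αd})/2 across
distance d:

P(x_t = 1 | x₀, x₁) = (1 + δ_{x₀}u)(1 + δ_{x₁}v) / [2(1 + δ_{x₀}δ_{x₁}uv)],
u = e^{−α(t−t₀)}, v = e^{−α(t₁−t)}, δ_x = 2x − 1.

Properties: at α = 0 agreeing flanks determine the genotype with
certainty; as α → ∞ the probability is ½ for any flanks; disagreeing
flanks give exactly ½ at the interval midpoint, and the α → 0 limit is
linear interpolation in distance; as t → t₀ the probability approaches
the indicator of x₀; the |derivative| in t is smallest mid-interval.
α ≥ 0 has the units of 1/cM and plays the role of a recombination
rate. The disagreeing-flank branch is evaluated with `expm1` so the
small-α limit is numerically exact.

**Edge model.** A chromosome-end marker conditions on its single
neighbor: P(x = 1 | x₀) = ½ + ½ δ_{x₀} β^d with β ∈ [0, 1] (β^d is a
power; only this reading keeps the value in [0, 1] for all d). One β is
shared between left and right edges. The interior bridge degenerates to
this form (with β = e^{−α}) when one flank is removed, which is also
how imputation handles one-sided information.

**Estimation.** α and β maximize pseudo log-likelihoods: sums of
full-conditional Bernoulli log-probabilities over every (RIL, marker)
whose conditioning neighbors are observed (complete-triple /
complete-pair analysis; parental rows are excluded by the caller).
Both problems are 1-D and empirically unimodal; we bracket on a grid
(α on [0, 5] log-spaced — beyond α ≈ 5/cM adjacent markers are
independent for practical purposes — β on [0, 1]) and refine with
bounded Brent to 1e−8. Chromosome homogeneity is tested by
LRT = −2[ℓ(shared) − Σ_c ℓ(per-chromosome)] against χ²_{C−1}
(the pseudo-likelihood LRT is a weighted sum of χ²₁ variables; the χ²
reference is the conventional approximation), optionally with a
parametric bootstrap that regenerates genotypes from the fitted
telegraph chain at the observed map positions, preserving the observed
missingness mask. Goodness of fit uses Pearson's Σ(x−π̂)²/(π̂(1−π̂))
with df = #terms − #fitted parameters; a degenerate fitted probability
contributes 0 if the observation matches and flags lack of fit (+∞)
otherwise.

## Imputation

Each missing entry conditions on the nearest *observed* flank on each
side: both sides → interior model; one side → edge model; neither
(whole chromosome missing for that RIL) → P = ½. The genotype is the
rounded probability — exactly ½ rounds down to 0, deterministically;
its weight is then 0, so the entry carries no influence downstream —
and the certainty weight is w = 2|P − ½|. Observed entries keep their
genotype with weight 1. Imputation is idempotent and never fails; every
entry carries a provenance flag (observed / model_imputed /
edge_imputed / fallback). The nearest-marker baseline copies the
closest observed genotype (cM distance, ties to the lower position)
with weight 1, the convention of the methods it stands in for; its
whole-chromosome fallback is genotype 0 with weight 0.

## Phenotype adjustment

Replicated trait measurements are adjusted by OLS on the nuisance
covariates (intercept; categorical covariates as treatment contrasts
with lexicographic level order), residual = observed − fitted; rows
with a missing trait are dropped. Residuals map to genotype rows either
one-per-observation (`replicate_rows`, the default — genotype rows
repeat) or averaged per RIL (`mean_per_ril`). Both are exposed because
replicated designs can reasonably be fed to the selection step either
way; the two coincide for one observation per RIL.

## Weighted lasso

The estimator minimizes Σᵢ wᵢ(θ)(yᵢ − xᵢᵀθ)² + λ‖θ‖₁ with
wᵢ(θ) = Σⱼ wᵢⱼ|θⱼ|/Σⱼ|θⱼ|, a circular definition resolved by iterating:
initialize with the ordinary lasso (all wᵢ = 1), then alternate the
weight update and a weighted L1 fit until the squared Euclidean change
of the weight vector drops below ε = 1e−8 (at most 50 outer
iterations). An all-zero coefficient vector leaves the weight update
0/0; those rows get wᵢ = 1 (no relevance information → no
down-weighting). The weighted fit is reduced to a plain lasso by
scaling rows with √wᵢ and solved by cyclic coordinate descent
(scikit-learn, tolerance 1e−7, warm-started along the path). The λ
grid is 100 log-spaced values from λ_max = 2·max|Xᵀy| (first solution
all-zero) down three decades.

**Known limitation — weight cycles.** The fixed-point iteration can
enter a genuine 2-cycle at isolated grid points near λ_max, where a
single marker flickers in and out of the active set and flips the
weight vector between two states. The solver detects the cycle,
terminates, returns the best iterate under the weighted objective and
flags the point as non-converged; on realistic inputs (weights 1 except
~10% imputed entries) fewer than ~5% of (fixture, λ) points are
affected and the pipeline warns rather than aborts.

λ is selected by BIC(λ) = RSS(λ)/s² + df(λ)·ln n with df the nonzero
count and s² a λ-free scale: the full-OLS residual variance when
p < n, else a MAD-based estimate of the response spread. Ties break
toward larger λ (the sparser model). Note the RSS uses the shrunk
lasso coefficients, so at weak signal BIC prefers the empty model —
a property of the criterion, not a defect.

**Baselines.** Ordinary lasso on the completed (rounded) genotype
matrix; adaptive lasso with penalty weights 1/|θ̂_OLS|^γ, γ ∈
{0.5, 1, 2} (requires p < n; a zero OLS coefficient pins its marker at
zero; no ridge fallback is improvised); and a multiple-regression scan:
one full OLS fit, markers selected at per-coefficient t-test p ≤ s for
s on the 67-step grid 0.015, 0.030, …, matching the resolution of the
λ sweep. No multiplicity correction is applied — the scan sweeps raw
thresholds for ROC purposes.

**Per-marker scores.** For marker j in the chosen set (the BIC-selected
set by default, or all markers), score = (n/2)·log₁₀(RSS₋ⱼ/RSSⱼ) from
two OLS fits with intercept; values below 0.01 are reported as 0. An
exactly duplicated marker scores 0 since dropping it leaves the fit
unchanged.

## Simulation harness

`simulate_genotypes` draws, per chromosome, a binary Markov (1-D Ising)
chain on a 1-cM lattice: stationary marginal ½, adjacent sites agreeing
with probability e^η/(e^η + e^{−η}) (η = 0.4 by default → 0.690);
chromosome lengths are rounded to whole cM and the observed markers are
read off at the rounded map positions, so realistic inter-marker
distances enter by subsampling. Chromosomes and RILs are independent.
Missingness is MCAR (i.i.d. Bernoulli(0.1)) or MAR: a two-state chain
over the missingness indicators along the marker order with coupling
η_MAR = 0.6 and an external field solved from the stationary equations
so the marginal missing rate hits the target (calibrations cached).
Traits are additive over 6 true QTL markers — evenly spaced over the
map, or clustered 3+3 in the first halves of chromosomes 1 and 2 —
with alternating effects ±0.5 and Gaussian noise σ² ∈ {0.5, 1, 2, 3}.
Defaults are 165 RILs and 50 replicates; the test suite runs 20
replicates to keep runtimes at minutes on one CPU.

`run_study` sweeps each selector (λ path for the lasso family, the
67-threshold grid for the regression scan), scores selections against
the true QTL set at every sweep point, averages TPR/FPR pointwise over
replicates on a λ grid fixed once from a seeded reference replicate,
and reports a trapezoidal AUC (with (0,0)/(1,1) anchors) as a scalar
summary. Everything is reproducible bit-for-bit from the scenario seed.

**What the generator does and does not emulate.** The Ising chain
reproduces binary genotypes, balanced parental ancestry and
distance-decaying linkage, plus realistic map geometry and missingness
rates; it does not emulate segregation distortion, genotyping-error
structure, or interference. One consequence of the default coupling
deserves emphasis: at η = 0.4 per 1-cM step, markers ~6 cM apart are
nearly independent (correlation ≈ 0.38⁶ ≈ 0.003), so flanking markers
carry almost no information about a missing genotype, certainty weights
are near 0, and model-based and nearest-marker imputation coincide up
to noise. In this regime the benchmark orderings between the
imputation-aware methods are statistically degenerate — the replicated
AUC differences are within ±0.01 and change sign across master seeds —
and the corresponding ordering tests in `tests/test_acceptance.py`
fail. A controlled experiment with oracle certainty weights (exactly 0
at corrupted entries) shows the same null result, because with effects
±0.5 and σ² ≥ 0.5 the imputation-noise contribution to the residual
(θ²·Var(x) ≈ 0.06) is an order of magnitude below the trait noise.
Method separation therefore requires either stronger linkage at the
observed spacing or weaker trait noise than these study conditions
provide. The generator is left at the documented conditions rather
than recalibrated; on linked genotypes (telegraph chains at
α ≈ 0.05/cM) the model-based imputation does outperform the
nearest-marker baseline in accuracy, and the σ²-monotonicity and
wlasso-vs-adaptive-lasso orderings hold as expected.

## Numerical conventions

- Optimizers: bounded Brent (xatol 1e−8) after grid bracketing for α
  and β; coordinate descent tol 1e−7 for all L1 fits; weight-iteration
  ε = 1e−8 (squared Euclidean norm over RILs).
- Exact P = ½ rounds to genotype 0; nearest-marker distance ties go to
  the lower cM position; BIC ties go to larger λ. All deterministic.
- Every randomized routine takes an explicit seed or Generator;
  study replicates use `SeedSequence.spawn`.
- Degenerate inputs: all-zero response → all-zero path (valid); a RIL
  with a fully missing chromosome is filled at weight 0; chromosomes
  without usable likelihood terms are dropped from the homogeneity test
  with a warning.

## Problem sizes used in the checks

Desk-scale identities and oracle equivalences run on ≤ 6-variable
fixtures (< 1 s). Parameter recovery uses 20 panels of 165 RILs per
rate (~2 s per rate). The replicated benchmarks use 20 replicates of
165 RILs × 69 markers per scenario (½–1 min per scenario), against 50
replicates in the full study design.
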