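# Methods

This note documents the models, numerical choices, and limitations behind
the package, in the order the pipeline runs them.

## Karyotype space and the missegregation kernel

A karyotype is a length-22 vector of non-negative integer autosome copy
numbers (genomic order; sex chromosomes excluded). Cells with any
chromosome at 0 copies, or above a cap (`max_copy`, default 8), are
non-viable. With 1–8 copies per autosome the space holds 8²² ≈ 7.4 × 10¹⁹
viable states, which is why fitness is charted only inside a local region.

Missegregation is modeled per chromosome copy: during one division, each
of the parent's N = Σ n_c copies missegregates independently with
probability p; a missegregating copy lands wholly in one daughter
(direction uniform), so daughters always satisfy d₁ + d₂ = 2 × parent
chromosome-wise. Two views of this kernel are kept deliberately separate:

- the **single-event approximation** used by inference and the transition
  matrix, P(αᵢ|αⱼ) = n_c p (1−p)^{N−1} / 2 for distance-1 pairs, and
- the **exact multi-event kernel** used by the agent-based model
  (stochastic draws; an exact per-chromosome convolution is available for
  small toy karyotypes and validates the sampler).

The kernel assumes a per-*copy* rate, so higher-ploidy cells missegregate
more often in total — the standard whole-chromosome model. An alternative
per-chromosome (ploidy-independent) rate would change the quasispecies
ploidy analysis; the kernel object is the single place to swap it.

The **charted region** is the union of Manhattan balls of radius 2
(configurable) around the frequent karyotypes, restricted to viable
states. Interpolation is refused outside it: anchors carry no information
further than two missegregations out.

## Frequent-karyotype fitness (replicator stage)

Sampled clone frequencies follow the continuous-time replicator equation;
its closed form is evaluated with log-sum-exp normalization so large
f·t products are safe. Frequency data identify fitness only up to an
additive constant; the gauge fixes the abundance-weighted mean fitness of
the frequent set at the first timepoint to 0. An externally measured
absolute growth rate can be added post hoc.

Initialization solves a weighted least-squares system on interval
log-frequency increments, Δlog xᵢ ≈ (fᵢ − c_k)Δt_k, with one free offset
c_k per interval absorbing the unknown mean fitness, weights equal to the
harmonic mean of the counts flanking the interval, and a 0.5 pseudo-count
before logs (the refinement stage handles zeros natively). Refinement
maximizes the multinomial likelihood of the counts jointly over f and the
initial frequency vector (softmax-parametrized; fitting x₀ jointly rather
than pinning it to the noisy first sample is the package's choice and is
configurable). The optimizer is L-BFGS-B with numerical gradients,
relative tolerance 1e-8; if it cannot improve on the initialization the
initialization is returned, and non-convergence warns rather than fails
silently. Uncertainty comes from a within-timepoint multinomial bootstrap
of cells.

Desk-scale recovery behavior: with 2000 cells per timepoint and 4–8
passages, pairwise fitness differences in the 0.05–0.3/day range are
recovered with Pearson r > 0.9 (the acceptance suite measures this).

## Neighbor fitness (mutational flux stage)

Neighbors of the frequent set are typically seen in 0–5 cells, so their
frequency is modeled as flux from frequent parents plus own growth. The
linear ODE is solved with an exact exponential integrating factor on a
dense time grid (201 points; trapezoid on the influx), with parent
trajectories taken from the fitted replicator solution and interpolated
in log space between observations. Influx and state are floored at zero:
with anchored (relative) fitness values, a negative parent rate would
otherwise produce a negative "flux", which has no physical reading here.
The neighbor starts at frequency 0 at the first observation time.

The MAP objective sums a binomial log-likelihood of the neighbor's counts
(absence is informative and bounds fᵢ from above) and one Normal prior
term N(fᵢ − fⱼ | μ_δ, σ_δ²) per adjacent frequent parent. The prior is
estimated from the data: pairwise fitness differences among *adjacent*
frequent clones, pooled symmetrically (so μ_δ = 0 by construction) with
σ_δ their standard deviation; with no adjacent pairs, σ_δ falls back to
the SD of all frequent fitness values. The fit is a bounded scalar
optimization on fᵢ ∈ [−2, 2]/day.

## Kriging interpolation and the CV score

Universal Kriging with a constant mean estimated by generalized least
squares, covariance Matérn ν = 3/2,
C(d) = σ²(1 + √3 d/ρ)exp(−√3 d/ρ) + τ²·1{d=0}. Distance is Euclidean on
the integer copy vectors (Manhattan by configuration; the kernel family
is fixed, the metric was an open choice). The Gram system is solved by
Cholesky with an escalating jitter (1e-10 → 1e-4) only if factorization
fails. With τ² = 0 the predictor interpolates anchors exactly (asserted to
1e-8 in the suite). A note on linear trends: a Matérn-3/2 kernel with
constant mean reproduces exactly linear landscapes only in the ρ → ∞
limit, where the system is numerically singular; in practice held-out
error on a dense grid bottoms out around 1e-6–1e-5 near ρ ≈ 3 × 10⁴.

Hyperparameters (σ², ρ, τ²) are estimated by profile maximum likelihood
in log space with 5 seeded Nelder-Mead multi-starts, ties broken by the
smallest ρ. When the anchor set exceeds 400, the likelihood is profiled
on a seeded subsample of 400 anchors and the full system is solved once
at the optimum; this keeps the O(n³) factorizations affordable without
visibly moving the optimum on these anchor densities.

**CV score** = 1 − SS_res/SS_tot over leave-one-out predictions of the
frequent anchors (leave-one-out R²; 1 is perfect, ≤ 0 means no better
than the mean; the Pearson correlation of the pairs is also reported in
diagnostics). Each fold removes the left-out frequent clone *and every
neighbor anchor derived solely from it*, because those neighbors' MAP
values are functions of the parent's estimate and would leak it. Neighbor
anchors shared with other parents are retained. Hyperparameters are fit
once on the full anchor set and held fixed across folds. On synthetic
ground truth the score behaves as intended: median CV is clearly higher
on smooth (λ = 2) than rugged (λ = 0.5) terrains and tracks ground-truth
Spearman accuracy, though single seeds can flip the ordering.

Landscape reliability intervals come from re-running the entire
frequent → neighbor → Kriging pipeline on cell-resampled data.

## Agent-based model and GRF landscapes

Time advances in fixed steps of dt (default 0.1 day); a cell divides in a
step with probability 1 − exp(−(basal + f)·dt). This Bernoulli thinning
converges to the continuous-time division process as dt → 0; at dt = 0.05
the realized log-growth rate is log(2 − e^{−r·dt})/dt, within 0.5% of r,
and the acceptance suite checks the simulation against exactly this
value. Fitness is a *net* growth rate: explicit death exists only through
non-viable daughters and dilution, so cells whose total rate is ≤ 0
simply stop dividing (they are washed out by passaging). Divisions are
processed per karyotype class: the number of divisions with at least one
missegregation is binomial with success 1 − (1−p)^N, and only those are
simulated copy-by-copy (conditioned on ≥ 1 event by inverse-CDF
truncation) — an exact, not approximate, batching.

Passaging: when the census reaches Nmax the flask is binomially diluted
to fraction `dilution` (default 0.1) and `sample_size` cells (default
500) are drawn without replacement (multivariate hypergeometric) as the
pseudo-sequencing snapshot.

Ground-truth landscapes are Gaussian random fields built from J random
planar sinusoids (default 100): f(k) = mean + (A/√J) Σ sin(w_j·k + φ_j)
with |w_j| = 2π/λ; larger wavelength λ gives longer correlation lengths
and smoother terrain. Evaluation is deterministic per seed.

**Study conditions emulated by the fixtures** (the `generate_fixture`
scenarios): capacity Nmax = 10⁴ with 10% carried over per passage,
missegregation probability p = 10⁻³ per chromosome copy per division,
basal division rate 1/day, GRF amplitude 0.3/day, 500 cells sequenced per
passage, 8 passages by default, simulations up to 300 days. The capacity
is a desk-scale working size for a framework whose flask capacities are
an order of magnitude larger; the amplitude makes selective differences
between common clones a few tenths per day, comparable to the replicator
stage's detectable range. Scenarios: smooth-GRF (λ = 2), rugged-GRF
(λ = 0.5), neutral (flat), two-peak (narrow high peak 4 gains away from
a broad diploid peak), wgd-mixture (near-diploid and near-tetraploid
founders, 1:1).

What the generator does *not* emulate: sub-chromosomal CNAs and
copy-number calling error in the binned data, clock-like variation in
passaging intervals, treatment switches, spatial structure, and
measurement batch effects. Passing tests therefore demonstrate that the
inference machinery is correct and calibrated under its own generative
assumptions — not that those assumptions hold in any particular
experimental dataset.

Forecasting seeds the ABM from the last observed snapshot (scaled to the
post-dilution census), replaces the fitness function with the fitted
landscape's lookup table (karyotypes outside the charted region receive a
penalty fitness, default −1/day, i.e. they effectively stop dividing),
and averages karyotype distributions over replicate seeds.

## Evaluation metrics

- **Angle metric**: the angle between mean-karyotype change vectors
  m(t₂) − m(t₁) in 22 dimensions. Mean-karyotype differences (rather than
  per-clone matching) give a single direction per passage pair, matching
  the random-unit-vector null. The Monte-Carlo test statistic is the
  median of per-unit median angles; the null redraws angles between
  independent Gaussian-normalized unit vectors matched to the observed
  sample sizes (median null angle ≈ 90°).
- **Wasserstein distance**: exact 1-Wasserstein with Manhattan ground
  metric (consistent with counting missegregations), solved as a
  transportation LP with HiGHS; supports here are small.
- **Baseline comparison**: a forecast beats the static no-evolution
  baseline only strictly; ties lose.
- **Overlap coefficient**: Σ min of frequencies.
- **Non-overlapping trajectories**: randomized maximal node-disjoint
  root-to-leaf paths in the passage DAG, for bootstrap replicates built
  on statistically independent lineages.
- **Δf profiles and similarity**: 44-vector of single-step fitness
  effects (chr1-loss, chr1-gain, …); profile similarity is Fisher-z
  transformed Pearson correlation over shared non-missing entries,
  capped at |z| = 6 to keep summaries finite. Inputs to mixed-model
  context analyses (per-fit Δf variances, |Δf|, pairwise correlations,
  distances) are computed and exported; the mixed models themselves are
  out of scope.
- **WGD**: a karyotype is WGD⁺ iff its modal copy number is ≥ 3; modal
  ties resolve to the higher mode (a 2/4 tie indicates substantial
  doubling; configurable). Aneuploidy accumulation is fit to
  y(t) = A(1 − e^{−rt}) with additive group effects on A and r
  (Levenberg-Marquardt; Wald tests from the Jacobian covariance). Δf
  distributions by WGD status are compared with a permutation KS test on
  per-fit means (fits, not karyotypes, are the exchangeable units),
  p = (1 + #{D* ≥ D})/(1 + n_perm).

## Emergence prediction

Candidates are in-region karyotypes absent from the sample S0; features
d₁…d₅ are the abundance-weighted fractions of the S0 population exactly
1…5 missegregations away (an unweighted per-karyotype variant is
available behind a flag), plus the interpolated fitness f. A look-ahead
guard rejects landscapes trained past S0. The logistic fit uses
statsmodels; on perfect separation or non-convergence it falls back to a
small L2 (ridge) penalty on non-intercept terms, reported as `penalized`.
Wald z-tests at P < 0.05 define significance; constant features are
dropped and reported as NaN.

## Quasispecies rate screen

The growth–mutation matrix over a charted region with per-state fitness
f_j (positive division rates; add a basal rate to anchored relative
values first):

- W[i,j] = f_j · 2 · P(one missegregation j→i) for distance-1 pairs,
- W[j,j] = f_j (2(1−p)^{N_j} − 1) (two daughters minus the consumed
  parent),
- all multi-event mass and flux to inviable or out-of-region states is
  explicit loss (column sum + loss = f_j exactly) — a conservative
  single-step approximation, never renormalized.

The steady state is the normalized leading eigenvector, computed by
shifted power iteration (shift = max(0, −min diag) + 0.1(max|W| + 1),
L1 tolerance 1e-10). At high p the matrix is nearly diagonal with
clustered leading eigenvalues and power iteration stalls; a Krylov
(ARPACK) or dense eigensolver then finishes, and only genuine
non-convergence raises (with a spectral-gap diagnostic). As p → 0 the
steady state collapses onto the fittest karyotype; above an error
threshold, dominance switches to broad-peak or low-ploidy quasispecies —
the low-ploidy advantage follows directly from the per-copy kernel
(fewer copies, fewer errors per division). The screen reports the
dominant karyotype per rate and its distance from the low-rate dominant;
group assignment ("x" fading, "y" rising with rate) is by the sign of
the Spearman correlation between abundance and rate among the top-N most
abundant states.

## Problem sizes in the shipped checks

The test suite and acceptance script run at deliberately desk-scale
sizes chosen by this package: 10 seeds × 2 terrains for the smooth/rugged
CV comparison (capacity 10⁴, 8 passages), 20 seeded datasets for
replicator recovery, 10⁵ draws for the angle null, 300/100 replicate
datasets for the KS and emergence type-I calibrations, and 4-chromosome
toy spaces for exhaustive kernel enumeration and the quasispecies switch
scenarios. These sizes make the qualitative claims (orderings,
calibration within Monte-Carlo error, existence of finite switch
thresholds) reproducible in minutes on one CPU.

## Known limitations

- Whole-chromosome counts only: no sub-chromosomal CNAs, structural
  variants, or allele-specific copies.
- Fitness offsets are not identified from frequencies; cross-dataset
  comparisons of absolute f require external growth-rate calibration.
- The neighbor prior's hyperparameters are estimated from adjacent
  frequent pairs, which can be few; the fallback SD is then coarse.
- The transition matrix ignores distance-≥2 jumps, so steady states at
  high p underestimate back-flux onto peaks; thresholds are accordingly
  conservative.
- WGD states arise only through the data or founder mix — the simulator
  has no genome-doubling event type.
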