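# Methods

## Model

`yuleimm` works with the linear birth process with immigration (BI
process). New families are founded at the points of a homogeneous Poisson
process of rate θ > 0 on the time axis; from its founding moment each
family grows as a Yule process: every current member independently gives
birth at rate λ > 0. Families never shrink and never interact, so a
realization is fully described by each family's founding time and birth
times. The state that matters for sampling theory is the counts-of-counts
vector C(t) = (C₁(t), C₂(t), …), where C_j(t) is the number of families
with j members at time t.

Three classical facts drive everything in the package:

- a family grown from one founder for time t (unit birth rate) has
  geometric size, P(B(t) = j) = e⁻ᵗ(1 − e⁻ᵗ)^{j−1};
- the C_j(t) are independent Poisson variables with mean θ(1 − e⁻ᵗ)ʲ/j,
  so the population size Z(t) is negative binomial with mean θ(eᵗ − 1);
- by the marking theorem for Poisson processes, any "family property"
  that depends only on a family's founding time and its own growth path
  (e.g. *has at least one birth in window I*) splits the founding process
  into independent Poisson sub-processes whose means are integrals of the
  marking probability.

All closed forms are derived at λ = 1; a general birth rate is handled by
the substitution t → λt, θ → θ/λ, which every public function applies
internally through `BIParams`.

## Observable families and the expected sample variance

A family is *observable* in a window when it has at least one event there.
We count the founding arrival as the family's first observable event: with
that convention S(a, b), the number of families observable in (a, b), is
Poisson with mean θ·log(e^b − e^a + 1), which reduces to the necessary θ·b
when a = 0. (Counting only births would break that boundary case.)

For two disjoint ordered windows the counts decompose as
S(I₁) = K + T(I₁∖I₂), S(I₂) = K + T(I₂∖I₁) with K, T₁, T₂ independent
Poissons (families observable in both windows / exactly one); hence
Cov(S(I₁), S(I₂)) = Var K = E K, with the explicit logarithmic mean
implemented in `analytic.decomposition_means`. The expected sample
variance of p sequential counts,

    E V_p = (1/(p(p−1))) Σ_{i<j} E(S_i − S_j)²,

then has a closed double-sum form over the window weights
w_i = e^{t_i} − e^{t_{i−1}}. Two partitions get dedicated forms:

- **equal windows** t_i = iτ/p, with γ = e^{λτ/p};
- **logarithmically equal windows**, e^{λt_i} − e^{λt_{i−1}} constant,
  which makes the counts i.i.d. Poisson and collapses the variance to
  (θ/λ)·log((2γ̃+1)/(γ̃+1)), γ̃ = (e^{λτ} − 1)/p.

All of these are evaluated through signed `logsumexp` so that scaled
horizons up to λτ ≈ 700 neither overflow nor lose the `+1` terms.

As λ → ∞ the equal-window variance tends to θτ(θτ+2)(p+1)/(12p) and the
log-equal one to 0 (`fisher.prop1_limits`); the monotone approach is
exercised in the tests rather than proved here.

## Fisher's multi-sampling problem

Matching expected cumulative sample sizes l_i = n₁+…+n_i to window
boundaries via θ(e^{t_i} − 1) = l_i gives t_i = log((θ+l_i)/θ). At those
times the per-window counts have means θ·log((θ+n_i)/θ) and the expected
sample variance becomes a function of the sample sizes alone
(`fisher.tilde_esv`); for equal sizes it is θ·log((2n+θ)/(n+θ)), which
increases to Fisher's classical θ·log 2 with O(1/n) error. The asymptotic
form for proportional sizes q_i = n_i/n is implemented on proportions,
not raw sizes, so the limit is well defined.

## Simulation design

Two exact samplers, checked against each other:

- **Event level** (`simulate_bi`): founding times are uniform order
  statistics of a Poisson(θ·horizon) count; within a family the j-th
  birth adds an Exp(jλ) gap, drawn in geometrically growing blocks until
  the horizon is passed. This gives full trajectories (needed for the
  first-n-individuals discretization and the waiting-time experiment) but
  costs one draw per birth, i.e. order (θ/λ)e^{λτ} per replicate.
- **Window skeleton** (`sample_window_counts`, `sample_family_table`):
  only each family's size at the window boundaries is drawn — geometric
  at the end of the founding window, then negative binomial NB(k, e^{−λδ})
  increments across later windows (the exact Yule transition from size k
  over a window of length δ). A family is observable in its founding
  window and in any window where its size increased. This samples the
  exact finite-dimensional law at cost O(families × p) regardless of how
  large the population grows, and is what the Monte-Carlo expected sample
  variance uses: at the study grid the scaled horizon reaches λτ = 12.5,
  i.e. ~2.7·10⁵ births for an early family, which the event-level sampler
  cannot enumerate at 5000 replicates.

The CRP jump chain (`sample_crp_sizes`) tracks, per arrival, the family
label of a uniformly chosen previous individual (size-biased joining)
vectorized across replicates. The first-n-individuals discretization
(`jump_counts`) pools arrivals and births in time order; the batch
version generates only each family's first n−1 births (later births can
never be among the first n events) and drops replicates with fewer than n
individuals by the horizon — harmless, because the jump-chain law is
independent of the population-size process, so conditioning on
{Z(horizon) ≥ n} does not tilt it. Conditional ESF samples are produced
by rejection on Z(t) = n at t = log((n+θ)/θ), the time that maximizes the
acceptance probability and provably does not affect the conditional law.

RNG: every stochastic function takes a seed or `numpy.random.Generator`;
batch samplers consume one stream, so results are reproducible given
(seed, parameters) but not guaranteed bit-identical across numpy
versions — statistical tests therefore use tolerance bands, not golden
outputs.

## Waiting times

Conditional on at least one family by time t, a uniformly chosen family
has log-series size N_t with parameter q_t = 1 − e⁻ᵗ (a typical founding
time is uniform, mixing the geometric), and given N_t = n the residual
time to the family's next birth is Exp(n) by memorylessness. The density,
the closed-form CDF (1/t)·log(e^{−u} + e^t − e^{t−u}) and the moments
follow from that mixture. The mean is Li₂(q_t)/t. For the variance two
expressions circulate: Li₃(q_t)/t, and the mixture-derived
2Li₃(q_t)/t − (Li₂(q_t)/t)². Quadrature of the density confirms the
derived form is the actual variance; `waiting_moments` returns both, with
the derived one documented as canonical. The polylogarithm is summed
directly with a geometric tail bound (< 1e−13), with ζ(n) at the x = 1
endpoint; `mpmath.polylog` serves only as a cross-check in the tests.

## Estimation

- **Watterson-type estimator** (log-equal windows, e^{t_i} = iγ+1, λ = 1):
  θ̂ = S̄/log(1+γ) is unbiased; its variance
  (θ/(p·log(γ+1)))·(1+(p−1)ρ) with ρ = 2 − log(2γ+1)/log(γ+1) does not
  vanish as p → ∞ because the window counts remain correlated.
- **Per-window moment system**: with u = e^{λt_i} − e^{λt_{i−1}}, the
  observed family count Ŝ and individual count N̂ satisfy
  Ŝ = (θ/λ)log(u+1), N̂ = (θ/λ)u in expectation. The ratio N̂/Ŝ =
  u/log(u+1) is strictly increasing from 1, so u is unique whenever
  N̂/Ŝ > 1; λ then solves the strictly monotone boundary equation (closed
  form log(1+u)/t₁ when the window starts at 0, otherwise a bracketed
  Brent root on the log scale), and θ = λN̂/u. Windows with Ŝ = 0 or
  N̂/Ŝ ≤ 1 + 1e−9 are unidentifiable and are skipped with a warning
  rather than poisoning the aggregate. Per-window estimates are averaged;
  their sample variances are reported as dispersion proxies. No pooled
  likelihood is attempted — each window is solved on its own, matching
  the per-observer framing of the method. Root tolerances are 1e−14 in
  the unknown, giving ~1e−10 recovery on noise-free inputs.

The `SequentialCountsModel` / `SequentialCountsResults` pair wraps this
fit in the conventional model-object idiom (constructors from DataFrame /
CSV, `fit()`, `summary()`).

## Problem sizes used in tests and the acceptance script

Monte-Carlo checks use 3-standard-error bands and chi-square / KS tests
at α = 0.001 with fixed seeds, sized so the whole suite stays light:
20 000 replicates for event-level marginals, 100 000 for skeleton-based
means and ESF goodness of fit, 5000 replicates for the expected-sample-
variance grid (tightening the reference table's 50-run estimates), 10 000
for estimator unbiasedness and the waiting-time KS test. The acceptance
script recomputes the full grid and all headline quantities in a few
seconds with the same sizes.

## Known limitations

- No deaths, no emigration, no time-varying immigration rate; the
  estimators assume the pure BI model.
- The moment system needs windows with real growth signal; sparse windows
  (Ŝ = 0 or N̂ ≈ Ŝ) are skipped, so very early windows of a slow process
  contribute nothing.
- The ESF enumeration is capped at n = 20 (partition count growth).
- Moment estimators from single noisy windows are biased at small θτ;
  only the noise-free inversion is exact, and the tests check scale, not
  unbiasedness, for the simulated moment system.
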