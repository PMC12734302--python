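# Methods

## Model and assumptions

The package implements the single-type Galton–Watson process: discrete,
non-overlapping generations; every individual draws its offspring count
independently from one fixed reproduction law; lineage size is the sum of
the draws. These assumptions are what make the PGF machinery exact — and
they are also the model's main limitation: no parent–offspring correlation
in reproductive success, no time-varying environments, no interaction
between individuals. The one place where independence breaks by
construction — allele copies in a small diploid population, where two
copies meeting in a homozygote changes their joint fate — is handled by a
different exact object, the Wright–Fisher Markov chain, rather than by
patching the branching process.

## Offspring laws

Four families, all exposing pmf, PGF, first two PGF derivatives, mean and
variance:

| family | parameters | PGF |
|---|---|---|
| empirical | f_0..f_kmax | Σ f_k s^k |
| Poisson | λ > 0 | e^{λ(s−1)} |
| geometric (support 0,1,…) | mean R > 0, p = 1/(1+R) | p/(1−(1−p)s) |
| negative binomial | r > 0, 0 < p < 1 | (p/(1−(1−p)s))^r |

Parametric PGFs and derivatives are closed-form, never truncated series.
The geometric law is parameterised by its mean so it is directly comparable
with a Poisson of the same mean (it has larger variance, hence a larger
extinction probability — relevant when reproductive skew is strong). The
negative binomial has no closed-form extinction probability and enters the
fixed-point solver numerically.

Empirical PMF vectors must be non-negative; total mass may deviate from 1
by at most 1e-9 (renormalised with a warning, to tolerate rounded published
tables), beyond which construction fails. Criticality is classified from
the mean with an equality tolerance of 1e-12.

## Extinction probability

Monotone fixed-point iteration q ← G(q) from q = 0 is the primary solver:
starting below the smallest root and iterating a nondecreasing convex
function converges to the smallest non-negative fixed point from below, for
every valid law. Iteration stops when successive iterates differ by less
than 1e-14 (convergence is geometric at rate G′(Q) < 1 away from
criticality). Critical laws short-circuit to Q = 1 because the iteration
there converges only sublinearly. Poisson and geometric laws dispatch to
their closed forms (Lambert W via `scipy.special.lambertw`, principal
branch, with domain validation and an explicit value at the branch point
z = −1/e where the library routine returns NaN); a quadratic-formula root
finder is kept as an independent cross-check for three-point laws.

## Extinction time

`iterate_q` records q_0..q_T, stopping when the increment drops below
tol·max(Q, 1e-3) (default tol 1e-12) or at t_max. Conditional moments
divide by Q throughout — in the subcritical regime Q = 1, so the
conditional and unconditional forms coincide. Two numerical safeguards:

- **Geometric tail bound.** Beyond the horizon the deficits Q − q_t
  contract by approximately c = G′(Q) per generation, so the residual mass
  is distributed as a geometric tail with ratio c and its exact
  contribution to the first two raw moments is added analytically. This
  makes the reported 4-significant-figure values independent of the exact
  stopping generation.
- **Dual-route check.** In the subcritical regime the tail-sum identities
  E(T) = Σ(1−q_t) and E(T²) = Σ(2t+1)(1−q_t) are computed alongside the
  PMF sums and must agree to 1e-6 relative; disagreement raises rather
  than silently reporting a truncation-biased number.

Critical laws with positive variance are returned with a divergence flag
and no moments — the conditional mean is infinite and reporting a large
finite number would be misleading. Laws with no zero-offspring class have
Q = 0 and no extinction time to condition on. Quantiles of T are read
directly off the cumulative iterates rather than through any normal
approximation (the distribution is strongly right-skewed).

## Population-size distributions

The distribution of Z_t is the coefficient vector of the t-fold PGF
composite, built by dense polynomial composition: powers of the previous
generation's coefficient vector by repeated convolution, combined with
weights f_k. For a finite law the support is k_max^t and composition is
exact (coefficients as small as 1e-31 are representable in double
precision; a −1e-15 floor guards rounding-induced negatives, which are
clamped to zero). Powers are built incrementally rather than by binary
exponentiation — at desk scale (support ≤ 15,625 for k_max = 5, t ≤ 6)
simplicity wins. Parametric laws require an explicit truncation size; the
dropped mass is tracked and reported, making the truncated coefficients
certified lower bounds. The zero-size coefficient of the composite equals
the iterate q_t, an identity used as a structural test between two
independent code paths.

## Wright–Fisher absorption analysis

The neutral chain on allele-count states 0..2N has binomial transition
rows; states 0 and 2N are absorbing. Fixation probabilities solve
(I−B)h = r on the transient block (for the neutral chain h_i = i/2N, which
is asserted to 1e-10 rather than assumed). Conditional mean absorption
times use the Doob h-transform: the fixation-conditioned transient block is
B̃_ij = B_ij h_j/h_i and expected steps solve (I−B̃)t = 1; symmetrically
with 1−h for loss. Dense linear algebra throughout — all cases of interest
have 2N+1 ≤ 33 states.

A second, independent route — propagating the state distribution and
averaging the absorption generation over a finite horizon
(`finite_horizon_absorption_times`) — converges to the linear-solve values
as the horizon grows and quantifies what short-horizon tabulations
understate. For N = 16 from one copy the converged conditional fixation
time is 61.1182 generations, while a 300-generation horizon yields 61.0634;
published tabulations of this quantity differ at that level depending on
the horizon used.

Kimura–Ohta diffusion approximations are provided in the stated closed
forms; a test asserts that the chain-vs-diffusion gap shrinks from N = 1 to
N = 16.

The selfing-individual model treats a population of exactly one selfing
heterozygote producing one offspring per generation: AA offspring lose the
new allele, BB offspring fix it, AB offspring renew the state, giving
Q = P_AA/(1−P_AB). Selection acts only in the haploid phase (the diploid
population size is fixed at 1): both gametes are drawn independently from
the post-selection pool with A-frequency p′ = p − s·p(1−p)/(1+s(1−p)), so
P_AA = p′², P_AB = 2p′(1−p′).

## Estimators

- λ̂ = Σ later censuses / Σ earlier censuses — the maximum-likelihood
  estimator of the offspring mean given observed generation sizes under a
  Poisson law; scale-invariant.
- N̂ = ln((1−Q)Z + Q)/ln λ̂ with Q = Q_Poisson(λ̂): generations since a
  single founder, corrected for the fact that an observed population is a
  surviving one. Reported unrounded.
- Top-coded family-size tables are fitted by right-censored Poisson
  maximum likelihood (the K+ bin contributes log(1−CDF(K−1))), maximised
  by bounded scalar optimisation to xatol 1e-10; a least-squares-on-bin-
  probabilities alternative sits behind `method="lsq"`. Tables may be
  proportions or percentages; per-cell rounding drift up to 0.5% of total
  mass is renormalised away, as real census tables carry exactly this kind
  of error.

## Simulator

`simulate_gw` draws each generation's total offspring exactly: for Poisson
laws as one Poisson(λ·Z_t) variate (exact by superposition), for empirical
laws as a multinomial split of Z_t across offspring counts, and for other
laws by per-individual inverse-CDF draws. One `numpy` Generator seeded from
`SimConfig.seed` makes output byte-identical for a fixed configuration.
Trajectories exceeding the size cap (default 10⁷) are frozen and flagged;
supercritical questions are extinction-or-escape, so capping does not bias
extinction statistics at horizons ≥ 100 generations. What the simulator
does *not* emulate mirrors the model assumptions above: no environmental
stochasticity, no reproductive correlations — so simulation-based test
passes validate the implementation against its own model, not the model
against field data.

## Test problem sizes

Stochastic checks run at 10,000–50,000 replicates with fixed seeds and
99% binomial acceptance intervals (50,000 for the per-generation extinction
curve and the generation-2 size histogram, where per-replicate cost is a
couple of generations; 10,000–20,000 for long-horizon extinction fractions
and conditional-time checks). The whole suite runs in a few seconds on one
core.

## Known limitations

- Single-type processes only: no dormancy states, no multi-type or
  age-structured extensions, no continuous-time (Gillespie) dynamics.
- No selection or dominance inside the Wright–Fisher chain; the diploid
  chain is neutral, with selection handled only in the selfing
  single-individual model's haploid phase.
- Confidence intervals for λ̂ are not provided; the estimators are point
  estimators conditioned on the observed censuses.
- Extinction-time "prediction windows" are reported as exact PMF quantiles
  only; mean-plus-multiple-of-variance summaries are deliberately avoided
  (the distribution is skewed and the variance has squared units).
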