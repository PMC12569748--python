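# Methods

This note documents the statistical content of `cgrfs`: the data model, the
three CGRFS estimators, the two bootstrap schemes, the confidence-interval
and band constructions, the frailty simulator, and the numerical conventions
the implementation fixes where the methodology leaves room.

## Data model and counting processes

Input data are right-censored sample paths of a multistate process in long
format (`id, from, to, time`), one row per observed direct transition and at
most one terminal `cens` row per individual. Times are continuous, strictly
positive days since transplantation; states are 0-based integers. Every path
must start in state 0, be connected with strictly increasing times, use only
transitions the model allows, and end either in censoring or in the
absorbing state — an open-ended path would leave the observation window
undefined, so it is rejected at validation.

From a dataset the package derives, per transition g→h, the counting process
N_gh (with individual identity retained on every jump — the wild bootstrap
needs it) and, per state g, the at-risk left limit Y_g(t−), the number of
individuals in g just before t and uncensored at t. An individual leaving g
at time t, by transition or censoring, still counts in Y_g(t−) ("events
before censoring"). All estimators live on the grid of distinct observed
transition times and are right-continuous step functions; queries between
jumps return the last value.

The progressive six-state model maps onto the illness-death model with
recovery by collapsing states {0, 2, 4} → 0, {1, 3} → 1, 5 → 2; event times
are untouched and no allowed transition maps to a self-loop.

## Estimators

**Nelson–Aalen.** Â_gh jumps by ΔN_gh(t)/Y_g(t−) when Y_g(t−) > 0 (else no
update); diagonal entries keep row sums at zero. It targets the partly
conditional cumulative transition rate, which is well defined without a
Markov assumption.

**Aalen–Johansen.** P̂(0, t) = ∏_{s≤t} (I + ΔÂ(s)), computed as a forward
matrix product over the grid. Rows sum to one by construction (to < 1e−12
numerically) and all entries stay in [0, 1]. CGRFS is P̂₀₀ + P̂₀₂ + P̂₀₄ in
the progressive model and P̂₀₀ in the illness-death model. Under random
censoring these are consistent for the state occupation probabilities even
when the process is non-Markov.

**Kaplan–Meier combination.** Five ordinary Kaplan–Meier estimators over
composite event processes in the progressive model: S₁ (first cGvHD onset or
prior death/relapse; risk set {0}), S₂ (second onset or prior death/relapse;
{0,1,2}), S₃ (recovery from the first episode or prior death/relapse;
{0,1}), S₄ (relapse-free survival; all transient states), S₅ (recovery from
the second episode or prior death/relapse; {0,1,2,3}). Each factor is
1 − d_j(t)/Y_{R_j}(t−) with d_j the aggregated event count; an empty risk
set leaves the curve unchanged. The combination S₁+S₂−S₃+S₄−S₅ estimates
CGRFS without any Markov assumption but can exit the unit interval; it is
reported **unclipped by default**, with `clip_unit` (or `clip=True`)
truncating to [0, 1] where a probability is required — the distinction
matters because the wild bootstrap realizations are unaffected by clipping
while the clipped point estimate enters the interval/band transformations.

Each component has a bilinear representation f_j(Â) = u_jᵀ Â v_j with
u_j(t) the Y-proportional weights over the risk states and v_j the indicator
of the event target states; the product integral of f_j reproduces Ŝ_j
exactly (this identity is asserted in the tests and anchors the wild
bootstrap's derivative formula). All excluded hazards (e.g. Â₀₂) vanish
identically under the progressive transition structure, which is what makes
the bilinear form exact.

**Ties and empty risk sets.** Tied transitions at one time enter as a single
aggregate increment ΔN_gh(t)/Y_g(t−) (one multiplicative factor with d_j
events); the continuous-time simulator never produces ties, but integer-time
test data do. Whenever a 1/Y term is needed, Y is the left limit Y(t−) and
the 1{Y > 0} convention applies; this t− choice is used consistently in the
estimators, in the u_j weights and in the ξ-process.

## Wild bootstrap

Every observed individual jump receives an independent standard-normal
multiplier — one draw per (individual, transition type, jump time), so a
recurrent 0→1 transition in the illness-death model gets a fresh draw per
episode. The multiplier process

ξ_gh(t) = √n Σ_i ∫₀ᵗ G_i;gh 1{Y_g > 0} dN_i;gh / Y_g

replaces the martingale increments dM by dN·G and shares the limit of
√n(Â − A). The estimator realizations are its image under the functional
delta method:

* **KM combination:** B̂(t) = −Ŝ₁I₁ − Ŝ₂I₂ + Ŝ₃I₃ − Ŝ₄I₄ + Ŝ₅I₅ with
  I_j(t) = Σ_{s≤t} u_jᵀ(s) Δξ(s) v_j(s), u_j evaluated at Y(s−). In the
  pure-survival reduction (only 0→5 events) all five terms collapse with net
  coefficient one to the classical Kaplan–Meier wild bootstrap
  −Ŝ(t)ξ₀₅(t), and the realization variance matches Greenwood's formula —
  both are regression-tested.
* **Aalen–Johansen:** D(t) = Σ_{s≤t} P̂(0, s−) Δξ(s) P̂(s, t), computed by
  the forward recursion D(t_k) = D(t_{k−1})(I + ΔÂ(t_k)) +
  P̂(0, t_{k−1})Δξ(t_k), which is algebraically identical to the
  prefix/suffix product form but needs no matrix inverses; the CGRFS
  realization sums row-0 entries over the functional's states. Since D rows
  sum to zero, summing over *all* states gives identically zero (tested).

Realizations are linear in the multipliers, so ensembles are vectorized
across replicates (the per-jump coefficients are computed once). Ensembles
store B realizations on the estimate's jump-time grid on the √n-difference
scale.

## Efron's bootstrap

Whole patients are redrawn i.i.d. with replacement (valid under random
censoring); risk sets are re-derived from scratch per resample and the
re-estimated curve is evaluated on the original grid. Realizations are
√n{CGRFŜ*(t) − CGRFŜ(t)}; for the KM combination both the resampled and the
original estimate are clipped to [0, 1] before centering, mirroring how the
combination is reported as a probability, while wild realizations are never
clipped.

## Confidence intervals and bands

Both constructions use the log–log transformation h(x) = log{−log(1 − x)}
(inverse 1 − exp(−eʸ)) so retransformed limits stay in [0, 1], and the weight

g(t) = {CGRFŜ(t) − 1} log{1 − CGRFŜ(t)} / √(n·var̂(t)),

with var̂ the replicate sample variance (denominator B − 1) divided by n.
Because dh(x) = −1/{(1 − x) log(1 − x)}, the studentization identity
g·dh = 1/√(n·var̂) holds exactly; the band computation uses it, and the
tests assert it to 1e−12.

* **Pointwise CI at t:** q is the (1 − α/2) empirical quantile of the
  realizations at t divided by √n; the interval is 1 − (1 − CGRFŜ)^θ with
  θ = exp[±q/({CGRFŜ − 1} log{1 − CGRFŜ})], evaluated in log space with the
  exponent clamped so estimates within floating error of the boundary yield
  the limiting bounds.
* **Simultaneous band over [t₁, t₂]:** q is the (1 − α) quantile of
  sup_t |B̂(t)|/√(n·var̂(t)) over the band grid; bounds are
  h⁻¹[h(CGRFŜ) ± q/(√n·g)].

Numerical conventions, fixed once: empirical quantiles use the ⌈B·p⌉-th
order statistic (conservative, standard in resampling); the band grid is the
estimate's jump times inside [t₁, t₂] plus the endpoints (the sup of a step
process is attained there); time points where the clipped estimate is 0 or 1
or var̂ = 0 are *degenerate* — they are excluded from the sup and carry
collapsed bounds equal to the clipped estimate, and in coverage experiments
they count as covered only when the truth equals that collapsed value. If
B·α/2 < 1 the extreme order statistic is used with a warning.

## Frailty simulator

The coverage study simulates the progressive six-state model with constant
per-day hazards α₀₁ = 0.0009, α₁₂ = 0.0008, α₂₃ = 0.001, α₃₄ = 0.00065,
α₀₅ = 0.00075, α₁₅ = α₂₅ = α₃₅ = α₄₅ = 0.0006, each multiplied by an
individual gamma frailty Z ~ Gamma(shape 2, scale 1) (mean 2, variance 2);
censoring is an independent Exp(0.00095) time. Conditional on Z the chain is
Markov with exponential sojourns; marginally the mixture is non-Markov: the
state-0 occupation is the gamma Laplace transform (1 + 0.00165·t)⁻², whose
implied hazard decreases in t. Both facts are exploited as analytic oracles
in the tests (occupation at t = 500 equals 0.3002; sojourns given an
injected frailty pass a Kolmogorov–Smirnov test; censoring draws are
independent of the frailty by construction and by a replay test).
Disabling censoring is an explicit flag; a zero censoring rate is rejected
rather than used as a stand-in for "no censoring".

The true CGRFS curve is approximated once per configuration by direct state
counting on 200,000 uncensored individuals (identical to the Aalen–Johansen
estimate in the absence of censoring — tested), optionally cached as CSV
keyed by a configuration digest.

**What the generator does and does not emulate.** It reproduces the study
conditions of the coverage experiment: constant conditional hazards, a
shared frailty acting multiplicatively on all transitions, independent
exponential censoring, and everyone starting event-free at time 0. Real
registry data have time-varying hazards, covariate-driven heterogeneity,
dependent censoring and reporting artifacts; passing coverage here shows
correctness of the estimators and bootstrap under random censoring and
Markov violation of the frailty type, not robustness to those features.

## Coverage experiment

Per replicate: simulate n patients; fit the three estimators; record whether
the unclipped combination leaves [0, 1] anywhere (a dataset-level count,
evaluated before clipping); per (estimator, method) task build B bootstrap
realizations and form 95% CIs at the requested times and bands over the
requested intervals; score containment of the truth (bands must contain it
at every evaluated grid point). All randomness flows from one master seed
through per-replicate substreams, so runs are reproducible and resumable.

Problem sizes: the package's desk-scale defaults are 200 replicates with
B = 400 at n = 200, which reproduce the qualitative and most quantitative
coverage patterns in about two minutes per (estimator, method) batch on one
CPU; the full-size study (1000 replicates, B = 1000, n ∈ {200, 400, 1000})
sits behind `--full-scale` and runs for hours.

## Known limitations

* At very late times (t = 2000, a handful of patients at risk of 200) the
  tail behaviour of bootstrap intervals is dominated by near-empty risk
  sets; the package's t− convention and conservative quantile give
  near-nominal tail coverage for the Aalen–Johansen estimators, and bands
  anchored at t₁ = 0 undercover because of the sparse earliest event times —
  moving the band start to t₁ = 10 restores near-nominal coverage.
* Left truncation, interval censoring, covariates, two-group difference
  bands and landmark transition-probability estimation are out of scope.
* The Kaplan–Meier combination requires the progressive structure; in the
  illness-death model with recovery only the Aalen–Johansen estimator is
  available (back-transitions preclude the combination).
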