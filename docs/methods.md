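# Methods

## Model

A metabolic network is a stoichiometric matrix `S` (M metabolites x N
reactions) with flux bounds `lb <= v <= ub` and a linear biomass functional
`lambda(v) = xi . v` (units 1/h).  At steady state (`S v = 0`) the feasible
fluxes form a convex polytope `P`.  The package studies the exponential
family on `P`,

    P_beta(v) = exp(beta * lambda(v)) / Z(beta),

the maximum-entropy distribution at a fixed mean growth rate.  `beta >= 0`
has units of time; the dimensionless combination `beta * lambda_max` (with
`lambda_max` the LP optimum of `lambda` over `P`) is the natural
optimization level, with `beta = 0` the uniform ensemble and
`beta -> inf` the FBA point.

Assumptions inherited from constraint-based modeling: the network is at
steady state; all kinetic and thermodynamic knowledge is condensed into the
signed flux bounds; growth is a fixed linear combination of fluxes.
Reversibility is expressed purely through negative lower bounds — reactions
are never split into irreversible pairs, so a reversible flux can change
sign along the ensemble.  Formally unbounded fluxes are capped at a
configurable +-1e4 mmol/gDW/h so the polytope is compact; the cap is a
modeling choice exposed in `load_model(cap=...)`.

## Polytope parameterization

Fluxes with `lb == ub` are removed and re-inserted as constants.  The
remaining equality system is solved by least squares (a residual beyond
`1e-8` relative signals infeasibility) and its null space is computed by
SVD with relative rank tolerance `1e-9` (the `rank_tol` argument).  The
reduced coordinates `t` satisfy `v = v0 + B t`, where `v0` is the Chebyshev
center: the point maximizing the minimal row-normalized slack of all box
constraints, found by LP (HiGHS).  A zero Chebyshev radius or an empty null
space raises an explicit degenerate-polytope error.  All user-facing fluxes
are reported in the original `v` coordinates.

**Rounding.**  Anisotropic polytopes mix slowly under isotropic proposals.
`round_polytope` estimates an invertible transform `T` by iterative
covariance whitening: draw uniform presamples (2000 by default), measure
their covariance `C`, and set `T = chol(C)` until the condition number of
`C` in whitened coordinates falls below `cond_target` (default 10) or
`max_rounds` (5) is reached; non-convergence is recorded in
`rounding_info`, never raised.  `T` only reshapes the proposal directions —
the stationary distribution is untouched — so rounding can never bias a
result, only speed it up.

## Hit-and-Run with exact chord sampling

Each step draws an isotropic unit direction in rounded coordinates,
computes the chord `[s-, s+]` cut by all box constraints, and samples the
new position from the exact one-dimensional density `~ exp(a s)` on the
chord, with rate `a = beta * (g . d)` (`g` is the growth gradient in
reduced coordinates).  The inverse CDF

    s = s- + log1p(U * expm1(a * delta)) / a

is rewritten anchored at the favored endpoint when `a*delta > 30` so no
exponential overflows, and degenerates to uniform when
`|a * delta| < 1e-12`.  Because the chord step is exact (no rejection, no
discretization), the sampler can be validated against closed forms; the
test suite holds it to the truncated-exponential CDF by Kolmogorov–Smirnov
on the interval fixture and to quadrature on 2–3-dimensional toys.

Defaults: `burn_in = 1000 * D` steps, `thin = D`, 4 chains started at the
interior point with a small isotropic jitter, all chains advanced
simultaneously as matrix rows (which is what makes 1e5-draw runs cheap in
pure numpy).  Per-sample growth rates are stored; importance reweighting to
a nearby `beta'` multiplies weights `exp((beta'-beta) * lambda)` and
refuses (raises) when the normalized effective sample size falls below 10%
of `n`.  Convergence is monitored by split-chain R-hat and ESS (ArviZ) per
reduced coordinate and for `lambda`; `beta < 0` is mathematically supported
behind an explicit flag but never used by the pipeline.

## Beta ladders, information, beta fitting

A ladder samples the ensemble on an ascending beta grid starting at 0
(default: geometric in `beta*lambda_max` from 1 to 400, prepended 0) and
tabulates mean growth, its SD and per-flux moments.  Because
`d ln Z / d beta = lambda_bar`, the entropy drop from uniform is obtained
by thermodynamic integration,

    I(beta) = [ beta*lambda_bar(beta) - integral_0^beta lambda_bar ] / ln 2   (bits),

with the trapezoid rule on the grid and standard errors propagated from the
per-point MC errors of `lambda_bar`.  A `lambda_bar` that decreases beyond
3 combined standard errors marks a bad ladder and raises.  `I` is exactly 0
at `beta = 0`, non-negative, and — up to MC noise — non-decreasing.

`fit_beta` inverts `lambda_bar(beta) = lambda_data` with common random
numbers: every candidate beta is evaluated with the same seed, making the
MC estimate of `lambda_bar(beta)` a deterministic, continuous, increasing
function so that ordinary root bracketing (brentq) applies; the attainable
tolerance is the MC error at the chosen sample size.  `lambda_data` at or
below the uniform mean returns `beta = 0` with a warning; at or above
`lambda_max` it is unreachable and raises.

Other ensemble operations: MSE against measured relative fluxes
(normalized to a reference uptake), per-flux log fold changes versus the
uniform ensemble with sign-change flags, per-flux variability shrinkage
fitted through the scaling regime `lambda_bar/lambda_max >= 0.90`
(proportional fit through the origin) together with the log-log slope of
the growth-flux SD versus `beta*lambda_max` for `beta*lambda_max >= 40`,
histogram growth marginals, and deterministic average-linkage clustering of
`1 - corr` (Pearson) matrices.

## Vertex-cone closed forms

When the growth optimum is a simple vertex of a D-dimensional polytope, the
uniform growth marginal is `q(lambda) = D (lambda_max-lambda)^(D-1) /
lambda_max^D`.  Substituting `u = lambda_max - lambda`, the tilted density
is a Gamma(D, 1/beta) truncated to `[0, lambda_max]`, so the partition
function, mean, SD and information are regularized incomplete-gamma
expressions, computed in log space and stable to `beta*lambda_max ~ 1e4`
(no exponentials are ever formed).  For `D = 1` the cone reduces exactly to
the interval toy, which the tests exploit as a shared oracle.  The simplex
fixtures are constructed so their growth marginal *is* the cone density,
giving an end-to-end analytic check of sampler + ensemble.

The mean-field fixed point of competitive growth solves
`Z(beta*) = N_C/N_0` (monotone in beta; brentq after bracket doubling).
With `D = 23` and `N_C/N_0 = 1e6` the exact root is
`beta* lambda_max = 53.92`; with `D = 3` and ratio 100 it is 9.60.  The
acceptance script reports the exact root — the cone form is an
approximation near the optimum, documented as such, and no attempt is made
to round it toward any nicer value.

## Population dynamics

Logistic competition `dn_i/dt = lambda_i n_i (1 - N/N_C)` integrates
exactly to `n_i(t) = n_i(0) exp(beta(t) lambda_i)`, so the package solves
only the scalar ODE `dbeta/dt = 1 - N(beta)/N_C` (RK45, rtol 1e-10) and
reconstructs all counts; the full coupled system survives in the test suite
as an independent oracle.  Stationarity is declared when
`1 - N/N_C` falls below a tolerance (1e-6 by default) and the stationary
frequencies are Boltzmann, `~ exp(beta* lambda_i)` with `beta*` the root of
`sum_i n_i(0) exp(beta lambda_i) = N_C`.

A caveat the tests make explicit: for strongly decaying phenotype densities
(e.g. the cone with `D = 23`), the population fixed point is dominated by
exponentially rare large-`lambda` phenotypes, so the empirical `beta*` of
any finite phenotype draw is biased *above* the analytic mean-field value —
the two agree only in a tail-resolved large-sample limit.  The tests
therefore assert the Boltzmann form and slope exactly, but only
order-of-magnitude agreement between empirical and mean-field `beta*`.

## Regulation cost model

Given matched `lambda_bar(beta)` and `I(beta)` curves and `K` regulatory
channels (default `K = D`, the number of polytope degrees of freedom), the
effective growth rate is

    lambda_eff(beta) = lambda_bar(beta) - alpha * K * (2^(2 I(beta)/K) - 1),

the Gaussian-channel capacity cost with price `alpha` (1/h per regulatory
unit).  `alpha` has no canonical empirical value and is a user input; since
`I` diverges as `lambda_bar -> lambda_max` while `lambda_bar` is bounded,
any `alpha > 0` produces an interior optimum in beta, which `optimal_beta`
locates on the grid and refines by a local quadratic fit.

## Growth-rate distribution fitting

`Q(lambda) ~ (lambda_max - lambda)^(D-1) exp(beta lambda)` is fitted to
single-cell growth rates by maximum likelihood: for fixed integer `D`,
`(beta, lambda_max)` are optimized by L-BFGS-B subject to `beta >= 0` and
`lambda_max > max(sample)`, from moment-based starts
(`beta ~ sqrt(D)/sd`); with `D` free (the default) the integer is profiled
over 1..50.  For `D = 1` the likelihood is monotone in `lambda_max` and the
optimizer correctly collapses to the classic uniform MLE
`lambda_max = max(sample)`.  Goodness of fit is reported as a KS test
against the fitted CDF.  Lineage SDs use the population (divide-by-n)
convention to match `Q`'s moment formulas; lineages with fewer than 2
events (configurable) are dropped with a count.  Transient filtering after
condition switches is the caller's responsibility (a mask or a drop-first-k
rule applied before fitting); no default masking is imposed.

## Synthetic data generator

`make_toy_network` produces interval, chain, diamond, simplex-D and
random-D models whose dimension, `lambda_max`, FBA vertex and (for
interval/chain/simplex) growth marginal are known analytically; the test
suite verifies each ground-truth record with independent oracles (row
reduction, vertex enumeration, Dirichlet sampling, quadrature) rather than
with the code paths under test.  `generate_lineage_data` draws per-lineage
growth rates from `Q` with optional multiplicative jitter of `lambda_max`
across lineages (the lineage effect) and one doubling time per event; byte
identical for a fixed seed.

What the generator emulates: the *distributional* structure of single-cell
growth data (lineage grouping, event counts, a lineage effect) and exact
draws from the model family.  What it does not: measurement noise on
elongation rates, correlated mother–daughter rates, transient dynamics
after condition switches, or model misspecification.  Passing recovery
tests therefore demonstrates correctness of the estimator under the model,
not robustness of the model on real traces.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to keep MC errors well
inside the asserted tolerances: ladders of 11–21 beta points at 3000–5000
draws; fluctuation-scaling runs on a D = 10 simplex with 8 geometric beta
points in `beta*lambda_max` within [40, 400] at 15000–20000 thinned draws
across 32 parallel chains; growth-fit recovery at n = 5000 events over 20
seeds.  Key tolerances: mass-balance residual `1e-8 * |S|` per sample and
`1e-6` relative on sample means; FBA zero-flux threshold
`1e-6 * max|v_max|`; FBA degeneracy probed with objective perturbations of
`1e-5` relative (large enough to clear the LP solver's dual tolerance);
ODE integration at rtol `1e-10`; root finds at xtol `1e-10`–`1e-12`.
Master seeds feed per-stage seeds through a stage-name-keyed hash so
partial reruns are reproducible.

## Known limitations

* Alternate FBA optima are flagged (degeneracy probe) but not resolved; on
  degenerate networks the zero-flux count depends on the vertex the LP
  returns.
* Rounding is a stochastic whitening heuristic with a reported condition
  number, not an exact ellipsoidal rounding with guarantees.
* Thermodynamic-integration information inherits trapezoid bias on coarse
  beta grids; the ladder's grid should be refined until `I` is stable.
* The cone marginal is exact only for simple-vertex optima; optimal faces
  of dimension > 0 fall outside it.
* Genome-scale networks are in principle supported (the sampler is
  polynomial per step) but have not been profiled here; no
  belief-propagation or Gaussian-approximation fast paths are provided.

## Pipeline config schema (`fluxent run`)

```yaml
model: {path: model.json, format: json}   # or: fixture: {kind: simplex, dim: 3}
seed: 0
beta_grid: {x_max: 400.0, n: 12}          # grid in beta*lambda_max
sampler: {n_samples: 5000, n_chains: 4}
rounding: {enable: true, n_presamples: 2000, cond_target: 10.0}
outdir: out/
```

Artifacts: `ladder.csv` (beta, lambda_bar, sigma, SE, I), `flux_means.csv`,
`summary.json` (D, lambda_max, zero-flux count, validation issues, rounding
record); every file carries the config hash and master seed.
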