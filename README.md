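# fluxent

Maximum-entropy flux ensembles on metabolic steady-state polytopes.

## The problem

Flux balance analysis (FBA) predicts a *single* flux configuration — the one
maximizing the growth rate over the feasible set

```
P = { v : S v = 0,  lb_i <= v_i <= ub_i },      lambda(v) = xi . v,
```

where `S` is the stoichiometric matrix of a metabolic reconstruction and
`lambda` is the biomass (growth) functional.  Real cells, however, show
substantial cell-to-cell growth-rate variability even in steady conditions.
`fluxent` implements the least-biased *distribution* over fluxes compatible
with a measured average growth rate: the Boltzmann ensemble

```
P_beta(v)  =  exp(beta * lambda(v)) / Z(beta)     for v in P,
```

which interpolates between uniform sampling of the polytope (`beta = 0`, no
optimization) and the FBA vertex (`beta -> inf`, full optimization).  The
single parameter `beta` (units of time) is fitted so that the ensemble mean
growth rate matches data; everything else — flux means and variabilities,
correlations, the growth-rate distribution `Q(lambda)`, the minimal
regulatory information `I(beta)` needed to reach a given growth rate, and
the fluctuation scaling `sigma ~ (beta*lambda_max)^-1` — follows without
further fitting.  The package is aimed at systems biologists doing
constraint-based modeling who want single-cell-level predictions, and at
quantitative biologists analysing single-cell growth-rate data.

What is inside:

* **model_io** — stoichiometric models (JSON / TSV dialects, SBML via
  cobrapy) with flux bounds and a biomass functional; measured-flux tables.
* **polytope** — affine parameterization of `P` in its `D` intrinsic
  dimensions, Chebyshev-center interior points, covariance-whitening
  rounding.
* **fba** — the `beta -> inf` limit by linear programming.
* **sampler** — Hit-and-Run with *exact* truncated-exponential sampling
  along each chord; importance reweighting within the exponential family;
  split-chain convergence diagnostics.
* **ensemble** — beta ladders, beta fitting, entropy-drop information
  curves by thermodynamic integration, MSE against measured fluxes, fold
  changes, variability scaling, growth marginals, correlation clustering.
* **analytic_cone** — closed-form vertex-cone approximation of
  `Q(lambda) ~ (lambda_max - lambda)^(D-1) e^(beta*lambda)` and the
  mean-field fixed point of competitive growth.
* **population** — logistic competition among heterogeneous phenotypes and
  its exact reduction to a scalar ODE; Boltzmann steady states.
* **regulation** — effective growth under Gaussian-channel information
  costs and its interior optimum.
* **growthfit** — maximum-likelihood fits of `Q(lambda)` to single-cell
  growth-rate data; lineage statistics; fluctuation-scaling regression.
* **fixtures** — toy networks with analytic ground truth and synthetic
  lineage data.

## Worked example

Sample the simplest non-trivial ensemble — one bounded flux `v in [0, 1]`
with `lambda(v) = v` — at `beta = 2`, and compare with the closed form:

```python
>>> import fluxent as fx
>>> model, truth = fx.make_toy_network("interval")
>>> P = fx.build_polytope(model)
>>> s = fx.hit_and_run(P, beta=2.0, n_samples=20000, seed=1)
>>> round(float(s.lambdas.mean()), 4)
0.6564
>>> fx.interval_moments(2.0)[0]          # exact: 1/(1-e^-2) - 1/2
0.6565176427496657
```

The mean growth rate moved from 0.5 (uniform) to 0.657: a mild optimization
level, with the full distribution still broad (`sd = 0.26`).

The closed-form cone model gives the headline numbers of a realistically
sized network (`D = 23` degrees of freedom) in microseconds:

```sh
$ fluxent cone --dim 23 --beta-lmax 120 --ratio 1e6
{"D": 23, "lambda_max": 1.0, "beta_lambda_max": 120.0,
 "lambda_mean": 0.8083333333333333, "sigma": 0.03996526269427257,
 "optimization_level": 0.8083333333333333,
 "info_bits": 51.223802840170436,
 "ratio": 1000000.0, "beta_star_lambda_max": 53.9223880458915}
```

Read: at `beta*lambda_max = 120` the ensemble grows at ~81% of the maximal
rate with ~4% fluctuations, and pure competitive growth starting from a
1 : 10^6 inoculum-to-carrying-capacity ratio would on its own sustain only
`beta*lambda_max ~ 54` — tighter optimization than that requires active
regulation, whose information demand `I(beta)` the ladder quantifies.

A full pipeline (validate → polytope → FBA → beta ladder) runs from a YAML
config and writes seed- and hash-stamped CSV/JSON artifacts:

```sh
$ fluxent run config.yaml     # see docs/methods.md for the config schema
```

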