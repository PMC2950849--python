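# rsfbayes

Hierarchical Bayesian resource-selection functions (RSF) for
use–availability foraging data, built for fine-grained habitat-selection
studies of ground-foraging birds in farmland mosaics of grass and bare
ground.

## The problem

Radiotracked (or directly observed) birds provide *used* foraging
locations; random points inside each individual's home range provide the
*available* alternatives. Contrasting the two with a logistic regression
on patch-scale covariates — the proportion of bare ground `b` in a small
sampling circle and the vegetation (sward) height `h` in cm — estimates
how strongly foraging birds select or avoid particular ground-vegetation
structures. Because accessibility of ground prey trades off against prey
abundance, selection is expected to peak at intermediate bare-ground
cover, so quadratic terms matter.

## The model

For record *j* of individual *i*, with `y = 1` for a used location and
`y = 0` for a random point,

```
y_j ~ Bernoulli(logit⁻¹(x_jᵀ β_i))          x_j ⊆ (1, b, b², h, h²)
β_ik ~ Normal(μ_k, σ_k²)                    independent across terms k
μ_k ~ Normal(0, 10²),  σ_k ~ Uniform(0, 10)
```

Covariates are standardized before sampling; squared terms are squares of
the standardized values. The random intercept and slopes let every
individual have its own selection curve while the population means μ give
the species-level pattern. Fitting uses an adaptive random-walk
Metropolis-within-Gibbs sampler written in this package (no external MCMC
engine): per-individual coefficient blocks, an exact conjugate draw for μ,
and a bounded random-walk step for σ, with proposal scales tuned toward
35% acceptance during burn-in and frozen afterwards.

On top of the sampler:

- **Model selection** over a fixed nine-formula candidate set
  (`b+b²+h+h²` … `intercept`, respecting marginality) ranked by DIC with
  conditional focus: `DIC = D̄ + pD`, `pD = D̄ − D(B̄)`.
- **Goodness of fit** by a χ² discrepancy posterior-predictive check
  reported as a Bayesian *P*-value (values near 0.5 indicate adequate fit).
- **Response curves**: per-individual conditional curves and the marginal
  (population-level) curve obtained by averaging over simulated new
  individuals from `Normal(μ, σ²)`, with equal-tailed 80% credible bands.
  Under balanced used:available sampling, 0.5 is the neutrality line —
  below it avoidance, above it preference.
- **Quadratic optimum**: the posterior of the bare-ground cover at which
  selection peaks, `b* = −β_b / (2 β_b²)` back-transformed to the raw
  scale.
- **Geometry**: minimum-convex-polygon home ranges, availability sampling
  with a 10 m exclusion buffer around used points, patch-covariate
  extraction in 1 m (or 5 m) circles, and 5-minute temporal thinning of
  telemetry tracks.
- **Synthetic data**: Gaussian-random-field grass/bare mosaics and
  use–availability datasets with known ground truth (species presets with
  13/8/7/5 individuals), so the whole pipeline is testable end to end.

## Worked example

Simulate a wryneck-style study (8 individuals, 30 used + 30 available
points each, quadratic bare-ground selection peaking at 50% cover plus a
weak sward-height avoidance), then rank the nine candidate models:

```
$ printf 'mcmc:\n  chains: 2\n  iterations: 2000\n  burn_in: 500\n' > fast.yaml
$ rsf simulate --species wryneck --seed 7 --n-used 30 --out sim
wryneck_01: 30 used, 30 available
wryneck_02: 30 used, 30 available
...
$ rsf select sim/records.csv --config fast.yaml --seed 11 --out sel
    model   deviance        pD       dDIC
   b+b2+h 550.701374 17.762549   0.000000
     b+b2 556.199435 16.125882   3.861394
b+b2+h+h2 551.169540 23.361962   6.067580
   b+h+h2 608.309398 20.455481  60.300956
        b 623.203660 10.869430  65.609167
     h+h2 627.917904 10.964109  70.418090
      b+h 625.060421 15.007486  71.603984
        h 642.857566  9.383768  83.777412
intercept 667.280605  1.856488 100.673171
best model: b+b2+h; Bayesian P = 0.38
```

Every model containing the quadratic bare-ground term beats every model
without it by more than 60 DIC units — the generated birds select
intermediate bare cover, and only `b²` can express that. The best model's
Bayesian *P*-value of 0.38 signals an adequate fit. `sel/` also contains
the best model's posterior draws, response-curve CSVs
(`level,covariate,grid,mean,lo80,hi80`), and the posterior of the
bare-ground optimum; `rsf curves sel/fit_best --plot` renders the
individual and marginal curves with the 0.5 neutrality line.

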