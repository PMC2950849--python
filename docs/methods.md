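# Methods

## Model and assumptions

The package analyses use–availability data: used foraging locations
(`y = 1`) versus random available points (`y = 0`) sampled inside each
individual's home range. The hierarchical Bernoulli-logit model is

    y_j | β_i ~ Bernoulli(logit⁻¹(x_jᵀ β_i)),   β_ik ~ N(μ_k, σ_k²),

with independent random effects across terms — no correlation matrix
between the random intercept and slopes. This independence is an
assumption, chosen to match the classic BUGS-era random-intercept-and-
slope formulation; correlated random effects are out of scope.

The design vector is a subset of `(1, b, b², h, h²)` where `b` is the
proportion of bare ground in the sampling circle (0–1) and `h` the mean
vegetation height (cm). Both are standardized to mean 0, sd 1 over the
dataset before sampling; squared terms are the squares of standardized
values, so the quadratic vertex maps back to the raw scale by the affine
inverse transform. All reporting (response curves, optima) is on the raw
scale.

The fitted "selection probability" is the probability that a point is a
used rather than an available point. It is a relative quantity: with
roughly balanced used:available counts per individual, 0.5 is neutral,
below 0.5 avoidance, above it preference. The package logs a warning when
per-individual imbalance exceeds 1.25:1, since the 0.5 convention then
drifts.

## Priors and sampler

Defaults: `μ_k ~ N(0, 10²)` on the standardized scale and
`σ_k ~ Uniform(0, 10)` — vague for logistic coefficients of standardized
covariates. Both are configurable (`Priors`).

Sampling is a bespoke adaptive random-walk Metropolis-within-Gibbs sweep:

1. **Individual blocks.** Each individual's whole coefficient vector gets
   a joint Gaussian random-walk proposal. Because the likelihood
   factorizes over individuals given their own coefficients, all blocks
   are proposed and accepted/rejected simultaneously in one vectorized
   step without breaking detailed balance.
2. **μ update.** Exact conjugate Gibbs draw (normal prior × normal
   "likelihood" of the I individual coefficients).
3. **σ update.** Random-walk Metropolis on σ itself, proposals outside
   `(0, σ_upper)` rejected; the target is `σ^(−I) exp(−SS/2σ²)` under the
   uniform prior.

Per-individual and per-σ proposal scales are multiplicatively adapted
every `adapt_window` (default 50) iterations of burn-in toward 35%
acceptance, then frozen, so every retained draw comes from a fixed,
valid Markov kernel. Chains are seeded from independent spawned
substreams of one integer seed; fits are bit-reproducible. Split R-hat
and effective sample size (via arviz) are attached per parameter; R-hat
above 1.1 is recorded as a warning on the result, never raised.

Defaults are 3 chains × 6000 iterations with 1000 burn-in. The repeated-
fit simulation studies in the test-suite use the package's reduced-scale
settings (2 × 3000 for single-model recovery, 2 × 2000 for multi-model
studies); pilot runs at several chain lengths showed DIC stable to well
under one unit at these lengths.

## DIC

Conditional focus throughout: the per-draw deviance is
`D = −2 log L(B)` given the individual-level coefficients, `D̄` its
posterior mean, and `pD = D̄ − D(B̄)` the plug-in at the posterior mean of
`B`. `DIC = D̄ + pD` holds as an exact identity by construction. With
this focus the intercept-only model has `pD ≈ 2` (population mean +
random-effect sd), which is the scale of complexity the candidate table
reports. Because the conditional deviance is convex in `B`, `pD` is
non-negative for genuine draws (Jensen); a negative value — possible only
with inconsistent inputs — warns and proceeds.

A known property of conditional-focus DIC, reproduced by the package's
null-recovery study: under a true intercept-only model it occasionally
(roughly 1–2 times in 10) prefers a noise covariate by more than 2 DIC
units. The model-selection tests use a binomial band (≥ 8/10) rather than
an exact requirement for this reason.

## Posterior-predictive check

For each retained draw, `T(y) = Σ (y_j − p_j)² / (p_j(1 − p_j))` is
computed for the observed data and for a replicate `y* ~ Bernoulli(p)`;
the Bayesian P-value is `Pr(T(y*) ≥ T(y))`. Probabilities are clamped to
`[1e−12, 1 − 1e−12]` (logged) before the discrepancy. The statistic is
computed on individual Bernoulli records, not on bins.

Calibration: for correctly specified data the P-value is comfortably
inside (0.05, 0.95). Power is limited — the record-level χ² on ungrouped
binary data is insensitive to smooth misspecification that the fitted
probabilities can partially absorb (the package's studies show omitted
quadratic curvature passes undetected, while a strong omitted cubic term
drives P-values to ~0.99). Users needing sharper diagnostics should bin
or group the discrepancy; that variant is not implemented.

## Response curves and the optimum

Individual curves apply each individual's posterior coefficient draws to
a standardized grid of the varied covariate, others held at their raw
means. The marginal (population) curve draws, per posterior draw of
`(μ, σ)`, `n_new` = 500 hypothetical individuals from `N(μ, σ²)` and
averages their inverse-logit responses; the Monte-Carlo marginalization
agrees with 20-node Gauss–Hermite quadrature to < 1e−3. Bands are
equal-tailed 80% posterior quantiles (not HPD); for strongly skewed
pointwise posteriors the band is clipped to contain the mean. An
intercept-only fit yields a flat curve at the neutrality level.

The selection optimum is the per-draw parabola vertex
`−β_lin/(2β_sq)`, evaluated only for draws with negative curvature
(interior optimum); the summary reports the interior fraction alongside
posterior mean and 80% interval, back-transformed to raw proportion.

## Geometry

Home ranges are 100% minimum convex polygons (convex hull of all used
locations; qhull). Collinear or < 3-point inputs raise an error rather
than yielding a zero-area polygon, because availability sampling needs
positive area. Availability points are rejection-sampled from the
polygon's bounding box, boundary-inclusive, strictly more than the
exclusion radius (default 10 m) from every used point of the same
individual; the attempt budget is 1000×n with an estimated feasible-
fraction floor of 0.5%, and exhausting it raises an error reporting the
estimate. Whether points should also avoid other individuals' used
locations is undefined in the underlying design; the package excludes
per-individual only.

Patch covariates integrate the landscape raster over the sampling circle
on a deterministic midpoint lattice with step radius/24 (≈1800 points),
rather than exact circle–cell intersection areas; against a 10⁴-point
Monte-Carlo integration the error is well under 0.02 in bare fraction.
Height on a circle with no vegetated cover is defined as 0 cm so the
covariate exists everywhere. Coordinates are planar metres; geographic
coordinates are rejected, never converted.

Track thinning keeps a foraging fix iff ≥ 5 minutes (configurable) have
passed since the last kept fix or the bird moved beyond `site_radius`
(default 10 m, the "different foraging site" rule — the radius is a
package parameterization of an otherwise verbal rule). Non-foraging
fixes are never kept; the pass is greedy and idempotent.

## Synthetic data

`make_landscape` thresholds a smoothed Gaussian random field at the
empirical quantile matching the target bare fraction (default 0.4) and
lays an independent truncated-normal height field (mean 15 cm, sd 5 cm)
over the vegetated cells. Default patch scale is 1.5 m: at the 1 m
sampling-circle scale this yields a realistic share (~30%) of circles
with intermediate bare cover; much coarser mosaics make the patch
covariate nearly binary. The field generator and the point sampler use
independently spawned substreams of the master seed.

`simulate_study` draws per-individual coefficients from `N(μ, σ²)`
(coefficients act on raw covariates), places each individual's home range
as the MCP of a uniform scatter (default radius 100 m) on a shared
800 × 800 m landscape, accepts candidate points with probability
proportional to `exp(βᵀx)` normalized by a pre-scan maximum, and samples
availability with the 10 m exclusion buffer. Species presets fix the
study structure: hoopoe 13, wryneck 8, woodlark 7 (5 m circles), common
redstart 5 individuals (no height measured); default 45 used + 45
available points per individual puts a four-species run at the same
order as the ~2,900 locations of a real multi-species campaign. The
intercept of the generating model is not a recovery target —
use–availability designs identify slopes, not absolute intercepts.

`simulate_from_model` skips the landscape and draws responses directly
from the hierarchical logistic family on within-dataset-standardized
covariates (bare ~ Beta(2,2), height ~ N(15,5) truncated at 0). This is
the construction under which standardized-scale truth is exactly defined,
so parameter-recovery and PPC-calibration studies use it.

What the generators do *not* emulate: telemetry error, movement
autocorrelation beyond the 5-minute thinning, central-place foraging
trips, and — in `simulate_from_model` — spatial autocorrelation of
covariates. Conversely the landscape generator *does* induce spatial
dependence between nearby records, which the exchangeable model reads as
extra signal; the null-recovery study therefore uses the exchangeable
generator, and passing tests on synthetic data do not certify robustness
to the spatial pseudo-replication present in real telemetry data.

## Numerical choices

- Log-likelihood in the overflow-safe form `yη − log(1 + e^η)`
  (`logaddexp`); non-finite linear predictors raise with the record index.
- χ² probability clamp 1e−12, logged.
- Credible intervals are equal-tailed quantiles; ties in DIC are reported
  in fit order, never resolved.
- Candidate-set fits derive per-model seeds as base seed + formula index,
  so a whole selection table reproduces from one integer.
- Test problem sizes: recovery studies use 13 individuals × ~100 records
  (20 replicates), selection studies 10 replicates of ~1200–2000 records;
  these match the scale of the motivating field studies while keeping a
  full suite run in a few minutes.

## Known limitations

- No spatial autocorrelation model, no step-selection (conditional
  logistic) formulation, no correlated random effects, no model
  averaging, no WAIC/LOO.
- The record-level χ² PPC has low power against smooth misspecification
  (see above).
- Conditional-focus DIC mildly favours overfitting under null truth.
- Selection probabilities are relative to the sampling design, not
  absolute probabilities of use.
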