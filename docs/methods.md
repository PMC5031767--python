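# Methods

## The population model

A study is modeled as a set of between-subject conditions, each with a fixed
sample size `n_c` and a multivariate-normal population over the shared
within-subject measures: mean vector `μ_c`, standard deviations `σ_c`, and a
correlation matrix `R_c` (covariance `Σ_c = diag(σ_c) R_c diag(σ_c)`).
Measures are modeled *jointly* even when only marginal tests are requested,
because paired within-subject tests depend on the correlation between the two
measures through `sd(diff) = √(σ₁² + σ₂² − 2ρσ₁σ₂)`.

Assumptions this inherits: normal populations, independent subjects,
between-subject independence of conditions, and — in the sense of a direct
replication — that the originally reported summary statistics are adequate
stand-ins for the population values. Nothing here estimates effect sizes from
raw data; the reported summaries *are* the model.

## Success as a conjunction

Each theoretical claim is operationalized as a list of test requirements:
either *significant in a stated direction* or *non-significant*, at a
per-test two-sided α (default 0.05; the convention of the literature the
method targets, exposed as a parameter because articles rarely state it).
Full success is the conjunction: every requirement met on the same simulated
data set. Two consequences follow directly:

- the joint probability can never exceed the weakest marginal (checked
  exactly, since marginals are counted on the same replications);
- tests sharing samples are dependent, so the joint probability is *not* the
  product of marginals within a study — that is why simulation, not
  closed-form power, is the estimator. Across independent *studies* the
  product rule does hold and is used for aggregation.

Direction enforcement matters: a significant result with the wrong sign
contradicts the original claim and is counted as failure. An
`enforce_direction=False` switch exists for sensitivity analysis; under the
null it moves the success rate of a significance requirement from α/2 to α.

## Test engine

Between-subject comparisons default to the pooled-variance Student t
(df = n₁+n₂−2), matching the analysis conventions of the early-2000s
literature this method is typically applied to; Welch's test is available via
`variant="welch"`. Paired comparisons are one-sample t-tests on the
per-subject differences. All p-values are two-sided; ties at exactly α count
as non-significant (probability zero under the continuous model). The
numerics are scipy's; this package adds the degenerate-sample guard and the
requirement classification.

A zero-variance sample (`DegenerateSampleError`) aborts an estimate rather
than counting as failure: under a continuous model it has probability zero,
so its occurrence means the design itself is malformed (e.g. a zero SD), and
silently absorbing it would bias the estimate of a quantity that is no longer
well defined.

## Monte-Carlo estimator

`estimate_success` draws `reps` simulated experiments (default 100,000 for
point estimates; sweeps default to 10,000 per grid point, which keeps a full
40-point curve near a minute while the binomial SE stays below 0.005). The
estimate is fully determined by a single integer seed: replications are
processed in fixed chunks of 4,096, each chunk driven by its own child stream
spawned from the master `SeedSequence`, with conditions sampled in design
order inside the chunk. The fixed chunk size makes the draw sequence — and
hence every reported number — independent of memory or vectorization
considerations; two runs with the same inputs are bitwise identical.
`reps < 100` is rejected outright (`InsufficientRepsError`): the Monte-Carlo
SE would exceed 0.05, which is larger than most of the differences the
method is used to detect.

Correlated normals are generated through the symmetric eigendecomposition of
`Σ` (not Cholesky), so exactly singular but valid PSD matrices — e.g.
correlation ±1 — sample correctly.

## Analytic oracle

For a *single* test the outcome probabilities are computed in closed form
from the noncentral t distribution (`power.py`), with the standardized
effects derived from the design: between-subject `d` uses the (n−1)-weighted
pooled σ of the two conditions (the articles this method examines rarely
define an effect size, so the package states its own convention); paired
`d_z` divides by `sd(diff)` above. Far-tail masses that underflow scipy's
`nct.cdf` are recovered via the `sf` symmetry and floored at 0.

The Monte-Carlo engine is validated against this oracle over randomized
single-test designs (exact agreement is expected because the fixture
generator produces homoscedastic conditions, under which the pooled t is
exactly noncentral-t distributed). The oracle is also the grid-search
reference for the location of a mixed criterion's ceiling. The test suite
additionally cross-checks the oracle itself against statsmodels' power
routines, keeping the two routes (simulation vs closed form) independent.

## Sweeps and aggregation

`success_curve` re-instantiates the design at each grid value with *equal*
allocation across conditions (unequal-allocation sweeps are out of scope) and
estimates success at each point with an independently derived seed, so grid
points are independent but the curve is reproducible. The default grid
5..200 in steps of 5 brackets both typical small-sample designs and the
large-n decline. Ties in the maximum break toward the smaller (cheaper) n.

`aggregate_product` multiplies per-study probabilities and raises the
excess-success flag below a threshold. The threshold is a reporting
convention (default 0.1, the customary value in the excess-significance
literature), so it is always printed alongside the product rather than
buried in the verdict.

## Synthetic data generator

`make_random_design` emulates the structure of the studies this method is
applied to: a handful of between-subject conditions (default 3), a few
correlated within-subject measures (default 2), per-condition sample sizes in
the 10–30 range typical of that literature, standardized effects of 0.2–0.8,
and correlation magnitudes of 0.1–0.6. Populations are homoscedastic (one SD
per measure shared across conditions) — the assumption under which the pooled
t-test and the noncentral-t oracle are exact. Correlation matrices are built
from signed one-factor loadings (`r_ij = s_i s_j √(t_i t_j)`), which is PSD by
construction; `corr_range` therefore bounds the *magnitude* of the
correlations and must lie within [0, 1). Expected directions of significance
requirements follow the true population effect, as they do in the real use
case (the original authors claimed the direction they observed).

What the generator does **not** emulate: non-normal or heteroscedastic
populations, unequal measure sets per condition, hierarchical designs,
selection effects in which tests get reported. Passing tests therefore show
that the estimator is correct *under its stated model*, not that real data
meet that model.

The three-condition priming template (`study1_template`) ships with the exact
test battery and sample sizes (13/12/14) but **no numeric population
parameters**: the original article prints none in its text, and fabricated
defaults could masquerade as the real ones. Parameters must be supplied
explicitly or loaded from the documented CSV schema (`load_parameters`); the
examples and tests use clearly-labeled synthetic values.

## Numerical and design choices

- Violations are *returned*, never raised, by `validate_design`, so a config
  file's problems are reported all at once; estimation raises
  `InvalidDesignError` carrying the same list.
- PSD tolerance for correlation matrices: smallest eigenvalue ≥ −1e−10,
  absorbing round-trip float noise from YAML/CSV; anything worse is rejected
  rather than repaired — a nearest-PSD projection would silently change the
  model being simulated.
- Only two-sided tests are offered; direction is enforced post hoc. This
  matches how the target literature reports tests and makes
  "wrong-direction significance" an explicit failure mode instead of an
  impossible event.
- Estimates are serialized at full float precision; rounding to the 3
  decimals used in prose is left to display code.

## Known limitations

- The method conditions on reported summaries; if those are far from the
  population values, so are the success probabilities (garbage in, garbage
  out — the sweep section of the README shows what can and cannot be
  concluded).
- Joint analytic probabilities for multi-test criteria are intentionally not
  implemented; dependence between tests sharing samples makes the simulation
  the reference.
- The excess-success flag is a screening diagnostic, not a hypothesis test
  with controlled error rates, and it cannot identify *which* practice
  (sampling, analysis, reporting, claim-fitting) produced the excess.
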