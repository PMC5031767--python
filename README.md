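# excess-success

Monte-Carlo diagnostics for experiment sets that look "too good to be true."

Many articles in psychology and biomedicine rest their claims on a *pattern*
of hypothesis-test outcomes: several tests must be significant in a stated
direction, and some must remain non-significant. Because sampling noise makes
occasional failures inevitable, a set of studies that *always* reproduces its
full pattern can itself be evidence of selective reporting, flexible analysis,
or claims fitted to noise. This package — aimed at meta-researchers, editors,
and anyone planning a replication — quantifies that intuition:

- **Replication-success probability.** Treat a study's reported means,
  standard deviations, sample sizes, and within-subject correlations as
  population values; simulate direct replications by drawing each condition
  from the corresponding multivariate normal; apply every test in the success
  criterion; and estimate `P(all requirements met)` as the fraction of fully
  successful simulated experiments, with its Monte-Carlo standard error
  `sqrt(p̂(1−p̂)/N)`.
- **Analytic single-test probabilities.** For one t-test with standardized
  effect `d` (between subjects) or `d_z` (paired), the probabilities of
  significant-in-direction / significant-wrong-direction / non-significant
  outcomes are tail masses of the noncentral t distribution with
  `δ = d·√(n₁n₂/(n₁+n₂))` (df = n₁+n₂−2) or `δ = d_z·√n` (df = n−1). These are
  the oracle the simulation engine is validated against.
- **Sample-size sweeps and the ceiling phenomenon.** When a criterion mixes
  significance and non-significance requirements, success peaks at an interior
  per-condition `n` and then *decreases*: growing power eventually pushes the
  small true effects behind the "null" tests across the threshold. The sweep
  reports the attainable maximum and where it occurs.
- **Multi-study aggregation.** For studies on independent samples the joint
  probability of full success is the product `P_TES = ∏ᵢ p̂ᵢ`; values below a
  stated threshold (default 0.1) raise the excess-success flag.

A significant result in the wrong direction never counts as success: the
toolkit asks whether the *reported* pattern would recur, sign included.

## Worked example

`examples/01_single_study_success.py` builds a three-condition priming design
(two correlated within-subject measures; synthetic population parameters),
attaches its seven-test criterion — five significant-in-direction, two
non-significant — and simulates 100,000 direct replications at the original
sample sizes (13/12/14):

```
per-test marginal success rates:
  rel_white_vs_black     requires significant     -> 0.999
  rel_black_vs_none      requires significant     -> 0.684
  ...
  irrel_white_vs_none    requires non_significant -> 0.945

joint success probability: 0.315 (MC standard error 0.0015, 100,000 replications)
```

Each test individually succeeds most of the time, yet the full conjunction
succeeds in under a third of replications — the gap between per-test power and
pattern-level replicability is the entire point of the method.

`examples/02_sample_size_ceiling.py` shows the ceiling: for a criterion with
one must-be-significant test (d = 0.5) and one must-stay-non-significant test
(d = 0.2), the joint success rises from 0.17 at n = 10 to a maximum of 0.674
at n = 90 per condition, then collapses to 0.000 by n = 2000.

`examples/03_multi_study_aggregate.py` aggregates five published per-study
success estimates (0.163, 0.380, 0.575, 0.450, 0.212): their product is
**0.003**, i.e. a fully successful replication of the whole set should occur
three times in a thousand attempts — and even with every study at its optimal
sample size the product only reaches **0.350**.

## Command line

The same operations are available as a thin CLI:

```bash
tes estimate spec.yaml --out report.json --reps 100000 --seed 1
tes sweep    spec.yaml --study study1 --n-min 5 --n-max 200 --step 5 --out curve.csv
tes aggregate spec.yaml --out report.csv --format csv --threshold 0.1
tes fixture  --seed 3 --out synthetic.yaml
```

Study specs are strict, versioned YAML (see `excess_success/specio.py` for the
schema); exit codes are 0 (ok), 2 (validation failure), 3 (degenerate sample).

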