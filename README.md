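# socmicro

Dyadic analysis of **social transmission of gut microbes** in group-living
animals, built around the merged-colony experimental design: bats (or any
hosts) from distant source colonies are housed together, their social
interactions are recorded on video, and their microbiomes are sampled over
time. The package answers the core question of that design — *does social
contact predict microbiome similarity, controlling for everything a shared
environment already equalizes?* — with permutation inference that respects
the pairwise (dyadic) structure of the data.

It is written for behavioural ecologists and microbiome researchers who
have: a taxon-by-sample abundance table (e.g. a merged MetaPhlAn profile),
roosting/cluster scan logs, timed contact-bout logs, and sample metadata.
A seeded colony simulator generates all of these under an explicit
contact-driven transmission model, so every inferential claim the package
makes is validated against known ground truth.

## What it computes

**Networks** (`socmicro.socialnet`)
- Clustering network: simple ratio index,
  `SRI(A,B) = x / (x + y_AB + y_A + y_B)` over scan periods.
- Oral-contact network: total dyadic bout duration (bouts ≥ 5 s, both
  directions) per hour of co-presence, passed through the bounded
  skew-reducing transform `t(x) = 1 − 1/(1 + x)` and z-scored over dyads.

**Microbiome similarity** (`socmicro.abundance`)
- `S = 1 − BC`, with Bray–Curtis `BC(u,v) = Σ|u−v| / Σ(u+v)` over taxa;
  Simpson diversity `1 − Σp²`; `relative` or `median_of_ratios`
  (size-factor) normalization.

**MRQAP-DSP** (`socmicro.mrqap`)
- Multiple regression of a dyadic response on dyadic predictors with
  node-permutation (quadratic assignment) inference, double-semi-partialing
  variant: each predictor's residual matrix is jointly row/column-permuted
  and the pivotal OLS *t* is compared across permutations. Exact exhaustive
  enumeration is available for small node sets, Monte-Carlo with the
  add-one rule `(1 + #as-extreme) / (1 + N)` otherwise.

**Convergence** (`socmicro.convergence`)
- For pairs sampled before and after a colony merge: fixed-effects model
  `similarity ~ time_scaled * dyad_type` (introduced pairs as baseline)
  with a null built by permuting time values *within* each dyad; per-dyad
  slope directions; percentile-bootstrap CIs.

**Simulator** (`socmicro.synthetic_colony`)
- Dirichlet base communities per source colony, affinity-driven roosting
  partitions, within-cluster contact bouts, bout-driven compositional
  mixing `m = 1 − exp(−τ·d)` plus daily log-normal drift, and multinomial
  sequencing-like sampling.

## Worked example

Simulate the default merged colony (3 source colonies × 9 bats, 120 days,
240 observed hours) and run the whole analysis:

```bash
socmicro run-all --out-dir out --seed 1
```

which prints:

```
pipeline complete; results in out
  MRQAP contact: beta=0.2809 p=0.000999
  MRQAP clustering: beta=0.1808 p=0.002997
  convergence interaction=-0.1455 p=0.000999
```

Reading: with both networks in the model, one standard deviation more
oral contact predicts **+0.28 SD** of gut-microbiome similarity and one SD
more co-clustering **+0.18 SD**, each controlling for the other, with
permutation p ≈ 0.001 (1000 node permutations). The negative time ×
dyad-type interaction (−0.15 per SD of time, within-dyad permutation
p ≈ 0.001) says introduced pairs converged while same-roost pairs
diverged; `out/results.json` additionally reports that all 25 pre/post
pairs changed in the predicted direction. `out/report.md` holds the
human-readable summary, and every intermediate matrix is written as CSV.

The same stages are available individually (`socmicro simulate`,
`networks`, `similarity`, `mrqap`, `convergence`) and as library
functions; see the module docstrings and `docs/methods.md`.

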