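# Methods

This note documents the statistical procedures implemented in `socmicro`,
the data-generating model behind the simulator, and the design choices
made where the methodology was genuinely open.

## 1. Dyadic data and why permutation inference

All core quantities are *dyadic*: one value per unordered pair of
individuals (microbiome similarity, association index, contact rate).
Rows of a dyadic regression are not independent — every individual
appears in n−1 dyads — so ordinary OLS p-values are invalid. The package
therefore treats OLS purely as a point-estimation device and obtains
p-values from node permutations: jointly relabelling the rows and columns
of a matrix by one bijection preserves the row/column dependence exactly,
so the permuted statistics form a valid null ensemble.

### MRQAP with double semi-partialing

For response matrix **Y** and predictors **X₁…X_p** (vectorized over the
unordered dyads, with intercept):

1. For each predictor k, regress **X_k** on the remaining predictors and
   re-assemble the residuals into a symmetric matrix **E_k**.
2. The observed statistic is the OLS *t* of **E_k** in the model
   `y ~ others + E_k` — algebraically identical to the *t* of **X_k** in
   the full model (Frisch–Waugh), but computed through the same code path
   as the permuted statistics so the identity permutation reproduces it
   exactly.
3. For each permutation, node-permute **E_k**, substitute it for **X_k**,
   refit, and record the *t* of the substituted column.
4. Two-sided p = (1 + #{|t_perm| ≥ |t_obs|}) / (1 + N) (add-one rule;
   guarantees p > 0 and the validity of the Monte-Carlo test). With
   `exhaustive=True` all n! permutations are enumerated and
   p = #{|t_perm| ≥ |t_obs|}/n! is exact (the identity is in the group,
   so p ≥ 1/n!).

The *t* (not the raw coefficient) is compared because it is pivotal:
its null distribution is insensitive to nuisance scale, which matters
under the heteroskedasticity typical of dyadic data. Comparisons use an
absolute tie tolerance of 1e-9 so that structurally identical
permutations (e.g. automorphisms of a block predictor) count as ties
rather than falling on either side by floating-point accident.

Permutations are drawn uniformly with replacement from the symmetric
group under a single seed. With one predictor (`qap_single`), the raw
predictor matrix is permuted (equivalent to permuting the response, and —
because the DSP residual on an intercept is just the centered predictor,
whose permutation stream yields the same *t* sequence — also the
no-partialing special case of the DSP engine).

**Missing dyads.** Bats with no usable dyads (e.g. no final gut sample)
are dropped whole; the remaining mask is then complete and a fast batched
solver handles all permutations at once. If a mask is incomplete at the
dyad level, node permutation is applied *before* the mask is re-imposed;
a permutation that moves a usable dyad onto a missing entry is refit on
its finite dyads (slow path). A rate whose denominator is zero (a pair
never co-present) is treated as missing, not as zero.

### Within-dyad time permutation (convergence)

Each analyzed dyad pairs one bat's fixed pre-merge reference sample with
a partner bat's repeated samples, giving a similarity series over time
(days since the reference). The fixed-effects model is

    similarity ~ time_scaled + same_roost + time_scaled : same_roost

with *introduced* pairs as the baseline level, so the interaction equals
the same-roost slope minus the introduced slope, and the prediction under
transmission is a **negative** interaction (introduced pairs converge,
same-roost pairs diverge). Time is centered and scaled to unit SD over
all points (sample SD), so slopes are per SD of time. Because the model
is saturated in dyad type, per-type slopes from separate fits coincide
with the joint fit.

The null permutes the time values among each dyad's own points,
independently per dyad: exchangeable under "no time trend" while
preserving every dyad's similarity values, its share of the design, and
the global time multiset (so the scaling constants are
permutation-invariant). The statistic is the interaction *t*; p uses the
add-one rule. Single-point dyads cannot be shuffled and are excluded
with a warning.

Degenerate case: perfectly flat data give a zero coefficient with zero
standard error in every permutation; *t* is defined as 0 there (and as
signed infinity for a perfect nonzero fit), so the flat case yields
p = 1 rather than NaN.

### Per-dyad directions and bootstrap

Per-dyad least-squares slopes of similarity on days are scored against
the prediction (positive for introduced, negative for same-roost); a
slope of exactly zero counts as *not* predicted and is flagged as a tie
(conservative). Group summaries use the percentile bootstrap: resample
the dyad-level values with replacement, take the 2.5/97.5 percentiles of
the bootstrap means. The bootstrap treats dyads as exchangeable units;
dyads sharing a bat are not independent, and the report carries this
caveat explicitly rather than modelling the dependence (a
multi-membership random-effects model is out of scope — the permutation
test above is the package's inference path for the interaction).

## 2. Networks

- **SRI**: x / (x + y_AB + y_A + y_B) with y_AB = both present but not in
  the same contiguous cluster — i.e. "both present, not associated"
  periods count in the denominator. Pairs never co-present get edge 0
  with a logged warning.
- **Contact rate**: bouts shorter than 5 s are discarded (a bout of
  exactly 5 s is kept); mouth-to-mouth and mouth-to-body bouts are
  pooled. Rate = total duration in both directions / hours of
  co-presence.
- **Transform**: t(x) = 1 − 1/(1+x), bounded in [0, 1), monotone. The
  alternative reading −1/(1+x) differs by an additive constant, so after
  standardization the two are elementwise identical; this equivalence is
  asserted in a test, making the choice inconsequential.
- **Standardization**: z-scoring over the unique unordered dyads
  (population SD). Centering is harmless in a regression with an
  intercept and makes coefficients comparable across predictors. The
  pipeline also standardizes the response, so MRQAP coefficients are in
  SD units on both sides.

## 3. Abundance handling

Input is a taxon-by-sample table (plain TSV, or a merged MetaPhlAn-style
dialect from which only species-level rows are kept, lineage prefixes
stripped, values treated as already-normalized). Validation rejects
negative values, duplicate labels and all-zero sample columns at read
time. Two normalizations are exposed:

- `relative` (default): columns to proportions. Bray–Curtis on
  proportions is the field's standard beta-diversity choice.
- `median_of_ratios`: the classic size-factor formula (median over taxa
  with nonzero geometric mean of count / geometric mean). This is a
  deliberate, documented stand-in for a variance-stabilizing transform:
  a VST proper needs a fitted dispersion trend, which is outside this
  package's scope, and the permutation machinery downstream is agnostic
  to the normalization choice — which is therefore a config option, not
  a hard-coded decision.

Similarity is 1 − Bray–Curtis (via `scipy.spatial.distance`), stored with
unit diagonal; every downstream statistic uses off-diagonal entries only.

## 4. The simulator

The generator is a first-class module: it produces every input format
the pipeline reads, under an explicit causal model with retrievable
ground truth.

**Model.** Colony c's bats start as i.i.d. Dirichlet draws from a
colony-specific concentration vector (a shared core block plus a
per-colony signature block — origin roost structures the microbiome).
After the merge day, bats interact for `hours_per_day` hours every day.
Each scan window draws a roosting partition by a sequential
preference-weighted process; co-clustering odds are proportional to a
log-normal per-dyad affinity × `grouping_preference` for same-roost
pairs. Oral-contact bouts arise **within clusters only** — clustering is
the sole source of contact opportunity — at a per-dyad rate scaled by a
second, independent log-normal contact affinity (grooming/food-sharing
propensity beyond mere proximity), with exponential durations. A dyad's
total contact of d seconds in a day mixes both compositions toward their
mean with weight m/2 each, m = 1 − exp(−τ·d): repeated short bouts
compose approximately like one long bout, and m → 1 makes the pair
identical. (The symmetric m/2 form is used precisely so that the
saturating limit is the pair mean; a full-weight simultaneous update
would swap the two compositions instead of equalizing them.) Each day
ends with multiplicative log-normal drift (SD `drift_sd` per taxon) and
renormalization. Faecal samples on scheduled days and one final gut
sample per bat are multinomial draws of `sequencing_depth` reads from
that day's latent composition.

**Observation model.** Only `n_hours` of the active hours — evenly
spaced days — are observed: the grouping scans, bout log and presence
log cover the observed hours only, emulating a video subsample of colony
life. Transmission uses all bouts. This is what gives the clustering
network its own predictive share alongside the contact network: both are
noisy, complementary measurements of true cumulative exposure.

**Default scenario** (the package's standard study conditions): 3
colonies × 9 bats (27), 100 taxa, 120-day horizon with the merge on day
14, 6 active hours/day, 240 observed hours (40 days), half-hourly scans
(480), τ = 0.003 per contact-second, drift SD 0.05/day, grouping
preference 3, co-clustering affinity log-SD 1.5, contact affinity log-SD
0.7, 0.1 bouts per co-clustered dyad-hour, mean bout 20 s, sequencing
depth 100 000. The faecal sampling schedule mirrors a 25-pair pre/post
design: five reference bats (colony A) sampled once before the merge and
five partner bats (two colony A, three colony B) sampled once before and
three times after, yielding 10 same-roost and 15 introduced pairs; the
pipeline restricts convergence references to bats whose faecal sampling
is entirely pre-merge, reproducing that fixed-reference design. These
settings were fixed once so that the generator exhibits the qualitative
phenomenon the pipeline is meant to detect — introduced pairs gaining
roughly +0.05…+0.1 similarity over the study while same-roost pairs
decline slightly, and both network coefficients recoverable — and are
not tuned per run.

**Negative control.** `shared_base=True` with `transmission_rate=0`
keeps the social assortment but removes both colony-specific base
communities and transmission: no mechanism then links behaviour to
microbiome structure, so the MRQAP contact coefficient must reject at
the nominal rate. (With colony-distinct bases and τ = 0, a contact
"effect" would reappear purely through colony confounding — that
configuration measures confounding, not test validity, and is therefore
not the control condition.)

**What the simulator does *not* emulate.** Taxon–taxon ecological
interactions, strain-level dynamics, environmental reservoirs, diet
shifts, antibiotic perturbations, compositional zero-inflation beyond
multinomial sampling, and observation error in behavioural scoring.
Passing tests demonstrate that the *inference machinery* is correct and
that the pipeline recovers a known transmission signal of realistic
size; they do not certify effect sizes in real colonies.

## 5. Numerical choices

- OLS inside permutation loops is solved by batched normal equations
  (3–4 coefficients, hundreds of dyads); singular batches fall back to
  the pseudo-inverse. The batched path is validated against statsmodels
  and against an independent pseudo-inverse oracle, and the permutation
  engines against full brute-force enumeration for n ≤ 6.
- Permutation tie rule: |t_perm| ≥ |t_obs| − 1e-9.
- Bray–Curtis values are clipped to [0, 1] only within 1e-9 round-off;
  larger violations raise.
- RNG: `numpy.random.default_rng` throughout; the simulator derives one
  independent stream per stage from (seed, stream-id) seed sequences, so
  each stage is individually reproducible; the pipeline derives analysis
  seeds as seed×1000 + offset (mod 2³¹).
- Deterministic dyad ordering: nodes sorted lexicographically by id,
  dyads enumerated i < j.

## 6. Problem sizes used in validation

The acceptance suite enumerates ≥50 exhaustive-QAP instances at n = 4–6
nodes; runs 500 null datasets × 200 permutations for each permutation
test's type-I error; 500 bootstrap-coverage simulations at n = 50; and
25 seeded pipeline replicates of the default scenario (plus 25 of the
negative control). These sizes give binomial 99% bands tight enough to
detect miscalibration of a few percentage points while keeping the suite
fast.

## 7. Known limitations

- Dyads sharing an individual are treated as exchangeable by the
  bootstrap and the dyad-level summaries (see caveat above); only the
  QAP/within-dyad permutation paths fully respect the dependence.
- The convergence response uses the fixed-reference design (one bat's
  pre-merge sample versus the partner's series); a symmetric variant
  using both bats' repeated samples is a possible extension.
- Whether the permutation tests should be one-sided (the transmission
  prediction is directional) is left to the caller; defaults are
  two-sided with a `sided` flag.
- `median_of_ratios` requires at least one taxon present in every
  sample; sparse tables should use `relative` or a pseudo-count.
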