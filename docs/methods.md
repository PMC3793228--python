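# Methods

## The question and the model

`paramodiv` compares the tempo of plant diversification across
biodiversity hotspots using only two observables per clade: its standing
species richness *N* and the age *T* (Ma) of its crown node, read from a
dated molecular phylogeny.  Under a constant-rate birth–death process
with speciation rate λ and extinction rate μ, the net diversification
rate is r = λ − μ.  The package inverts the expected richness of such a
process to estimate r, then aggregates, compares, and stress-tests those
estimates.

### Rate estimators (`paramodiv.rates`)

**Pure birth (Kendall–Moran).**  With no extinction the expected
richness of a crown group of age T is 2e^{rT}, so

    r̂ = (ln N − ln N0) / T,

with N0 = 2 for a crown group (the two daughters of the crown node) and
N0 = 1 for a stem lineage.  The crown convention (N0 = 2) is the package
default: it is the convention under which published crown-clade rate
tables reproduce (e.g. N = 17, T = 0.42 gives ln(17/2)/0.42 = 5.10),
whereas N0 = 1 would not.  N0 = 1 remains selectable.

**With extinction (Magallón–Sanderson).**  For a relative extinction
fraction ε = μ/λ ∈ [0, 1), the estimator inverts the expected richness
*conditioned on the clade surviving to the present*.  Writing
x = e^{rT} and the single-lineage extinction probability
α = ε(x−1)/(x−ε):

    stem:  E[N | survival]           = x / (1 − α)            ⇒ r̂ = ln(N(1−ε) + ε)/T
    crown: E[N | ≥1 daughter alive]  = 2x / (1 − α²)          ⇒ closed form below

    crown r̂ = (1/T)·[ ln( (N/2)(1−ε²) + 2ε + ((1−ε)/2)·√(N(Nε² − 8ε + 2Nε + N)) ) − ln 2 ]

At ε = 0 both reduce exactly to the pure-birth forms.  The test suite
verifies the closed forms against an independent bisection inversion of
the conditional-expectation equations to 1e-8 over random (N, T, ε); the
crown form was confirmed numerically to invert the "at least one
daughter survives" conditioning (not "both survive").

Report output is rounded to 2 decimals, round-half-even; comparisons
against published two-decimal values use ±0.005.

### Hotspot aggregation (`paramodiv.hotspots`)

The hotspot mean is the arithmetic mean of the **unrounded** per-lineage
mean-age rates.  Its uncertainty is a 95% **percentile bootstrap**
(default 1000 resamples of the lineages with replacement; CI at the
2.5/97.5 empirical percentiles).  Percentile rather than BCa or normal:
it is the simplest seed-reproducible reading of "a 95% bootstrap
interval", and at n = 13 lineages the refinements are not resolvable
anyway.  Rates from minimum and maximum crown ages are carried through
as upper/lower envelopes but never enter the mean.

Two per-area metrics: species/km² (richness/area) and speciation events
per Myr per km² (unrounded mean rate / area).  A validation report
recomputes every printed species/km² cell from its own area and
richness columns; a printed cell is accepted when it equals the
recomputation either **rounded or truncated** to its printed decimals
(published tables mix both conventions — one otherwise-consistent cell
matches only under truncation).  Cells matching neither (two in the
packaged eight-hotspot table) are flagged, not reproduced: the package
never copies a number it cannot recompute.

### Fastest-lineage resampling (`paramodiv.resampling`)

The procedure estimates the probability that the single fastest-evolving
lineage in a stratified draw comes from each hotspot.  One step draws
k = 5 lineages per hotspot without replacement, pools them, sorts by
rate descending, and records the top lineage's hotspot together with the
length of the top-of-ranking run from that hotspot.  1000 steps form one
process (per-hotspot proportion fastest; maximum run).  1000 independent
processes give the mean and 2.5/97.5 percentile CI of both statistics.

Design choices where the procedure was underdetermined:

- **"Consecutive fastest lineages from the same region"** is implemented
  as the within-step top-of-ranking run length, maximized over steps —
  the only reading invariant to the arbitrary ordering of independent
  steps.  The alternative (streaks of consecutive *steps* won by one
  hotspot) is reported as a secondary `max_step_run` column.
- **Replacement:** "without replacement" applies within a step; pools
  are restored between steps (a 5–13-lineage pool cannot sustain 1000
  draws otherwise).
- **Ties** break lexicographically by lineage id (measure-zero for
  continuous rates, but reproducible).
- **Random streams:** iteration i uses `SeedSequence([seed, i])`, so
  iterations are independent, reproducible, and parallelizable.
- The same fixed rate table is used for all iterations; rates are not
  re-estimated per iteration.

`exact_fastest_probability` enumerates the product of per-hotspot
k-subsets (bounded at 10⁶ joint draws) and is the oracle the Monte
Carlo is tested against: at 10⁵ steps the estimates agree within 3σ
binomial error (< 0.01 absolute) on oracle-sized tables.

### Chronogram operations (`paramodiv.trees`)

Chronograms are rooted trees with branch lengths in Myr, read from
Newick or NEXUS (dendropy underneath; plain Newick is treated as rooted
at its basal node, explicit `[&U]` is rejected).  Ultrametricity is
required for age-based operations, with tolerance 1e-6 relative to tree
height (dating software emits rounding noise); the check itself is a
pure predicate returning the maximum root-to-tip spread.  Node ages are
heights above the present; tips are clamped to exactly 0.

A tip counts as a **Pleistocene divergence** when its parent node in the
chronogram is younger than 2.58 Ma (base of the Pleistocene).  The
boundary is strict (<) by default — "within the last 2.58 Myr" read as
strictly younger — with an inclusive option.  "Divergence from the
closest relative" is operationalized as the tip's parent-node age; with
denser sampling (conspecific tips, unsampled sisters) the parent node
need not be the true sister-species split, which is a limitation of any
per-tip reading on a sampled tree.  Children of a polytomy all use the
polytomy's age.  Branch lengths are assumed to be in Myr; no unit
auto-detection is attempted.

### Simulators (`paramodiv.simulate`)

The Yule and birth–death generators exist to give the estimators and the
resampling machinery inputs with known truth:

- **Yule** (`μ = 0`): Gillespie simulation from a two-lineage crown
  start; stop at fixed height (crown age equals it exactly) or at a tip
  count (the clock then runs one extra exponential waiting time so
  pendant edges are positive).  Event times are recorded and must equal
  the node ages of the emitted tree to 1e-9 — internal bookkeeping is
  cross-checked, not trusted.
- **Birth–death**: same process with deaths; extinct subtrees are pruned
  and unifurcations suppressed to give the reconstructed extant tree.
  `condition_on_survival` rejection-samples (cap 10⁵) until ≥ 2 lineages
  survive; rejection rather than importance weighting, for exactness and
  simplicity.  When one of the two founders dies out the reconstructed
  crown age is younger than the stop time.
- **Synthetic rate tables**: per-hotspot lineage rates are log-normal
  (`exp(Normal(location, spread))`).  Log-normal because real
  per-lineage rates are positive and strongly right-skewed (within one
  hotspot the packaged table spans 0.18 to 5.10); this is a modeling
  choice for the generator, not a claim about the data.

What these generators do **not** emulate: dating error on node ages
(ages are exact), among-lineage rate variation within a clade,
non-constant rates through time, and incomplete taxon sampling.  Tests
passing on simulated trees therefore validate the estimators under
their own model assumptions, not the realism of those assumptions for
empirical chronograms.

### Recovery experiments and what they can show

A single (N, T) pair is one draw from a heavy-tailed richness
distribution, so a single-tree estimate is irreducibly noisy: for crown
Yule trees the per-tree relative error of r̂ has median ≈ 0.5/(λT) —
about 13% at λT = 4 — no matter how the estimator is implemented.  The
recovery checks therefore test *aggregates*: the median crown estimate
over 500 Yule trees (λ = 0.5, T = 8) recovers λ within 10% (observed
≈ 4%, the small-sample bias of inverting at the median rather than the
mean of N), and the ε-matched crown estimator averaged over 2000
conditioned birth–death trees (ε = 0.5) recovers r = λ − μ within 15%
(observed ≈ 10%; conditioning on survival biases richness upward, and
the estimator's conditioning only partially matches the simulator's).
Problem sizes (500 and 2000 trees, 10⁵ Monte-Carlo steps for the
resampling check) were chosen as the smallest that make the binomial/
sampling error bars decisively smaller than the tolerances being
checked.

### Determinism

Every stochastic stage takes an integer seed and derives substreams via
`numpy.random.SeedSequence` counter keys.  The full pipeline
(`run_full_analysis`) writes a report recording seed, package version
and validation flags; two runs with the same config and seed are
byte-identical.

## Known limitations

- The method-of-moments estimator assumes rate constancy and complete
  richness counts; undersampled clades bias r̂ downward, and the choice
  of crown vs stem age changes the estimate materially for young clades.
- Hotspot means treat lineages as exchangeable draws; lineage ages and
  sizes vary widely, and no phylogenetic non-independence correction is
  attempted (none is defined for this design).
- The package consumes dated trees and lineage tables; estimating the
  chronograms themselves (calibrations, clock models, posterior
  summarization) is out of scope.
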