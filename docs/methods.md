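# Methods

## The hierarchical process

The simulator is an exact event-driven (Gillespie) implementation of a
two-level branching process. State is the set of living incipient
lineages, each belonging to exactly one full species. With n living
lineages and per-lineage rates λᵢ (incipient branching), μᵢ (incipient
loss) and λ_f (conversion to full species), waiting times are drawn from
an exponential with total rate n·(λᵢ+μᵢ+λ_f); the affected lineage is
chosen uniformly and the event kind with probabilities proportional to the
three rates. Rates are homogeneous across lineages and time — no
diversity-dependence, no trait- or age-dependence — so the incipient-level
process is a linear birth–death process and every species-level pattern is
emergent. Time is in Myr throughout; rates are per lineage per Myr. The
run starts from a single lineage in a single species at t = 0 and stops at
the horizon `t_max`, when the last lineage dies, or when the live-lineage
count would exceed `max_lineages` (default 50,000), which raises an
explicit capped-growth error carrying the partial result — growth is never
silently truncated.

Event semantics:

- **branch** adds a new incipient lineage to the same species.
- **loss** removes the lineage. The event is labeled `reabsorption` when
  the species retains at least one other living lineage, and
  `species_extinction` when the lost lineage was the species' last. The
  label is thus a deterministic function of state, and species extinction
  is emergent: a species dies exactly when its membership reaches zero
  through a loss. `check_emergent_extinction` re-derives this from the
  event log and is exercised on random replicates in the tests.
- **conversion** gives the chosen lineage a fresh species identity
  containing only itself; incipient lineages it spawned earlier remain in
  the old species. This is the simplest reading of a per-lineage
  "full-species formation" rate and matches the protracted-speciation
  convention of treating speciation completion as a property of a single
  lineage. The alternative (the converting lineage carries its incipient
  descendants along) is defensible but couples conversion to the whole
  subtree; we did not implement it. A lineage may convert more than once.

One consequence deserves emphasis: when the *sole* living lineage of a
species converts, the old species ends without any loss event. We treat
this as anagenetic replacement, not extinction — it is recorded with end
cause `replaced` in the species records, and the emergent-extinction
invariant is stated as "a species disappears only at a species-extinction
loss or a sole-member conversion".

## Species trees

`collapse_to_species_tree` derives the tree of full species: the parent of
species S is the species its founding lineage belonged to at conversion.
Node times follow one of two conventions, chosen per call and recorded in
run metadata: `conversion_time` (default — the moment the founder became a
full species) or `incipient_origin_time` (the moment the founder
originated within the parent species). With `extant_only`, species with no
living lineage at the horizon are pruned and unifurcations suppressed,
yielding an ultrametric tree with tips at age 0.

`sampled_species_tree` is a third, deliberately different view: the
incipient genealogy pruned to one representative living lineage per extant
species (the oldest, i.e. the lowest lineage id), with divergence times
taken from the genealogy itself. This is the quantity a molecular
phylogeny of one specimen per species estimates. The distinction matters
for timing signal: under high turnover the conversion-time tree carries a
pull of the present (recent conversions have not yet had time to die), the
genealogy-sampled tree instead carries the protracted-speciation deficit
of recent divergences (recently branched lineages have rarely completed
conversion), plus the survivorship excess of early branches. Measured at
λᵢ=1.0, μᵢ=0.9, λ_f=0.1, t_max=15 over 200 survival-conditioned
replicates, mean γ is +0.9 for conversion-time trees, ≈0 for
incipient-origin trees, and −0.47 (one-sided p ≈ 2×10⁻⁸) for sampled
trees. The early-burst prediction is therefore operationalized on
`sampled_species_tree`; the collapse conventions remain available and
tested for the structural statistics.

## Summary statistics

- **LTT**: the curve starts at (0, 1) at the origin (the root edge is part
  of the tree), steps +1 at each split (+c−1 at a c-furcation, which only
  externally supplied trees can contain) and −1 at tips that end before
  the horizon (the maximum tip depth). Log-linearity of the baseline LTT
  is assessed on the replicate-averaged log lineage count over a fixed
  time grid — individual replicates scatter around the exponential mean
  with O(1) spread in log-space at every time, so a regression through raw
  pooled points understates the linearity of the curve itself.
- **γ (Pybus–Harvey)**: computed from internode intervals of an
  ultrametric tree (tolerance 10⁻⁹ × height), ≥3 tips; scale-invariant.
  For pure-birth trees of fixed tip count its mean is 0. Note that
  *selecting* fixed-duration pure-birth trees by a minimum tip count
  biases γ negative (measured −0.25 at λ=1, t=3.5, n≥20); the tests pin
  both facts.
- **Colless index**: raw (unnormalized) sum of |left − right| tip-count
  differences; polytomies are rejected rather than randomly resolved (the
  simulators never produce them).
- **Incipient histogram**: raw integer bins over species alive at the
  query time; skewness is the adjusted Fisher–Pearson sample estimator
  (`scipy.stats.skew(..., bias=False)`), reported as undefined (None) with
  fewer than three species or zero variance.
- **Effective rates**: per-species realized speciation rate = conversions
  originating from the species' lineages ÷ lineage-Myr exposure
  (integrated membership over the species' lifetime, from event-log
  replay). Effective extinction exposure is μᵢ/H_k with H_k the k-th
  harmonic number — the reciprocal of the expected time for all k current
  members to be lost under the loss rate alone (ignoring branching and
  conversion, which only lengthen species survival); it is monotonically
  decreasing in membership, the property the model predicts.

## Estimators

- `richness_age_rate`: λ̂ = ln(n)/t, the pure-birth single-ancestor
  expectation; a minimum-bound style estimate (extinction only raises the
  true rate). The headline reproduction (450 species, 0.015 Myr → 400) is
  reported to one significant figure since the inputs are order-of-
  magnitude figures.
- `waiting_time_to_rate`: rate = 10⁶/(generations × years-per-generation).
  Note the exact conversion of a 200,000-generation waiting time is 5
  events/lineage/Myr; published ranges quoting 2 as the lower end reflect
  waiting times above 200,000 generations ("more than"), so the arithmetic
  is implemented exactly and the discrepancy documented rather than
  patched.
- `fit_yule`: closed form λ̂ = (n−2)/E for a crown clade, with E the total
  lineage-time exposure (equal to the crown tree's total branch length);
  n−2 is the number of branching events observed after the crown split.
- `fit_birth_death`: numerical ML under the reconstructed-process
  likelihood conditioned on survival of both crown lineages
  (Nee–May–Harvey form; published variants differ in conditioning, so this
  choice is stated here and shared with the log-likelihood reported by
  `fit_yule`, making the models exactly nested). Optimization is bounded
  L-BFGS-B over (log r, a) with r = λ−μ > 0 and a = μ/λ ∈ [0, 1), from
  three starts (a₀ ∈ {0, 0.5, 0.9}, r₀ = Yule MLE); the Yule boundary is
  returned when it is at least as likely as the best interior point, and
  non-convergence of all starts raises rather than returning a silent
  best-effort value. Because μ̂ is a boundary MLE, roughly half of
  pure-birth datasets yield exactly 0 and the rest small positive values.

All estimators sort branching times internally, so input order is
irrelevant, and all are dimensionally coherent (rescaling times by c
rescales rates by 1/c to ≤10⁻⁹ relative error).

## Defaults and the simulated regime

The shipped defaults (λᵢ = 1.0, μᵢ = 0.5, λ_f = 0.03 per lineage per Myr,
t_max = 10) place incipient-lineage formation ~33× above full-species
formation, inside the 30–40× range estimated for bird subspeciation
relative to speciation, with half of incipient lineages failing per Myr so
that most incipient forms never become species. The early-burst
experiments use a higher-turnover regime (μᵢ/λᵢ = 0.9, λ_f = 0.1,
t_max = 15) where survivorship bias is strong. Replicate r of a batch is
seeded with seed + r (seed + r·max_tries under survival conditioning, so
rejection streams never overlap); a single seeded generator drives each
replicate, making event logs bit-reproducible.

## What the synthetic data does and does not show

All analyses run on the package's own simulations; no empirical trees are
bundled. The generator realizes exactly the model's assumptions —
memoryless homogeneous rates, no geography, no genetics of hybridization,
no diversity-dependence, complete and error-free trees. Passing tests
therefore demonstrate internal consistency of the model and correctness of
the statistics and estimators on clean ultrametric input, not that real
clades diversify this way: empirical phylogenies add estimation error,
incomplete sampling, and non-constant rates that the estimators here do
not model. Inference of (λᵢ, μᵢ, λ_f) from real trees is out of scope by
design; the package simulates the hierarchical model and fits only the
standard one-level birth–death family.

## Problem sizes and numerical choices

Monte-Carlo checks use sizes chosen to make the assertions sharp at
3-standard-error tolerances: 1,000 replicates for pure-birth mean
diversity, 2,000 for the critical-process mean, ≥500 surviving replicates
for the pooled incipient histogram, 200 survival-conditioned replicates
for the early-burst test, 200 hundred-tip trees for Yule recovery (the
closed form makes λ̂ unbiased, so a 5% median-bias bound is comfortable),
and 100 reconstructed trees with ≥50 tips for birth–death recovery.
Ultrametricity tolerance is 10⁻⁹ × height; BD optimizer tolerance is
10⁻¹² on the objective; branch lengths and event times are serialized with
17 significant digits for bit-exact round-trips. Degenerate inputs raise:
γ on <3 tips or non-ultrametric trees, Colless on polytomies, estimators
on nonpositive times, effective rates on zero exposure, membership queries
outside [0, horizon].

## Known limitations

- The spec-level species tree is defined by species parentage; for
  questions about divergence-time signal use `sampled_species_tree`, which
  is what phylogenies estimate.
- `fit_birth_death` assumes complete extant sampling of a crown clade and
  can sit on the μ = 0 boundary; standard errors are not reported.
- The event log grows linearly with events; very high-rate, long-horizon
  runs should lower `max_lineages` or the horizon.
- `waiting_time_to_rate` treats generations as fixed-length; overlapping
  generations or variable generation times need external averaging.
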