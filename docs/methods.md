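# Methods

## Problem

A gene `y` in species `t` is a *best match* of a gene `x` if no other
gene of species `t` has a more recent last common ancestor with `x` in
the gene tree: `lca(x, y) ⪯ lca(x, y')` for all `y'` with
`σ(y') = σ(y)`.  Best matches are the evolutionary objects that
orthology-detection pipelines try to approximate with reciprocal best
*hits*, i.e. smallest sequence distances.  The two coincide only under a
molecular clock; lineage-specific rate asymmetries between paralogs
(sub-/neofunctionalization) break the correspondence even for perfectly
measured, additive distances.

The package provides (i) three inference strategies that recover best
matches from a distance matrix, and (ii) a complete simulation system for
gene-family histories with rate asymmetries, so that the inference can be
scored against exact truth.

## Inference

**ε-best hits.**  For each focal gene `x` and target species `t`, report
every `y` with `d(x, y) ≤ (1 + ε) · min_{y'} d(x, y')`.  A relative
floating-point margin (default `1e-9`) keeps mathematically exact ties
together.  The sweep utility selects the ε maximizing the mean
per-scenario F-measure (ties go to the smallest ε).

**NJ + midpoint rooting.**  Neighbor joining (via scikit-bio) is exact on
additive data, so the only error source is the root placement; the root
is put at the midpoint of a longest leaf-to-leaf path and best matches
are read off the rooted tree.  Negative NJ branch-length estimates on
noisy input are clamped to zero; this can only move the midpoint, never
change the topology.  This method isolates the damage done by rooting
errors under rate asymmetry.

**Quartet method.**  The unrooted quartet topology on four leaves is
called from the three pair-sums of the four-point condition; a split is
accepted only when its sum is smaller than both alternatives by more
than `rel_tol` times the largest sum (default `1e-9`; the strict
inequality of the criterion needs a floating-point margin), otherwise
the star `×` is returned.  If `z` is an outgroup for `{x, y', y''}`, the
quartet translates into an order between `lca(x, y')` and
`lca(x, y'')`:

* `(x y' | y'' z)` → `lca(x, y')` is lower → arc `y'' → y'`;
* `(x y'' | y' z)` → arc `y' → y''`;
* `(x z | y' y'')` or `×` → equality → both arcs.

Arcs point from the gene with the larger lca to the smaller one, so the
best matches are the *sink* strongly connected component of the
auxiliary digraph (computed by boolean-closure reachability; the
candidate sets are small).  Under exact data with valid outgroups the
sink component is unique and equals the true best-match set; on noisy
data several sink components can arise and their union is returned.

**Outgroup choice.**  With a known species tree, outgroup *genes* are
taken from outgroup *species*.  Two strategies:

* `rootside` — species `z` with `lca_S(z, lca_S(σ(x), t))` at the
  species root; up to 20 genes (configurable) are sampled uniformly from
  those species.  Species pairs whose lca *is* the root have no such
  outgroup and are excluded from inference and scoring alike.
* `closest` — every relative outgroup species is a candidate, ranked by
  the depth of its joint lca with `lca_S(σ(x), t)` (closest first).
  Candidate genes are screened with the incongruence certificate: if a
  gene quartet `(x, y, z₁, z₂)` conflicts with the species quartet, an
  ancient duplication above the joint species lca is certain and both
  `z` genes are discarded.  The screen is budget-capped (50 quartets per
  candidate) because exhaustive screening is quadratic in the outgroup
  pool; if everything is filtered, the rootside pool is used as
  fallback.

When several outgroups vote on one candidate pair, the calls are
aggregated by majority; in the default mode star votes count toward
equality and ties become equality (both arcs), in `omit` mode unresolved
pairs contribute no arc.  Outgroups cannot be validated from data alone:
duplications pre-dating the species root make every choice of `z`
wrong for some pairs, which is the method's irreducible error source.
The package ships the three minimal failure configurations (two
pre-root duplications with one colour extinct below the focal gene) as
regression tests producing exactly the expected FN/FP patterns.

## Simulation

**Species trees.**  Topologies come from an innovation-type branching
process: species are feature sets; gaining a globally new feature, or
losing a feature so that an unseen genotype results, founds a new
lineage.  The published description of that model leaves the event mix
unspecified; we use equal probabilities for gain and loss attempts,
which produces moderately imbalanced trees, and treat the generator as
interchangeable (a Yule alternative is behind a flag) since none of the
correctness guarantees depend on topology realism.  Dates on [0, 1] are
assigned top-down: for an inner child `v` of `u`, with `k` speciations
strictly between `v` and a uniformly sampled leaf below it,
`τ(v) = τ(u)(1 − r/(k+2))`, `r ~ U(0, 2)`, so the expected time step is
`τ(u)/(k+2)` and dates stay strictly positive.

**Gene families.**  A Gillespie simulation runs one gene family down the
dated species tree under constant per-gene duplication, loss and HGT
rates.  Waiting times are exponential with total rate
`R = n_genes · (D + L + H)`; when a waiting time crosses a speciation,
the clock advances to the speciation, gene content is copied into the
daughter branches, and a fresh waiting time is drawn — valid because the
exponential clock is memoryless.  Duplicates stay in their branch, HGT
copies land uniformly in one of the other branches alive at that moment
(skipped as a null event if none exists).  The simulator records the
full reconciliation: speciation vertices map to species vertices,
duplication/HGT vertices and loss leaves to species branches, so ancient
duplications and root-crossing lineage counts are exact, not inferred.
Benchmark configurations use `H = 0`, matching the scope of the
theoretical guarantees; the machinery supports `H > 0` for
completeness.

**Rate asymmetries.**  Edge lengths (expected substitutions) arise from
two layers.  Per species branch, a baseline lognormal rate with
log-variance `σ₀²·(branch duration)` (default `σ₀² = 0.2`), mean-shifted
by `−σ²/2` so that `E[ω] = ω_parent`; the pre-speciation branch gets the
conserved mean rate exactly (default 1.0).  Per gene-tree edge, a
conserved/divergent mark with a piecewise-constant relative rate list:
conserved edges run at 1.0; divergent edges draw from `1 + Γ(shape,
scale)`.  Duplications of a conserved edge choose a fate with weights
(conservation, subfunctionalization, neofunctionalization), default
(⅓, ⅓, ⅓): both children conserved, both divergent, or one of each.
Divergent edges redraw their Gamma rate at speciations and pass
divergence to both duplicates.  A loss that leaves a single copy in its
species branch reverts the survivor to the conserved state from the loss
time onward.  The Gamma parameters were calibrated in the source
literature against a yeast whole-genome duplication but not published;
we default to shape 2.0, scale 0.5 (divergent mean rate 2.0) and expose
both parameters, plus a `Uniform(1, r_max]` alternative.  The edge
length is the branch baseline times the time-integral of the relative
rate list; with conserved-only fates and `σ₀² = 0` the distances are
ultrametric (clock limit), which the tests use as an exactness anchor
for the ε-method.

**Noise.**  (a) Multiplicative: one randomly chosen entry at a time is
rescaled by `N(1, s)`; proposals that are non-positive or violate the
triangle inequality against the current matrix are rejected, and the
process runs until `C(n, 2)` acceptances (pairs are drawn with
replacement, so some entries are hit repeatedly).  A per-slot retry cap
(10⁵) guards termination.  Non-positive proposals must be rejected
outright — a negative distance can satisfy no metric axiom.  Metric
repair of fully perturbed matrices is deliberately out of scope.
(b) Convex: `(1−α)D + αD'` with `D'` additive from an independently
simulated dated tree on the same leaf count (leaves matched by order) —
metric by convexity, non-additive in general, systematically biased.

**Sequences.**  Gap-free alignments evolve site-i.i.d. along the
observable tree: K80 for DNA (κ is the transition/transversion *rate*
ratio; an event-count ratio `R` corresponds to `κ = 2R`), WAG for
proteins, root sequences from the stationary distribution, and per-edge
transition matrices `expm(Q · rate_scale · ℓ)`.  Distances are
re-estimated with the Jukes-Cantor transform (saturated pairs `p ≥ 3/4`
are capped at twice the largest finite estimate in the matrix, keeping
NJ and quartet sums computable) or with the BLOSUM62 score distance
`1 − S(a,b)/max(S(a,a), S(b,b))` for proteins, which we validate for
monotonicity in divergence rather than numeric agreement with any
particular pipeline.  Quartet mapping classifies each column of a
4-sequence alignment into the 15 identity patterns; the three split
scores count full-support patterns once and single-extra-state patterns
half, and are normalised to sum to one.  The weighted variant scores
every column by its isolation index under a character metric and
reduces exactly to the unweighted scores for the trivial metric (a
tested identity).  A call is made only for a strict maximum; ties and
all-uninformative alignments yield the star.

## Evaluation protocol

Per scenario, recall/precision/F are computed over directed arcs
restricted to gene pairs whose (unordered) species pair admits outgroup
genes; the same restriction applies to every method so the comparison is
fair.  Outgroup availability (the `t5`-style statistic) is the fraction
of all `n(n−1)/2` unordered gene pairs — same-species pairs included —
whose species pair has a rootside outgroup species with at least one
surviving gene.  Scenarios are rejected and redrawn when fewer than two
species carry genes or no species pair is evaluable; redraw counts are
recorded.  The study driver uses counter-based per-scenario seeds
(`SeedSequence([master, index])`), so runs are reproducible and
order-independent.

Ancient-duplication statistics come straight from the simulated
reconciliation: the count of duplication vertices on the pre-root
species branch, and the number of gene lineages alive at the first
speciation (the preimage count of the species root).  The latter is
counted in the *extended* tree — lineages that die out later still
count, but lineages lost before the root do not — matching the regime in
which the at-most-two-preimages exactness guarantee is stated.

## Problem sizes

The bundled study driver and the reproduction script use 300 scenarios
for the inference comparisons and 500 for the duplication statistics,
with species counts uniform on [3, 50] and duplication/loss rates
uniform on [0.5, 1.0); these sizes give stable medians and 10th
percentiles while keeping a full run in the minutes range on one core.
The test suite uses smaller ensembles chosen per property.

## What the simulations do and do not show

The generator produces additive (noiseless) or metric (noisy) distance
data with known truth, heavy rate asymmetry between paralogs and
realistic gene content variation.  It does not model alignment error,
indels, among-site rate variation, assembly or annotation artifacts,
gene conversion or incomplete lineage sorting — so passing benchmarks
bound the error of the *best-hit→best-match* conversion itself, not of a
full sequence-analysis pipeline.  Known limitations: multiple ancient
duplications defeat any outgroup choice (the failure-catalog cases);
midpoint rooting fails systematically under strong asymmetry (by
design, as a comparison point); the incongruence filter is a one-sided
certificate and leaves undetected ancient duplications behind.
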