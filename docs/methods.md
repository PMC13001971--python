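# Methods

This note documents the modelling conventions, parameter defaults, and
numerical choices in `trophonet`, and what the synthetic-data tests do and
do not demonstrate about real species lists.

## Niche axis and link rules

Trophic positions are min–max scaled log10 body masses computed over the
*consumers* of a community; producers are pinned at `n = 0` regardless of
mass (a 500 kg tree is still a basal resource). Degenerate communities
(one consumer, or all consumer masses equal) place consumers at 0.5 so a
feeding interval is still definable. A consumer with no recorded mass is a
hard error: positions, not diets, carry most of the topological signal, so
silently guessing them would be worse than failing.

Two feeding-range parameterizations are implemented:

* **classic** (default): `r = n·x`, `x ~ Beta(1, 1/(2C) − 1)`, so
  `E[x] = 2C` and the expected connectance of the unconstrained model is
  `C`. This is the standard niche-model calibration.
* **literal**: `r ~ Beta(1, 2C)` truncated to `r ≤ 2n` (inverse-CDF
  truncation, exact and rejection-free). At `C = 0.12` the untruncated mean
  range is `1/1.24 ≈ 0.81` — most consumers would cover most of the axis,
  so realized connectance before the diet filter approaches saturation.
  The mode is kept for fidelity experiments, not as a default.

In both modes `c ~ U[r/2, n]`, which keeps the interval above the producer
end of the axis. The interval test is a closed interval on both ends.
Cannibalistic self-links are disabled by default in constrained builds
(they can never satisfy the "eats something" check anyway) and enabled in
the **pure** unconstrained model, as in the classic niche model: Monte
Carlo verification shows the pure model's mean realized connectance sits
on `C` only when the diagonal counts (0.1200 vs 0.1172 without, at
`N = 100`, `C = 0.12`, 200 replicates).

### Diet compatibility

Coarse diet categories map to resource classes: herbivore→producer,
insectivore→Insecta, piscivore→fish clades, carnivore/scavenger→animals,
planktivore→small aquatic animals (≤ 0.1 g, configurable), detritivore→
producers (treated as basal; no explicit detritus pool is modelled),
omnivore→anything. An empty or `unknown` diet is treated as fully
agnostic: the alternative (no links, then forced relaxation) would make
data gaps systematically distort topology rather than degrade gracefully.
Producer resources bypass the allometric test entirely and are taken with
probability `C` by any grazer (herbivore, omnivore, detritivore, unknown).

### Relaxation

Uneven lists (an insectivore with no insects listed) leave spare nodes.
Relaxation proceeds in stages, in lexicographic taxon order for
determinism: a starving consumer first drops the diet filter and links to
the in-interval resource nearest its optimum; if its interval is empty it
links to the nearest-position resource overall; an uneaten producer then
receives a uniformly drawn grazer (or any consumer if none). Self-links
never satisfy the requirement. With relaxation on, every consumer has ≥ 1
off-diagonal prey and every producer ≥ 1 consumer — checked exhaustively
in the test suite over 100 generated communities.

### Replicates

`replicates = max(3, round(K / log10 N))` with `K = 100`, the floor
keeping consistency and spread statistics defined for the largest
communities.

## Descriptors

Conventions that required a decision:

* `IND`/`OUT` average in/out degree over species with non-zero respective
  degree; otherwise both would equal the mean link count `AVL` and carry no
  independent information. `ASYM = Σ|in−out| / Σ(in+out)` (0 for an empty
  network) is a bounded asymmetry summary.
* Cohen chains are maximal simple basal→top paths; prefixes are not
  separate chains, and a path stuck in a cycle (cannot reach a top node)
  is not a chain. Enumeration is DFS with caps on chain count (10⁶),
  chain length (30) and visited partial paths; hitting any cap sets a
  `truncated` flag rather than silently under-counting.
* `LOOP1 = Σ|T − Tᵀ|/(2N²)` exactly as traditionally printed — it measures
  link *asymmetry* (it vanishes on reciprocal pairs); the count of mutual
  pairs is exposed separately (`mutual_pairs`).
* Nestedness: rows and columns are sorted by decreasing degree (stable for
  ties) and the reference packs each row's links into its leftmost cells —
  a maximally nested stepped region with the same size and link count.
  `NEST` is the fraction of links outside the reference; perfectly nested
  matrices score exactly 0, and the value is in [0, 1] always.
* β diversity is the literal `2·shared/(N_i + N_T)` formula; note it can
  only reach 1 when the site equals the pool, so "β = 1 means no exclusive
  species" holds only in that limiting sense.
* Model error against the pure-model baseline uses ≥ 20 baseline
  replicates; vector descriptors (DEG/GEN/VUL) compare zero-padded
  relative-frequency vectors by mean absolute difference.
* The power-law exponent is an exact discrete (Hurwitz-zeta) MLE maximized
  numerically — the common continuous approximation is badly biased at
  `kmin = 1`, which is where degree data start.

Community detection runs Louvain on the undirected unweighted projection
(directed modularity has no consensus definition for food webs), 10
restarts with derived seeds, keeping the best Newman–Girvan score. Bridge
species are ranked by the participation coefficient
`p = 1 − Σ_m (k_m/k)²`, ties broken lexicographically.

## Trait enrichment

Missing masses are first computed from lengths via per-taxon-group
`mass = a·size^b` tables (shipped defaults are order-of-magnitude values
and explicitly editable config — the machinery, not the coefficients, is
the contract). Remaining gaps use nearest-taxonomic-relative inference,
searching co-listed relatives genus→family→order→class→phylum: numeric
traits take the geometric mean (masses span many orders of magnitude;
an arithmetic mean would be dominated by the largest relative),
categorical traits the union. Imputation reads from a snapshot of the
input, so it is order-independent and idempotent, and never overwrites a
measured value. Free-text diet terms are coarse-grained by exact, then
longest-substring lookup in an editable term table.

Taxonomic **collapse** (rarefaction) deliberately uses the *arithmetic*
mean for member traits: aggregation averages a known, co-ranked group,
whereas imputation extrapolates across unknown scale — the asymmetry is
intentional.

## Synthetic communities

The generator emulates wetland-like inventories: ≥ 25% producers by
default (guild mix producer 0.30, herbivore 0.25, insectivore 0.15,
carnivore 0.15, omnivore 0.10, detritivore 0.05), log-uniform masses per
guild spanning 9 decades overall, 30% single-diet specialists, mixed
aquatic/terrestrial habitat use, and a consistent taxonomy whose classes
follow mass and habitat (small consumers are insects, mid-size strict
aquatics are fish, amphibious mid-size taxa are amphibians). Genus sizes
are drawn mostly monospecific (probabilities 0.8/0.15/0.05 for 1/2/3
congeners), matching the high genus:species ratios of local assemblages —
this matters for taxonomic-collapse experiments, where genus-level lists
should retain most of the species-level richness.

What the generator does *not* emulate: abundance structure, geographic or
seasonal turnover, name noise/synonymy, and the empirical skew of body-mass
distributions (real lists oversample conspicuous vertebrates). Passing
tests on these communities demonstrate algorithmic correctness and the
qualitative structural regime (positive modularity ~0.2–0.4, 4–6 modules,
heavier impact of herbivore removal than random removal), not calibration
against any particular real wetland.

Two ensemble-level findings deserve an honest caveat. First, the degree
distributions of the generated webs are exponential-tailed: their log-log
survival functions are concave, not convex, in both niche modes — a
finite power-law exponent can always be fitted, but the generated
communities do not reproduce a strict scale-free shape. Second, the median
Louvain module count across a 30-site ensemble is typically 5 (4 under
some seeds), at the upper edge of the "around 4" regime reported for real
wetland inventories. Both are properties of the synthetic study
conditions, which we chose not to tune.

## Multilayer builds

Animals are unfolded into larval and adult nodes; larvae weigh one tenth
of the adult on the niche axis (the order-of-magnitude convention applied
to mass, since the axis is log-mass). Producers stay single nodes.
Habitat layers follow the record: single-habitat taxa keep both stages in
that layer; mixed-habitat taxa go through a config rule table (defaults:
Amphibia/Odonata-like → aquatic larva, adult in both layers crossing
repeatedly; Culicidae-like → aquatic larva, terrestrial adult crossing
once; Aves-like → adult in both layers; unmatched mixed taxa get the
amphibious default and a review flag). Amphibious adults are single nodes
with two-layer membership rather than per-layer duplicates. A 4×4
compartment operator over (stage × layer) vetoes trophic links between
incompatible compartments; the default admits within-compartment links
only, with cross-compartment feeding arising from multi-layer membership.
Communities above 200 species are rejected — the unfolded network grows
unmanageably.

## Problem sizes and tolerances

Test and acceptance runs use 30-site ensembles with richness 30–150, 6–10
replicates per site in rarefaction experiments, capped chain/loop
enumeration (2·10⁴ chains / 2·10³ loops inside rarefaction reports), and
200 replicates for connectance calibration — sizes at which every result
in this note reproduces in well under a minute per experiment. Monte Carlo
equalities are asserted within 3 standard errors; standardized differences
use the unperturbed ensemble's standard deviation, with a +inf sentinel
(and warning) when that spread is exactly zero.
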