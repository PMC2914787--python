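# Methods

## The model

`speciesim` is an individual-based model of sympatric speciation in a
bounded two-dimensional morphospace. Each organism is a point
(x, y) ∈ [0, 45]², the two axes standing for abstract phenotypic traits
(units are arbitrary "trait units"). The model iterates generations, each
consisting of:

1. **Assortative mating.** Every organism picks its Euclidean nearest other
   organism as mate. The relation need not be symmetric (A's nearest may be
   B while B's nearest is C); every organism still produces one brood with
   its chosen mate.
2. **Reproduction.** An organism at position p produces F(p) offspring,
   where F is the fitness landscape value at p rounded half-away-from-zero
   and clamped to {1, 2, 3, 4}. Parents vanish after reproducing — the
   generations do not overlap.
3. **Mutation-bounded placement.** Per trait axis, an offspring coordinate
   falls inside the parental coordinate interval extended by the maximum
   mutation size μ on each side. Two kernels:
   - *uniform*: c = (min(c₁,c₂) − μ) + r·(|c₁−c₂| + 2μ), r ~ U(0,1);
   - *normal*: c = ½(c₁+c₂) + ε·(|c₁−c₂| + 2μ), ε ~ N(0, b²) with
     b = 0.1581, redrawn until c lies inside the μ-extended interval.
   Under both kernels μ is a hard bound. Coordinates falling outside the
   morphospace are redrawn (up to 100 times, then clipped); organisms
   cannot exist beyond the boundaries.
4. **Random death.** A fraction ρ ~ U(0, 0.70), drawn once per generation,
   is removed: round(ρ·N) victims chosen uniformly without replacement.
5. **Overpopulation thinning.** In uniformly random order, an offspring is
   kept iff no already-kept offspring lies strictly closer than the
   overpopulation radius 0.25; all surviving pairs end up ≥ 0.25 apart.
6. **Landscape update** (below).

Runs start from 300 founders placed uniformly at random and end after a
configured number of generations or when fewer than two organisms remain
(extinction).

## The fitness landscape

The landscape originates from a 12×12 matrix of fitness levels drawn i.i.d.
uniform on [1, 4] and is expanded to the continuous morphospace by bilinear
interpolation, with the 12 nodes per axis at i·45/11 (i = 0..11) so the
interpolant spans the full square. `fitness_at` evaluates the continuous
interpolant directly; the discrete 45×45 matrix is a sampled view
(`Landscape.sample_field`), avoiding a double interpolation and grid-edge
off-by-one artifacts.

Dynamics:

- **shifting** — every λ = 2 generations the last column of the coarse
  matrix is discarded, the others shift one position, and a fresh random
  column enters at the front, translating the landscape gradually along +x.
- **feedback** — each generation, every coarse cell loses
  0.0071 × (organisms binned to that cell); the total subtracted amount is
  returned in equal shares to all 144 cells, conserving the grand sum to
  1e-9 relative. Organisms bin to cell (⌊y/3.75⌋, ⌊x/3.75⌋). Cell values may
  leave [1, 4]; they are deliberately *not* clamped (clamping would break
  conservation) — the realized brood size is clamped instead. Feedback is
  applied after the new generation is finalized, using the survivors'
  positions: depletion is caused by the organisms now living there.
- **static** — control mode; the field never changes.

## Species detection

A species is a reproductively isolated cluster: the closed set of organisms
connected through who-mated-with-whom. Operationally, clusters are the
connected components of the undirected graph with an edge from every
organism to its nearest (mate) and to its second-nearest other organism.
This equals the iterative closure ("collect everyone that the organism, its
mate and its second neighbour mated with; repeat for everyone found")
*once overlapping closed sets are merged*: the raw per-seed closure relation
is asymmetric, so closures from different seeds can be overlapping proper
subsets, and the requirement that every organism belong to exactly one
cluster forces the merge. The test suite keeps the literal set-based closure
(with merging) as an independent oracle and checks equivalence on random
instances up to n = 50.

Within-cluster diversity is the mean Euclidean distance over all unordered
member pairs, averaged *unweighted* over clusters with at least two members;
singletons are excluded, and a generation whose clusters are all singletons
has undefined (NaN) diversity. For clusters above 1024 members the mean
pairwise distance is estimated from an evenly strided 1024-member subsample
(sampling error well under 1% of typical diversity values); all smaller
clusters — and everything the oracle tests touch — are exact.

## Order parameters and experiment design

Per generation the run records population size, cluster count, diversity,
the largest realized brood and (when relevant) the labelled-lineage
fraction and the heritable-μ distribution. Run summaries average over
generations with population > 0 only, so runs ending in extinction still
contribute their surviving generations. The population–cluster correlation
is Pearson's r over those generations, reported as NaN (never coerced to 0)
when fewer than three points exist or either series is constant.

The five standard experiments cross landscape dynamics × mutation kernel
(four sweep experiments) and add a heritable-μ competition. Sweeps repeat
seeded runs per μ and aggregate with across-replicate means and sample
standard deviations (a single replicate reports sd = 0). Default μ grids:
0.05–1.0 for the uniform kernel and 0.05–1.5 for the normal kernel, whose
transitions sit at larger μ because zero-mean normal offsets are mostly
small. `find_optimal_mu` returns the argmax of mean cluster count, ties
broken toward smaller μ, flagging when the maximum is not interior.

**Lineage tracing.** One random founder is labelled; the label propagates
through *either* parent. The per-generation labelled fraction and its
maximum are recorded; fixation (ratio 1.0) and lineage loss (ratio 0) are
both absorbing.

**Competition.** Founder μ values are i.i.d. U(0, 1); each offspring takes
the μ of one parent chosen by a fair coin, and that inherited μ bounds the
offspring's own placement draw. Extinct μ values never reappear, so the set
of distinct values shrinks monotonically. *Dominance* is assessed at
μ-histogram-bin resolution (10 bins on [0, 1], configurable): the dominance
generation is the first at which the modal bin's carriers exceed half the
population. The bin view is used because the surviving carriers concentrate
on a narrow μ band long before neutral drift singles out one exact founder
float among thousands of organisms — demanding an exact-value majority
would make the dominance time a pure drift-fixation time (order of the
population size in generations), which is not what a histogram of the
population shows. The most-carried exact value (`dominant_mu`) and the
per-value fractions are reported alongside.

## Numerical and implementation choices

- **RNG discipline.** One `numpy` Generator per run; draws occur in a fixed
  order (landscape init → placement → per generation: μ inheritance →
  kernel draws and redraws → ρ → death victims → thinning order → landscape
  refresh), making trajectories bitwise reproducible from the seed.
  Replicates and sweep cells receive independent child streams via
  `SeedSequence.spawn`.
- **Nearest neighbours.** Populations up to 128 use a brute-force search
  with exact (distance, id) tie-breaking (lowest id wins); larger
  populations use a `scipy.spatial.cKDTree`, where exact distance ties are
  measure-zero (and excluded from generation 1 on by the 0.25 spacing).
- **Connected components** via `scipy.sparse.csgraph` on the mate +
  second-neighbour edge list; labels are canonicalized by first appearance
  in id order so the partition is invariant under relabeling.
- **Thinning** is implemented by elimination: processing organisms in the
  random order, a still-alive organism is kept and its conflicting
  neighbours (from a KD-tree pair query, strict inequality) are removed;
  this is provably identical to the keep-if-no-kept-neighbour greedy rule
  and is checked against a naive oracle replaying the same order.
- **Degenerate inputs.** μ = 0 with coincident parents reproduces the
  parental point exactly; populations of two have no second neighbour
  (mate edges only); a single organism is one singleton cluster; fewer than
  two organisms raise an extinction signal.

## Desk scale

The full-scale study design (1000 generations, 5 replicates per μ, μ step
0.05) is available via `--scale full`. The package's desk scale — used by
the test suite and the acceptance script — runs 300 generations with 3
replicates (sweeps), 20 replicates (lineage tracing at μ = 0.5) and 9–10
replicates (competition), keeping every experiment within minutes on one
CPU while leaving the qualitative structure (extinction-prone low μ, sharp
rise, population plateau, interior cluster maximum, interior diversity
minimum) clearly resolvable. By 300 generations populations at intermediate
μ have long reached their thinning-limited equilibrium, so the
per-generation averages are dominated by stationary behaviour just as in
longer runs.

## What the simulator does and does not show

All inputs are generated internally; there is no empirical data. The model
demonstrates that bounded mutation size, nearest-neighbour assortative
mating and local crowding are *sufficient* for stable reproductive
clustering, and that species counts are maximized at intermediate μ. It
abstracts away genetics (no genomes, no diploidy), geography (morphospace
is not physical space, so the speciation mode is sympatric by
construction), and ecology beyond a scalar fitness field; the overpopulation
radius and landscape statistics are fixed rather than evolved. Conclusions
about real taxa are outside its scope.

## Known limitations

- The mating graph is rebuilt from scratch each generation; there is no
  mate fidelity or refusal.
- Competition mode couples placement to the inherited μ; the alternative
  (placement bounded by the brood-producing parent's μ) was not explored.
- Above ~10⁴ organisms per generation the KD-tree passes still scale
  near-linearly, but the per-cluster diversity measurement becomes the
  dominant cost.
- `dominance_generation` depends on the chosen histogram resolution;
  per-value fractions are recorded so any other definition can be computed
  from the series.
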