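# Methods

## Scope

`seedbench` compares ten seed-selection ("seeding") strategies by how quickly a
susceptible–infected (SI) cascade started from their seed sets covers the
largest connected component (LCC) of a social network.  It generates its own
study networks — scale-free graphs with tunable clustering, classified into
density/clustering categories — and aggregates two summaries: an
outperformance ranking of strategies and a degeneracy (Jaccard overlap) matrix
between their seed sets.

## Network generation

Networks grow one node at a time.  Starting from `m` isolated founders (the
first growing node links to all of them), every new node contributes exactly
`m` distinct edges: the first by preferential attachment (target sampled with
probability proportional to degree, via a repeated-endpoints list), and each
of the remaining `m − 1` by triad formation with probability `p_triad` — an
edge to a uniformly chosen, not-yet-connected neighbour of the most recent
preferential-attachment target — otherwise by another preferential-attachment
step.  A triad step that finds no eligible neighbour falls back to
preferential attachment, so the final graph always has exactly `(n − m)·m`
edges, is connected, simple, and has a right-skewed degree distribution.
Triad formation closes triangles, so the mean local clustering coefficient
`<C>` increases with `p_triad` at fixed density.

Categories use three classes for both density and clustering — Low `[0, 0.1]`,
Medium `(0.1, 0.2]`, High `(0.2, 1]` — yielding six realisable acronyms
(LD-LC … HD-HC); MD-LC, HD-LC and HD-MC cannot be realised as connected graphs
in this family and are rejected.  Size classes are small/medium/large =
200/1000/2000 nodes.  Each (category, size) pair carries default density and
clustering targets (`netgen.DEFAULT_TARGETS`) equal to the achieved batch
means of the reference study's generated networks; `m` is the integer
minimising `|(n − m)·m − δ·n(n−1)/2|` for the density target, and `p_triad`
comes from calibration.

### Clustering calibration

`calibrate_triad_probability` estimates the achievable bracket
`[<C>(p=0), <C>(p=1)]` from `reps` realisations per endpoint (default 3) and
raises a `CalibrationError` naming the bracket when the target lies outside
it.  Inside, a stochastic bisection draws fresh realisations at each iterate
and stops when the realised mean is within `tolerance / 2` of the target
(default tolerance 0.02), leaving headroom so that independent realisations at
the returned `p_triad` stay within `tolerance`.  All randomness is derived
from one integer seed, so calibration is reproducible.

An important model property: the clustering ceiling `<C>(p=1)` falls as `m`
grows (a new node's `m` neighbours form, at best, a star around its anchor,
contributing ~2/m to its local clustering).  Measured ceilings at the denser
reference settings are therefore well below some published targets — e.g.
`n=1000, m=40` reaches at most ≈ 0.22 versus a 0.43 target — so the
high-clustering categories at medium/large sizes (and HD-HC small, where the
response is additionally non-monotone in `p_triad`) cannot be calibrated to
their default targets under this generator.  The calibration error is the
designed behaviour in that case; the corresponding acceptance check is left
failing rather than substituting a different growth model.

### Category batches

`generate_category_batch` derives per-network seeds as `seed + index` and
enforces the category-membership invariant by bounded re-draws: a realisation
whose clustering lands outside the class interval is regenerated with a
displaced seed (≤ 50 attempts).  This matters only when a target sits at a
class boundary (LD-LC's clustering target 0.10 is the Low/Medium edge); the
batch-recovery tests instead sample without rejection, mirroring the
calibrate-then-generate study procedure.

## Communities

Louvain modularity maximisation (resolution 1, seeded visit order) backs
`detect_communities`; it runs once per network and the partition is reused by
every strategy and run.  Community ids are relabelled deterministically
(larger communities first, ties by smallest member).  Newman–Girvan modularity
`Q = Σ_c [e_c/Ne − (d_c/2Ne)²]` is implemented directly and cross-checked in
the tests against a naive pairwise-sum oracle and an exhaustive
all-partitions maximisation on an 8-node two-clique fixture.

## Seeding strategies

All strategies receive the LCC and a fixed seed-set size `s`.  For generated
networks `s` defaults to the number of detected communities; for loaded
networks the convention is `s = round(p·N_LCC)` for proportions
p ∈ {0.01, 0.04, 0.07, 0.10}.  Score ties everywhere are broken by a seeded
uniform draw inside the tied block.

* **degree / betweenness / closeness / pagerank** — top-`s` nodes by the
  global score (PageRank damping 0.85, tolerance 1e−9).
* **kcore** — `s` nodes uniformly from the maximal k-core, topping up from the
  (k−1)-core and below when a shell is too small.  Note that in this growth
  family every node arrives with degree `m`, so the graph is `m`-degenerate
  and the maximal core usually spans nearly the whole graph: k-core seeding is
  then close to uniform sampling, and its overlap with the hub-seeking
  strategies is small.
* **voterank** — iterative: every node starts with voting ability 1; a node's
  score is the sum of its neighbours' abilities (so the first pick is a
  maximum-degree node); selecting a node zeroes its ability and lowers each
  neighbour's ability by `1/<k>` (floored at 0), with `<k>` the initial mean
  degree, held fixed throughout.
* **ambassadors / community_hubs** — communities sorted by size (descending,
  ties by id); cycle through them, picking per community the unselected member
  with the highest external (ambassadors) or internal (community_hubs) degree;
  exhausted communities are skipped, so every community is represented before
  any is revisited.
* **random_hubs** — repeatedly draw a uniform node and take its
  highest-degree neighbour, skipping duplicates, bounded by `50·s` draws
  (nodes that are nobody's top neighbour are unreachable by construction).
* **random** — uniform without replacement; the baseline.

## SI dynamics

Time advances in synchronous steps.  Each susceptible node samples exactly one
neighbour uniformly; if that neighbour is infected (state at the start of the
step), the node becomes infected with probability `g`, else nothing happens.
Infected nodes never recover; new infections become infectious the next step.
The per-step infection probability of a node with `i` infected out of `k`
neighbours is therefore `g·i/k`.  This dilution is deliberate — it is what
makes tightly co-located seed sets (e.g. k-core picks inside one dense region)
slow — and it means that even at `g = 1` the front advances stochastically:
the time to full coverage is bounded below by, and generally exceeds, the
largest BFS distance to the seed set, with equality only in special
geometries (a star seeded at the hub, the dyad).  Tests validate the dynamics
against exact Markov-chain absorption times (2ⁿ-state linear recursion) on
≤ 6-node graphs, the geometric waiting time on the dyad, per-run monotonicity
of the infected set, and the BFS lower bound.

Runs are capped at `max_steps = 10⁶`; truncated runs carry an explicit
unreached flag, raise on `spreading_efficiency`, and are excluded from ranking
comparisons (their count is visible in the records table).

## Ranking and degeneracy

Per (network, g, s, run) cell, each strategy's outperformance count is the
number of competitors with strictly larger spreading time; ties award nothing
to either side, so counts sum to C(10, 2) minus the tied pairs.  Counts are
summed over runs, networks and (by default) the whole probability grid, and
strategies are ranked 0–9 by total; tied totals share the better rank.

The degeneracy coefficient of two seed sets is their Jaccard overlap
`|A∩B| / |A∪B|`; the batch matrix averages it per strategy pair over networks
(evaluated at one seed-set size per strategy — the smallest requested, which
under the communities rule is the only one).  It is symmetric with an exactly
unit diagonal.

## Reproducibility

Every stochastic component takes an integer seed.  The benchmark derives
per-(network, strategy, size, g, run) seeds through `numpy.random.SeedSequence`
from the single experiment seed, so repeated runs write byte-identical CSVs,
while strategies and runs still receive independent streams.

## Problem sizes used by the test and acceptance runs

Structural-recovery and overlap checks use 30 networks per batch, as in the
reference design, at all three sizes; the full spreading benchmark trend
(decentralized strategies above the random baseline on small LD-LC networks)
is asserted on a scaled design of 5 networks × 5 runs over the default
probability grid {0.25, 0.5, 0.75, 1.0}, which keeps the whole suite in the
minutes range on one core.

## What the synthetic networks do and do not show

The generator reproduces skewed degree distributions, tunable clustering,
small diameters and — at low density — community structure, which is what the
strategy comparison needs.  It does not model homophily or attribute-driven
mixing, degree assortativity control, weighted or temporal ties, or networks
beyond ~10⁴ nodes; passing tests therefore support conclusions about
structure-dependent seeding efficiency in this family, not about any
particular empirical network.  Readers with their own data can load edge
lists / GraphML / GML through `seedbench.read_graph` (directed inputs are
symmetrized, self-loops dropped) and run the same pipeline.

## Known limitations

* The clustering ceiling excludes some high-clustering category/size
  combinations (see calibration above); their defaults raise rather than
  silently drift.
* Louvain is stochastic across seeds; community counts on a given network can
  differ by a few units between visit orders, which propagates into `s` under
  the communities rule.  The seed is recorded in every partition.
* `random_hubs` cannot return nodes that are nobody's highest-degree
  neighbour, so its bounded draw can fail for `s` close to `n` on
  heterogeneous graphs.
* The SI model is the interaction-limited cascade described above; SIR/SIS,
  thresholds and complex contagion are out of scope.
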