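# Methods

## The problem

When a virus family co-diverges with its hosts, the virus phylogeny mirrors
the host phylogeny; host jumping (cross-species transmission) breaks that
mirror. `cophy` quantifies where a virus–host pair sits between those
extremes using only tree *topology* — deliberately so, because viral
substitution saturation destroys temporal signal long before it corrupts
topology, making branch-length- or time-based co-phylogenetic comparisons
unreliable at the family scale.

## The normalized topological distance (nPH85)

Let `T_H` and `T_V` be the host and virus trees over the same tip set
(after host-tree expansion, below), viewed as unrooted topologies. Each
internal edge induces a nontrivial bipartition (split) of the tips. The
Penny–Hendy distance is

```
PH85 = |U_H| + |U_V|
```

where `U_H` is the set of host splits that are *incompatible* with at
least one virus split, and symmetrically for `U_V`. Two splits `A|A'` and
`B|B'` are incompatible when all four intersections `A∩B, A∩B', A'∩B,
A'∩B'` are non-empty — they cannot coexist in any one tree.

Using incompatibility rather than plain set membership is what makes
polytomies first-class: a polytomous clade is at distance zero from any of
its resolutions (an unresolved node asserts nothing that a resolution
contradicts). On binary trees the two readings coincide — a binary tree's
split set is maximal-compatible, so any split absent from it must conflict
with it — and PH85 reduces to the classic Robinson–Foulds symmetric
difference. The test suite verifies this equivalence against both a
brute-force split enumeration and dendropy's independent implementation.

Raw PH85 grows with tree size, so it is normalized by an empirical
maximum: the tips of the virus tree are randomly permuted `n_rand` times
(default 1000) with PH85 recomputed each time, and

```
nPH85 = PH85 / max(PH85_observed, PH85_perm_1, ..., PH85_perm_n)
```

Including the observed value in the maximum caps nPH85 at exactly 1.
nPH85 = 0 means identical topologies (co-divergence); nPH85 = 1 means no
clades in common (pervasive host switching). Because the denominator
depends only on the two tree *shapes*, the statistic is invariant to
where in the tree an incongruence sits, and — with the denominator fixed —
strictly increasing in the number of conflicting clades. Both properties
are covered by tests. A running-maximum trace is available to check that
the permutation count has converged (for the tree sizes used here the
maximum is typically reached within the first few hundred replicates).

Defaults: 1000 randomizations, permuting the second (virus) tree. The
choice of which tree to permute and whether to include the observed value
are exposed in `AnalysisConfig`.

### Pipeline around the metric

1. **Host-tree expansion.** Real data sets have more viruses than hosts
   (several viruses can infect one host species). Each host tip carrying
   `m > 1` viruses becomes a polytomy of `m` virus-labeled tips; `m = 1`
   tips are relabeled; unmapped host tips are pruned so the two tip sets
   match exactly. Under the conflict convention these polytomies are
   metric-neutral (tested).
2. **Support collapse.** Virus-tree nodes with support (e.g. aLRT)
   strictly below 0.8 are contracted into polytomies, removing
   topologically uncertain signal. Nodes without a support value are never
   collapsed — host cladograms assembled from the literature carry no
   supports and must pass through unchanged. The 0.8 default corresponds
   to an aLRT false-positive rate below ~0.1.
3. **Uncertainty summary.** The *overall* nPH85 is computed directly on
   the possibly polytomous pair. All polytomies in both trees are then
   randomly resolved 100 times (seeded) and nPH85 recomputed per
   replicate; the report gives the overall value, the replicate mean, and
   the equal-tail 95% percentile range (2.5–97.5). When neither tree has
   a polytomy the replicates are skipped (they would all be the identical
   binary pair) and all summary fields equal the overall value.

Random resolution merges uniformly chosen pairs of child lineages until a
node is binary. Every refinement is reachable with positive probability;
exact uniformity over refinements is not claimed (nothing downstream
requires it — the summary only needs a seeded, well-spread sample).

## Relative node depth

To ask *where* incongruence falls, each host clade (non-root internal
node, rooted sense) is tested against the virus tree with the rooted
incompatibility test: two clades conflict when they overlap but neither
contains the other. For a conflicting clade the raw node depth is the
number of internal nodes in its subtree (including its own node): a cherry
scores 1, deeper clades more. Dividing by the maximum raw depth over all
candidate clades gives the relative node depth in `(0, 1]`: values near 0
mean host switching near the tips (recent events), 1 means the deepest
divergence in the tree is disrupted. Tips and the root are excluded from
both the candidates and the normalizing maximum, so the deepest
nontrivial clade normalizes to exactly 1 and cherries approach 0 as trees
grow. An alternative convention counting tips as well is available via
`count_tips=True`.

## Event-cost reconciliation

The distance is agnostic about *why* trees disagree. To attribute
incongruence to events, `cophy` computes an exact minimum-cost
reconciliation under the untimed duplication–transfer–loss (DTL) model:
every virus node maps to a host node; internal virus nodes are explained
by co-divergence (cost 0), duplication (1), or host jump (1, the transfer
of one child lineage to a non-ancestral, non-descendant host lineage);
extinctions (1) are implied losses where a lineage survives on only one
side of a host speciation. The default 0/1/1/1 scheme is conservative
toward co-divergence. The optimum is found by dynamic programming over
(virus node × host node) with the standard enter-and-descend ("in") and
incomparable-landing ("out") auxiliary tables; complexity is
`O(|V| · |H|²)`.

No time-consistency constraint is imposed on transfers. A timed search
(as in genetic-algorithm reconcilers) can differ on instances where every
untimed optimum is time-inconsistent; the untimed model was chosen
because it is exactly specified, polynomial, and verifiable against
exhaustive enumeration — which the tests do on all small instances.

`enumerate_optima` backtracks through *all* optimal DP choices and
returns the distinct event-count vectors among minimum-cost solutions
(with a configurable cap and a truncation flag), giving per-event
min–max ranges; ties are reported, never broken silently.
`event_proportions` divides counts by the total number of events
(co-divergence + duplication + host jump + extinction), displayed at two
decimals.

Reconciliation requires binary trees; polytomies are resolved (seeded)
first, mirroring the resolution protocol of the distance pipeline.

## The tanglegram simulator

The simulator provides ground truth the real data cannot: tanglegrams
with a *known* number of host switches.

- **Host trees** grow under a Yule process (uniform random tip
  splitting). Since every statistic here is topology-only, branching
  times are irrelevant and are not simulated.
- **Virus trees** start as tip-relabeled copies of the expanded host tree
  (pure co-divergence; per-host polytomies are randomly resolved), then
  receive `n_switches` SPR moves: prune a uniformly chosen clade, regraft
  on a uniformly chosen edge outside it. SPR is the tree-rearrangement
  analog of a single transfer event. Edges that would reproduce the same
  unrooted topology (the edge the subtree came from, which has two rooted
  representations around a binary root) are excluded, so every switch
  changes the unrooted topology — on trees this size, that guarantees at
  least one conflicting clade per switch.
- Because later switches can partially cancel earlier ones, each
  simulated pair logs the *realized* incongruent-clade count next to the
  requested switch count; across the validation grid the two correlate at
  Spearman ρ > 0.9.
- **Support values** can be assigned to internal nodes, with a chosen
  fraction drawn from `[0, 0.8)` (collapsed at the default threshold) and
  the rest from `[0.8, 1]`, to exercise the collapse/resolve pipeline.

Default conditions mirror the validation regime: 100-tip host trees, one
virus per host, fully supported nodes, switch count swept from 0 to 20.
The acceptance suite runs this grid at full scale (20 replicates per
point, 1000 randomizations per distance) and checks that the mean nPH85
rises monotonically from exactly 0.

What the simulator does *not* emulate: sequence-level error and
phylogenetic reconstruction noise, duplication/extinction events,
preferential host switching toward related hosts, and non-uniform
sampling. Passing simulation tests therefore validates the metric and its
implementation, not the biological inference on any particular empirical
data set — in particular, preferential switching between close relatives
would mimic co-divergence for any topology-based method.

## Tanglegram untangling and comparative statistics

Crossing counting reduces to inversion counting of the induced
permutation (merge-sort, `O(n log n)`; an `O(n²)` pair scan is the test
oracle). Lines sharing a host tip are parallel, never crossing.
`untangle` is a deterministic barycenter hill-climb: children of each
internal node are reordered by the mean position of their partners on the
opposite side, keeping a reordering only when it strictly reduces
crossings, alternating sides until stable. It is a heuristic with the
contract "never worse than the input ordering"; on small instances the
tests compare it against the exhaustive minimum over all rotation
combinations and require near-optimality, not optimality.

`family_comparison` computes the Pearson correlation (two-sided) between
per-family nPH85 and the number of viruses sampled, and a Welch
(unequal-variance) two-sample t-test of DNA- versus RNA-genome families.
Welch was chosen over the pooled-variance t-test because family group
sizes and spreads are unequal by construction; with identical groups the
statistic degenerates to 0, and degenerate inputs (too few families, zero
variance, an empty group) drop the statistic with an explanatory note
rather than failing.

## Numerical and engineering notes

- Splits are held as boolean tip-membership matrices; the permutation
  null evaluates all replicates by batched float32 matrix products
  (pairwise intersection sizes) plus threshold tests, ~0.15 s for a
  100-tip pair at 1000 permutations on one core.
- `nPH85` is defined as 0 whenever the numerator or the denominator is 0
  (e.g. two star trees): zero conflicting clades is the co-divergent
  extreme.
- All randomness (resolutions, permutations, simulations) flows through
  explicit integer seeds; identical seeds give identical results across
  runs and platforms.
- Newick parsing is delegated to dendropy; internal-node labels parsing
  as floats in `[0, 1]` become supports, anything else stays a label.
  Branch lengths are read and ignored by every metric.
- Known limitations: the untangler is a local optimizer; the DTL model is
  untimed (see above); `enumerate_optima` is exponential in the worst
  case and intended for trees below ~25 tips; the depth statistic has no
  null distribution — it describes where incongruence sits, not whether
  it is significant.
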