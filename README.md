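# cophy

Quantitative co-phylogenetics for virus–host tree pairs: how much of a
virus family's history is co-divergence with its hosts, and how much is
cross-species transmission (host jumping)?

If related viruses co-diverged with their hosts, the virus and host
phylogenies share a topology; host jumps make them incongruent. `cophy`
turns that intuition into numbers:

- **nPH85** — a normalized Penny–Hendy topological distance between the
  (unrooted) virus and host trees. PH85 is twice the number of "unique"
  clades: splits of one tree that are incompatible with the other
  (all four side-intersections non-empty), which makes a polytomy and any
  of its resolutions distance zero, and reduces to the classic
  Robinson–Foulds symmetric difference on binary trees. It is normalized
  by the maximum PH85 over 1000 random tip permutations, giving
  `nPH85 ∈ [0, 1]`: 0 = identical topologies (co-divergence), 1 = no
  clades in common (pervasive host switching). Comparable across families
  with different numbers of taxa, and insensitive to *where* in the tree
  the incongruence sits.
- **Relative node depth** — for each host clade that conflicts with the
  virus tree, the number of internal nodes in its subtree divided by the
  tree-wide maximum: near 0 for host jumps at the tips (recent), 1 for
  disruption of the deepest divergence (ancient).
- **Event-cost reconciliation** — an exact untimed
  duplication–transfer–loss dynamic program mapping the virus tree onto
  the host tree with co-divergence / duplication / host-jump / extinction
  events (default costs 0/1/1/1), including enumeration of all co-optimal
  event-count vectors and event proportions.
- **A tanglegram simulator** — Yule host trees, co-diverging virus copies
  perturbed by a known number of SPR "host switches", optional aLRT-like
  support values — used to validate the whole pipeline end to end.
- **Tanglegram untangling** (crossing-minimizing branch rotations) and
  **family-level statistics** (nPH85 vs. sampling effort; DNA vs. RNA
  genome comparison).

Intended users: molecular evolution / virus evolution researchers with a
virus gene tree (Newick, supports as internal-node labels), a host
cladogram (polytomies fine), and a two-column `virus<TAB>host` table.

## Worked example

Simulate a 12-host tanglegram with 3 host switches, then analyze it:

```sh
cophy simulate --n-hosts 12 --switches 3 --seed 42 --out demo
cophy dist --host demo.host.nwk --virus demo.virus.nwk --map demo.assoc.tsv \
    --n-rand 1000 --seed 1 --json
```

```json
{
  "ph85": 10,
  "denominator": 18,
  "overall": 0.5555555555555556,
  "mean": 0.5555555555555556,
  "p2.5": 0.5555555555555556,
  "p97.5": 0.5555555555555556
}
```

Ten splits conflict between the pair; the largest distance attainable for
these tree shapes (over 1000 tip permutations) is 18, so nPH85 ≈ 0.56 —
midway between full co-divergence (0) and no shared history (1). The
mean and percentiles equal the overall value because this pair has no
polytomies to resolve (with collapsed low-support nodes they would summarize
100 random resolutions).

```sh
cophy reconcile --host demo.host.nwk --virus demo.virus.nwk --map demo.assoc.tsv
```

```json
{
  "cost": 3.0,
  "counts": {"codivergence": 8, "duplication": 0, "host_jump": 3, "extinction": 0},
  "proportions": {"codivergence": 0.73, "duplication": 0.0, "host_jump": 0.27, "extinction": 0.0}
}
```

The reconciliation recovers exactly the 3 simulated switches as host-jump
events, with the remaining 8 internal nodes explained by co-divergence.

```sh
cophy depth --host demo.host.nwk --virus demo.virus.nwk --map demo.assoc.tsv
```

```text
clade	raw_depth	relative_depth
h3.v1,h4.v1	1	0.1667
h5.v1,h6.v1	1	0.1667
...
h3.v1,h4.v1,h5.v1,h6.v1,h7.v1,h8.v1,h9.v1	6	1.0000
```

Incongruence here spans shallow cherries (0.17) up to the deepest
nontrivial clade (1.0). Other subcommands: `cophy tangle` (untangled
tanglegram, optional SVG), `cophy compare` (per-family statistics table),
`cophy run` (YAML-driven multi-family pipeline).

See `docs/methods.md` for the model details, conventions, and
limitations.

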