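"""Event-cost co-phylogenetic reconciliation.

Maps every virus-tree node onto the host tree and explains the history
with four event types: co-divergence (virus and host speciate together),
duplication (virus lineage splits within one host lineage), host jump
(one child lineage transfers to a non-ancestral host lineage) and
extinction (a virus lineage is lost on one side of a host speciation).
Each event carries a non-negative cost — by default 0/1/1/1 for
co-divergence/duplication/host-jump/extinction, a scheme conservative
toward co-divergence — and the optimum is the minimum total cost.

The model is the standard *untimed* duplication–transfer–loss (DTL)
reconciliation, solved exactly by dynamic programming over
(virus node x host node).  No time-consistency constraint is imposed on
transfers, which keeps the optimum polynomial and exactly checkable by
exhaustive enumeration on small instances.  Ties among optimal event
histories can be enumerated (:func:`enumerate_optima`) to report the range
of event proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .trees import Association, Tree, TreeError

__all__ = [
    "EventCosts",
    "Event",
    "Reconciliation",
    "OptimaSet",
    "reconcile",
    "enumerate_optima",
    "event_proportions",
]

_INF = math.inf


@dataclass(frozen=True)
class EventCosts:
    codivergence: float = 0.0
    duplication: float = 1.0
    host_jump: float = 1.0
    extinction: float = 1.0

    def __post_init__(self):
        if min(self.codivergence, self.duplication, self.host_jump, self.extinction) < 0:
            raise ValueError("event costs must be non-negative")


@dataclass(frozen=True)
class Event:
    kind: str  # codivergence | duplication | host_jump | extinction | leaf
    virus: tuple[str, ...]
    host: tuple[str, ...]


@dataclass(frozen=True)
class Reconciliation:
    cost: float
    codivergence: int
    duplication: int
    host_jump: int
    extinction: int
    events: tuple[Event, ...] = ()

    @property
    def counts(self) -> dict[str, int]:
        return {
            "codivergence": self.codivergence,
            "duplication": self.duplication,
            "host_jump": self.host_jump,
            "extinction": self.extinction,
        }

    @property
    def total_events(self) -> int:
        return sum(self.counts.values())


def event_proportions(rec: Reconciliation) -> dict[str, float]:
    """Each event count divided by the total number of events (sums to 1)."""
    total = rec.total_events
    if total == 0:
        raise ValueError("reconciliation has zero events; proportions undefined")
    return {kind: count / total for kind, count in rec.counts.items()}


# ---------------------------------------------------------------------------
# indexing helpers
# ---------------------------------------------------------------------------


class _Index:
    """Postorder-indexed view of a rooted binary tree."""

    def __init__(self, tree: Tree):
        self.nodes = list(tree.postorder())
        self.pos = {id(nd): i for i, nd in enumerate(self.nodes)}
        self.children = [
            [self.pos[id(c)] for c in nd.children] for nd in self.nodes
        ]
        self.is_leaf = [nd.is_leaf for nd in self.nodes]
        self.label = [nd.label for nd in self.nodes]
        self.tips = [tuple(sorted(nd.tip_set())) for nd in self.nodes]
        self.root = len(self.nodes) - 1
        n = len(self.nodes)
        # desc[i] = set of indices in the subtree of i (including i)
        self.desc: list[set[int]] = [set() for _ in range(n)]
        for i, nd in enumerate(self.nodes):
            self.desc[i].add(i)
            for c in self.children[i]:
                self.desc[i] |= self.desc[c]
        self.comparable = [
            [j in self.desc[i] or i in self.desc[j] for j in range(n)]
            for i in range(n)
        ]


def _prepare(host: Tree, virus: Tree, assoc: Association):
    for name, tree in (("host", host), ("virus", virus)):
        if not tree.is_binary():
            raise TreeError(
                f"{name} tree is not binary; resolve polytomies before reconciling"
            )
    unmapped = virus.leaf_set() - assoc.virus_tips
    if unmapped:
        raise TreeError(f"virus tips without a host mapping: {sorted(unmapped)}")
    absent = {assoc[v] for v in virus.leaf_set()} - host.leaf_set()
    if absent:
        raise TreeError(f"viruses mapped to absent hosts: {sorted(absent)}")
    return _Index(host), _Index(virus)


# ---------------------------------------------------------------------------
# the dynamic program
# ---------------------------------------------------------------------------


class _DP:
    """c[p][h]: optimal cost of embedding virus subtree p with p mapped at h.

    in_[p][h] additionally allows the lineage to enter at h and survive in
    only one child at each host speciation it passes (one extinction per
    skipped speciation).  out_[p][h] is the best placement on any host node
    incomparable with h (the landing site of a host jump).
    """

    def __init__(self, H: _Index, V: _Index, assoc: Association, costs: EventCosts):
        self.H, self.V, self.costs = H, V, costs
        nh, nv = len(H.nodes), len(V.nodes)
        self.c = [[_INF] * nh for _ in range(nv)]
        self.in_ = [[_INF] * nh for _ in range(nv)]
        self.opts: list[list[list[tuple]]] = [[[] for _ in range(nh)] for _ in range(nv)]
        self.host_of = {}
        for i in range(nh):
            if H.is_leaf[i]:
                self.host_of[H.label[i]] = i

        L = costs.extinction
        for p in range(nv):
            if V.is_leaf[p]:
                target = self.host_of[assoc[V.label[p]]]
                self.c[p][target] = 0.0
            else:
                p1, p2 = V.children[p]
                for h in range(nh):
                    self._options(p, h, p1, p2)
            # in_ over host postorder (children precede parents)
            for h in range(nh):
                best = self.c[p][h]
                for f in H.children[h]:
                    best = min(best, self.in_[p][f] + L)
                self.in_[p][h] = best

    def out(self, p: int, h: int) -> float:
        comp = self.H.comparable[h]
        row = self.c[p]
        return min(
            (row[j] for j in range(len(comp)) if not comp[j]), default=_INF
        )

    def out_args(self, p: int, h: int):
        val = self.out(p, h)
        comp = self.H.comparable[h]
        return val, [
            j for j in range(len(comp)) if not comp[j] and self.c[p][j] == val
        ]

    def _options(self, p: int, h: int, p1: int, p2: int):
        cs = self.costs
        opts = []
        if not self.H.is_leaf[h]:
            f, g = self.H.children[h]
            for x, y in ((p1, p2), (p2, p1)):
                v = cs.codivergence + self.in_[x][f] + self.in_[y][g]
                opts.append((v, ("codivergence", x, f, y, g)))
        opts.append(
            (cs.duplication + self.in_[p1][h] + self.in_[p2][h], ("duplication", p1, p2))
        )
        for x, y in ((p1, p2), (p2, p1)):
            v = cs.host_jump + self.in_[x][h] + self.out(y, h)
            opts.append((v, ("host_jump", x, y)))
        best = min(v for v, _ in opts)
        self.c[p][h] = best
        if best < _INF:
            self.opts[p][h] = [o for v, o in opts if v == best]

    # -- backtracking one optimum ---------------------------------------
    def trace(self) -> list[tuple[str, int, int]]:
        """(event kind, virus node, host node) records of one optimum."""
        root = self.V.root
        best = min(self.c[root])
        if best == _INF:
            raise TreeError("no valid reconciliation exists")
        h0 = self.c[root].index(best)
        events: list[tuple[str, int, int]] = []
        self._trace_at(root, h0, events)
        return events

    def _descend(self, p: int, h: int, events) -> int:
        """Follow the in_ chain from h to the node where p actually maps."""
        L = self.costs.extinction
        while self.in_[p][h] < self.c[p][h]:
            stepped = False
            for f in self.H.children[h]:
                if self.in_[p][f] + L == self.in_[p][h]:
                    events.append(("extinction", p, h))
                    h = f
                    stepped = True
                    break
            if not stepped:  # pragma: no cover - DP consistency guard
                raise AssertionError("broken in-chain during backtracking")
        return h

    def _trace_at(self, p: int, h: int, events):
        if self.V.is_leaf[p]:
            events.append(("leaf", p, h))
            return
        kind, *rest = self.opts[p][h][0]
        if kind == "codivergence":
            x, f, y, g = rest
            events.append(("codivergence", p, h))
            self._trace_at(x, self._descend(x, f, events), events)
            self._trace_at(y, self._descend(y, g, events), events)
        elif kind == "duplication":
            p1, p2 = rest
            events.append(("duplication", p, h))
            self._trace_at(p1, self._descend(p1, h, events), events)
            self._trace_at(p2, self._descend(p2, h, events), events)
        else:
            x, y = rest
            events.append(("host_jump", p, h))
            self._trace_at(x, self._descend(x, h, events), events)
            _, args = self.out_args(y, h)
            self._trace_at(y, args[0], events)


def reconcile(
    host: Tree,
    virus: Tree,
    assoc: Association,
    costs: EventCosts | None = None,
) -> Reconciliation:
    """Globally optimal DTL reconciliation of a binary virus/host pair.

    Returns one optimum (ties broken deterministically) with its per-event
    counts, total cost, and per-node event placements.  Every internal
    virus node receives exactly one of co-divergence, duplication or host
    jump; extinctions are implied losses along host lineages.
    """
    if costs is None:
        costs = EventCosts()
    H, V = _prepare(host, virus, assoc)
    dp = _DP(H, V, assoc, costs)
    raw = dp.trace()

    tally = {"codivergence": 0, "duplication": 0, "host_jump": 0, "extinction": 0}
    events = []
    for kind, p, h in raw:
        if kind in tally:
            tally[kind] += 1
        events.append(Event(kind, V.tips[p], H.tips[h]))
    cost = (
        tally["codivergence"] * costs.codivergence
        + tally["duplication"] * costs.duplication
        + tally["host_jump"] * costs.host_jump
        + tally["extinction"] * costs.extinction
    )
    return Reconciliation(
        cost=cost,
        codivergence=tally["codivergence"],
        duplication=tally["duplication"],
        host_jump=tally["host_jump"],
        extinction=tally["extinction"],
        events=tuple(events),
    )


# ---------------------------------------------------------------------------
# enumeration of co-optimal event-count vectors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OptimaSet:
    """Distinct event-count vectors among minimum-cost reconciliations."""

    reconciliations: tuple[Reconciliation, ...]
    truncated: bool = False

    def __iter__(self):
        return iter(self.reconciliations)

    def __len__(self):
        return len(self.reconciliations)

    def event_ranges(self) -> dict[str, tuple[int, int]]:
        """min/max count per event type across the optima (for boxplots)."""
        out = {}
        for kind in ("codivergence", "duplication", "host_jump", "extinction"):
            vals = [r.counts[kind] for r in self.reconciliations]
            out[kind] = (min(vals), max(vals))
        return out


class _Capped:
    """Set of count vectors with a global size cap."""

    def __init__(self, limit: int):
        self.limit = limit
        self.truncated = False

    def cap(self, vectors: set[tuple]) -> frozenset:
        if len(vectors) > self.limit:
            self.truncated = True
            vectors = set(sorted(vectors)[: self.limit])
        return frozenset(vectors)


def _vec_add(u, v):
    return (u[0] + v[0], u[1] + v[1], u[2] + v[2], u[3] + v[3])


def enumerate_optima(
    host: Tree,
    virus: Tree,
    assoc: Association,
    costs: EventCosts | None = None,
    limit: int = 10000,
) -> OptimaSet:
    """All distinct event-count vectors among minimum-cost reconciliations.

    Backtracks through every optimal choice of the dynamic program,
    combining child solution sets; intended for modest tree sizes (tens of
    tips).  If more than ``limit`` distinct vectors arise at any point the
    result is truncated and flagged.
    """
    if costs is None:
        costs = EventCosts()
    H, V = _prepare(host, virus, assoc)
    dp = _DP(H, V, assoc, costs)
    capper = _Capped(limit)
    L = costs.extinction
    nh = len(H.nodes)
    ZERO = frozenset({(0, 0, 0, 0)})
    EMPTY = frozenset()

    csets: list[list[frozenset]] = [[EMPTY] * nh for _ in V.nodes]
    insets: list[list[frozenset]] = [[EMPTY] * nh for _ in V.nodes]

    for p in range(len(V.nodes)):
        if V.is_leaf[p]:
            for h in range(nh):
                csets[p][h] = ZERO if dp.c[p][h] == 0 else EMPTY
        else:
            for h in range(nh):
                if dp.c[p][h] == _INF:
                    continue
                acc: set[tuple] = set()
                for opt in dp.opts[p][h]:
                    kind = opt[0]
                    if kind == "codivergence":
                        _, x, f, y, g = opt
                        inc, a, b = (1, 0, 0, 0), insets[x][f], insets[y][g]
                    elif kind == "duplication":
                        _, p1, p2 = opt
                        inc, a, b = (0, 1, 0, 0), insets[p1][h], insets[p2][h]
                    else:
                        _, x, y = opt
                        _, args = dp.out_args(y, h)
                        landed = set()
                        for j in args:
                            landed |= csets[y][j]
                        inc, a, b = (0, 0, 1, 0), insets[x][h], frozenset(landed)
                    for u in a:
                        for v in b:
                            acc.add(_vec_add(inc, _vec_add(u, v)))
                csets[p][h] = capper.cap(acc)
        # in-sets over host postorder
        for h in range(nh):
            if dp.in_[p][h] == _INF:
                continue
            acc = set()
            if dp.c[p][h] == dp.in_[p][h]:
                acc |= csets[p][h]
            for f in H.children[h]:
                if dp.in_[p][f] + L == dp.in_[p][h]:
                    acc |= {_vec_add(u, (0, 0, 0, 1)) for u in insets[p][f]}
            insets[p][h] = capper.cap(acc)

    root = V.root
    best = min(dp.c[root])
    if best == _INF:
        raise TreeError("no valid reconciliation exists")
    final: set[tuple] = set()
    for h in range(nh):
        if dp.c[root][h] == best:
            final |= csets[root][h]
    final = capper.cap(final)

    recs = tuple(
        Reconciliation(
            cost=cd * costs.codivergence
            + du * costs.duplication
            + hj * costs.host_jump
            + ex * costs.extinction,
            codivergence=cd,
            duplication=du,
            host_jump=hj,
            extinction=ex,
        )
        for cd, du, hj, ex in sorted(final)
    )
    return OptimaSet(recs, truncated=capper.truncated)
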