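"""The nPH85 topological distance between a host and a virus tree.

The raw statistic is the Penny–Hendy (PH85) bipartition distance: twice the
number of "unique" clades, i.e. clades found in one tree that cannot coexist
with the other tree's clades.  Uniqueness is realized as *split conflict*
(the classic four-intersection incompatibility test) rather than plain
set-membership, so that a polytomy and any of its resolutions are at
distance zero; on binary trees the two readings coincide with the classic
symmetric-difference distance.

PH85 grows with tree size, so it is normalized by the largest distance
observed when the tips of one tree are randomly permuted (1000 permutations
by default): ``nPH85 = PH85 / max PH85``, ranging from 0 (identical
topologies, co-divergence) to 1 (no clades in common, rampant host
switching).  Branch lengths play no role; the trees are compared as
unrooted topologies.

Split sets are held as boolean tip-membership matrices, so the permutation
null reduces to batched matrix products over relabeled split rows.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace

import numpy as np

from .trees import (
    AnalysisConfig,
    Association,
    Tree,
    TreeError,
    collapse_low_support,
    expand_host_tree,
    resolve_polytomies,
)

__all__ = [
    "Split",
    "DistanceResult",
    "nontrivial_splits",
    "splits_conflict",
    "ph85",
    "unique_splits",
    "randomized_max_ph85",
    "nph85",
    "nph85_summary",
]


@dataclass(frozen=True)
class Split:
    """A nontrivial bipartition of a tip-label set (unrooted clade).

    ``side`` is the canonical representative: the smaller side, ties broken
    by lexicographic order of the sorted labels.
    """

    side: frozenset[str]
    other: frozenset[str]

    @classmethod
    def canonical(cls, side, universe) -> "Split":
        side = frozenset(side)
        other = frozenset(universe) - side
        if len(side) < 2 or len(other) < 2:
            raise TreeError("a nontrivial split needs >= 2 tips on each side")
        if (len(side), sorted(side)) > (len(other), sorted(other)):
            side, other = other, side
        return cls(side, other)

    @property
    def universe(self) -> frozenset[str]:
        return self.side | self.other

    def __repr__(self) -> str:
        return "|".join(",".join(sorted(s)) for s in (self.side, self.other))


def splits_conflict(s1: Split, s2: Split) -> bool:
    """True iff the two bipartitions cannot coexist in one tree.

    Classic incompatibility: all four pairwise side intersections are
    non-empty.  A split never conflicts with itself.
    """
    if s1.universe != s2.universe:
        raise TreeError("splits are over different tip sets")
    return bool(
        s1.side & s2.side
        and s1.side & s2.other
        and s1.other & s2.side
        and s1.other & s2.other
    )


def nontrivial_splits(tree: Tree) -> set[Split]:
    """All nontrivial splits of the unrooted view of ``tree``.

    One split per internal edge; the root is treated as an unlabeled vertex,
    so rootedness does not affect the result.
    """
    universe = tree.leaf_set()
    n = len(universe)
    out: set[Split] = set()
    if n < 4:
        return out
    for nd in tree.postorder():
        if nd is tree.root or nd.is_leaf:
            continue
        clade = nd.tip_set()
        if 2 <= len(clade) <= n - 2:
            out.add(Split.canonical(clade, universe))
    return out


# ---------------------------------------------------------------------------
# vectorized split-matrix internals
# ---------------------------------------------------------------------------


class _SplitMatrix:
    """Split sets of a tree as rows of a boolean tip-membership matrix."""

    __slots__ = ("bools", "floats", "sizes", "n")

    def __init__(self, bools: np.ndarray, n: int):
        self.n = n
        if bools.size:
            # canonical orientation: tip 0 always on the "out" side
            flip = bools[:, 0]
            bools = np.where(flip[:, None], ~bools, bools)
            bools = np.unique(bools, axis=0)
        self.bools = bools
        self.floats = bools.astype(np.float32)
        self.sizes = (
            bools.sum(axis=1).astype(np.float32)
            if bools.size
            else np.zeros(0, dtype=np.float32)
        )

    @classmethod
    def from_tree(cls, tree: Tree, index: dict[str, int]) -> "_SplitMatrix":
        n = len(index)
        rows = []
        masks: dict[int, np.ndarray] = {}
        for nd in tree.postorder():
            if nd.is_leaf:
                m = np.zeros(n, dtype=bool)
                m[index[nd.label]] = True
            else:
                m = np.zeros(n, dtype=bool)
                for c in nd.children:
                    m |= masks.pop(id(c))
                if nd is not tree.root and 2 <= int(m.sum()) <= n - 2:
                    rows.append(m.copy())
            masks[id(nd)] = m
        bools = np.array(rows, dtype=bool) if rows else np.zeros((0, n), dtype=bool)
        return cls(bools, n)

    def permuted(self, perms: np.ndarray) -> np.ndarray:
        """Split rows after relabeling tips by each permutation.

        ``perms`` has shape (R, n); returns float32 of shape (R, k, n).
        """
        if not self.bools.size:
            return np.zeros((perms.shape[0], 0, self.n), dtype=np.float32)
        stacked = self.bools[:, perms]          # (k, R, n)
        return np.swapaxes(stacked, 0, 1).astype(np.float32)


def _conflict_counts(A: "_SplitMatrix", Bp: np.ndarray) -> np.ndarray:
    """PH85 between A and each replicate of split rows ``Bp``.

    ``Bp`` has shape (R, k2, n) float32; returns an integer vector of
    length R.  Two splits conflict iff all four side intersections are
    non-empty, which reduces to threshold tests on the pairwise
    intersection sizes |side1 & side2| obtained from one matrix product.
    """
    R = Bp.shape[0]
    if A.floats.shape[0] == 0 or Bp.shape[1] == 0:
        return np.zeros(R, dtype=int)
    inter = Bp @ A.floats.T                          # (R, k2, k1)
    a = A.sizes[None, None, :]
    b = Bp.sum(axis=2)[:, :, None]
    conflict = (inter > 0) & (inter < a) & (inter < b) & (a + b - inter < A.n)
    u1 = conflict.any(axis=1).sum(axis=1)
    u2 = conflict.any(axis=2).sum(axis=1)
    return (u1 + u2).astype(int)


def _check_tip_sets(t1: Tree, t2: Tree) -> list[str]:
    s1, s2 = t1.leaf_set(), t2.leaf_set()
    if s1 != s2:
        raise TreeError(
            "tip sets differ: only in first="
            f"{sorted(s1 - s2)}, only in second={sorted(s2 - s1)}"
        )
    return sorted(s1)


# ---------------------------------------------------------------------------
# public metric
# ---------------------------------------------------------------------------


def unique_splits(t1: Tree, t2: Tree) -> set[Split]:
    """Splits of ``t1`` that conflict with at least one split of ``t2``."""
    _check_tip_sets(t1, t2)
    s2 = nontrivial_splits(t2)
    return {s for s in nontrivial_splits(t1) if any(splits_conflict(s, t) for t in s2)}


def ph85(t1: Tree, t2: Tree) -> int:
    """Penny–Hendy topological distance: twice the number of unique clades.

    A clade is unique when its split is incompatible with the other tree,
    so a polytomous clade is at distance zero from any of its resolutions.
    Symmetric in its arguments; equals the classic symmetric-difference
    distance on binary trees.
    """
    labels = _check_tip_sets(t1, t2)
    index = {lab: i for i, lab in enumerate(labels)}
    A = _SplitMatrix.from_tree(t1, index)
    B = _SplitMatrix.from_tree(t2, index)
    ident = np.arange(len(labels))[None, :]
    return int(_conflict_counts(A, B.permuted(ident))[0])


def randomized_max_ph85(
    t1: Tree,
    t2: Tree,
    n_randomizations: int = 1000,
    seed: int = 0,
    include_observed: bool = True,
    return_trace: bool = False,
    _chunk: int = 64,
):
    """Largest PH85 over random tip relabelings of ``t2`` (``t1`` fixed).

    This estimates the maximum attainable distance for the pair of tree
    shapes and is the denominator of the normalized distance.  With
    ``include_observed`` the unpermuted distance joins the replicates, so
    the normalized distance can never exceed 1.  With ``return_trace`` the
    non-decreasing running maximum per replicate is also returned
    (useful to check that the permutation count has converged).
    """
    labels = _check_tip_sets(t1, t2)
    n = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    A = _SplitMatrix.from_tree(t1, index)
    B = _SplitMatrix.from_tree(t2, index)
    rng = np.random.default_rng(seed)

    values = np.zeros(n_randomizations, dtype=int)
    pos = 0
    while pos < n_randomizations:
        take = min(_chunk, n_randomizations - pos)
        perms = rng.permuted(np.tile(np.arange(n), (take, 1)), axis=1)
        values[pos: pos + take] = _conflict_counts(A, B.permuted(perms))
        pos += take

    if include_observed:
        ident = np.arange(n)[None, :]
        observed = int(_conflict_counts(A, B.permuted(ident))[0])
        running = np.maximum.accumulate(np.maximum(values, observed))
    else:
        running = np.maximum.accumulate(values)
    best = int(running[-1])
    if return_trace:
        return best, running.astype(int)
    return best


def nph85(t1: Tree, t2: Tree, config: AnalysisConfig | None = None) -> float:
    """Normalized topological distance in ``[0, 1]``.

    0 means identical topologies (or no conflicting clades at all, e.g. a
    star tree, where the normalizing maximum is 0); 1 means no clades in
    common.
    """
    if config is None:
        config = AnalysisConfig()
    observed = ph85(t1, t2)
    if observed == 0:
        return 0.0
    denom = randomized_max_ph85(
        t1,
        t2,
        n_randomizations=config.n_randomizations,
        seed=config.seed,
        include_observed=config.include_observed,
    )
    if denom == 0:
        return 0.0
    return observed / denom


@dataclass(frozen=True)
class DistanceResult:
    """nPH85 with its uncertainty summary across random polytomy resolutions."""

    ph85: int
    denominator: int
    nph85: float
    overall: float
    mean: float
    percentile_low: float
    percentile_high: float
    resolution_values: tuple[float, ...] = ()

    def as_dict(self) -> dict:
        return {
            "ph85": self.ph85,
            "denominator": self.denominator,
            "overall": self.overall,
            "mean": self.mean,
            "p2.5": self.percentile_low,
            "p97.5": self.percentile_high,
        }


def nph85_summary(
    host: Tree,
    virus: Tree,
    assoc: Association,
    config: AnalysisConfig | None = None,
) -> DistanceResult:
    """Full distance pipeline for a host/virus pair.

    The host tree is expanded so multi-virus hosts become (metric-neutral)
    polytomies; virus nodes below the support threshold are collapsed.  The
    *overall* distance is computed directly on the possibly polytomous pair
    (the conflict convention makes polytomies first-class).  Uncertainty
    from the collapsed nodes is then summarized by randomly resolving all
    polytomies in both trees ``n_resolutions`` times and reporting the mean
    and equal-tail 95% percentile range of the per-resolution distances.
    """
    if config is None:
        config = AnalysisConfig()
    expanded = expand_host_tree(host, assoc)
    collapsed = collapse_low_support(virus, config.support_threshold)
    _check_tip_sets(expanded, collapsed)

    observed = ph85(expanded, collapsed)
    denom = randomized_max_ph85(
        expanded,
        collapsed,
        n_randomizations=config.n_randomizations,
        seed=config.seed,
        include_observed=config.include_observed,
    )
    overall = 0.0 if observed == 0 or denom == 0 else observed / denom

    if not (expanded.has_polytomy() or collapsed.has_polytomy()):
        values = (overall,)
        mean = lo = hi = overall
    else:
        rng = random.Random(config.seed)
        vals = []
        for _ in range(config.n_resolutions):
            sh = rng.randrange(2**31)
            sv = rng.randrange(2**31)
            sr = rng.randrange(2**31)
            h_res = resolve_polytomies(expanded, sh)
            v_res = resolve_polytomies(collapsed, sv)
            vals.append(nph85(h_res, v_res, replace(config, seed=sr)))
        values = tuple(vals)
        mean = float(np.mean(vals))
        lo, hi = (float(x) for x in np.percentile(vals, [2.5, 97.5]))

    return DistanceResult(
        ph85=observed,
        denominator=denom,
        nph85=overall,
        overall=overall,
        mean=mean,
        percentile_low=lo,
        percentile_high=hi,
        resolution_values=values,
    )
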