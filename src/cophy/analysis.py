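"""Tanglegram layout/untangling and family-level comparative statistics.

A tanglegram draws the host tree on the left, the virus tree on the right,
and a line per association.  Congruent histories permit leaf orderings with
few line crossings, so the crossing count is a visual proxy for
co-divergence.  :func:`untangle` hill-climbs over branch rotations
(barycenter ordering of children, alternating sides) until no rotation
reduces the crossing count.

:func:`family_comparison` reproduces the across-family statistics: the
Pearson correlation between a family's normalized topological distance and
its number of sampled viruses, and a Welch t-test comparing DNA- against
RNA-genome families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trees import Association, Node, Tree, TreeError

__all__ = [
    "TanglegramLayout",
    "FamilyRecord",
    "ComparisonReport",
    "count_crossings",
    "untangle",
    "family_comparison",
]


@dataclass(frozen=True)
class TanglegramLayout:
    host_order: tuple[str, ...]
    virus_order: tuple[str, ...]
    association: Association
    crossings: int


def _crossings(host_order, virus_order, assoc: Association) -> int:
    """Number of crossing association lines, by inversion counting."""
    hpos = {lab: i for i, lab in enumerate(host_order)}
    if len(hpos) != len(host_order):
        raise TreeError("host order is not a permutation")
    vpos = {lab: i for i, lab in enumerate(virus_order)}
    if len(vpos) != len(virus_order):
        raise TreeError("virus order is not a permutation")
    # lines sorted by virus position; crossings = inversions among host
    # positions (ties = same host tip: parallel lines, no crossing)
    seq = [hpos[assoc[v]] for v in virus_order]
    return _count_inversions(seq)


def _count_inversions(seq) -> int:
    """Merge-sort inversion count (strict inversions only)."""

    def rec(a):
        if len(a) <= 1:
            return a, 0
        mid = len(a) // 2
        left, nl = rec(a[:mid])
        right, nr = rec(a[mid:])
        merged = []
        inv = nl + nr
        i = j = 0
        while i < len(left) and j < len(right):
            if left[i] <= right[j]:
                merged.append(left[i])
                i += 1
            else:
                merged.append(right[j])
                j += 1
                inv += len(left) - i
        merged.extend(left[i:])
        merged.extend(right[j:])
        return merged, inv

    return rec(list(seq))[1]


def count_crossings(layout: TanglegramLayout) -> int:
    """Crossing count of a layout (pairs of lines ordered oppositely)."""
    return _crossings(layout.host_order, layout.virus_order, layout.association)


def untangle(host: Tree, virus: Tree, assoc: Association, max_rounds: int = 50) -> TanglegramLayout:
    """Minimize tanglegram crossings by rotating branches.

    Deterministic hill-climb: children of each internal node are reordered
    by the barycenter of their partners' positions on the opposite side; a
    reordering is kept only if it strictly reduces the crossing count.
    Alternates sides until a full round makes no progress.  The result
    never has more crossings than the input leaf orders.
    """
    assoc.validate(virus, host)
    host = host.copy()
    virus = virus.copy()
    by_host = assoc.by_host()

    def orders():
        return tuple(host.leaf_labels()), tuple(virus.leaf_labels())

    def score():
        h, v = orders()
        return _crossings(h, v, assoc)

    def partner_positions(side: str):
        """leaf label -> positions of its partners on the other side."""
        h_order, v_order = orders()
        if side == "host":
            vpos = {lab: i for i, lab in enumerate(v_order)}
            return {h: [vpos[v] for v in by_host.get(h, [])] for h in h_order}
        hpos = {lab: i for i, lab in enumerate(h_order)}
        return {v: [hpos[assoc[v]]] for v in v_order}

    current = score()
    for _ in range(max_rounds):
        improved = False
        for tree, side in ((virus, "virus"), (host, "host")):
            partners = partner_positions(side)
            for nd in tree.internal_nodes():
                original = list(nd.children)

                def barycenter(child: Node) -> float:
                    pos = [p for leaf in child.leaves() for p in partners[leaf.label]]
                    return float(np.mean(pos)) if pos else float("inf")

                reordered = sorted(original, key=barycenter)
                if reordered == original:
                    continue
                nd.children = reordered
                trial = score()
                if trial < current:
                    current = trial
                    improved = True
                    partners = partner_positions(side)
                else:
                    nd.children = original
        if not improved:
            break

    h_order, v_order = orders()
    return TanglegramLayout(h_order, v_order, assoc, current)


# ---------------------------------------------------------------------------
# family-level comparative statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilyRecord:
    family: str
    nph85: float
    n_viruses: int
    genome_type: str  # "DNA" or "RNA"
    segmented: bool | None = None
    sense: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.nph85 <= 1.0:
            raise ValueError("nph85 must be in [0, 1]")
        if self.n_viruses < 1:
            raise ValueError("n_viruses must be >= 1")
        if self.genome_type.upper() not in ("DNA", "RNA"):
            raise ValueError("genome_type must be DNA or RNA")


@dataclass(frozen=True)
class ComparisonReport:
    pearson_r: float | None
    pearson_p: float | None
    t_statistic: float | None
    t_p: float | None
    mean_dna: float | None
    mean_rna: float | None
    n_dna: int
    n_rna: int
    notes: tuple[str, ...] = ()


def family_comparison(records: list[FamilyRecord]) -> ComparisonReport:
    """Across-family statistics on normalized topological distances.

    Pearson correlation (two-sided) of nPH85 against the number of viruses
    sampled per family, and a Welch two-sample t-test of DNA- versus
    RNA-genome families.  Degenerate inputs (too few records, zero
    variance, an empty genome group) drop the affected statistic and add a
    note instead of failing.
    """
    notes: list[str] = []
    x = np.array([r.n_viruses for r in records], dtype=float)
    y = np.array([r.nph85 for r in records], dtype=float)

    pearson_r = pearson_p = None
    if len(records) < 3:
        notes.append("correlation skipped: fewer than 3 families")
    elif np.std(x) == 0 or np.std(y) == 0:
        notes.append("correlation skipped: zero variance")
    else:
        res = stats.pearsonr(x, y)
        pearson_r, pearson_p = float(res.statistic), float(res.pvalue)

    dna = np.array([r.nph85 for r in records if r.genome_type.upper() == "DNA"])
    rna = np.array([r.nph85 for r in records if r.genome_type.upper() == "RNA"])
    mean_dna = float(dna.mean()) if dna.size else None
    mean_rna = float(rna.mean()) if rna.size else None

    t_stat = t_p = None
    if dna.size < 2 or rna.size < 2:
        notes.append("t-test skipped: each genome group needs >= 2 families")
    elif np.std(dna) == 0 and np.std(rna) == 0:
        if np.allclose(dna.mean(), rna.mean()):
            t_stat, t_p = 0.0, 1.0
        else:
            notes.append("t-test skipped: zero variance in both groups")
    else:
        res = stats.ttest_ind(dna, rna, equal_var=False)
        t_stat, t_p = float(res.statistic), float(res.pvalue)

    return ComparisonReport(
        pearson_r=pearson_r,
        pearson_p=pearson_p,
        t_statistic=t_stat,
        t_p=t_p,
        mean_dna=mean_dna,
        mean_rna=mean_rna,
        n_dna=int(dna.size),
        n_rna=int(rna.size),
        notes=tuple(notes),
    )
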