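"""Relative node depth: where in the host tree does incongruence sit?

A host clade is *incongruent* when its tip set cannot be a clade of the
virus tree (rooted incompatibility: the two tip sets overlap without being
nested).  For each incongruent clade the raw node depth is the number of
internal nodes in its subtree (including its own node), so cherries score 1
and the deepest clades score highest.  Dividing by the largest raw depth
over all candidate host clades gives the *relative node depth* in
``(0, 1]``: values near 0 mean host switching near the tips (recent),
values near 1 mean switching at the deepest divergences (ancient).

Both trees must share a tip set (expand the host tree first) and are used
in their rooted sense.
"""

from __future__ import annotations

from dataclasses import dataclass

from .trees import Tree, TreeError

__all__ = [
    "DepthEntry",
    "DepthResult",
    "incongruent_host_clades",
    "relative_node_depths",
]


@dataclass(frozen=True)
class DepthEntry:
    clade: tuple[str, ...]
    raw_depth: int
    relative_depth: float


@dataclass(frozen=True)
class DepthResult:
    entries: tuple[DepthEntry, ...]
    max_raw_depth: int

    def max_relative_depth(self) -> float:
        return max((e.relative_depth for e in self.entries), default=0.0)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


def _clades_incompatible(x: frozenset, y: frozenset) -> bool:
    """Rooted clade incompatibility: overlapping but neither nested."""
    return bool(x & y) and bool(x - y) and bool(y - x)


def _candidate_clades(tree: Tree):
    """(node, tip set) for every non-root internal node with >= 2 tips."""
    out = []
    for nd in tree.postorder():
        if nd is tree.root or nd.is_leaf:
            continue
        tips = nd.tip_set()
        if len(tips) >= 2:
            out.append((nd, tips))
    return out


def incongruent_host_clades(host: Tree, virus: Tree) -> set[frozenset[str]]:
    """Host clades (tip sets) that conflict with the virus tree.

    A collapsed (polytomous) virus tree has fewer clades and therefore
    fewer chances to conflict, mirroring the polytomy convention of the
    topology distance.
    """
    if host.leaf_set() != virus.leaf_set():
        raise TreeError(
            "tip sets differ: only in host="
            f"{sorted(host.leaf_set() - virus.leaf_set())}, "
            f"only in virus={sorted(virus.leaf_set() - host.leaf_set())}"
        )
    virus_clades = [tips for _, tips in _candidate_clades(virus)]
    return {
        tips
        for _, tips in _candidate_clades(host)
        if any(_clades_incompatible(tips, vc) for vc in virus_clades)
    }


def _raw_depth(node, count_tips: bool) -> int:
    internal = sum(1 for nd in node.postorder() if not nd.is_leaf)
    if not count_tips:
        return internal
    return internal + sum(1 for nd in node.postorder() if nd.is_leaf)


def relative_node_depths(host: Tree, virus: Tree, count_tips: bool = False) -> DepthResult:
    """Raw and relative node depths for every incongruent host clade.

    ``count_tips`` switches the raw depth from internal-node counts (the
    default, under which the deepest nontrivial clade normalizes to exactly
    1) to total node counts.  The root and the leaves are excluded from
    both the candidates and the normalizing maximum.
    """
    bad = incongruent_host_clades(host, virus)
    candidates = _candidate_clades(host)
    if not candidates:
        return DepthResult((), 0)
    max_raw = max(_raw_depth(nd, count_tips) for nd, _ in candidates)
    entries = []
    for nd, tips in candidates:
        if tips in bad:
            raw = _raw_depth(nd, count_tips)
            entries.append(
                DepthEntry(tuple(sorted(tips)), raw, raw / max_raw)
            )
    entries.sort(key=lambda e: (e.raw_depth, e.clade))
    return DepthResult(tuple(entries), max_raw)
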