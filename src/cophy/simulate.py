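"""Synthetic tanglegram generator with known host-switch counts.

Host trees are grown under a Yule process (uniform random lineage
splitting; branching times are irrelevant because all downstream metrics
are topology-only).  The virus tree starts as a tip-relabeled copy of the
expanded host tree — pure co-divergence — and each simulated host switch is
a subtree-prune-regraft (SPR) move: a clade is pruned and regrafted onto a
random edge outside itself, the tree-rearrangement analog of one transfer
event.  Because later switches can partially undo earlier ones, every
simulated pair records the *realized* number of incongruent host clades
alongside the requested switch count.

Support values can be sprinkled on internal nodes (a chosen fraction drawn
below the collapse threshold of 0.8) to exercise the collapse/resolve
pipeline end to end.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .distance import unique_splits
from .trees import Association, Node, Tree, TreeError, expand_host_tree, resolve_polytomies

__all__ = [
    "SimulationConfig",
    "SwitchRecord",
    "SimulatedPair",
    "yule_tree",
    "assign_supports",
    "spr",
    "derive_virus_tree",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated tanglegram.

    Defaults mirror the validation regime the metric was designed for:
    100-tip host trees, one virus per host, fully supported nodes, and a
    switch count swept by the caller.
    """

    n_hosts: int = 100
    n_switches: int = 0
    viruses_per_host: int | tuple[int, ...] = 1
    low_support_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_hosts < 3:
            raise ValueError("n_hosts must be >= 3")
        if self.n_switches < 0:
            raise ValueError("n_switches must be >= 0")
        if not 0.0 <= self.low_support_fraction <= 1.0:
            raise ValueError("low_support_fraction must be in [0, 1]")
        if isinstance(self.viruses_per_host, int):
            if self.viruses_per_host < 1:
                raise ValueError("viruses_per_host must be >= 1")
        else:
            vph = tuple(self.viruses_per_host)
            if len(vph) != self.n_hosts or min(vph) < 1:
                raise ValueError(
                    "per-host virus counts must list one positive count per host"
                )
            object.__setattr__(self, "viruses_per_host", vph)


@dataclass(frozen=True)
class SwitchRecord:
    """One host switch: the pruned clade and its new sibling clade."""

    pruned: tuple[str, ...]
    regraft_sibling: tuple[str, ...]


@dataclass(frozen=True)
class SimulatedPair:
    host: Tree
    virus: Tree
    association: Association
    switch_log: tuple[SwitchRecord, ...]
    n_incongruent: int


def yule_tree(n: int, seed: int, prefix: str = "t") -> Tree:
    """Rooted binary tree with ``n`` tips grown by uniform tip splitting."""
    if n < 2:
        raise ValueError("a Yule tree needs at least 2 tips")
    rng = random.Random(seed)
    root = Node()
    tips = [root.add_child(Node()), root.add_child(Node())]
    while len(tips) < n:
        victim = tips.pop(rng.randrange(len(tips)))
        tips.append(victim.add_child(Node()))
        tips.append(victim.add_child(Node()))
    for i, tip in enumerate(tips):
        tip.label = f"{prefix}{i + 1}"
    return Tree(root)


def assign_supports(tree: Tree, low_support_fraction: float, seed: int) -> Tree:
    """Give every non-root internal node a support value.

    A seeded fraction of nodes draws uniformly from [0, 0.8) (doomed to be
    collapsed at the default 0.8 threshold); the rest from [0.8, 1].
    """
    if not 0.0 <= low_support_fraction <= 1.0:
        raise ValueError("low_support_fraction must be in [0, 1]")
    rng = random.Random(seed)
    out = tree.copy()
    for nd in out.postorder():
        if nd.is_leaf or nd is out.root:
            continue
        if rng.random() < low_support_fraction:
            nd.support = rng.random() * 0.8
        else:
            nd.support = 0.8 + rng.random() * 0.2
    return out


def _find_clade(tree: Tree, tips: frozenset[str]) -> Node:
    for nd in tree.postorder():
        if nd.tip_set() == tips:
            return nd
    raise TreeError(f"no clade with tips {sorted(tips)}")


def _detach_subtree(tree: Tree, node: Node) -> None:
    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    if len(parent.children) == 1:
        only = parent.children[0]
        grand = parent.parent
        if grand is None:
            only.parent = None
            only.support = None
            tree.root = only
        else:
            idx = grand.children.index(parent)
            grand.children[idx] = only
            only.parent = grand


def _regraft(tree: Tree, node: Node, sibling: Node) -> None:
    parent = sibling.parent
    joint = Node()
    if parent is None:
        joint.add_child(sibling)
        joint.add_child(node)
        tree.root = joint
    else:
        idx = parent.children.index(sibling)
        joint.add_child(sibling)
        joint.add_child(node)
        joint.parent = parent
        parent.children[idx] = joint


def spr(tree: Tree, prune_tips, regraft_sibling_tips) -> Tree:
    """Targeted subtree-prune-regraft: prune the clade with ``prune_tips``
    and regraft it as the sibling of the clade with ``regraft_sibling_tips``
    (looked up after pruning).  Returns a new tree."""
    out = tree.copy()
    node = _find_clade(out, frozenset(prune_tips))
    if node.parent is None:
        raise TreeError("cannot prune the root")
    _detach_subtree(out, node)
    sibling = _find_clade(out, frozenset(regraft_sibling_tips))
    _regraft(out, node, sibling)
    out.validate()
    return out


def _random_spr(tree: Tree, rng: random.Random) -> SwitchRecord:
    """One uniform SPR in place; guaranteed to change the topology."""
    n = len(tree)
    # viable prune candidates leave enough of the tree to host a regraft
    # edge that is not the one the subtree came from
    candidates = [
        nd
        for nd in tree.postorder()
        if nd.parent is not None and n - len(nd.tip_set()) >= 3
    ]
    if not candidates:
        raise TreeError("tree too small for a host-switch (SPR) move")
    node = rng.choice(candidates)
    parent = node.parent
    parent_was_root = parent.parent is None and len(parent.children) == 2
    old_sibling = next(c for c in parent.children if c is not node)
    pruned_tips = tuple(sorted(node.tip_set()))
    _detach_subtree(tree, node)
    # Re-inserting on the edge the subtree came from would undo the move in
    # the unrooted sense: that edge is the one above the old sibling, or —
    # when the old parent was the root — either edge below the new root.
    if parent_was_root:
        undo = set(old_sibling.children)
    else:
        undo = {old_sibling}
        sp = old_sibling.parent
        if sp is not None and sp.parent is None and len(sp.children) == 2:
            # edge above the binary root's other child is the same unrooted
            # edge as the one above the old sibling
            undo.add(next(c for c in sp.children if c is not old_sibling))
    targets = [
        nd
        for nd in tree.postorder()
        if nd.parent is not None and nd not in undo
    ]
    sibling = rng.choice(targets)
    record = SwitchRecord(pruned_tips, tuple(sorted(sibling.tip_set())))
    _regraft(tree, node, sibling)
    return record


def derive_virus_tree(host: Tree, config: SimulationConfig) -> SimulatedPair:
    """Simulate a virus tree co-diverging with ``host`` plus host switches.

    The association assigns ``viruses_per_host`` viruses to each host tip
    (named ``<host>.v<k>``); the expanded host tree is copied, per-host
    polytomies are randomly resolved, and ``n_switches`` random SPR moves
    are applied.  The realized incongruent-clade count is measured with the
    topology-distance machinery, since successive switches may cancel.
    """
    if not host.is_binary():
        raise TreeError("host tree must be binary")
    rng = random.Random(config.seed)
    hosts = host.leaf_labels()
    vph = config.viruses_per_host
    counts = [vph] * len(hosts) if isinstance(vph, int) else list(vph)
    mapping = {}
    for h, m in zip(hosts, counts):
        for k in range(1, m + 1):
            mapping[f"{h}.v{k}"] = h
    assoc = Association(mapping)

    expanded = expand_host_tree(host, assoc)
    virus = resolve_polytomies(expanded, seed=rng.randrange(2**31))
    log = []
    for _ in range(config.n_switches):
        log.append(_random_spr(virus, rng))
    if config.low_support_fraction > 0:
        virus = assign_supports(
            virus, config.low_support_fraction, seed=rng.randrange(2**31)
        )
    n_incongruent = len(unique_splits(expanded, virus))
    return SimulatedPair(host, virus, assoc, tuple(log), n_incongruent)
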