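"""Tree data model, Newick I/O, and tanglegram pre-processing.

The analyses in this package compare a virus phylogeny against a host
cladogram.  Both are represented by a small rooted :class:`Tree` whose
internal nodes may carry branch-support values in ``[0, 1]`` (e.g. aLRT
statistics) and whose nodes may be multifurcating.  Newick parsing is
delegated to :mod:`dendropy`; internal node labels that parse as a float in
``[0, 1]`` are interpreted as supports, anything else is kept as a plain
label.

Pre-processing steps provided here:

* :func:`expand_host_tree` — grow the host tree so its tip set matches the
  virus tip set (hosts carrying several viruses become polytomies; the
  extra polytomies are neutral for the topology distance).
* :func:`collapse_low_support` — contract poorly supported internal edges
  into polytomies.
* :func:`resolve_polytomies` — seeded random binary refinement.
"""

from __future__ import annotations

import random
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

__all__ = [
    "Node",
    "Tree",
    "Association",
    "AnalysisConfig",
    "TreeError",
    "parse_newick",
    "write_newick",
    "expand_host_tree",
    "collapse_low_support",
    "resolve_polytomies",
]


class TreeError(ValueError):
    """Raised for malformed trees, Newick strings or associations."""


class Node:
    """A node of a rooted (possibly multifurcating) phylogeny."""

    __slots__ = ("children", "parent", "label", "support", "length")

    def __init__(self, label=None, support=None, length=None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.label: str | None = label
        self.support: float | None = support
        self.length: float | None = length

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["Node"]:
        for nd in self.postorder():
            if nd.is_leaf:
                yield nd

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        yield from reversed(out)

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def tip_set(self) -> frozenset[str]:
        return frozenset(nd.label for nd in self.leaves())

    def copy(self) -> "Node":
        dup = Node(self.label, self.support, self.length)
        for child in self.children:
            dup.add_child(child.copy())
        return dup

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"Node({self.label!r})"
        return f"Node(<{len(self.children)} children>)"


class Tree:
    """A rooted phylogeny with uniquely labeled tips.

    The topology-distance machinery treats the tree as unrooted (the root is
    just an unlabeled vertex); clade-based statistics (node depth,
    reconciliation) use the rooted view.
    """

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self.validate()

    # -- basic queries ---------------------------------------------------
    def leaves(self) -> list[Node]:
        return list(self.root.leaves())

    def leaf_labels(self) -> list[str]:
        return [nd.label for nd in self.root.leaves()]

    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_labels())

    def __len__(self) -> int:
        return len(self.leaf_labels())

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        return [
            nd
            for nd in self.postorder()
            if not nd.is_leaf and (include_root or nd is not self.root)
        ]

    def is_binary(self) -> bool:
        return all(len(nd.children) == 2 for nd in self.internal_nodes())

    def has_polytomy(self) -> bool:
        return any(len(nd.children) > 2 for nd in self.internal_nodes())

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), self.rooted)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        labels = [nd.label for nd in self.root.leaves()]
        if any(lab is None or lab == "" for lab in labels):
            raise TreeError("all tips must carry a non-empty label")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
        for nd in self.postorder():
            if not nd.is_leaf and len(nd.children) < 2 and nd is not self.root:
                raise TreeError("internal nodes must have >= 2 children")

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str, rooted: bool = True) -> "Tree":
        return parse_newick(text, rooted=rooted)

    def to_newick(self, supports: bool = True, lengths: bool = False) -> str:
        def fmt(nd: Node) -> str:
            if nd.is_leaf:
                s = _quote_label(nd.label)
            else:
                inner = ",".join(fmt(c) for c in nd.children)
                lab = ""
                if supports and nd.support is not None:
                    lab = _format_float(nd.support)
                elif nd.label:
                    lab = _quote_label(nd.label)
                s = f"({inner}){lab}"
            if lengths and nd.length is not None:
                s += f":{_format_float(nd.length)}"
            return s

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({len(self)} tips)"


def _format_float(x: float) -> str:
    s = f"{x:.10g}"
    return s


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "(),:;[]' \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_newick(text: str, rooted: bool = True) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Internal-node labels that are numeric and fall in ``[0, 1]`` are read as
    branch supports (PhyML-style aLRT annotation); other labels are kept
    verbatim and never trigger support-based collapsing.  Branch lengths are
    parsed but ignored by all topology metrics.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises rich, position-bearing errors
        raise TreeError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            return Node(label=label, length=dnode.edge.length)
        node = Node(length=dnode.edge.length)
        raw = dnode.label
        if raw is not None:
            try:
                val = float(raw)
            except (TypeError, ValueError):
                node.label = raw
            else:
                if 0.0 <= val <= 1.0:
                    node.support = val
                else:
                    node.label = raw
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return Tree(convert(dtree.seed_node), rooted=rooted)


def write_newick(tree: Tree, path: str | Path, **kwargs) -> None:
    Path(path).write_text(tree.to_newick(**kwargs) + "\n")


def read_newick(path: str | Path, rooted: bool = True) -> Tree:
    return parse_newick(Path(path).read_text(), rooted=rooted)


# ---------------------------------------------------------------------------
# associations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Association:
    """Many-to-one map from virus tip labels to host tip labels."""

    mapping: Mapping[str, str]

    def __post_init__(self):
        object.__setattr__(self, "mapping", dict(self.mapping))

    def __getitem__(self, virus: str) -> str:
        return self.mapping[virus]

    def __len__(self) -> int:
        return len(self.mapping)

    def items(self):
        return self.mapping.items()

    @property
    def virus_tips(self) -> frozenset[str]:
        return frozenset(self.mapping)

    @property
    def host_tips(self) -> frozenset[str]:
        return frozenset(self.mapping.values())

    def by_host(self) -> dict[str, list[str]]:
        """Host label -> sorted list of virus labels mapped to it."""
        out: dict[str, list[str]] = {}
        for v, h in self.mapping.items():
            out.setdefault(h, []).append(v)
        return {h: sorted(vs) for h, vs in out.items()}

    def validate(self, virus: Tree, host: Tree) -> None:
        missing = virus.leaf_set() - self.virus_tips
        if missing:
            raise TreeError(f"virus tips without a host mapping: {sorted(missing)}")
        extra = self.virus_tips - virus.leaf_set()
        if extra:
            raise TreeError(f"mapped viruses absent from the virus tree: {sorted(extra)}")
        absent = self.host_tips - host.leaf_set()
        if absent:
            raise TreeError(f"viruses mapped to absent hosts: {sorted(absent)}")

    @classmethod
    def identity(cls, labels) -> "Association":
        return cls({lab: lab for lab in labels})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Association":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = [c.lower() for c in df.columns]
        if cols[:2] != ["virus", "host"]:
            raise TreeError(
                f"association table must have columns 'virus'\\t'host', got {list(df.columns)}"
            )
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(sorted(self.mapping.items()), columns=["virus", "host"])
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs for the normalized-distance pipeline.

    support_threshold
        Internal nodes with support strictly below this are collapsed
        (default 0.8, i.e. a false-positive rate below ~0.1 for aLRT).
    n_resolutions
        Number of seeded random resolutions used to summarize uncertainty
        from collapsed/polytomous nodes (default 100).
    n_randomizations
        Number of tip-label permutations used to estimate the maximum
        attainable topological distance (default 1000).
    include_observed
        Whether the observed (unpermuted) distance participates in the
        normalizing maximum, capping the normalized distance at exactly 1.
    """

    support_threshold: float = 0.8
    n_resolutions: int = 100
    n_randomizations: int = 1000
    seed: int = 0
    include_observed: bool = True

    def __post_init__(self):
        if not 0.0 <= self.support_threshold <= 1.0:
            raise ValueError("support_threshold must be in [0, 1]")
        if self.n_resolutions < 1 or self.n_randomizations < 1:
            raise ValueError("replicate counts must be >= 1")


# ---------------------------------------------------------------------------
# pre-processing operations
# ---------------------------------------------------------------------------


def expand_host_tree(host: Tree, assoc: Association) -> Tree:
    """Expand the host tree so its tip set equals the virus tip set.

    A host tip carrying ``m`` viruses becomes a polytomy of ``m`` virus tips
    (for ``m == 1`` the tip is simply relabeled).  Host tips with no mapped
    virus are pruned, so the returned tip set equals the virus tip set
    exactly.
    """
    by_host = assoc.by_host()
    absent = set(by_host) - set(host.leaf_set())
    if absent:
        raise TreeError(f"viruses mapped to absent hosts: {sorted(absent)}")

    tree = host.copy()
    unused = [leaf for leaf in tree.leaves() if leaf.label not in by_host]
    for leaf in unused:
        _detach(tree, leaf)
    for leaf in tree.leaves():
        viruses = by_host[leaf.label]
        if len(viruses) == 1:
            leaf.label = viruses[0]
        else:
            leaf.label = None
            for v in viruses:
                leaf.add_child(Node(v))
    tree.validate()
    return tree


def _detach(tree: Tree, node: Node) -> None:
    """Remove ``node`` (and its subtree), suppressing unary nodes."""
    parent = node.parent
    if parent is None:
        raise TreeError("cannot detach the root")
    parent.children.remove(node)
    node.parent = None
    if len(parent.children) == 1:
        only = parent.children[0]
        grand = parent.parent
        if grand is None:
            only.parent = None
            tree.root = only
        else:
            idx = grand.children.index(parent)
            grand.children[idx] = only
            only.parent = grand


def collapse_low_support(tree: Tree, threshold: float = 0.8) -> Tree:
    """Contract internal edges whose child-node support is < ``threshold``.

    The strict inequality follows the usual "collapse below the cutoff"
    convention.  Nodes without a support value (host cladograms, the root)
    are never collapsed, so trees lacking supports pass through unchanged.
    """
    out = tree.copy()
    doomed = [
        nd
        for nd in out.postorder()
        if nd is not out.root
        and not nd.is_leaf
        and nd.support is not None
        and nd.support < threshold
    ]
    for nd in doomed:
        parent = nd.parent
        idx = parent.children.index(nd)
        for child in nd.children:
            child.parent = parent
        parent.children[idx: idx + 1] = nd.children
        nd.children = []
        nd.parent = None
    return out


def resolve_polytomies(tree: Tree, seed: int, rng: random.Random | None = None) -> Tree:
    """Refine every polytomy into a binary subtree by uniform random pairing.

    At each step two of the outstanding child lineages are chosen uniformly
    at random and joined under a new (support-free) node.  Every binary
    refinement is reachable; the same seed always yields the same tree.
    """
    if rng is None:
        rng = random.Random(seed)
    out = tree.copy()
    for nd in list(out.postorder()):
        while len(nd.children) > 2:
            i, j = sorted(rng.sample(range(len(nd.children)), 2))
            a, b = nd.children[i], nd.children[j]
            joint = Node()
            joint.add_child(a)
            joint.add_child(b)
            joint.parent = nd
            nd.children[i] = joint
            del nd.children[j]
    return out
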