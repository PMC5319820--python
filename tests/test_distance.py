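"""PH85 / nPH85: examples, brute-force oracles, and invariants."""

import itertools
import random

import dendropy
import numpy as np
import pytest

from cophy import (
    AnalysisConfig,
    Association,
    Split,
    TreeError,
    expand_host_tree,
    nontrivial_splits,
    nph85,
    nph85_summary,
    ph85,
    parse_newick,
    randomized_max_ph85,
    resolve_polytomies,
    splits_conflict,
    yule_tree,
)
from conftest import caterpillar, random_binary_pair


# -- independent oracles -----------------------------------------------------


def brute_splits(tree):
    """Nontrivial splits as canonical frozensets, by direct enumeration."""
    universe = tree.leaf_set()
    n = len(universe)
    out = set()
    for nd in tree.postorder():
        if nd is tree.root or nd.is_leaf:
            continue
        clade = nd.tip_set()
        if 2 <= len(clade) <= n - 2:
            other = universe - clade
            out.add(min(clade, other, key=lambda s: (len(s), sorted(s))))
    return out


def brute_conflict(s1, s2, universe):
    c1, c2 = universe - s1, universe - s2
    return all((s1 & s2, s1 & c2, c1 & s2, c1 & c2))


def brute_ph85(t1, t2):
    """Conflict-based PH85 computed purely with frozensets."""
    universe = t1.leaf_set()
    sp1, sp2 = brute_splits(t1), brute_splits(t2)
    u1 = sum(1 for s in sp1 if any(brute_conflict(s, t, universe) for t in sp2))
    u2 = sum(1 for s in sp2 if any(brute_conflict(s, t, universe) for t in sp1))
    return u1 + u2


def relabeled(tree, mapping):
    out = tree.copy()
    for leaf in out.leaves():
        leaf.label = mapping[leaf.label]
    return out


# -- nontrivial_splits -------------------------------------------------------


class TestSplits:
    def test_balanced_quartet_has_one_split(self):
        t = parse_newick("((a,b),(c,d));")
        assert nontrivial_splits(t) == {Split.canonical({"a", "b"}, t.leaf_set())}

    def test_star_has_none(self):
        assert nontrivial_splits(parse_newick("(a,b,c,d,e);")) == set()

    def test_caterpillar_unrooted_splits(self):
        t = parse_newick("(((a,b),c),d,e);")
        assert {s.side for s in nontrivial_splits(t)} == {
            frozenset({"a", "b"}),
            frozenset({"d", "e"}),
        }

    def test_rootedness_is_ignored(self):
        rooted = parse_newick("((a,b),(c,d));")
        other_rooting = parse_newick("(a,(b,(c,d)));")
        assert nontrivial_splits(rooted) == nontrivial_splits(other_rooting)


class TestSplitsConflict:
    def test_crossing_quartets_conflict(self):
        u = {"a", "b", "c", "d"}
        s1 = Split.canonical({"a", "b"}, u)
        s2 = Split.canonical({"a", "c"}, u)
        assert splits_conflict(s1, s2)

    def test_nested_splits_compatible(self):
        u = set("abcde")
        s1 = Split.canonical({"a", "b"}, u)
        s2 = Split.canonical({"a", "b", "c"}, u)
        assert not splits_conflict(s1, s2)

    def test_self_compatible(self):
        s = Split.canonical({"a", "b"}, set("abcd"))
        assert not splits_conflict(s, s)

    def test_different_universes_raise(self):
        s1 = Split.canonical({"a", "b"}, set("abcd"))
        s2 = Split.canonical({"a", "b"}, set("abce"))
        with pytest.raises(TreeError):
            splits_conflict(s1, s2)


# -- ph85 --------------------------------------------------------------------


class TestPH85:
    def test_identical_trees_zero(self):
        t = yule_tree(10, seed=1)
        assert ph85(t, t.copy()) == 0

    def test_crossed_quartets(self):
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,c),(b,d));")
        assert ph85(t1, t2) == 2

    def test_polytomy_vs_resolution_is_zero(self):
        poly = parse_newick("((a,b,c),d,e);")
        res = parse_newick("(((a,b),c),d,e);")
        assert ph85(poly, res) == 0

    def test_tip_mismatch_raises(self):
        with pytest.raises(TreeError, match="only in"):
            ph85(parse_newick("((a,b),c);"), parse_newick("((a,b),d);"))

    @pytest.mark.parametrize("seed", range(20))
    def test_symmetry(self, seed):
        t1, t2 = random_binary_pair(9, seed)
        assert ph85(t1, t2) == ph85(t2, t1)

    def test_matches_bruteforce_on_1000_random_binary_pairs(self):
        """On binary trees the conflict-based distance equals the classic
        symmetric-difference distance; check both against oracles."""
        rng = random.Random(42)
        for _ in range(1000):
            n = rng.randrange(4, 9)
            t1, t2 = random_binary_pair(n, rng.randrange(2**31))
            fast = ph85(t1, t2)
            assert fast == brute_ph85(t1, t2)
            assert fast == len(brute_splits(t1) ^ brute_splits(t2))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dendropy_rf_on_binary_trees(self, seed):
        """Independent library cross-check on binary trees."""
        t1, t2 = random_binary_pair(12, seed)
        taxa = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick", taxon_namespace=taxa)
        d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick", taxon_namespace=taxa)
        rf = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert ph85(t1, t2) == rf

    @pytest.mark.parametrize("seed", range(10))
    def test_resolution_of_polytomous_tree_at_distance_zero(self, seed):
        from cophy import assign_supports, collapse_low_support

        t = assign_supports(yule_tree(14, seed), 0.5, seed)
        poly = collapse_low_support(t, 0.8)
        res = resolve_polytomies(poly, seed + 1)
        assert ph85(poly, res) == 0


# -- randomized maximum ------------------------------------------------------


class TestRandomizedMax:
    def test_quartet_max_is_two(self):
        """All 24 relabelings of a quartet give PH85 in {0, 2}; the seeded
        maximum over 1000 draws reaches 2."""
        t = parse_newick("((a,b),(c,d));")
        labels = t.leaf_labels()
        values = set()
        for perm in itertools.permutations(labels):
            values.add(brute_ph85(t, relabeled(t, dict(zip(labels, perm)))))
        assert values == {0, 2}
        assert randomized_max_ph85(t, t.copy(), 1000, seed=0) == 2

    def test_star_trees_zero(self):
        t = parse_newick("(a,b,c,d,e);")
        assert randomized_max_ph85(t, t.copy(), 50, seed=0) == 0

    def test_trace_is_nondecreasing(self):
        t1, t2 = random_binary_pair(12, 3)
        best, trace = randomized_max_ph85(t1, t2, 200, seed=5, return_trace=True)
        assert len(trace) == 200
        assert all(b >= a for a, b in zip(trace, trace[1:]))
        assert trace[-1] == best

    def test_observed_included_in_denominator(self):
        c1 = caterpillar([f"x{i}" for i in range(1, 11)])
        c2 = caterpillar(["x1", "x6", "x2", "x7", "x3", "x8", "x4", "x9", "x5", "x10"])
        assert randomized_max_ph85(c1, c2, 10, seed=0) >= ph85(c1, c2)


# -- nph85 -------------------------------------------------------------------


class TestNPH85:
    def test_identical_trees_zero(self):
        t = yule_tree(20, seed=9)
        cfg = AnalysisConfig(n_randomizations=50, seed=1)
        assert nph85(t, t.copy(), cfg) == 0.0

    def test_no_shared_clades_is_one(self):
        c1 = caterpillar([f"x{i}" for i in range(1, 11)])
        c2 = caterpillar(["x1", "x6", "x2", "x7", "x3", "x8", "x4", "x9", "x5", "x10"])
        assert nontrivial_splits(c1).isdisjoint(nontrivial_splits(c2))
        cfg = AnalysisConfig(n_randomizations=1000, seed=1)
        assert nph85(c1, c2, cfg) == 1.0

    def test_half_distance_case(self):
        """PH85 = 2 by hand; the maximum over all 120 relabelings is 4."""
        t1 = parse_newick("(((a,b),c),d,e);")
        t2 = parse_newick("(((a,c),b),d,e);")
        assert ph85(t1, t2) == 2
        labels = t1.leaf_labels()
        brute_max = max(
            brute_ph85(t1, relabeled(t2, dict(zip(labels, perm))))
            for perm in itertools.permutations(labels)
        )
        assert brute_max == 4
        cfg = AnalysisConfig(n_randomizations=500, seed=2)
        assert nph85(t1, t2, cfg) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_bounded_in_unit_interval(self, seed):
        t1, t2 = random_binary_pair(15, seed)
        cfg = AnalysisConfig(n_randomizations=100, seed=seed)
        assert 0.0 <= nph85(t1, t2, cfg) <= 1.0

    def test_multi_virus_expansion_neutrality(self):
        """A virus tree that just resolves the per-host polytomies of the
        expanded host tree is at distance 0."""
        host = yule_tree(8, seed=4, prefix="h")
        mapping = {}
        k = 0
        for h in host.leaf_labels():
            for _ in range(2):
                mapping[f"v{k}"] = h
                k += 1
        expanded = expand_host_tree(host, Association(mapping))
        virus = resolve_polytomies(expanded, seed=99)
        cfg = AnalysisConfig(n_randomizations=100, seed=0)
        assert nph85(expanded, virus, cfg) == 0.0

    def test_depth_position_invariance(self):
        """A single mismatched clade scores the same nPH85 whether it sits
        at a shallow or a deep node (same tree shapes, same seed)."""
        labs = [f"x{i}" for i in range(1, 11)]
        host = caterpillar(labs)
        swap_shallow = labs.copy()
        swap_shallow[2], swap_shallow[4] = swap_shallow[4], swap_shallow[2]
        swap_deep = labs.copy()
        swap_deep[5], swap_deep[7] = swap_deep[7], swap_deep[5]
        v_shallow = caterpillar(swap_shallow)
        v_deep = caterpillar(swap_deep)
        assert ph85(host, v_shallow) == ph85(host, v_deep)
        cfg = AnalysisConfig(n_randomizations=200, seed=7)
        assert nph85(host, v_shallow, cfg) == nph85(host, v_deep, cfg)

    def test_monotone_in_conflicting_clades_with_fixed_denominator(self):
        """With the same tree shapes (hence the same seeded denominator),
        more incongruent nodes means a strictly larger nPH85."""
        labs = [f"x{i}" for i in range(1, 13)]
        host = caterpillar(labs)
        cfg = AnalysisConfig(n_randomizations=300, seed=11)
        values = []
        for n_swaps in range(4):
            perm = labs.copy()
            for j in range(n_swaps):
                i0 = 3 * j
                perm[i0], perm[i0 + 2] = perm[i0 + 2], perm[i0]
            values.append(nph85(host, caterpillar(perm), cfg))
        assert values[0] == 0.0
        assert all(b > a for a, b in zip(values, values[1:]))


# -- summary pipeline --------------------------------------------------------


class TestSummary:
    def test_binary_pair_all_fields_equal(self):
        host = yule_tree(8, seed=2, prefix="h")
        mapping = {f"v{i}": h for i, h in enumerate(host.leaf_labels())}
        virus = yule_tree(8, seed=3, prefix="v")
        # relabel virus tips to the mapped names
        for leaf, name in zip(virus.leaves(), mapping):
            leaf.label = name
        cfg = AnalysisConfig(n_resolutions=10, n_randomizations=100, seed=0)
        res = nph85_summary(host, virus, Association(mapping), cfg)
        assert res.overall == res.mean == res.percentile_low == res.percentile_high
        assert res.nph85 == res.overall

    def test_identity_pipeline_is_zero(self):
        host = yule_tree(9, seed=6, prefix="h")
        mapping = {f"{h}.v1": h for h in host.leaf_labels()}
        virus = expand_host_tree(host, Association(mapping))
        cfg = AnalysisConfig(n_resolutions=5, n_randomizations=50, seed=0)
        res = nph85_summary(host, virus, Association(mapping), cfg)
        assert res.ph85 == 0
        assert res.overall == res.mean == 0.0

    def test_mean_within_resolution_extremes(self):
        host = yule_tree(10, seed=8, prefix="h")
        mapping = {f"v{i}": h for i, h in enumerate(host.leaf_labels())}
        from cophy import assign_supports

        virus = expand_host_tree(host, Association(mapping))
        virus = assign_supports(yule_tree(10, seed=12, prefix="x"), 0.3, seed=5)
        for leaf, name in zip(virus.leaves(), mapping):
            leaf.label = name
        cfg = AnalysisConfig(n_resolutions=20, n_randomizations=100, seed=1)
        res = nph85_summary(host, virus, Association(mapping), cfg)
        vals = res.resolution_values
        assert min(vals) <= res.mean <= max(vals)
        assert res.percentile_low <= res.mean <= res.percentile_high
        assert 0.0 <= res.overall <= 1.0
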