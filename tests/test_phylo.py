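import io
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diagmark.core_io import Alignment, TaxonMap
from diagmark.distances import DistanceMatrix
from diagmark.phylo import (LabellingError, RootingError, TreeStateError,
                            bootstrap_support, discrimination_success_rate,
                            is_monophyletic, nj_tree, parse_newick_string,
                            root_with_outgroup, tree_to_newick, upgma_tree)

# ---------------------------------------------------------------------------
# Independent oracle: exhaustive unrooted topology enumeration with
# least-squares branch fitting. A tree is represented as an undirected edge
# list over leaves 0..n-1 and internal nodes n, n+1, ...


def enumerate_topologies(n_leaves: int):
    """All unrooted binary leaf-labelled topologies (3, 15, 105 for n=4,5,6).

    Leaves are nodes 0..n-1; internal nodes are numbered from n upward."""
    hub = n_leaves  # star over leaves 0,1,2
    trees = [([(0, hub), (1, hub), (2, hub)], n_leaves + 1)]
    for leaf in range(3, n_leaves):
        nxt = []
        for edges, counter in trees:
            for k in range(len(edges)):
                u, v = edges[k]
                w = counter
                new_edges = edges[:k] + edges[k + 1:] + [(u, w), (w, v), (leaf, w)]
                nxt.append((new_edges, counter + 1))
        trees = nxt
    return [edges for edges, _ in trees]


def tree_paths(edges, n_leaves):
    """pair -> set of edge indices on the leaf-to-leaf path."""
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))

    def path(a, b):
        stack = [(a, None, [])]
        seen = set()
        while stack:
            node, prev, used = stack.pop()
            if node == b:
                return used
            seen.add(node)
            for nbr, idx in adj[node]:
                if nbr not in seen:
                    stack.append((nbr, node, used + [idx]))
        raise AssertionError("disconnected")

    return {(a, b): path(a, b)
            for a, b in itertools.combinations(range(n_leaves), 2)}


def splits_of(edges, n_leaves, labels):
    """Canonical unrooted bipartitions (side not containing min label)."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    def side(u, v):
        seen = {u}
        stack = [v]
        comp = set()
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            if node < n_leaves:
                comp.add(node)
            stack.extend(adj[node] - seen)
        return comp

    all_leaves = frozenset(labels)
    ref = min(all_leaves)
    out = set()
    for u, v in edges:
        comp = frozenset(labels[i] for i in side(u, v))
        if ref in comp:
            comp = all_leaves - comp
        if 1 < len(comp) < n_leaves - 1:
            out.add(comp)
    return out


def least_squares_topology(D, labels):
    """Best-fit topology by exhaustive least squares over all topologies."""
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    d = np.array([D[i, j] for i, j in pairs])
    best, best_rss = None, np.inf
    for edges in enumerate_topologies(n):
        paths = tree_paths(edges, n)
        A = np.zeros((len(pairs), len(edges)))
        for r, pair in enumerate(pairs):
            for e in paths[pair]:
                A[r, e] = 1.0
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        rss = float(((A @ x - d) ** 2).sum())
        if rss < best_rss:
            best, best_rss = edges, rss
    return splits_of(best, n, labels)


def random_additive_matrix(rng, n_leaves):
    """Distances generated by path sums on a random binary tree."""
    topos = enumerate_topologies(n_leaves)
    edges = topos[rng.integers(0, len(topos))]
    lengths = rng.uniform(0.05, 1.0, size=len(edges))
    paths = tree_paths(edges, n_leaves)
    D = np.zeros((n_leaves, n_leaves))
    for (i, j), used in paths.items():
        D[i, j] = D[j, i] = sum(lengths[e] for e in used)
    labels = [f"t{i}" for i in range(n_leaves)]
    return DistanceMatrix(labels=labels, values=D, model="p"), edges, lengths, labels


def leaf_path_length(tree, name):
    node = tree.find_leaf(name)
    total = 0.0
    while node.parent is not None:
        total += node.length or 0.0
        node = node.parent
    return total


def pairwise_tree_distance(tree, a, b):
    mrca = tree.mrca([a, b])

    def up(name):
        node = tree.find_leaf(name)
        total = 0.0
        while node is not mrca:
            total += node.length or 0.0
            node = node.parent
        return total

    return up(a) + up(b)


class TestNeighborJoining:
    def test_three_leaves_closed_form(self):
        D = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        m = DistanceMatrix(labels=["a", "b", "c"], values=D, model="p")
        tree = nj_tree(m)
        # three-point formulas: la=(dab+dac-dbc)/2 etc.
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_additive_four_leaf_exact_lengths(self):
        rng = np.random.default_rng(11)
        m, edges, lengths, labels = random_additive_matrix(rng, 4)
        tree = nj_tree(m)
        for a, b in itertools.combinations(labels, 2):
            assert pairwise_tree_distance(tree, a, b) == pytest.approx(
                m.get(a, b), abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25)
    def test_additive_recovery_vs_least_squares(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        m, edges, lengths, labels = random_additive_matrix(rng, n)
        tree = nj_tree(m)
        want = least_squares_topology(m.values, labels)
        assert tree.bipartitions() == want

    def test_tie_breaking_deterministic(self):
        D = np.full((4, 4), 1.0)
        np.fill_diagonal(D, 0.0)
        m = DistanceMatrix(labels=list("abcd"), values=D, model="p")
        t1 = tree_to_newick(nj_tree(m))
        t2 = tree_to_newick(nj_tree(m))
        assert t1 == t2
        # equidistant: the lowest-index pair (a, b) is joined first
        assert nj_tree(m).bipartitions() == {frozenset({"c", "d"})}

    def test_too_few_labels(self):
        m = DistanceMatrix(labels=["a", "b"], values=np.zeros((2, 2)), model="p")
        with pytest.raises(ValueError):
            nj_tree(m)

    def test_non_finite_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.inf
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels=list("abc"), values=D, model="p"))

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(5)
        D = rng.uniform(0.1, 1.0, size=(6, 6))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        tree = nj_tree(DistanceMatrix(labels=[f"t{i}" for i in range(6)],
                                      values=D, model="p"))
        assert all((n.length or 0.0) >= 0 for n in tree.root.walk()
                   if n is not tree.root)

    def test_matches_dendropy_on_random_matrix(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(17)
        for _ in range(5):
            m, *_ , labels = random_additive_matrix(rng, 6)
            csv = "," + ",".join(labels) + "\n"
            for i, lab in enumerate(labels):
                csv += lab + "," + ",".join(str(v) for v in m.values[i]) + "\n"
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=io.StringIO(csv), delimiter=",")
            ref = pdm.nj_tree()
            ref_tree = parse_newick_string(
                ref.as_string(schema="newick").split("]")[-1].strip())
            assert nj_tree(m).bipartitions() == ref_tree.bipartitions()


class TestUpgma:
    def test_two_leaves_root_at_half(self):
        D = np.array([[0, 0.2], [0.2, 0]])
        tree = upgma_tree(DistanceMatrix(labels=["a", "b"], values=D, model="p"))
        assert tree.rooted
        assert leaf_path_length(tree, "a") == pytest.approx(0.1)
        assert leaf_path_length(tree, "b") == pytest.approx(0.1)

    def test_ultrametric_recovery(self):
        # ((a:1,b:1):1,(c:1.5,d:1.5):0.5) -> d(a,b)=2, d(c,d)=3, cross=4
        D = np.array([
            [0, 2, 4, 4],
            [2, 0, 4, 4],
            [4, 4, 0, 3],
            [4, 4, 3, 0],
        ], dtype=float)
        tree = upgma_tree(DistanceMatrix(labels=list("abcd"), values=D, model="p"))
        assert is_monophyletic(tree, {"a", "b"})
        assert is_monophyletic(tree, {"c", "d"})
        for a, b in itertools.combinations("abcd", 2):
            assert pairwise_tree_distance(tree, a, b) == pytest.approx(D["abcd".index(a),
                                                                         "abcd".index(b)])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25)
    def test_ultrametric_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        D = rng.uniform(0.1, 1.0, size=(n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        tree = upgma_tree(DistanceMatrix(labels=[f"t{i}" for i in range(n)],
                                         values=D, model="p"))
        depths = [leaf_path_length(tree, f"t{i}") for i in range(n)]
        assert max(depths) - min(depths) < 1e-9


class TestRooting:
    def four_leaf_tree(self):
        D = np.array([
            [0.0, 0.2, 0.5, 0.6],
            [0.2, 0.0, 0.5, 0.6],
            [0.5, 0.5, 0.0, 0.3],
            [0.6, 0.6, 0.3, 0.0],
        ])
        return nj_tree(DistanceMatrix(labels=["a1", "a2", "b1", "out"],
                                      values=D, model="p"))

    def test_single_outgroup_rooting(self):
        rooted = root_with_outgroup(self.four_leaf_tree(), ["out"])
        assert rooted.rooted
        assert len(rooted.root.children) == 2
        assert rooted.root.children[0].leaf_names() == frozenset({"out"})

    def test_rooting_preserves_unrooted_splits(self):
        unrooted = self.four_leaf_tree()
        rooted = root_with_outgroup(unrooted, ["out"])
        assert rooted.bipartitions() == unrooted.bipartitions()

    def test_rooting_preserves_path_lengths(self):
        unrooted = self.four_leaf_tree()
        rooted = root_with_outgroup(unrooted, ["out"])
        for a, b in itertools.combinations(["a1", "a2", "b1", "out"], 2):
            assert pairwise_tree_distance(rooted, a, b) == pytest.approx(
                pairwise_tree_distance(unrooted, a, b), abs=1e-12)

    def test_two_accession_outgroup_stem_rooting(self):
        D = np.array([
            [0.0, 0.1, 0.9, 1.0],
            [0.1, 0.0, 0.9, 1.0],
            [0.9, 0.9, 0.0, 0.2],
            [1.0, 1.0, 0.2, 0.0],
        ])
        tree = nj_tree(DistanceMatrix(labels=["a1", "a2", "o1", "o2"],
                                      values=D, model="p"))
        rooted = root_with_outgroup(tree, ["o1", "o2"])
        assert rooted.root.children[0].leaf_names() == frozenset({"o1", "o2"})

    def test_missing_outgroup(self):
        with pytest.raises(LabellingError):
            root_with_outgroup(self.four_leaf_tree(), ["zzz"])

    def test_non_separable_outgroup(self):
        # a1 and b1 are on opposite sides of every internal edge
        with pytest.raises(RootingError):
            root_with_outgroup(self.four_leaf_tree(), ["a1", "b1"])


class TestMonophyly:
    def rooted(self, newick):
        return parse_newick_string(newick, rooted=True)

    def test_clean_clade(self):
        t = self.rooted("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        assert is_monophyletic(t, {"a1", "a2"})

    def test_interleaved_not_monophyletic(self):
        t = self.rooted("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        assert not is_monophyletic(t, {"a1", "a2"})

    def test_singleton_always_monophyletic(self):
        t = self.rooted("((a1:1,b1:1):1,c1:2);")
        assert is_monophyletic(t, {"c1"})
        assert is_monophyletic(t, {"a1"})

    def test_unrooted_tree_is_error(self):
        t = parse_newick_string("((a:1,b:1):1,(c:1,d:1):1);", rooted=False)
        with pytest.raises(TreeStateError):
            is_monophyletic(t, {"a", "b"})

    def test_unknown_leaf_is_error(self):
        t = self.rooted("((a1:1,a2:1):1,b1:2);")
        with pytest.raises(LabellingError):
            is_monophyletic(t, {"a1", "zzz"})

    def test_rotation_invariance(self):
        t1 = self.rooted("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        t2 = self.rooted("((b2:1,b1:1):1,(a2:1,a1:1):1);")
        assert is_monophyletic(t1, {"a1", "a2"}) == is_monophyletic(t2, {"a1", "a2"})


class TestDiscriminationRate:
    def tm(self, mapping, outgroup=("out",)):
        mapping = dict(mapping)
        for o in outgroup:
            mapping[o] = "OUT"
        return TaxonMap(assignments=mapping, outgroup=set(outgroup))

    def test_all_six_monophyletic_100(self):
        newick = ("(out:1,((a1:1,a2:1):1,((b1:1,b2:1):1,((c1:1,c2:1):1,"
                  "((d1:1,d2:1):1,((e1:1,e2:1):1,(f1:1,f2:1):1):1):1):1):1):1);")
        t = parse_newick_string(newick, rooted=True)
        tm = self.tm({f"{x}{i}": x.upper() for x in "abcdef" for i in (1, 2)})
        report = discrimination_success_rate(t, tm)
        assert report.rate_percent == pytest.approx(100.0)
        assert report.n_monophyletic == 6 and report.n_taxa == 6

    def test_three_of_six_monophyletic_50(self):
        # a, b, c monophyletic; d, e, f interleaved
        newick = ("(out:1,((a1:1,a2:1):1,((b1:1,b2:1):1,((c1:1,c2:1):1,"
                  "((d1:1,e1:1):1,((d2:1,f1:1):1,(e2:1,f2:1):1):1):1):1):1):1);")
        t = parse_newick_string(newick, rooted=True)
        tm = self.tm({f"{x}{i}": x.upper() for x in "abcdef" for i in (1, 2)})
        report = discrimination_success_rate(t, tm)
        assert report.rate_percent == pytest.approx(50.0)

    def test_fully_interleaved_zero(self):
        t = parse_newick_string("(out:1,((a1:1,b1:1):1,(a2:1,b2:1):1):1);",
                                rooted=True)
        tm = self.tm({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert discrimination_success_rate(t, tm).rate_percent == 0.0

    def test_outgroup_not_scored(self):
        t = parse_newick_string("(out:1,(a1:1,(b1:1,b2:1):1):1);", rooted=True)
        tm = self.tm({"a1": "A", "b1": "B", "b2": "B"})
        report = discrimination_success_rate(t, tm)
        assert {t_ for t_, _ in report.monophyly} == {"A", "B"}

    def test_taxon_absent_from_tree_is_error(self):
        t = parse_newick_string("(out:1,(a1:1,a2:1):1);", rooted=True)
        tm = self.tm({"a1": "A", "a2": "A", "b1": "B"})
        with pytest.raises(LabellingError):
            discrimination_success_rate(t, tm)


class TestBootstrap:
    def diagnostic_alignment(self):
        # one repeated column pattern separating {a1,a2} from {b1,b2}
        return Alignment(name="x", accessions=["a1", "a2", "b1", "b2"],
                         sequences=["A" * 40, "A" * 40, "G" * 40, "G" * 40])

    def test_invariant_resampling_gives_full_support(self):
        tree = bootstrap_support(self.diagnostic_alignment(), None, "p",
                                 method="nj", replicates=50, seed=1)
        supports = [n.support for n in tree.root.walk()
                    if n.support is not None]
        assert supports and all(s == pytest.approx(100.0) for s in supports)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        from conftest import random_alignment
        aln = random_alignment(rng, 6, 60)
        t1 = bootstrap_support(aln, None, "p", "nj", replicates=30, seed=42)
        t2 = bootstrap_support(aln, None, "p", "nj", replicates=30, seed=42)
        s1 = sorted(n.support for n in t1.root.walk() if n.support is not None)
        s2 = sorted(n.support for n in t2.root.walk() if n.support is not None)
        assert s1 == s2

    def test_supports_in_range(self):
        rng = np.random.default_rng(9)
        from conftest import random_alignment
        aln = random_alignment(rng, 5, 40)
        tree = bootstrap_support(aln, None, "k2p", "nj", replicates=20, seed=3)
        for n in tree.root.walk():
            if n.support is not None:
                assert 0.0 <= n.support <= 100.0


class TestNewick:
    def test_round_trip(self):
        text = "((a:1,b:2):0.5,c:3);"
        tree = parse_newick_string(text)
        back = parse_newick_string(tree_to_newick(tree))
        assert back.leaf_names() == {"a", "b", "c"}
        assert tree_to_newick(back) == tree_to_newick(tree)

    def test_support_rendering(self):
        tree = parse_newick_string("((a:1,b:2)87:0.5,c:3);")
        internal = tree.root.children[0]
        assert internal.support == 87.0
        assert ")87:" in tree_to_newick(tree)

    def test_unbalanced_parenthesis(self):
        with pytest.raises(ValueError):
            parse_newick_string("((a:1,b:2:0.5,c:3);")

    def test_missing_semicolon(self):
        with pytest.raises(ValueError):
            parse_newick_string("(a,b)")
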