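from itertools import combinations

import numpy as np
import pytest

from mdartools.phylo import (
    DistanceMatrix,
    bootstrap_supports,
    nj_tree,
    p_distance,
)
from mdartools.sequence_io import AlignedSet


class TestPDistance:
    def test_identical_rows_are_zero(self):
        aln = AlignedSet([("a", "MKTAYIAKQR"), ("b", "MKTAYIAKQR")])
        assert p_distance(aln).d[0, 1] == 0.0

    def test_single_mismatch_over_ten(self):
        aln = AlignedSet([("a", "AAAAAAAAAA"), ("b", "AAAAAAAAAT")])
        assert p_distance(aln).d[0, 1] == pytest.approx(0.1)

    def test_pairwise_deletion_excludes_gap_columns(self):
        aln = AlignedSet([("a", "AAAAAAAAAA-"), ("b", "AAAAAAAAAAT")])
        assert p_distance(aln).d[0, 1] == 0.0

    def test_x_mismatches_everything_including_x(self):
        aln = AlignedSet([("a", "XAAAAAAAAA"), ("b", "XAAAAAAAAA")])
        assert p_distance(aln).d[0, 1] == pytest.approx(0.1)

    def test_too_few_comparable_columns_names_pair(self):
        aln = AlignedSet([("a", "AAAA------"), ("b", "----TTTTTT")])
        with pytest.raises(ValueError, match="'a' and 'b'"):
            p_distance(aln)

    def test_poisson_correction(self):
        aln = AlignedSet([("a", "AAAAAAAAAA"), ("b", "AAAAAAAATT")])
        d = p_distance(aln, correction="poisson").d[0, 1]
        assert d == pytest.approx(-np.log(0.8))

    def test_symmetry_zero_diagonal_and_range(self, default_family):
        _, aligned, _ = default_family
        dm = p_distance(aligned)
        assert np.allclose(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0)
        assert np.all((dm.d >= 0) & (dm.d <= 1))


def random_additive_matrix(rng, n):
    """Random unrooted binary tree via sequential taxon insertion; returns
    (labels, matrix, splits) with the matrix built by path sums."""
    labels = [chr(ord("A") + i) for i in range(n)]
    # edges as dict node -> list of (neighbor, length); internal nodes are ints
    next_node = [n]
    edges = {}

    def add_edge(u, v, w):
        edges.setdefault(u, []).append([v, w])
        edges.setdefault(v, []).append([u, w])

    def blen():
        return float(rng.uniform(0.05, 0.5))

    # start from the 3-star on taxa 0,1,2
    center = next_node[0]
    next_node[0] += 1
    for t in range(3):
        add_edge(t, center, blen())
    for t in range(3, n):
        # split a uniformly chosen existing edge
        pairs = set()
        for u in edges:
            for v, _ in edges[u]:
                pairs.add(tuple(sorted((u, v), key=str)))
        u, v = list(sorted(pairs))[rng.integers(0, len(pairs))]
        w = next(wt for nb, wt in edges[u] if nb == v)
        mid = next_node[0]
        next_node[0] += 1
        edges[u] = [e for e in edges[u] if e[0] != v]
        edges[v] = [e for e in edges[v] if e[0] != u]
        w1 = w * float(rng.uniform(0.2, 0.8))
        add_edge(u, mid, w1)
        add_edge(mid, v, w - w1)
        add_edge(t, mid, blen())

    def path_length(src, dst):
        stack = [(src, 0.0, None)]
        while stack:
            node, dist, prev = stack.pop()
            if node == dst:
                return dist
            for nb, wt in edges[node]:
                if nb != prev:
                    stack.append((nb, dist + wt, node))
        raise AssertionError("disconnected tree")

    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = path_length(i, j)

    def leaves_below(node, prev):
        if node < n:
            return {labels[node]}
        out = set()
        for nb, _ in edges[node]:
            if nb != prev:
                out |= leaves_below(nb, node)
        return out

    all_set = frozenset(labels)
    anchor = min(all_set)
    splits = set()
    for u in edges:
        for v, _ in edges[u]:
            if u >= n and v >= n and u < v:
                side = frozenset(leaves_below(u, v))
                key = frozenset(all_set - side) if anchor in side else side
                splits.add(key)
    return labels, d, splits


def ls_best_topology(labels, d):
    """Oracle: enumerate every unrooted topology, least-squares fit branch
    lengths to the distance matrix, return the split set of the best fit."""
    n = len(labels)

    def enumerate_topologies(taxa):
        # each topology: list of edges between nodes; leaves 0..n-1
        base = [("c", 0), ("c", 1), ("c", 2)]
        tops = [base]
        counter = 0
        for t in range(3, n):
            new_tops = []
            for top in tops:
                for k in range(len(top)):
                    counter += 1
                    mid = f"m{counter}_{k}"
                    u, v = top[k]
                    cand = [e for i, e in enumerate(top) if i != k]
                    cand += [(u, mid), (mid, v), (mid, t)]
                    new_tops.append(cand)
            tops = new_tops
        return tops

    pairs = list(combinations(range(n), 2))
    best = (np.inf, None)
    for top in enumerate_topologies(range(n)):
        adj = {}
        for a, b in top:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)

        def path_edges(src, dst):
            stack = [(src, [], None)]
            while stack:
                node, used, prev = stack.pop()
                if node == dst:
                    return used
                for nb in adj[node]:
                    if nb != prev:
                        idx = top.index((node, nb)) if (node, nb) in top else top.index((nb, node))
                        stack.append((nb, used + [idx], node))

        A = np.zeros((len(pairs), len(top)))
        y = np.array([d[i, j] for i, j in pairs])
        for row, (i, j) in enumerate(pairs):
            for idx in path_edges(i, j):
                A[row, idx] = 1.0
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = float(((A @ coef - y) ** 2).sum())
        if resid < best[0]:
            best = (resid, (top, adj))
    top, adj = best[1]

    def leaves_below(node, prev):
        if isinstance(node, int):
            return {labels[node]}
        out = set()
        for nb in adj[node]:
            if nb != prev:
                out |= leaves_below(nb, node)
        return out

    all_set = frozenset(labels)
    anchor = min(all_set)
    splits = set()
    for a, b in top:
        if not isinstance(a, int) and not isinstance(b, int):
            side = frozenset(leaves_below(a, b))
            key = frozenset(all_set - side) if anchor in side else side
            splits.add(key)
    return splits


class TestNjTree:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths["A"] == pytest.approx(0.05, abs=1e-9)
        assert lengths["B"] == pytest.approx(0.15, abs=1e-9)
        assert lengths["C"] == pytest.approx(0.25, abs=1e-9)

    def test_three_taxon_pendant_sum_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.uniform(0.05, 0.5, size=3)
            # build a metric from a star: d_ij = x_i + x_j (always additive)
            d = np.zeros((3, 3))
            d[0, 1] = d[1, 0] = x[0] + x[1]
            d[0, 2] = d[2, 0] = x[0] + x[2]
            d[1, 2] = d[2, 1] = x[1] + x[2]
            tree = nj_tree(DistanceMatrix(["A", "B", "C"], d))
            total = sum(c.length for c in tree.root.children)
            assert total == pytest.approx((d[0, 1] + d[0, 2] + d[1, 2]) / 2)

    def test_two_taxon_convention(self):
        tree = nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 0.5], [0.5, 0]])))
        assert {c.length for c in tree.root.children} == {0.25}

    def test_single_taxon_errors(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A"], np.zeros((1, 1))))

    def test_four_taxon_additive_recovery_with_branch_lengths(self):
        # ((A:0.1,B:0.1):0.2,C:0.1,D:0.1) as an additive matrix
        d = np.array(
            [
                [0.0, 0.2, 0.4, 0.4],
                [0.2, 0.0, 0.4, 0.4],
                [0.4, 0.4, 0.0, 0.2],
                [0.4, 0.4, 0.2, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], d))
        assert set(tree.splits()) == {frozenset({"C", "D"})}
        # additive matrices are reproduced exactly: check a path distance
        lengths = {n.name: n.length for n in tree.root.postorder() if n.is_leaf()}
        assert lengths["A"] == pytest.approx(0.1, abs=1e-9)

    def test_recovers_random_additive_topologies(self):
        # NJ is consistent on additive matrices; verify against the
        # exhaustive least-squares topology oracle for 50 random trees
        rng = np.random.default_rng(11)
        for trial in range(50):
            n = int(rng.integers(4, 7))
            labels, d, true_splits = random_additive_matrix(rng, n)
            tree = nj_tree(DistanceMatrix(labels, d))
            assert set(tree.splits()) == true_splits
            assert ls_best_topology(labels, d) == true_splits

    def test_topology_agrees_with_scikit_bio_nj(self):
        # independent implementation cross-check on generic (tie-free)
        # random metric matrices
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(5, 9))
            labels = [f"t{i}" for i in range(n)]
            x = rng.uniform(0.1, 1.0, size=(n, n))
            d = (x + x.T) / 2 + 1.0  # metric-ish, symmetric, zero diag
            np.fill_diagonal(d, 0.0)
            ours = nj_tree(DistanceMatrix(labels, d))
            theirs = skbio_nj(
                skbio.DistanceMatrix(d, ids=labels)
            )
            all_set = frozenset(labels)
            anchor = min(all_set)
            their_splits = set()
            for node in theirs.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= n - 2:
                    their_splits.add(
                        frozenset(all_set - side) if anchor in side else side
                    )
            assert set(ours.splits()) == their_splits

    def test_negative_branch_clamping_preserves_pair_distance(self):
        # a non-additive matrix known to drive one pendant negative
        d = np.array(
            [
                [0.0, 0.1, 0.6, 0.6],
                [0.1, 0.0, 0.15, 0.6],
                [0.6, 0.15, 0.0, 0.3],
                [0.6, 0.6, 0.3, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], d))
        for node in tree.root.postorder():
            assert node.length >= 0.0


class TestBootstrap:
    def test_uniform_alignment_gives_full_support(self):
        # every column identically supports the same cherry
        rows = [
            ("A", "A" * 20),
            ("B", "A" * 20),
            ("C", "T" * 20),
            ("D", "T" * 20),
        ]
        tree = bootstrap_supports(AlignedSet(rows), n_reps=50, seed=5)
        supports = [n.support for n in tree.splits().values()]
        assert supports and all(s == 100 for s in supports)

    def test_zero_replicates_errors(self, default_family):
        _, aligned, _ = default_family
        with pytest.raises(ValueError):
            bootstrap_supports(aligned, n_reps=0, seed=1)

    def test_fixed_seed_is_deterministic(self, default_family):
        _, aligned, _ = default_family
        t1 = bootstrap_supports(aligned, n_reps=30, seed=9)
        t2 = bootstrap_supports(aligned, n_reps=30, seed=9)
        s1 = {k: n.support for k, n in t1.splits().items()}
        s2 = {k: n.support for k, n in t2.splits().items()}
        assert s1 == s2

    def test_invariant_to_leaf_order(self, default_family):
        _, aligned, _ = default_family
        reversed_aln = AlignedSet(list(reversed(aligned.records)))
        t1 = bootstrap_supports(aligned, n_reps=30, seed=9)
        t2 = bootstrap_supports(reversed_aln, n_reps=30, seed=9)
        s1 = {k: n.support for k, n in t1.splits().items()}
        s2 = {k: n.support for k, n in t2.splits().items()}
        assert s1 == s2
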