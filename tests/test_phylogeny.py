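"""Neighbor joining against its consistency guarantee on additive distances."""

import itertools

import numpy as np
import pytest

import trunkscope as ts
from trunkscope.phylogeny import ascii_tree

from conftest import make_site, matrix_from_rows


# ---------------------------------------------------------------------------
# test-side tree utilities (independent of the package's tree structures)

def random_unrooted_topology(rng, taxa):
    """Edge list of a random unrooted binary tree built by leaf insertion."""
    nodes = list(taxa)
    internal = 0

    def new_internal():
        nonlocal internal
        internal += 1
        return f"__i{internal}"

    center = new_internal()
    edges = [(center, t) for t in taxa[:3]]
    for taxon in taxa[3:]:
        idx = int(rng.integers(0, len(edges)))
        a, b = edges.pop(idx)
        mid = new_internal()
        edges.extend([(a, mid), (mid, b), (mid, taxon)])
    return edges


def edges_with_lengths(edges, rng):
    return {e: float(rng.uniform(0.5, 2.0)) for e in edges}


def pairwise_path_lengths(edges, lengths, leaves):
    adj = {}
    for (a, b), w in lengths.items():
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))
    out = {}
    for src in leaves:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in leaves:
            out[(src, dst)] = dist[dst]
    return out


def phylo_tree_path_lengths(tree):
    """Leaf-to-leaf path lengths of a PhyloTree via its parent links."""

    def ancestors(node):
        out = []
        cur = node
        while cur is not None:
            out.append(cur)
            cur = cur.parent
        return out

    leaves = tree.leaves()
    out = {}
    for a in leaves:
        anc_a = ancestors(a)
        depth_a = {}
        d = 0.0
        for node in anc_a:
            depth_a[id(node)] = d
            d += node.branch_length or 0.0
        for b in leaves:
            d = 0.0
            cur = b
            while id(cur) not in depth_a:
                d += cur.branch_length or 0.0
                cur = cur.parent
            out[(a.name, b.name)] = d + depth_a[id(cur)]
    return out


def least_squares_topology(taxa, dvec_fn, rng_unused=None):
    """Exhaustive search over all unrooted topologies; least-squares fit of
    branch lengths to the distances; returns the splits of the best topology."""
    n = len(taxa)
    best = None
    for edges in all_topologies(taxa):
        edge_list = list(edges)
        pairs = list(itertools.combinations(taxa, 2))
        X = np.zeros((len(pairs), len(edge_list)))
        y = np.array([dvec_fn(a, b) for a, b in pairs])
        adj = {}
        for idx, (a, b) in enumerate(edge_list):
            adj.setdefault(a, []).append((b, idx))
            adj.setdefault(b, []).append((a, idx))

        def path_edges(src, dst):
            # DFS for the unique path
            stack = [(src, None, [])]
            seen = {src}
            while stack:
                u, _, used = stack.pop()
                if u == dst:
                    return used
                for v, idx in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append((v, u, used + [idx]))
            raise AssertionError("disconnected topology")

        for row, (a, b) in enumerate(pairs):
            for idx in path_edges(a, b):
                X[row, idx] = 1.0
        coef, residual, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((X @ coef - y) ** 2).sum())
        if best is None or rss < best[0] - 1e-12:
            best = (rss, topology_splits(edges, taxa))
    return best[1]


def all_topologies(taxa):
    """All unrooted binary topologies by recursive leaf insertion."""
    if len(taxa) == 3:
        yield tuple(("__c", t) for t in taxa)
        return
    counter = [0]

    def expand(edges, remaining):
        if not remaining:
            yield tuple(edges)
            return
        taxon, rest = remaining[0], remaining[1:]
        for i in range(len(edges)):
            counter[0] += 1
            mid = f"__m{counter[0]}"
            a, b = edges[i]
            new_edges = edges[:i] + edges[i + 1 :] + [(a, mid), (mid, b), (mid, taxon)]
            yield from expand(new_edges, rest)

    base = [("__c", t) for t in taxa[:3]]
    yield from expand(base, list(taxa[3:]))


def topology_splits(edges, taxa):
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    taxa_set = frozenset(taxa)
    splits = set()
    for a, b in edges:
        # leaves on b's side when edge (a,b) removed
        stack, seen = [b], {a, b}
        side = set()
        while stack:
            u = stack.pop()
            if u in taxa_set:
                side.add(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        side = frozenset(side)
        other = taxa_set - side
        if 1 < len(side) < len(taxa) - 1:
            splits.add(frozenset([side, other]))
    return splits


# ---------------------------------------------------------------------------


class TestBinaryProfiles:
    def test_profiles_and_all_zero_outgroup(self, toy_matrix):
        p = ts.binary_profiles(toy_matrix)
        assert p.taxa == ["r1", "r2", "r3", "germline"]
        assert p.profiles.shape == (4, 3)
        assert not p.profiles[3].any()
        assert p.profiles[0].sum() == 3  # r1 carries all three sites

    def test_trunk_only_matrix_gives_identical_region_profiles(self):
        m = matrix_from_rows(
            {make_site(1): (1, 1), make_site(2): (1, 1)}, regions=["r1", "r2"]
        )
        p = ts.binary_profiles(m)
        assert (p.profiles[0] == p.profiles[1]).all()
        assert p.profiles[2].sum() == 0

    def test_profile_sums_match_matrix_column_sums(self):
        ds = ts.generate_dataset(ts.SimParams(seed=2))
        kept, _ = ts.filter_callset(ds.callset)
        m = ts.build_presence_matrix(kept, ts.EXONIC)
        p = ts.binary_profiles(m)
        assert p.profiles[: m.n_regions].sum(axis=1).tolist() == m.values.sum(
            axis=0
        ).tolist()


class TestHammingDistances:
    def test_hand_counts(self):
        p = ts.BinaryProfileSet(
            taxa=["a", "b"],
            profiles=np.array([[0, 1, 1, 0], [0, 0, 1, 1]], dtype=bool),
            site_keys=[("1", i, "A", "T") for i in range(4)],
        )
        D = ts.hamming_distance_matrix(p)
        assert D.d[0, 1] == 2.0
        assert D.d[0, 0] == 0.0
        Dp = ts.hamming_distance_matrix(p, metric="pdist")
        assert Dp.d[0, 1] == pytest.approx(0.5)

    def test_distance_to_germline_is_site_count(self, toy_matrix):
        p = ts.binary_profiles(toy_matrix)
        D = ts.hamming_distance_matrix(p)
        g = p.taxa.index("germline")
        for j, region in enumerate(toy_matrix.regions):
            assert D.d[j, g] == toy_matrix.values[:, j].sum()


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = ts.DistanceMatrix(
            taxa=["A", "B", "C"],
            d=np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float),
        )
        tree = ts.neighbor_joining(D)
        lengths = {c.name: c.branch_length for c in tree.root.children}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(3.0),
                           "C": pytest.approx(5.0)}

    def test_two_taxa_single_edge(self):
        D = ts.DistanceMatrix(taxa=["A", "B"], d=np.array([[0, 4], [4, 0]], float))
        tree = ts.neighbor_joining(D)
        dists = phylo_tree_path_lengths(tree)
        assert dists[("A", "B")] == pytest.approx(4.0)

    def test_four_taxon_additive_recovery(self):
        # distances generated from ((A:1,B:2):1,(C:3,D:4))
        taxa = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = ts.neighbor_joining(ts.DistanceMatrix(taxa=taxa, d=d))
        assert tree.splits() == {frozenset([frozenset("AB"), frozenset("CD")])}
        dists = phylo_tree_path_lengths(tree)
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                assert dists[(a, b)] == pytest.approx(d[i, j], abs=1e-9)

    def test_equal_distances_tie_breaks_to_first_pair(self):
        n = 4
        d = np.ones((n, n)) - np.eye(n)
        tree = ts.neighbor_joining(ts.DistanceMatrix(taxa=list("ABCD"), d=d))
        assert tree.splits() == {frozenset([frozenset("AB"), frozenset("CD")])}

    def test_invalid_matrices_error(self):
        bad = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            ts.neighbor_joining(ts.DistanceMatrix(taxa=["A", "B"], d=bad))
        neg = np.array([[0, -1], [-1, 0]], dtype=float)
        with pytest.raises(ValueError, match="nonnegative"):
            ts.neighbor_joining(ts.DistanceMatrix(taxa=["A", "B"], d=neg))

    def test_recovers_random_additive_trees_exactly(self):
        """The classical consistency guarantee, n up to 8, 1e-9 tolerance."""
        rng = np.random.default_rng(14)
        for trial in range(15):
            n = int(rng.integers(4, 9))
            taxa = [f"t{i}" for i in range(n)]
            edges = random_unrooted_topology(rng, taxa)
            lengths = edges_with_lengths(edges, rng)
            true_d = pairwise_path_lengths(edges, lengths, taxa)
            d = np.array([[true_d[(a, b)] for b in taxa] for a in taxa])
            tree = ts.neighbor_joining(ts.DistanceMatrix(taxa=taxa, d=d))
            assert tree.splits() == topology_splits(edges, taxa)
            recovered = phylo_tree_path_lengths(tree)
            for a in taxa:
                for b in taxa:
                    assert recovered[(a, b)] == pytest.approx(
                        true_d[(a, b)], abs=1e-9
                    )

    def test_matches_exhaustive_least_squares_topology(self):
        """NJ topology equals the best least-squares topology at n = 4 and 5."""
        rng = np.random.default_rng(15)
        for n in (4, 5):
            for _ in range(5):
                taxa = [f"t{i}" for i in range(n)]
                edges = random_unrooted_topology(rng, taxa)
                lengths = edges_with_lengths(edges, rng)
                true_d = pairwise_path_lengths(edges, lengths, taxa)
                d = np.array([[true_d[(a, b)] for b in taxa] for a in taxa])
                tree = ts.neighbor_joining(ts.DistanceMatrix(taxa=taxa, d=d))
                ls_splits = least_squares_topology(
                    taxa, lambda a, b: true_d[(a, b)]
                )
                assert tree.splits() == ls_splits

    def test_taxon_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(16)
        n = 6
        taxa = [f"t{i}" for i in range(n)]
        edges = random_unrooted_topology(rng, taxa)
        lengths = edges_with_lengths(edges, rng)
        true_d = pairwise_path_lengths(edges, lengths, taxa)
        d = np.array([[true_d[(a, b)] for b in taxa] for a in taxa])
        tree1 = ts.neighbor_joining(ts.DistanceMatrix(taxa=taxa, d=d))
        perm = rng.permutation(n)
        taxa2 = [taxa[i] for i in perm]
        d2 = d[np.ix_(perm, perm)]
        tree2 = ts.neighbor_joining(ts.DistanceMatrix(taxa=taxa2, d=d2))
        assert tree1.splits() == tree2.splits()

    def test_leaf_set_and_edge_count(self):
        rng = np.random.default_rng(17)
        n = 7
        taxa = [f"t{i}" for i in range(n)]
        d = rng.uniform(1, 5, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tree = ts.neighbor_joining(ts.DistanceMatrix(taxa=taxa, d=d))
        assert sorted(tree.leaf_names()) == taxa

        def count_edges(node):
            return len(node.children) + sum(count_edges(c) for c in node.children)

        assert count_edges(tree.root) == 2 * n - 3


class TestRooting:
    def test_three_taxon_star_rooted_on_outgroup(self):
        D = ts.DistanceMatrix(
            taxa=["A", "B", "C"],
            d=np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float),
        )
        tree = ts.root_on_outgroup(ts.neighbor_joining(D), "C")
        assert len(tree.root.children) == 2
        names = {c.name for c in tree.root.children}
        assert "C" in names
        ingroup = next(c for c in tree.root.children if c.name != "C")
        assert sorted(l.name for l in ingroup.leaves()) == ["A", "B"]
        # C's pendant edge (length 5) split at its midpoint
        c_child = next(c for c in tree.root.children if c.name == "C")
        assert c_child.branch_length == pytest.approx(2.5)

    def test_rooting_preserves_topology_and_path_lengths(self):
        rng = np.random.default_rng(18)
        taxa = [f"t{i}" for i in range(6)]
        edges = random_unrooted_topology(rng, taxa)
        lengths = edges_with_lengths(edges, rng)
        true_d = pairwise_path_lengths(edges, lengths, taxa)
        d = np.array([[true_d[(a, b)] for b in taxa] for a in taxa])
        unrooted = ts.neighbor_joining(ts.DistanceMatrix(taxa=taxa, d=d))
        rooted = ts.root_on_outgroup(unrooted, "t0")
        assert rooted.splits() == unrooted.splits()
        rec = phylo_tree_path_lengths(rooted)
        for a in taxa:
            for b in taxa:
                assert rec[(a, b)] == pytest.approx(true_d[(a, b)], abs=1e-9)
        back = ts.unroot(rooted)
        assert back.splits() == unrooted.splits()

    def test_missing_outgroup_errors(self, toy_matrix):
        tree = ts.region_tree(toy_matrix, root=False)
        with pytest.raises(KeyError, match="nope"):
            ts.root_on_outgroup(tree, "nope")

    def test_clades_of_regions_sharing_subclones_group_together(self):
        """Two groups of regions dominated by disjoint branch clones separate."""
        rows = {}
        pos = 1
        for _ in range(10):  # trunk sites
            rows[make_site(pos)] = (1, 1, 1, 1)
            pos += 1
        for _ in range(15):  # clade {r1, r2}
            rows[make_site(pos)] = (1, 1, 0, 0)
            pos += 1
        for _ in range(15):  # clade {r3, r4}
            rows[make_site(pos)] = (0, 0, 1, 1)
            pos += 1
        m = matrix_from_rows(rows, regions=["r1", "r2", "r3", "r4"])
        tree = ts.region_tree(m)
        split = frozenset(
            [frozenset(["r1", "r2"]), frozenset(["r3", "r4", "germline"])]
        )
        assert split in tree.splits()

    def test_ascii_render_mentions_all_leaves(self, toy_matrix):
        tree = ts.region_tree(toy_matrix)
        art = ascii_tree(tree)
        for name in [*toy_matrix.regions, "germline"]:
            assert name in art
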