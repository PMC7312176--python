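"""Distance-matrix and neighbor-joining tests.

NJ is validated against its defining consistency property: on an additive
matrix (path lengths of a tree with positive branch lengths) it must
recover the generating topology and metric exactly.  Random additive
matrices are built by an independent path-length computation over random
trees, and dendropy parses the emitted Newick as the external check.
"""

import itertools

import dendropy
import numpy as np
import pytest

from pcnv import (
    DistanceMatrix,
    PCNVector,
    compute_pcnv,
    euclidean_distance_matrix,
    nj_tree,
    to_newick,
)
from pcnv.simulate import SimulationConfig, make_clusters


def vec(vid, comps):
    return PCNVector(tuple(comps), vid, 100)


def random_additive_matrix(rng, n_taxa):
    """Build a random binary tree, then its leaf path-length matrix.

    Returns (labels, matrix, leaf-distance dict). Independent of the NJ
    code: the tree is grown by random leaf attachment and distances come
    from explicit path sums over the edge list.
    """
    # grow an unrooted binary tree by splitting random edges
    labels = [f"t{i}" for i in range(n_taxa)]
    edges = {}  # node -> {neighbor: length}

    def add_edge(a, b, w):
        edges.setdefault(a, {})[b] = w
        edges.setdefault(b, {})[a] = w

    def blen():
        return float(rng.uniform(0.1, 2.0))

    add_edge("t0", "t1", blen())
    internal = itertools.count()
    for leaf in labels[2:]:
        # pick a random existing edge and split it with a new internal node
        all_edges = [(a, b) for a in edges for b in edges[a] if a < b]
        a, b = all_edges[rng.integers(len(all_edges))]
        w = edges[a].pop(b)
        edges[b].pop(a)
        mid = f"i{next(internal)}"
        u = float(rng.uniform(0.05, 0.95)) * w
        add_edge(a, mid, u)
        add_edge(mid, b, w - u)
        add_edge(mid, leaf, blen())

    def path_length(src, dst):
        # BFS over the tree
        stack = [(src, 0.0, None)]
        while stack:
            node, dist, prev = stack.pop()
            if node == dst:
                return dist
            for nb, w in edges[node].items():
                if nb != prev:
                    stack.append((nb, dist + w, node))
        raise AssertionError("disconnected tree")

    d = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            d[i, j] = d[j, i] = path_length(labels[i], labels[j])
    return labels, d


def newick_leaf_distances(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1, t2 in itertools.combinations(tree.taxon_namespace, 2):
        out[frozenset((t1.label, t2.label))] = pdm.patristic_distance(t1, t2)
    return out


class TestDistanceMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(("a", "b"), np.array([[1.0, 2.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="duplicate"):
            DistanceMatrix(("a", "a"), np.zeros((2, 2)))

    def test_identical_vectors_distance_zero(self):
        a = vec("a", range(18))
        b = vec("b", range(18))
        dm = euclidean_distance_matrix([a, b])
        assert dm.d[0, 1] == 0.0

    def test_3_4_5_triangle(self):
        comps = [0.0] * 18
        c2 = comps.copy(); c2[0] = 3.0; c2[1] = 4.0
        dm = euclidean_distance_matrix([vec("a", comps), vec("b", c2)])
        assert dm.d[0, 1] == 5.0

    def test_metric_on_random_vectors(self):
        rng = np.random.default_rng(0)
        vecs = [vec(f"v{i}", rng.normal(size=18)) for i in range(8)]
        dm = euclidean_distance_matrix(vecs)
        assert np.all(dm.d >= 0)
        np.testing.assert_array_equal(dm.d, dm.d.T)
        n = len(dm)
        for i, j, k in itertools.permutations(range(n), 3):
            assert dm.d[i, j] <= dm.d[i, k] + dm.d[k, j] + 1e-12

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance_matrix([vec("a", range(18))])


class TestNJ:
    def test_four_taxon_known_tree(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) — additive distances by path sums
        labels = ("a", "b", "c", "d")
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(labels, d))
        dists = tree.leaf_distances()
        for i, j in itertools.combinations(range(4), 2):
            assert dists[frozenset((labels[i], labels[j]))] == pytest.approx(
                d[i, j], abs=1e-9
            )
        # split {a,b} | {c,d} must be present
        nwk = to_newick(tree)
        ext = newick_leaf_distances(nwk)
        assert ext[frozenset(("a", "b"))] == pytest.approx(3.0, abs=1e-9)

    def test_equidistant_matrix_gives_equal_pendants(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = nj_tree(DistanceMatrix(("a", "b", "c", "d"), d))
        leaves = {lf.name: lf.length for lf in tree.root.leaves()}
        assert len(set(round(v, 12) for v in leaves.values())) == 1

    def test_nj_consistency_random_additive(self):
        # the defining property: exact recovery on additive input
        rng = np.random.default_rng(7)
        for rep in range(50):
            n = int(rng.integers(4, 9))
            labels, d = random_additive_matrix(rng, n)
            tree = nj_tree(DistanceMatrix(tuple(labels), d))
            got = tree.leaf_distances()
            for i, j in itertools.combinations(range(n), 2):
                assert got[frozenset((labels[i], labels[j]))] == pytest.approx(
                    d[i, j], abs=1e-9
                )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        labels, d = random_additive_matrix(rng, 6)
        dm = DistanceMatrix(tuple(labels), d)
        base = nj_tree(dm).leaf_distances()
        perm = rng.permutation(6)
        permuted = nj_tree(dm.permuted(perm)).leaf_distances()
        for key, val in base.items():
            assert permuted[key] == pytest.approx(val, abs=1e-9)

    def test_agrees_with_skbio_on_additive_input(self):
        # independent NJ implementation as cross-check
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(11)
        labels, d = random_additive_matrix(rng, 7)
        ours = nj_tree(DistanceMatrix(tuple(labels), d)).leaf_distances()
        sk = skbio_nj(SkbioDM(d, ids=labels))
        for i, j in itertools.combinations(labels, 2):
            assert ours[frozenset((i, j))] == pytest.approx(
                sk.find(i).distance(sk.find(j)), abs=1e-6
            )

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(("a", "b"), np.zeros((2, 2))))

    def test_negative_branch_clamped_and_recorded(self):
        # deliberately non-additive matrix that forces a negative estimate
        d = np.array(
            [
                [0, 1, 10, 10],
                [1, 0, 1, 10],
                [10, 1, 0, 1],
                [10, 10, 1, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(("a", "b", "c", "d"), d))
        clamped = [
            n for n in tree.root.leaves() if n.pre_clamp_length is not None
        ]
        for n in tree.root.leaves():
            assert n.length >= 0
        allowed = nj_tree(
            DistanceMatrix(("a", "b", "c", "d"), d), allow_negative=True
        )
        assert any(lf.length < 0 for lf in allowed.root.leaves()) == bool(clamped)


class TestNewick:
    def test_three_taxon_star_form(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        nwk = to_newick(nj_tree(DistanceMatrix(("a", "b", "c"), d)))
        assert nwk.endswith(";")
        assert nwk.count("(") == 1  # single star

    def test_roundtrip_preserves_topology_and_lengths(self):
        rng = np.random.default_rng(5)
        labels, d = random_additive_matrix(rng, 6)
        tree = nj_tree(DistanceMatrix(tuple(labels), d))
        ext = newick_leaf_distances(to_newick(tree))
        for key, val in tree.leaf_distances().items():
            assert ext[key] == pytest.approx(val, abs=1e-6)

    def test_labels_with_specials_quoted(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        nwk = to_newick(nj_tree(DistanceMatrix(("st. 1", "b", "c"), d)))
        assert "'st. 1'" in nwk
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == {"st. 1", "b", "c"}


class TestEndToEndTree:
    def test_clusters_are_monophyletic(self):
        ds = make_clusters(
            SimulationConfig(n_clusters=2, per_cluster=4, length=2000, sub_rate=0.01, seed=3)
        )
        dm = euclidean_distance_matrix([compute_pcnv(r) for r in ds.records])
        tree = dendropy.Tree.get(data=to_newick(nj_tree(dm)), schema="newick")
        tree.encode_bipartitions()
        cluster1 = {r.id for r in ds.records if ds.labels[r.id] == "cluster1"}
        taxa = set(tree.taxon_namespace.labels())
        split_found = any(
            {t.label for t in bip.leafset_taxa(tree.taxon_namespace)} in (cluster1, taxa - cluster1)
            for bip in tree.bipartition_encoding
        )
        assert split_found
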