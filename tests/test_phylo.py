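"""Neighbor joining, midpoint rooting and the monophyly screen."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from pteridosurvey.distances import DistanceMatrix
from pteridosurvey.io import SurveyChecklist
from pteridosurvey.phylo import (
    assess_monophyly,
    leaf_path_lengths,
    midpoint_root,
    neighbor_joining,
    prune_undefined,
    read_newick,
    write_newick,
)

from conftest import make_checklist


def dm_from_array(ids, d, min_overlap=1) -> DistanceMatrix:
    d = np.asarray(d, dtype=float)
    ov = np.full(d.shape, 10_000, dtype=np.int64)
    return DistanceMatrix(tuple(ids), d, ov, min_overlap)


def random_ultrametric(rng, n) -> tuple[np.ndarray, list[str]]:
    """Random UPGMA-style ultrametric matrix via random coalescent heights."""
    ids = [f"L{i:02d}" for i in range(n)]
    clusters = {i: [i] for i in range(n)}
    height = {i: 0.0 for i in range(n)}
    d = np.zeros((n, n))
    h = 0.0
    nxt = n
    while len(clusters) > 1:
        h += rng.uniform(0.05, 0.5)
        a, b = rng.choice(list(clusters), size=2, replace=False)
        for x in clusters[a]:
            for y in clusters[b]:
                d[x, y] = d[y, x] = 2 * h
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        height[nxt] = h
        nxt += 1
    return d, ids


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        ids = ["A", "B", "C", "D"]
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        tree = neighbor_joining(dm_from_array(ids, d))
        paths = leaf_path_lengths(tree)
        for i in range(4):
            for j in range(i + 1, 4):
                key = tuple(sorted((ids[i], ids[j])))
                assert paths[key] == pytest.approx(d[i][j], abs=1e-9)

    def test_three_taxa_closed_form(self):
        ids = ["A", "B", "C"]
        d = [[0, 2, 4], [2, 0, 4], [4, 4, 0]]
        tree = neighbor_joining(dm_from_array(ids, d))
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_ultrametric_path_metric_recovered(self, rng):
        for _ in range(5):
            n = int(rng.integers(5, 12))
            d, ids = random_ultrametric(rng, n)
            tree = neighbor_joining(dm_from_array(ids, d))
            paths = leaf_path_lengths(tree)
            for i in range(n):
                for j in range(i + 1, n):
                    key = tuple(sorted((ids[i], ids[j])))
                    assert paths[key] == pytest.approx(d[i, j], abs=1e-9)

    def test_undefined_pairs_rejected_with_advice(self):
        d = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
        ov = np.array([[100, 100, 0], [100, 100, 100], [0, 100, 100]])
        dm = DistanceMatrix(("a", "b", "c"), d, ov, 10)
        with pytest.raises(ValueError, match="remove one specimen"):
            neighbor_joining(dm)

    def test_matches_skbio_topology_on_additive_matrix(self, rng):
        """Cross-check against an independent NJ implementation."""
        skbio = pytest.importorskip("skbio")
        n = 8
        d, ids = random_ultrametric(rng, n)
        # perturb slightly so there are no Q ties, then both NJ runs
        # must agree on topology (RF distance 0)
        noise = rng.uniform(0, 1e-3, size=(n, n))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        d = d + noise
        ours = neighbor_joining(dm_from_array(ids, d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(
            data=ours.as_string(schema="newick"),
            schema="newick",
            taxon_namespace=tns,
        )
        t2 = dendropy.Tree.get(
            data=str(theirs),
            schema="newick",
            taxon_namespace=tns,
        )
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert rf == 0

    def test_prune_undefined_minimal(self):
        d = np.array(
            [
                [0, 0.1, np.nan, 0.3],
                [0.1, 0, 0.2, 0.3],
                [np.nan, 0.2, 0, 0.1],
                [0.3, 0.3, 0.1, 0],
            ]
        )
        ov = np.where(np.isnan(d), 0, 1000).astype(np.int64)
        np.fill_diagonal(ov, 1000)
        dm = DistanceMatrix(("a", "b", "c", "d"), d, ov, 10)
        pruned, removed = prune_undefined(dm)
        assert len(removed) == 1
        assert pruned.defined.all()


class TestMidpointRoot:
    def test_symmetric_cherry(self):
        ids = ["A", "B", "C"]
        d = [[0, 2, 4], [2, 0, 4], [4, 4, 0]]
        rooted = midpoint_root(neighbor_joining(dm_from_array(ids, d)))
        # longest path A..C or B..C = 4; root 2.0 from C
        depths = {}
        for lf in rooted.leaf_node_iter():
            node, total = lf, 0.0
            while node.parent_node is not None:
                total += node.edge.length or 0.0
                node = node.parent_node
            depths[lf.taxon.label] = total
        assert depths["C"] == pytest.approx(2.0)

    def test_caterpillar_longest_path_brute_force(self, rng):
        d, ids = random_ultrametric(rng, 9)
        tree = neighbor_joining(dm_from_array(ids, d))
        paths = leaf_path_lengths(tree)
        dmax = max(paths.values())
        rooted = midpoint_root(tree)
        depths = {}
        for lf in rooted.leaf_node_iter():
            node, total = lf, 0.0
            while node.parent_node is not None:
                total += node.edge.length or 0.0
                node = node.parent_node
            depths[lf.taxon.label] = total
        assert max(depths.values()) == pytest.approx(dmax / 2, abs=1e-9)

    def test_path_lengths_preserved(self, rng):
        d, ids = random_ultrametric(rng, 7)
        tree = neighbor_joining(dm_from_array(ids, d))
        before = leaf_path_lengths(tree)
        after = leaf_path_lengths(midpoint_root(tree))
        for key, val in before.items():
            assert after[key] == pytest.approx(val, abs=1e-9)

    def test_zero_length_tree_warns(self):
        ids = ["A", "B", "C", "D"]
        d = np.zeros((4, 4))
        tree = neighbor_joining(dm_from_array(ids, d))
        with pytest.warns(UserWarning, match="zero"):
            rooted = midpoint_root(tree)
        assert rooted.is_rooted


def _random_labeled_tree(rng, n_taxa, max_specimens=3):
    """Random rooted binary tree whose leaves are specimens of taxa."""
    labels = []
    taxon_of = {}
    for t in range(n_taxa):
        k = int(rng.integers(1, max_specimens + 1))
        for j in range(k):
            sid = f"T{t:02d}_s{j}"
            labels.append(sid)
            taxon_of[sid] = f"Taxon {t:02d}"
    rng.shuffle(labels)
    tns = dendropy.TaxonNamespace(labels)
    nodes = [
        dendropy.Node(taxon=tns.get_taxon(lb)) for lb in labels
    ]
    for node in nodes:
        node.edge.length = float(rng.uniform(0.01, 1.0))
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[max(i, j)], nodes[min(i, j)]
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.01, 1.0))
        parent.add_child(a)
        parent.add_child(b)
        nodes = [x for x in nodes if x not in (a, b)] + [parent]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    cl = make_checklist(
        {
            taxon: [s for s, t in taxon_of.items() if t == taxon]
            for taxon in set(taxon_of.values())
        }
    )
    return tree, cl, taxon_of


def brute_force_monophyly(tree, taxon_of) -> dict[str, str]:
    """Oracle: enumerate every node's leaf set and look for exact matches."""
    clades = []
    for node in tree.preorder_node_iter():
        clades.append(
            frozenset(lf.taxon.label for lf in node.leaf_iter())
        )
    out = {}
    for taxon in sorted(set(taxon_of.values())):
        members = frozenset(
            s for s, t in taxon_of.items() if t == taxon
        )
        if len(members) == 1:
            out[taxon] = "trivial"
        else:
            out[taxon] = (
                "monophyletic"
                if members in clades
                else "non-monophyletic"
            )
    return out


class TestMonophyly:
    def test_clade_is_monophyletic(self):
        tree = dendropy.Tree.get(
            data="((x1:1,(x2:1,x3:1):1):1,(y1:1,y2:1):1);",
            schema="newick",
        )
        tree.is_rooted = True
        cl = make_checklist({"X a": ["x1", "x2", "x3"], "Y b": ["y1", "y2"]})
        result = assess_monophyly(tree, cl)
        assert result == {"X a": "monophyletic", "Y b": "monophyletic"}

    def test_interleaved_taxon_flagged(self):
        tree = dendropy.Tree.get(
            data="((z1:1,(y1:1,z2:1):1):1,z3:1);", schema="newick"
        )
        tree.is_rooted = True
        cl = make_checklist({"Z a": ["z1", "z2", "z3"], "Y b": ["y1"]})
        result = assess_monophyly(tree, cl)
        assert result["Z a"] == "non-monophyletic"
        assert result["Y b"] == "trivial"

    def test_agrees_with_bruteforce_on_random_trees(self, rng):
        for _ in range(50):
            tree, cl, taxon_of = _random_labeled_tree(
                rng, n_taxa=int(rng.integers(3, 8))
            )
            assert assess_monophyly(tree, cl) == brute_force_monophyly(
                tree, taxon_of
            )

    def test_rotation_invariance(self, rng):
        tree, cl, taxon_of = _random_labeled_tree(rng, 6)
        before = assess_monophyly(tree, cl)
        for node in tree.preorder_node_iter():
            if len(node.child_nodes()) == 2:
                a, b = node.child_nodes()
                node.remove_child(a)
                node.add_child(a)  # reverse child order
        assert assess_monophyly(tree, cl) == before

    def test_missing_specimen_raises(self):
        tree = dendropy.Tree.get(data="(x1:1,y1:1);", schema="newick")
        tree.is_rooted = True
        cl = make_checklist({"X a": ["x1", "x2"], "Y b": ["y1"]})
        with pytest.raises(KeyError, match="x2"):
            assess_monophyly(tree, cl)
        relaxed = assess_monophyly(tree, cl, allow_missing=True)
        assert relaxed["X a"] == "trivial"

    def test_unrooted_rejected(self):
        tree = dendropy.Tree.get(data="(x1:1,y1:1,z1:1);", schema="newick")
        tree.is_rooted = False
        cl = make_checklist({"X a": ["x1"], "Y b": ["y1"], "Z c": ["z1"]})
        with pytest.raises(ValueError, match="rooted"):
            assess_monophyly(tree, cl)


class TestNewickIO:
    def test_roundtrip(self, rng, tmp_path):
        d, ids = random_ultrametric(rng, 6)
        tree = midpoint_root(neighbor_joining(dm_from_array(ids, d)))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        before = leaf_path_lengths(tree)
        after = leaf_path_lengths(back)
        assert set(before) == set(after)
        for key in before:
            assert after[key] == pytest.approx(before[key], rel=1e-5)
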