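"""Distance-tree construction and per-taxon monophyly screening.

A neighbor-joining tree built from the p-distance matrix gives a fast,
deterministic screen for species whose specimens do not group together —
the pattern that flags putative hybrids and species complexes in barcode
surveys.  This is a screen on a distance tree, not a likelihood analysis:
no support values are computed, and zero-length internal edges produced by
identical sequences are retained in the resolved binary topology.

Trees are dendropy objects throughout and serialize to standard Newick.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import dendropy
import numpy as np

from .distances import DistanceMatrix
from .io import SurveyChecklist

__all__ = [
    "assess_monophyly",
    "leaf_path_lengths",
    "midpoint_root",
    "neighbor_joining",
    "prune_undefined",
    "read_newick",
    "write_newick",
]


def prune_undefined(dm: DistanceMatrix) -> tuple[DistanceMatrix, list[str]]:
    """Remove the fewest specimens needed to leave every pair defined.

    Greedy: repeatedly drop the specimen with the most undefined pairs
    (ties broken toward the lexicographically last id, so that of two
    interchangeable partial sequences the first-sorted one survives).
    Returns the pruned matrix and the removed ids.
    """
    keep = list(range(dm.n))
    removed: list[str] = []
    while True:
        sub = ~dm.defined[np.ix_(keep, keep)]
        counts = sub.sum(axis=1)
        if counts.sum() == 0:
            break
        worst = max(
            range(len(keep)),
            key=lambda k: (counts[k], dm.specimen_ids[keep[k]]),
        )
        removed.append(dm.specimen_ids[keep[worst]])
        keep.pop(worst)
    if not removed:
        return dm, []
    sel = np.array(keep, dtype=int)
    pruned = DistanceMatrix(
        tuple(dm.specimen_ids[i] for i in keep),
        dm.d[np.ix_(sel, sel)].copy(),
        dm.overlap[np.ix_(sel, sel)].copy(),
        dm.min_overlap,
    )
    return pruned, removed


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining on the Q-criterion.

    Requires every pair defined and n >= 3.  Ties on Q are broken by
    merging the pair whose (lexicographically sorted) cluster labels are
    smallest, where a cluster's label is its smallest leaf id; this makes
    topologies reproducible for matrices with many identical sequences.
    Negative branch lengths are clamped to 0 with the deficit moved to the
    sister edge (the pair's total length is preserved).
    """
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 specimens")
    if not dm.defined.all():
        bad = np.argwhere(~dm.defined)
        i, j = bad[0]
        raise ValueError(
            "distance matrix has undefined pairs (e.g. "
            f"{dm.specimen_ids[i]!r} vs {dm.specimen_ids[j]!r}); impute the "
            "missing distances or remove one specimen of each pair before "
            "tree building"
        )

    tns = dendropy.TaxonNamespace(list(dm.specimen_ids))
    nodes: list[dendropy.Node] = []
    labels: list[str] = []
    for sid in dm.specimen_ids:
        node = dendropy.Node(taxon=tns.get_taxon(sid))
        nodes.append(node)
        labels.append(sid)

    size = 2 * n - 2
    D = np.zeros((size, size))
    D[:n, :n] = dm.d
    active = list(range(n))
    next_idx = n

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        iu = np.triu_indices(r, k=1)
        qvals = Q[iu]
        qmin = qvals.min()
        tie_positions = np.flatnonzero(qvals == qmin)
        best = min(
            tie_positions,
            key=lambda p: tuple(
                sorted((labels[active[iu[0][p]]], labels[active[iu[1][p]]]))
            ),
        )
        ai, aj = iu[0][best], iu[1][best]
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (R[ai] - R[aj]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0

        parent = dendropy.Node()
        nodes[i].edge.length = float(li)
        nodes[j].edge.length = float(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))

        k = next_idx
        next_idx += 1
        for a in active:
            if a in (i, j):
                continue
            dk = 0.5 * (D[i, a] + D[j, a] - dij)
            D[k, a] = dk
            D[a, k] = dk
        active = [a for a in active if a not in (i, j)] + [k]

    # final 3-cluster star: closed-form 3-point branch lengths
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    root = dendropy.Node()
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        nodes[idx].edge.length = float(ln)
        root.add_child(nodes[idx])

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def _adjacency(
    tree: dendropy.Tree,
) -> dict[dendropy.Node, list[tuple[dendropy.Node, float]]]:
    adj: dict[dendropy.Node, list[tuple[dendropy.Node, float]]] = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            ln = child.edge.length or 0.0
            adj.setdefault(node, []).append((child, ln))
            adj.setdefault(child, []).append((node, ln))
    return adj


def leaf_path_lengths(
    tree: dendropy.Tree,
) -> dict[tuple[str, str], float]:
    """Patristic distance for every unordered leaf pair, keyed sorted."""
    adj = _adjacency(tree)
    leaves = [lf for lf in tree.leaf_node_iter()]
    out: dict[tuple[str, str], float] = {}
    for leaf in leaves:
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            node = stack.pop()
            for nbr, ln in adj.get(node, ()):
                if nbr not in dist:
                    dist[nbr] = dist[node] + ln
                    stack.append(nbr)
        for other in leaves:
            if other is leaf:
                continue
            key = tuple(sorted((leaf.taxon.label, other.taxon.label)))
            out[key] = dist[other]
    return out


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a copy of the tree at the midpoint of its longest leaf-to-leaf path.

    Ties on path length are broken toward the lexicographically smallest
    leaf-name pair.  A tree whose every path has length zero is rooted on
    its first internal edge, with a warning.
    """
    tree = tree.clone(depth=1)
    paths = leaf_path_lengths(tree)
    if not paths:
        raise ValueError("tree has fewer than 2 leaves")
    dmax = max(paths.values())

    if dmax == 0.0:
        warnings.warn(
            "all path lengths are zero; rooting on first internal edge",
            stacklevel=2,
        )
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and not node.is_leaf():
                _insert_root_on_edge(tree, node, 0.0)
                tree.is_rooted = True
                return tree
        # pathological: no internal edges (star); root stays at seed
        tree.is_rooted = True
        return tree

    pair = min(k for k, v in paths.items() if v == dmax)
    name_to_leaf = {
        lf.taxon.label: lf for lf in tree.leaf_node_iter()
    }
    start, end = name_to_leaf[pair[0]], name_to_leaf[pair[1]]

    # recover the node path from start to end
    adj = _adjacency(tree)
    prev: dict[dendropy.Node, dendropy.Node] = {}
    dist = {start: 0.0}
    stack = [start]
    while stack:
        node = stack.pop()
        for nbr, ln in adj.get(node, ()):
            if nbr not in dist:
                dist[nbr] = dist[node] + ln
                prev[nbr] = node
                stack.append(nbr)
    path = [end]
    while path[-1] is not start:
        path.append(prev[path[-1]])
    path.reverse()  # start .. end

    half = dmax / 2.0
    cum = 0.0
    for u, v in zip(path, path[1:]):
        ln = _edge_length_between(u, v)
        if cum + ln >= half:
            offset = half - cum  # distance from u along the (u, v) edge
            if v.parent_node is u:
                child, from_parent = v, offset
            else:
                child, from_parent = u, ln - offset
            if from_parent in (0.0, ln) and ln > 0:
                node = child.parent_node if from_parent == 0.0 else child
                if node.parent_node is None or node.is_leaf():
                    _insert_root_on_edge(tree, child, from_parent)
                else:
                    tree.reroot_at_node(node, update_bipartitions=False)
            else:
                _insert_root_on_edge(tree, child, from_parent)
            tree.is_rooted = True
            return tree
        cum += ln
    raise AssertionError("midpoint not found on longest path")  # pragma: no cover


def _edge_length_between(u: dendropy.Node, v: dendropy.Node) -> float:
    child = v if v.parent_node is u else u
    return child.edge.length or 0.0


def _insert_root_on_edge(
    tree: dendropy.Tree, child: dendropy.Node, from_parent: float
) -> None:
    parent = child.parent_node
    total = child.edge.length or 0.0
    parent.remove_child(child)
    new_node = parent.new_child(edge_length=from_parent)
    new_node.add_child(child)
    child.edge.length = total - from_parent
    tree.reroot_at_node(new_node, update_bipartitions=False)


def _mrca(leaves: list[dendropy.Node]) -> dendropy.Node:
    """Most recent common ancestor of the given leaf nodes."""
    def chain(node: dendropy.Node) -> list[dendropy.Node]:
        out = [node]
        while out[-1].parent_node is not None:
            out.append(out[-1].parent_node)
        return out

    common = set(chain(leaves[0]))
    for leaf in leaves[1:]:
        common &= set(chain(leaf))
    # the common ancestor furthest from the root is first along any chain
    for node in chain(leaves[0]):
        if node in common:
            return node
    raise AssertionError("disjoint leaf chains")  # pragma: no cover


def assess_monophyly(
    tree: dendropy.Tree,
    checklist: SurveyChecklist,
    allow_missing: bool = False,
) -> dict[str, str]:
    """Classify each taxon as monophyletic, non-monophyletic or trivial.

    Taxa with a single specimen in the tree are 'trivial'.  A multi-specimen
    taxon is monophyletic iff the smallest clade containing all its
    specimens contains no other taxon's specimen.  Taxa with no specimens in
    the tree are skipped; a taxon with only some of its specimens present
    raises an error (the tree does not match the checklist) unless
    ``allow_missing`` is set, in which case the present specimens are
    assessed (the pipeline uses this after pruning unplaceable partial
    sequences).
    """
    if not tree.is_rooted:
        raise ValueError("monophyly assessment requires a rooted tree")
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    by_taxon: dict[str, list[str]] = {}
    for sid, taxon in checklist.specimen_map.items():
        by_taxon.setdefault(taxon, []).append(sid)

    result: dict[str, str] = {}
    for taxon, sids in sorted(by_taxon.items()):
        present = [s for s in sids if s in leaf_labels]
        if not present:
            continue
        if len(present) < len(sids) and not allow_missing:
            missing = sorted(set(sids) - leaf_labels)
            raise KeyError(
                f"taxon {taxon!r}: specimen(s) {missing} absent from tree"
            )
        if len(present) == 1:
            result[taxon] = "trivial"
            continue
        leaves = [
            lf for lf in tree.leaf_node_iter()
            if lf.taxon.label in set(present)
        ]
        mrca = _mrca(leaves)
        clade_size = sum(1 for _ in mrca.leaf_iter())
        result[taxon] = (
            "monophyletic" if clade_size == len(present) else "non-monophyletic"
        )
    return result


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write Newick with branch lengths at 6 significant digits."""
    tree.write(
        path=str(path),
        schema="newick",
        real_value_format_specifier=".6g",
        suppress_rooting=False,
    )


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
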