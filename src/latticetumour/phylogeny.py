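"""Trees from single-cell genotype matrices and from the true lineage.

Under infinite sites without back mutation the maximum-parsimony tree of a
noise-free genotype matrix is the perfect phylogeny, which this module
builds directly: mutations are grouped into clusters by identical
cell-membership columns, clusters are nested by containment, and each
cluster becomes an edge whose length is the number of mutations in it.
Matrices with incompatible column pairs (only possible with the noise
knobs switched on) fall back to a greedy compatibility ordering by column
support with lexicographic tie-breaks.

Edge lengths are always in mutation-count units; leaf labels are cell ids.
"""

from __future__ import annotations

import math
import random
import warnings

import dendropy
import numpy as np

from .engine import TumourState
from .sequencing import CellGenotypeMatrix

EULER_GAMMA = 0.5772156649015329


def build_tree(matrix: CellGenotypeMatrix) -> dendropy.Tree:
    """Perfect phylogeny (greedy for conflicted matrices) of a genotype matrix.

    All-identical cells yield a star tree with a single trunk.
    """
    if matrix.n_cells < 2:
        raise ValueError("need >= 2 cells to build a tree")
    data = matrix.data
    # cluster mutations by identical membership columns
    patterns, inverse = np.unique(data.T, axis=0, return_inverse=True)
    sizes = np.bincount(inverse, minlength=len(patterns))  # mutations per cluster
    support = patterns.sum(axis=1)
    keep = support > 0  # drop mutations absent from every sampled cell
    order = sorted(
        np.nonzero(keep)[0],
        key=lambda c: (-int(support[c]), patterns[c].tobytes()),
    )
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    root = tree.seed_node
    root.edge.length = 0.0
    children: dict[int, dict[int, dendropy.Node]] = {id(root): {}}
    for i, cid in enumerate(matrix.cell_ids):
        node = root
        for c in order:
            if not patterns[c, i]:
                continue
            slot = children.setdefault(id(node), {})
            nxt = slot.get(c)
            if nxt is None:
                nxt = node.new_child(edge_length=float(sizes[c]))
                slot[c] = nxt
            node = nxt
        leaf = node.new_child(edge_length=0.0)
        leaf.taxon = tns.require_taxon(label=str(int(cid)))
    # a cluster private to one cell is that cell's terminal edge: collapse
    # the zero-length pendant below it
    for leaf in list(tree.leaf_node_iter()):
        parent = leaf.parent_node
        if (
            parent is not None
            and parent is not tree.seed_node
            and len(parent.child_nodes()) == 1
            and parent.taxon is None
        ):
            parent.taxon = leaf.taxon
            parent.remove_child(leaf)
    return tree


def true_sampled_tree(state: TumourState, cell_ids) -> dendropy.Tree:
    """Restriction of the simulator's lineage tree to the sampled cells.

    Unary internal nodes are suppressed (their mutation counts accumulate
    onto the compressed edge); internal nodes keep the recorded division
    time as a ``time`` attribute.  Each live cell occupies its own leaf
    node of the lineage, so leaves map one-to-one onto sampled cells.
    """
    cell_ids = np.asarray(cell_ids)
    tree_rec = state.lineage
    cell_nodes = {state.cells[int(c)].node: int(c) for c in cell_ids}
    if len(cell_nodes) != len(cell_ids):
        raise ValueError("sampled cells do not map to distinct lineage nodes")
    nodes = np.fromiter(cell_nodes.keys(), dtype=np.int64)
    counts = tree_rec.subtree_cell_counts(nodes)
    tns = dendropy.TaxonNamespace()
    out = dendropy.Tree(taxon_namespace=tns)
    out.is_rooted = True
    parent = tree_rec.parent
    mut_n = tree_rec.mut_n
    times = tree_rec.time
    # bottom-up assembly: for each marked node collect built (subtree, edge) pairs
    pending: dict[int, list] = {}
    for v in range(len(parent) - 1, -1, -1):
        if counts[v] == 0:
            continue
        entries = pending.pop(v, [])
        if v in cell_nodes:
            nd = dendropy.Node()
            nd.taxon = tns.require_taxon(label=str(cell_nodes[v]))
            nd.time = times[v]
            result = (nd, float(mut_n[v]))
        elif len(entries) == 1:
            child_nd, elen = entries[0]
            result = (child_nd, elen + float(mut_n[v]))
        else:
            nd = dendropy.Node()
            nd.time = times[v]
            for child_nd, elen in entries:
                nd.add_child(child_nd)
                child_nd.edge.length = elen
            result = (nd, float(mut_n[v]))
        if v == 0:
            # keep an explicit root; the single child edge is the trunk
            root = out.seed_node
            root.time = 0.0
            nd, elen = result
            root.add_child(nd)
            nd.edge.length = elen
        else:
            pending.setdefault(parent[v], []).append(result)
    return out


def branch_lengths(tree: dendropy.Tree) -> np.ndarray:
    """All edge lengths (mutation units), sorted ascending."""
    out = [
        e.length
        for e in tree.preorder_edge_iter()
        if e.head_node is not tree.seed_node and e.length is not None
    ]
    return np.sort(np.asarray(out, dtype=float))


def branching_times(tree: dendropy.Tree) -> np.ndarray:
    """Sorted internal-node times; falls back to root-distances in mutation
    units (with a warning) when division times were not recorded."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    if all(hasattr(n, "time") for n in internals):
        return np.sort(np.asarray([n.time for n in internals], dtype=float))
    warnings.warn(
        "tree has no node times; using mutation-depth proxy for branching times",
        stacklevel=2,
    )
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return np.sort(np.asarray([n.root_distance for n in internals], dtype=float))


def _leaf_depths(tree: dendropy.Tree, unit: str = "edges") -> np.ndarray:
    depths = []
    for leaf in tree.leaf_node_iter():
        d = 0.0
        nd = leaf
        while nd.parent_node is not None:
            d += 1.0 if unit == "edges" else (nd.edge.length or 0.0)
            nd = nd.parent_node
        depths.append(d)
    return np.asarray(depths)


def _colless_once(tree: dendropy.Tree, seed: int) -> float:
    t = tree.clone(depth=1)
    t.resolve_polytomies(rng=random.Random(seed))
    total = 0
    counts = {}
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            counts[id(nd)] = 1
        else:
            ch = [counts[id(c)] for c in nd.child_nodes()]
            counts[id(nd)] = sum(ch)
            if len(ch) == 2:
                total += abs(ch[0] - ch[1])
    return float(total)


def _pairwise_tip_structure(tree: dendropy.Tree):
    """Pairwise tip path distances (branch-length units) and the depths of
    the corresponding MRCA nodes, one entry per unordered tip pair."""
    rd = {}
    depth_e = {}
    for nd in tree.preorder_node_iter():
        p = nd.parent_node
        rd[id(nd)] = (rd[id(p)] + (nd.edge.length or 0.0)) if p else 0.0
        depth_e[id(nd)] = (depth_e[id(p)] + 1) if p else 0
    tipdists, mrca_depths = [], []
    leafsets = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            leafsets[id(nd)] = np.asarray([rd[id(nd)]])
        else:
            groups = [leafsets.pop(id(c)) for c in nd.child_nodes()]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    cross = groups[a][:, None] + groups[b][None, :] - 2.0 * rd[id(nd)]
                    tipdists.append(cross.ravel())
                    mrca_depths.append(
                        np.full(cross.size, rd[id(nd)], dtype=float)
                    )
            leafsets[id(nd)] = np.concatenate(groups)
    if tipdists:
        return np.concatenate(tipdists), np.concatenate(mrca_depths)
    return np.empty(0), np.empty(0)


def _stats(x: np.ndarray) -> dict:
    if len(x) == 0:
        return {"mean": math.nan, "median": math.nan, "sd": math.nan, "sum": 0.0}
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "sum": float(np.sum(x)),
    }


def tree_statistics(tree: dendropy.Tree, seed: int = 0,
                    n_refinements: int = 100) -> dict:
    """Balance indices (Sackin, Colless, with Yule/PDA normalisations),
    cophenetic-distance statistics, branch-length statistics and maximum
    node depth.

    Multifurcations are resolved for Colless by seeded random binary
    refinement averaged over ``n_refinements`` draws (SD reported).
    """
    tree = tree.clone(depth=1)
    tree.suppress_unifurcations()  # unary trunk nodes would distort depths
    n = sum(1 for _ in tree.leaf_node_iter())
    if n < 2:
        raise ValueError("tree statistics need >= 2 leaves")
    depths = _leaf_depths(tree, unit="edges")
    sackin = float(depths.sum())
    harmonic = sum(1.0 / j for j in range(2, n + 1))
    is_binary = all(
        len(nd.child_nodes()) == 2
        for nd in tree.preorder_internal_node_iter()
        if nd.child_nodes()
    )
    reps = 1 if is_binary else n_refinements
    colless_draws = np.asarray([_colless_once(tree, seed + i) for i in range(reps)])
    colless = float(colless_draws.mean())
    tipdists, mrca_depths = _pairwise_tip_structure(tree)
    bl = branch_lengths(tree)
    internal_edge_depths = []
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf():
            d = 0
            p = nd
            while p.parent_node is not None:
                d += 1
                p = p.parent_node
            internal_edge_depths.append(d)
    return {
        "n_leaves": n,
        "sackin": sackin,
        "sackin_yule": (sackin - 2.0 * n * harmonic) / n,
        "sackin_pda": sackin / n**1.5,
        "colless": colless,
        "colless_sd": float(colless_draws.std(ddof=1)) if reps > 1 else 0.0,
        "colless_yule": (colless - n * math.log(n) - n * (EULER_GAMMA - 1.0 - math.log(2.0))) / n,
        "colless_pda": colless / n**1.5,
        "cophenetic_tip_stats": _stats(tipdists),
        "cophenetic_node_stats": _stats(mrca_depths),
        "branch_length_stats": _stats(bl),
        "max_node_depth": int(max(internal_edge_depths)) if internal_edge_depths else 0,
    }


def intermixing_by_bulk(tree: dendropy.Tree, tags: dict, rng=None,
                        n_permutations: int = 199):
    """How phylogenetically intermixed cells from different bulks are.

    Score: fraction of cross-bulk leaf pairs whose cophenetic distance is
    smaller than the median same-bulk pair distance (0 when bulks form
    exact clades, higher means more intermixing), with a permutation
    p-value over tag shuffles (lower tail: observed more segregated).
    """
    leaves = [nd.taxon.label for nd in tree.leaf_node_iter()]
    labels = np.asarray([tags[l] for l in leaves])
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    nL = len(leaves)
    D = np.zeros((nL, nL))
    for i in range(nL):
        for j in range(i + 1, nL):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[leaves[i]], taxa[leaves[j]])
    iu = np.triu_indices(nL, k=1)

    def score(lab):
        same = lab[iu[0]] == lab[iu[1]]
        d = D[iu]
        if not same.any() or same.all():
            raise ValueError("need both same-bulk and cross-bulk pairs")
        med_same = np.median(d[same])
        return float(np.mean(d[~same] < med_same))

    obs = score(labels)
    if n_permutations <= 0:
        return obs, float("nan")
    rng = np.random.default_rng() if rng is None else rng
    count = 0
    for _ in range(n_permutations):
        if score(rng.permutation(labels)) <= obs:
            count += 1
    return obs, float((1 + count) / (1 + n_permutations))


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted Robinson-Foulds distance, matching leaves by label."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    a.is_rooted = False  # compare unrooted topologies
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
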