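"""Per-domain tree building and incongruence calling.

Trees are built by neighbor joining on saturation-corrected p-distances,
with column-resampling bootstrap percentages as branch support.  Externally
computed trees (e.g. maximum-likelihood trees with aBayes supports) can be
plugged in through :func:`repchimera.io.read_newick` — every downstream
operation only needs a leaf-labelled tree with supports.

Incongruence between the nuclease and helicase trees is assessed two ways:
a tanglegram layout whose residual line crossings summarize topological
disagreement, and a per-leaf displacement statistic — one minus the Jaccard
similarity of the leaf's smallest phylogenetic neighborhoods in the two
(support-collapsed) trees.  A leaf whose neighborhoods barely overlap sits
among different relatives in the two trees, the signature of a domain swap.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Sequence

import dendropy
import numpy as np

from .io import GAP, Alignment, ValidationError, set_support, support_of

P_MAX = 0.95
MIN_SHARED_COLUMNS = 20


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(m, m.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.all(np.isfinite(m)):
            raise ValidationError("distance matrix must be finite")
        if np.any(np.diag(m) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise ValidationError("distances must be non-negative")


@dataclasses.dataclass(frozen=True)
class LeafDisplacement:
    id: str
    neighborhood_nuclease: frozenset[str]
    neighborhood_helicase: frozenset[str]
    displacement: float
    flagged: bool


# ---------------------------------------------------------------------------
# distances


def _encode(aln: Alignment) -> np.ndarray:
    arr = np.frombuffer(
        "".join(r.residues for r in aln.records).encode("ascii"), dtype=np.uint8
    ).reshape(len(aln), aln.length)
    return arr


def _pair_masks(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair per-column mismatch and shared (both non-gap) boolean arrays."""
    arr = _encode(aln)
    nongap = arr != ord(GAP)
    shared = nongap[:, None, :] & nongap[None, :, :]
    mismatch = (arr[:, None, :] != arr[None, :, :]) & shared
    return mismatch, shared


def _distances_from_counts(
    mm: np.ndarray, sh: np.ndarray, ids: Sequence[str], warn: bool = True
) -> np.ndarray:
    n = len(ids)
    zero = (sh == 0) & ~np.eye(n, dtype=bool)
    if zero.any() and warn:
        i, j = np.argwhere(zero)[0]
        raise ValidationError(
            f"sequences {ids[i]!r} and {ids[j]!r} share no alignment columns"
        )
    p = mm / np.maximum(sh, 1)
    p = np.minimum(p, P_MAX)
    d = -np.log(1.0 - p)
    np.fill_diagonal(d, 0.0)
    low = (sh < MIN_SHARED_COLUMNS) & ~np.eye(n, dtype=bool)
    if low.any():
        ok = d[~low]
        fill = float(ok.max()) if ok.size else -np.log(1.0 - P_MAX)
        if warn:
            warnings.warn(
                f"{int(low.sum() // 2)} sequence pair(s) share fewer than "
                f"{MIN_SHARED_COLUMNS} columns; their distance is set to the "
                "matrix maximum",
                stacklevel=3,
            )
        d[low] = fill
    return (d + d.T) / 2.0


def pairwise_distance(aln: Alignment) -> DistanceMatrix:
    """Saturation-corrected p-distances, ``d = -ln(1 - min(p, 0.95))``.

    ``p`` is the mismatch fraction over columns where both sequences hold a
    residue.  Pairs sharing fewer than 20 columns get the matrix maximum
    (with a warning); a pair sharing no columns is an error.
    """
    mm, sh = _pair_masks(aln)
    d = _distances_from_counts(
        mm.sum(axis=2), sh.sum(axis=2), aln.ids, warn=True
    )
    return DistanceMatrix(tuple(aln.ids), d)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree with deterministic tie-breaking.

    At each agglomeration step the pair minimizing the Q criterion is
    joined; exact ties resolve to the lowest row-major index pair.  Negative
    branch-length estimates are clamped to zero.  The result is an unrooted
    tree (trifurcation at the seed node) that recovers the generating
    topology exactly on additive matrices.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(ids)
    nodes: list[dendropy.Node] = []
    for label in ids:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes.append(node)
    D = dm.matrix.astype(float).copy()
    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # first occurrence = lowest (i, j)
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        vj = D[i, j] - vi
        parent = dendropy.Node()
        nodes[i].edge.length = max(0.0, vi)
        nodes[j].edge.length = max(0.0, vj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.empty((n - 1, n - 1))
        D2[: n - 2, : n - 2] = D[np.ix_(keep, keep)]
        D2[n - 2, : n - 2] = dnew[keep]
        D2[: n - 2, n - 2] = dnew[keep]
        D2[n - 2, n - 2] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    root = dendropy.Node()
    a.edge.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.edge.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.edge.length = max(0.0, 0.5 * (dac + dbc - dab))
    for child in (a, b, c):
        root.add_child(child)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions and support


def _leafset_below(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def bipartitions(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    """Non-trivial bipartitions keyed by the side without the reference leaf.

    The reference leaf is the alphabetically first label, so keys are
    comparable across trees on the same leaf set.
    """
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(all_leaves)
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = _leafset_below(node)
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.setdefault(side, node)
    return out


def bootstrap_support(
    aln: Alignment, n_reps: int = 100, seed: int = 0
) -> dendropy.Tree:
    """Point-estimate NJ tree with column-resampling bootstrap supports.

    Each replicate resamples alignment columns with replacement, rebuilds
    the NJ tree and records its bipartitions; the support of each internal
    edge of the point tree is the percentage of replicates containing that
    bipartition.
    """
    if n_reps < 10:
        raise ValidationError("need at least 10 bootstrap replicates")
    mm, sh = _pair_masks(aln)
    ids = aln.ids
    point = nj_tree(
        DistanceMatrix(
            tuple(ids),
            _distances_from_counts(mm.sum(axis=2), sh.sum(axis=2), ids),
        )
    )
    counts: dict[frozenset[str], int] = {key: 0 for key in bipartitions(point)}
    rng = np.random.default_rng(seed)
    L = aln.length
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        d = _distances_from_counts(
            mm[:, :, cols].sum(axis=2),
            sh[:, :, cols].sum(axis=2),
            ids,
            warn=False,
        )
        rep = nj_tree(DistanceMatrix(tuple(ids), d))
        for key in bipartitions(rep):
            if key in counts:
                counts[key] += 1
    for key, node in bipartitions(point).items():
        set_support(node, 100.0 * counts[key] / n_reps)
    return point


def collapse_low_support(
    tree: dendropy.Tree, threshold: float = 70.0
) -> dendropy.Tree:
    """Contract internal edges with support below the threshold.

    Leaves are never removed.  Edges whose support is unknown are retained
    with a warning.
    """
    out = tree.clone(depth=1)
    unknown = 0
    for node in list(out.preorder_internal_node_iter()):
        if node is out.seed_node or node.parent_node is None:
            continue
        s = support_of(node)
        if s is None:
            unknown += 1
            continue
        if s < threshold:
            node.edge.collapse()
    if unknown:
        warnings.warn(
            f"{unknown} internal edge(s) without support were retained",
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# tanglegram ordering


class _LNode:
    """Mutable layout node: children can be reordered freely."""

    __slots__ = ("children", "label", "leaves")

    def __init__(self, label=None):
        self.children: list[_LNode] = []
        self.label = label
        self.leaves: frozenset[str] = frozenset()

    def finalize(self) -> frozenset[str]:
        if self.label is not None:
            self.leaves = frozenset([self.label])
        else:
            self.leaves = frozenset().union(
                *(c.finalize() for c in self.children)
            )
            return self.leaves
        return self.leaves


def _layout_tree(tree: dendropy.Tree) -> _LNode:
    def build(node: dendropy.Node) -> _LNode:
        if node.is_leaf():
            return _LNode(node.taxon.label)
        ln = _LNode()
        ln.children = [build(c) for c in node.child_nodes()]
        return ln

    root = build(tree.seed_node)
    root.finalize()
    return root


def _leaf_order(root: _LNode) -> list[str]:
    out: list[str] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.label is not None:
            out.append(node.label)
        else:
            stack.extend(reversed(node.children))
    return out


def count_crossings(order1: Sequence[str], order2: Sequence[str]) -> int:
    """Line crossings of a tanglegram drawn with these two leaf orders."""
    pos2 = {label: i for i, label in enumerate(order2)}
    seq = np.array([pos2[label] for label in order1])
    n = len(seq)
    return int(sum((seq[i] > seq[i + 1 :]).sum() for i in range(n - 1)))


_MAX_PERM_CHILDREN = 6


def _optimize_side(root: _LNode, pos: dict[str, int]) -> None:
    """Reorder children to minimize crossings against fixed positions.

    Crossings decompose into independent per-node terms between child
    blocks, so choosing each node's child order (exhaustively for up to 6
    children, by barycenter otherwise) is optimal for a fixed other side.
    """

    def sorted_positions(node: _LNode) -> np.ndarray:
        return np.sort([pos[l] for l in node.leaves])

    def visit(node: _LNode) -> None:
        if node.label is not None:
            return
        for c in node.children:
            visit(c)
        kids = node.children
        m = len(kids)
        if m < 2:
            return
        spos = [sorted_positions(c) for c in kids]
        inv = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                if i != j:
                    # pairs (u in i, v in j) with pos[u] > pos[v]
                    not_inverted = np.searchsorted(
                        spos[i], spos[j], side="right"
                    ).sum()
                    inv[i, j] = len(spos[i]) * len(spos[j]) - not_inverted
        if m <= _MAX_PERM_CHILDREN:
            best, best_cost = None, None
            for perm in itertools.permutations(range(m)):
                cost = sum(
                    inv[perm[a], perm[b]]
                    for a in range(m)
                    for b in range(a + 1, m)
                )
                if best_cost is None or cost < best_cost:
                    best, best_cost = perm, cost
            node.children = [kids[i] for i in best]
        else:
            bary = [float(np.mean(s)) for s in spos]
            node.children = [
                kids[i] for i in sorted(range(m), key=lambda i: bary[i])
            ]

    visit(root)


def _rotation_states(root: _LNode) -> int:
    total = 1
    stack = [root]
    while stack:
        node = stack.pop()
        if node.label is None:
            k = len(node.children)
            total *= math.factorial(k) if k <= 10 else 10**9
            stack.extend(node.children)
            if total > 10**9:
                return 10**9
    return total


def _enumerate_orders(node: _LNode):
    """Yield every leaf order reachable by rotating internal nodes."""
    if node.label is not None:
        yield [node.label]
        return
    child_orders = [list(_enumerate_orders(c)) for c in node.children]
    for perm in itertools.permutations(range(len(node.children))):
        for combo in itertools.product(*(child_orders[i] for i in perm)):
            yield [label for part in combo for label in part]


_EXACT_STATE_LIMIT = 4096


def tanglegram_order(
    tree_nuclease: dendropy.Tree, tree_helicase: dendropy.Tree
) -> tuple[list[str], list[str], int]:
    """Crossing-minimized tanglegram leaf orders and the crossing count.

    Small instances (one tree with at most 4096 rotation states) are solved
    exactly: that tree's rotations are enumerated and, for each, the other
    tree is reordered optimally.  Larger instances use alternating optimal
    one-side reordering until no improvement.
    """
    l1 = set(lf.taxon.label for lf in tree_nuclease.leaf_node_iter())
    l2 = set(lf.taxon.label for lf in tree_helicase.leaf_node_iter())
    if l1 != l2:
        raise ValidationError(
            f"leaf sets differ: only in first tree {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}"
        )
    r1 = _layout_tree(tree_nuclease)
    r2 = _layout_tree(tree_helicase)
    s1, s2 = _rotation_states(r1), _rotation_states(r2)
    if min(s1, s2) <= _EXACT_STATE_LIMIT:
        swap = s2 < s1
        small, big = (r2, r1) if swap else (r1, r2)
        best = None
        for order_small in _enumerate_orders(small):
            pos = {label: i for i, label in enumerate(order_small)}
            _optimize_side(big, pos)
            order_big = _leaf_order(big)
            x = count_crossings(order_big, order_small)
            if best is None or x < best[2]:
                best = (order_big, order_small, x)
                if x == 0:
                    break
        order_big, order_small, crossings = best
        if swap:
            return order_big, order_small, crossings
        return order_small, order_big, crossings
    # alternating heuristic
    order1, order2 = _leaf_order(r1), _leaf_order(r2)
    best = count_crossings(order1, order2)
    for _ in range(50):
        _optimize_side(r1, {label: i for i, label in enumerate(order2)})
        order1 = _leaf_order(r1)
        _optimize_side(r2, {label: i for i, label in enumerate(order1)})
        order2 = _leaf_order(r2)
        x = count_crossings(order1, order2)
        if x >= best:
            break
        best = x
    return order1, order2, best


# ---------------------------------------------------------------------------
# leaf displacement


def _adjacency(tree: dendropy.Tree):
    adj: dict[dendropy.Node, list[tuple[dendropy.Node, float]]] = {}
    for node in tree.preorder_node_iter():
        adj.setdefault(node, [])
        for child in node.child_nodes():
            w = child.edge.length or 0.0
            adj[node].append((child, w))
            adj.setdefault(child, []).append((node, w))
    return adj


def _farthest_leaf_path(
    adj, start: dendropy.Node
) -> list[dendropy.Node]:
    """Path from ``start`` to its farthest leaf (branch-length distance,
    ties broken by smallest leaf label)."""
    dist = {start: 0.0}
    prev = {start: None}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb, w in adj[node]:
            if nb not in dist:
                dist[nb] = dist[node] + w
                prev[nb] = node
                stack.append(nb)
    leaves = [n for n in dist if n.is_leaf() and n is not start]
    best_d = max(dist[n] for n in leaves)
    far = min(
        (n for n in leaves if dist[n] == best_d), key=lambda n: n.taxon.label
    )
    path = [far]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    return list(reversed(path))  # start ... far


def _component_leaves(adj, start, forbidden_edge) -> set[str]:
    a, b = forbidden_edge
    seen = {start}
    stack = [start]
    labels = set()
    while stack:
        node = stack.pop()
        if node.is_leaf():
            labels.add(node.taxon.label)
        for nb, _ in adj[node]:
            if {node, nb} == {a, b}:
                continue
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return labels


def _neighborhood(
    tree: dendropy.Tree, neighborhood_min: int
) -> dict[str, frozenset[str]]:
    """Smallest phylogenetic neighborhood of every leaf.

    The tree is rooted, for each leaf, at that leaf's farthest point; the
    neighborhood is the leaf set of the smallest clade containing the leaf
    and at least ``neighborhood_min`` other leaves, minus the leaf itself.
    """
    adj = _adjacency(tree)
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) - 2 < neighborhood_min:
        raise ValidationError(
            f"tree with {len(leaves)} leaves is too small for "
            f"neighborhood_min={neighborhood_min}"
        )
    out: dict[str, frozenset[str]] = {}
    for leaf in leaves:
        path = _farthest_leaf_path(adj, leaf)
        found = None
        for i in range(1, len(path)):
            # component on the leaf's side when cutting edge (path[i-1], path[i])
            comp = _component_leaves(adj, leaf, (path[i - 1], path[i]))
            neigh = comp - {leaf.taxon.label}
            if len(neigh) >= neighborhood_min:
                found = frozenset(neigh)
                break
        if found is None:
            found = frozenset(
                l.taxon.label for l in leaves
            ) - {leaf.taxon.label, path[-1].taxon.label}
        out[leaf.taxon.label] = found
    return out


def leaf_displacement(
    tree_nuclease: dendropy.Tree,
    tree_helicase: dendropy.Tree,
    neighborhood_min: int = 5,
    displacement_threshold: float = 0.8,
) -> list[LeafDisplacement]:
    """Per-leaf neighborhood displacement between the two domain trees.

    ``displacement = 1 - |N1 & N2| / |N1 | N2|`` over the two smallest
    neighborhoods; a leaf is flagged when displacement exceeds the
    threshold.  Symmetric in the tree arguments.
    """
    l1 = set(lf.taxon.label for lf in tree_nuclease.leaf_node_iter())
    l2 = set(lf.taxon.label for lf in tree_helicase.leaf_node_iter())
    if l1 != l2:
        raise ValidationError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}"
        )
    n1 = _neighborhood(tree_nuclease, neighborhood_min)
    n2 = _neighborhood(tree_helicase, neighborhood_min)
    out = []
    for label in sorted(l1):
        a, b = n1[label], n2[label]
        jac = len(a & b) / len(a | b)
        disp = 1.0 - jac
        out.append(
            LeafDisplacement(
                label, a, b, disp, disp > displacement_threshold
            )
        )
    return out
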