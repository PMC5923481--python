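"""Independent oracles used across the test suite.

Everything here is deliberately naive (plain loops, exhaustive
enumeration) and shares no ranking/sorting/tree code with the package, so
it can serve as a cross-check.
"""

from __future__ import annotations

import itertools
import random

import dendropy
import numpy as np

from repchimera.connectedness import local_alignment_score


# ---------------------------------------------------------------------------
# connectedness brute force


def brute_connectedness(nuc_seqs, hel_seqs, fraction, threshold):
    """Naive all-pairs scores, naive sort, naive set intersection.

    ``nuc_seqs`` / ``hel_seqs``: dict id -> ungapped residues.
    Returns dict id -> (k, common, score, flagged).
    """
    ids = sorted(nuc_seqs)
    out = {}
    for qid in ids:
        tops = {}
        for name, seqs in (("nuc", nuc_seqs), ("hel", hel_seqs)):
            scored = []
            for sid in ids:
                if sid == qid:
                    continue
                scored.append((sid, local_alignment_score(seqs[qid], seqs[sid])))
            # naive selection sort, score desc then id asc
            ordered = []
            pool = list(scored)
            while pool:
                best = pool[0]
                for cand in pool[1:]:
                    if cand[1] > best[1] or (
                        cand[1] == best[1] and cand[0] < best[0]
                    ):
                        best = cand
                pool.remove(best)
                ordered.append(best[0])
            k = int(fraction * len(ordered))
            if k < 1:
                k = 1
            tops[name] = set(ordered[:k])
        k = max(len(tops["nuc"]), len(tops["hel"]))
        common = len([i for i in tops["nuc"] if i in tops["hel"]])
        score = common / k
        out[qid] = (k, common, score, score < threshold)
    return out


# ---------------------------------------------------------------------------
# random trees / additive matrices


def random_binary_tree(labels, rng: random.Random, min_bl=0.1, max_bl=1.0):
    """Random binary tree over labels with uniform branch lengths."""
    taxa = dendropy.TaxonNamespace(list(labels))
    nodes = []
    for label in labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        node.edge.length = rng.uniform(min_bl, max_bl)
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        parent = dendropy.Node()
        parent.edge.length = rng.uniform(min_bl, max_bl)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0])
    tree.seed_node.edge.length = None
    return tree


def path_distance_matrix(tree):
    """Leaf-to-leaf path-length matrix via plain graph traversal."""
    adj = {}
    for node in tree.preorder_node_iter():
        adj.setdefault(node, [])
        for child in node.child_nodes():
            w = child.edge.length or 0.0
            adj[node].append((child, w))
            adj.setdefault(child, []).append((node, w))
    leaves = sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)
    ids = [lf.taxon.label for lf in leaves]
    n = len(ids)
    D = np.zeros((n, n))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, w in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + w
                    stack.append(nb)
        for j, dst in enumerate(leaves):
            D[i, j] = dist[dst]
    return ids, D


def unrooted_bipartitions(tree):
    """Non-trivial bipartitions as frozensets of the side lacking the
    alphabetically first leaf (naive recomputation per edge)."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(all_leaves)
    out = set()
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


# ---------------------------------------------------------------------------
# exhaustive tanglegram oracle


def _all_leaf_orders(node):
    """Every leaf order reachable by permuting children, recursively."""
    if node.is_leaf():
        yield (node.taxon.label,)
        return
    kids = node.child_nodes()
    sub = [list(_all_leaf_orders(c)) for c in kids]
    for perm in itertools.permutations(range(len(kids))):
        for combo in itertools.product(*(sub[i] for i in perm)):
            yield tuple(l for part in combo for l in part)


def naive_crossings(order1, order2):
    pos2 = {l: i for i, l in enumerate(order2)}
    total = 0
    for i in range(len(order1)):
        for j in range(i + 1, len(order1)):
            if pos2[order1[i]] > pos2[order1[j]]:
                total += 1
    return total


def exhaustive_min_crossings(tree1, tree2):
    """Minimum crossings over every rotation state of both trees."""
    orders2 = list(set(_all_leaf_orders(tree2.seed_node)))
    best = None
    for o1 in set(_all_leaf_orders(tree1.seed_node)):
        for o2 in orders2:
            x = naive_crossings(o1, o2)
            if best is None or x < best:
                best = x
                if best == 0:
                    return 0
    return best
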