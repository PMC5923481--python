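"""End-to-end orchestration: score, tree, call, purge, regroup, report.

The two detection routes — low domain connectedness and high dual-tree
leaf displacement — are complementary: the hit-overlap score resolves
recent swaps among close relatives, the tree comparison catches older
events over longer phylogenetic distances.  A protein flagged by both is
called a chimera; a protein flagged by exactly one lands in a "review"
tier rather than being silently auto-resolved, mirroring how conflicting
evidence must be adjudicated case by case.  After purging, well-supported
monophyletic groups are read off the rebuilt full-length tree.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .connectedness import ConnectednessResult, score_all
from .congruence import (
    LeafDisplacement,
    bipartitions,
    bootstrap_support,
    collapse_low_support,
    leaf_displacement,
    pairwise_distance,
    tanglegram_order,
)
from .domains import (
    DomainSplit,
    locate_walker_a,
    logo_matrix,
    split_alignment,
    trim_columns,
)
from .io import (
    Alignment,
    RunConfig,
    SequenceRecord,
    ValidationError,
    support_of,
    write_fasta,
    write_newick,
)

TIER_CHIMERA = "chimera"
TIER_REVIEW = "review"
TIER_CLEAN = "clean"


@dataclasses.dataclass(frozen=True)
class ChimeraCall:
    id: str
    score: float
    displacement: float
    score_flag: bool
    tree_flag: bool
    tier: str


@dataclasses.dataclass(frozen=True)
class GroupReport:
    label: str
    members: tuple[str, ...]
    min_support: float
    size: int


def call_chimeras(
    connectedness_results: list[ConnectednessResult],
    displacements: list[LeafDisplacement],
    strict: bool = False,
) -> list[ChimeraCall]:
    """Combine the two detectors into per-protein tiers.

    Both flags -> "chimera"; exactly one -> "review"; neither -> "clean".
    With ``strict`` the review tier is folded into "chimera" (union rule).
    """
    conn = {r.query_id: r for r in connectedness_results}
    disp = {d.id: d for d in displacements}
    if set(conn) != set(disp):
        missing = set(conn) ^ set(disp)
        raise ValidationError(f"id sets differ between detectors: {sorted(missing)}")
    calls = []
    for qid in sorted(conn):
        c, d = conn[qid], disp[qid]
        nflags = int(c.flagged) + int(d.flagged)
        if nflags == 2:
            tier = TIER_CHIMERA
        elif nflags == 1:
            tier = TIER_CHIMERA if strict else TIER_REVIEW
        else:
            tier = TIER_CLEAN
        calls.append(
            ChimeraCall(qid, c.score, d.displacement, c.flagged, d.flagged, tier)
        )
    return calls


def purge(
    records: list[SequenceRecord],
    calls: list[ChimeraCall],
    mode: str = "default",
) -> tuple[list[SequenceRecord], list[str]]:
    """Remove called chimeras from the dataset.

    Mode "default" removes only tier "chimera"; mode "strict" also removes
    the "review" tier.
    """
    tiers = {c.id: c.tier for c in calls}
    missing = [r.id for r in records if r.id not in tiers]
    if missing:
        raise ValidationError(f"calls missing for records: {missing}")
    if mode == "strict":
        drop_tiers = {TIER_CHIMERA, TIER_REVIEW}
    elif mode == "default":
        drop_tiers = {TIER_CHIMERA}
    else:
        raise ValidationError(f"unknown purge mode {mode!r}")
    kept = [r for r in records if tiers[r.id] not in drop_tiers]
    removed = [r.id for r in records if tiers[r.id] in drop_tiers]
    return kept, removed


def reduction_percent(n_before: int, n_after: int) -> int:
    """Whole-percent dataset reduction, e.g. 647 -> 380 is a 41% reduction."""
    if n_before <= 0 or n_after < 0 or n_after > n_before:
        raise ValidationError("invalid counts for reduction report")
    return round(100.0 * (1.0 - n_after / n_before))


def reduction_report(n_before: int, n_after: int) -> str:
    return (
        f"kept {n_after} of {n_before} sequences "
        f"(a {reduction_percent(n_before, n_after)}% reduction)"
    )


def find_supported_groups(
    tree: dendropy.Tree, min_support: float = 70.0, min_size: int = 5
) -> list[GroupReport]:
    """Maximal well-supported monophyletic groups of a purged tree.

    The tree is collapsed at ``min_support``; groups are then read off the
    unrooted topology from its center — the internal node minimizing the
    maximum path length to any leaf.  Divergent clades radiate from near
    that point, while unresolved deep edges have already collapsed into it.
    A group is a maximal subtree hanging off the center path with at least
    ``min_size`` leaves whose stem and every internal edge carry support
    >= ``min_support``; maximality makes the groups disjoint.
    """
    work = collapse_low_support(tree, min_support)
    all_leaves = frozenset(lf.taxon.label for lf in work.leaf_node_iter())
    if len(all_leaves) < min_size:
        return []
    ref = min(all_leaves)
    supmap = {
        side: support_of(node) for side, node in bipartitions(work).items()
    }

    adj: dict[dendropy.Node, list[dendropy.Node]] = {}
    for node in work.preorder_node_iter():
        adj.setdefault(node, [])
        for child in node.child_nodes():
            adj[node].append(child)
            adj.setdefault(child, []).append(node)

    internal = [n for n in adj if not n.is_leaf()]
    if not internal:
        return []

    def eccentricity(node: dendropy.Node) -> float:
        dist = {node: 0.0}
        stack = [node]
        best = 0.0
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in dist:
                    edge = v.edge if v.parent_node is u else u.edge
                    dist[v] = dist[u] + (edge.length or 0.0)
                    if v.is_leaf():
                        best = max(best, dist[v])
                    stack.append(v)
        return best

    def signature(node: dendropy.Node) -> str:
        return min(lf.taxon.label for lf in node.leaf_iter())

    center = min(internal, key=lambda n: (round(eccentricity(n), 9), signature(n)))

    def subtree_info(
        root: dendropy.Node, parent: dendropy.Node
    ) -> tuple[frozenset[str], list[float | None]]:
        """Leaves below the directed edge parent->root, plus the supports
        of the stem and every internal edge inside the subtree."""
        leaves: set[str] = set()
        edge_sides: list[frozenset[str]] = []

        def collect(u: dendropy.Node, p: dendropy.Node) -> frozenset[str]:
            if u.is_leaf():
                return frozenset([u.taxon.label])
            below: frozenset[str] = frozenset()
            for v in adj[u]:
                if v is p:
                    continue
                below = below | collect(v, u)
            edge_sides.append(below)
            return below

        side = collect(root, parent)
        leaves.update(side)
        sups = []
        for s in edge_sides:  # includes the stem (the last entry is `side`)
            key = s if ref not in s else all_leaves - s
            sups.append(supmap.get(key))
        return frozenset(leaves), sups

    groups: list[GroupReport] = []

    def visit(node: dendropy.Node, parent: dendropy.Node) -> None:
        if node.is_leaf():
            return
        leaves, sups = subtree_info(node, parent)
        if (
            len(leaves) >= min_size
            and all(s is not None and s >= min_support for s in sups)
        ):
            groups.append(
                GroupReport(
                    "pending", tuple(sorted(leaves)),
                    min(float(s) for s in sups), len(leaves),
                )
            )
            return  # maximal: do not descend
        for nb in adj[node]:
            if nb is not parent:
                visit(nb, node)

    for nb in adj[center]:
        visit(nb, center)
    groups.sort(key=lambda g: g.members[0])
    return [
        GroupReport(f"group{i + 1}", g.members, g.min_support, g.size)
        for i, g in enumerate(groups)
    ]


# ---------------------------------------------------------------------------
# report bundle


def _fmt(x: float) -> str:
    return format(float(x), ".6f")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_pipeline(
    aln: Alignment,
    config: RunConfig | None = None,
    out_dir: str | Path = "repchimera_out",
) -> dict:
    """Run the whole analysis on an aligned full-length dataset.

    Stages: locate Walker A and split -> connectedness scores -> per-domain
    NJ+bootstrap trees, collapsed -> tanglegram and leaf displacement ->
    tiered chimera calls -> purge -> purged full-length tree -> supported
    groups -> Walker A logo matrix -> manifest.  Identical input and
    configuration reproduce the bundle byte-identically.

    Returns a dict with the in-memory results and output paths.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise ValidationError(f"stage {name!r} failed: {exc}") from exc

        return _Ctx()

    with stage("split"):
        split_col = locate_walker_a(aln, config.walker_a_pattern)
        split = split_alignment(aln, split_col)
        _write_tsv(
            pd.DataFrame(
                {
                    "split_column": [split_col],
                    "nuclease_columns": [split.nuclease_block.length],
                    "helicase_columns": [split.helicase_block.length],
                }
            ),
            out / "split_report.tsv",
        )

    with stage("connectedness"):
        conn = score_all(split, config)
        _write_tsv(
            pd.DataFrame(
                {
                    "id": [c.query_id for c in conn],
                    "k": [c.k for c in conn],
                    "common": [c.common for c in conn],
                    "score": [_fmt(c.score) for c in conn],
                    "flagged": [int(c.flagged) for c in conn],
                }
            ),
            out / "connectedness.tsv",
        )

    with stage("domain_trees"):
        seeds = np.random.SeedSequence(config.seed).spawn(3)
        tree_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
        nuc_trim = trim_columns(split.nuclease_block, config.gap_keep_fraction)
        hel_trim = trim_columns(split.helicase_block, config.gap_keep_fraction)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nuc_tree = bootstrap_support(
                nuc_trim, config.bootstrap_reps, tree_seeds[0]
            )
            hel_tree = bootstrap_support(
                hel_trim, config.bootstrap_reps, tree_seeds[1]
            )
        write_newick(nuc_tree, out / "nuclease_tree.nwk")
        write_newick(hel_tree, out / "helicase_tree.nwk")
        nuc_coll = collapse_low_support(nuc_tree, config.support_collapse)
        hel_coll = collapse_low_support(hel_tree, config.support_collapse)

    with stage("tanglegram"):
        order1, order2, crossings = tanglegram_order(nuc_coll, hel_coll)
        _write_tsv(
            pd.DataFrame(
                {
                    "nuclease_order": order1,
                    "helicase_order": order2,
                }
            ),
            out / "tanglegram_order.tsv",
        )
        disp = leaf_displacement(
            nuc_coll,
            hel_coll,
            config.neighborhood_min,
            config.displacement_threshold,
        )
        _write_tsv(
            pd.DataFrame(
                {
                    "id": [d.id for d in disp],
                    "displacement": [_fmt(d.displacement) for d in disp],
                    "flagged": [int(d.flagged) for d in disp],
                }
            ),
            out / "displacement.tsv",
        )

    with stage("call"):
        calls = call_chimeras(conn, disp, strict=config.strict)
        _write_tsv(
            pd.DataFrame(
                {
                    "id": [c.id for c in calls],
                    "score": [_fmt(c.score) for c in calls],
                    "displacement": [_fmt(c.displacement) for c in calls],
                    "score_flag": [int(c.score_flag) for c in calls],
                    "tree_flag": [int(c.tree_flag) for c in calls],
                    "tier": [c.tier for c in calls],
                }
            ),
            out / "calls.tsv",
        )

    with stage("purge"):
        mode = "strict" if config.strict else "default"
        kept, removed = purge(list(aln.records), calls, mode=mode)
        write_fasta(kept, out / "purged.fasta")
        (out / "purge_report.txt").write_text(
            reduction_report(len(aln), len(kept))
            + "\nremoved: "
            + (",".join(removed) if removed else "none")
            + "\n"
        )

    with stage("group"):
        purged_aln = aln.subset([r.id for r in kept])
        purged_trim = trim_columns(purged_aln, config.gap_keep_fraction)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full_tree = bootstrap_support(
                purged_trim, config.bootstrap_reps, tree_seeds[2]
            )
        write_newick(full_tree, out / "purged_tree.nwk")
        groups = find_supported_groups(
            full_tree, config.support_collapse, config.min_group_size
        )
        _write_tsv(
            pd.DataFrame(
                {
                    "group": [g.label for g in groups],
                    "size": [g.size for g in groups],
                    "min_support": [_fmt(g.min_support) for g in groups],
                    "members": [",".join(g.members) for g in groups],
                }
            ),
            out / "groups.tsv",
        )

    with stage("logo"):
        walker_logo = logo_matrix(
            split.helicase_block, (0, min(8, split.helicase_block.length)),
            motif_name="walker_a",
        )
        from .io import AMINO_ACIDS

        logo_df = pd.DataFrame(
            walker_logo.matrix, columns=list(AMINO_ACIDS)
        ).map(_fmt)
        logo_df.insert(0, "column", range(len(logo_df)))
        logo_df["information_bits"] = [
            _fmt(b) for b in walker_logo.information
        ]
        _write_tsv(logo_df, out / "walker_a_logo.tsv")

    with stage("manifest"):
        cfg_items = sorted(dataclasses.asdict(config).items())
        cfg_text = "\n".join(f"{k}={v}" for k, v in cfg_items)
        input_hash = hashlib.sha256(
            "".join(f">{r.id}\n{r.residues}\n" for r in aln.records).encode()
        ).hexdigest()
        (out / "manifest.txt").write_text(
            f"package=repchimera {__version__}\n"
            f"input_sha256={input_hash}\n"
            f"config_sha256={hashlib.sha256(cfg_text.encode()).hexdigest()}\n"
            + cfg_text
            + "\n"
        )

    return {
        "split": split,
        "connectedness": conn,
        "nuclease_tree": nuc_tree,
        "helicase_tree": hel_tree,
        "crossings": crossings,
        "displacements": disp,
        "calls": calls,
        "kept": kept,
        "removed": removed,
        "groups": groups,
        "out_dir": out,
    }
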