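"""Synthetic two-domain protein families with planted domain-swap chimeras.

The generator emulates the statistical structure that chimera detection
relies on: several divergent clades radiating from a single ancestor
(deep inter-clade relationships deliberately unresolved, as in highly
diverse virus datasets), an N-terminal nuclease domain carrying conserved
HUH motifs I-III, a C-terminal helicase domain opening with an invariant
Walker A motif followed by Walker B, motif C and an arginine-finger motif,
and a controllable fraction of taxa whose helicase domain is copied from a
member of a different clade.

Sequences evolve by per-site amino-acid replacement along the guide tree:
on a branch of length ``t`` (expected substitutions/site) each unmasked
site is replaced with probability ``1 - exp(-t)``, the replacement drawn
from a fixed background amino-acid frequency vector.  Motif sites never
mutate.  Indels are not simulated, so the output is pre-aligned (gap-free);
detector testing is thereby isolated from aligner behaviour.
"""

from __future__ import annotations

import dataclasses
import re

import dendropy
import numpy as np

from .io import AMINO_ACIDS, SequenceRecord, ValidationError

#: Robinson-Robinson amino-acid background frequencies, ACDEFGHIKLMNPQRSTVWY order
BACKGROUND = np.array(
    [
        0.0785, 0.0192, 0.0535, 0.0668, 0.0397, 0.0733, 0.0229, 0.0537,
        0.0595, 0.0934, 0.0224, 0.0448, 0.0520, 0.0426, 0.0512, 0.0712,
        0.0584, 0.0661, 0.0131, 0.0342,
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()

WALKER_A = "GPPGTGKT"

#: default conserved motifs: (offset, residues) per domain
DEFAULT_NUCLEASE_MOTIFS = ((12, "FTLNN"), (60, "HLH"), (110, "YCSK"))
DEFAULT_HELICASE_MOTIFS = (
    (0, WALKER_A),      # Walker A opens the helicase domain
    (40, "VIDDF"),      # Walker B
    (75, "ITSN"),       # motif C
    (100, "RRI"),       # arginine finger
)


@dataclasses.dataclass(frozen=True)
class MotifMask:
    """Immutable motif positions for one domain."""

    motifs: tuple[tuple[int, str], ...]

    def positions(self) -> set[int]:
        out: set[int] = set()
        for offset, residues in self.motifs:
            out.update(range(offset, offset + len(residues)))
        return out

    def max_end(self) -> int:
        return max((o + len(r) for o, r in self.motifs), default=0)

    def apply(self, sequence: str) -> str:
        chars = list(sequence)
        for offset, residues in self.motifs:
            if offset + len(residues) > len(chars):
                raise ValidationError(
                    f"motif at {offset} extends past sequence length {len(chars)}"
                )
            chars[offset : offset + len(residues)] = residues
        return "".join(chars)


@dataclasses.dataclass(frozen=True)
class TruthRecord:
    """Simulator ground truth for one taxon."""

    id: str
    nuclease_clade: str
    helicase_clade: str
    is_chimera: bool

    def __post_init__(self) -> None:
        if self.is_chimera != (self.nuclease_clade != self.helicase_clade):
            raise ValidationError(
                f"{self.id}: is_chimera inconsistent with clade labels"
            )


@dataclasses.dataclass(frozen=True)
class SimSpec:
    """Study conditions for one simulated family.

    Defaults: 4 clades of 12 taxa, nuclease 160 aa / helicase 120 aa,
    1.5 expected substitutions/site between clade roots and 0.4 within a
    clade — divergent but alignable clades whose deep relationships carry
    little signal, as in real two-domain replication protein datasets.
    """

    n_clades: int = 4
    taxa_per_clade: int = 12
    chimera_fraction: float = 0.0
    nuclease_len: int = 160
    helicase_len: int = 120
    inter_clade_divergence: float = 1.5
    intra_clade_divergence: float = 0.4
    seed: int = 0
    nuclease_motifs: tuple[tuple[int, str], ...] = DEFAULT_NUCLEASE_MOTIFS
    helicase_motifs: tuple[tuple[int, str], ...] = DEFAULT_HELICASE_MOTIFS

    def __post_init__(self) -> None:
        if self.n_clades < 2:
            raise ValidationError("need at least 2 clades")
        if self.taxa_per_clade < 3:
            raise ValidationError("need at least 3 taxa per clade")
        if self.n_clades * self.taxa_per_clade < 12:
            raise ValidationError("need at least 12 taxa in total")
        if not 0 <= self.chimera_fraction < 1:
            raise ValidationError("chimera_fraction must be in [0, 1)")
        if self.inter_clade_divergence <= self.intra_clade_divergence:
            raise ValidationError(
                "inter-clade divergence must exceed intra-clade divergence"
            )
        MotifMask(self.nuclease_motifs).apply("A" * self.nuclease_len)
        MotifMask(self.helicase_motifs).apply("A" * self.helicase_len)

    @property
    def n_taxa(self) -> int:
        return self.n_clades * self.taxa_per_clade


def clade_label(index: int) -> str:
    return f"c{index + 1}"


def taxon_label(clade_index: int, taxon_index: int) -> str:
    return f"c{clade_index + 1}_t{taxon_index + 1:02d}"


def simulate_clade_tree(spec: SimSpec) -> dendropy.Tree:
    """Guide tree: clades radiate from a single root (star backbone).

    Each clade stem has length ``inter_clade_divergence / 2`` so clade
    roots sit ``inter_clade_divergence`` apart; within a clade, a random
    bifurcating ultrametric topology places leaves
    ``intra_clade_divergence / 2`` from the clade root.  Deterministic for
    a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    labels = [
        [taxon_label(c, t) for t in range(spec.taxa_per_clade)]
        for c in range(spec.n_clades)
    ]
    taxa = dendropy.TaxonNamespace([l for grp in labels for l in grp])
    root = dendropy.Node()
    half_intra = spec.intra_clade_divergence / 2.0
    for c in range(spec.n_clades):
        # random topology by sequential pair joining; node heights evenly
        # spaced so leaves sit half_intra below the clade root
        lineages: list[tuple[dendropy.Node, float]] = []
        for label in labels[c]:
            node = dendropy.Node()
            node.taxon = taxa.get_taxon(label)
            lineages.append((node, 0.0))
        m = len(lineages)
        for step in range(1, m):
            height = half_intra * step / (m - 1) if m > 1 else half_intra
            i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
            (a, ha), (b, hb) = lineages[i], lineages[j]
            parent = dendropy.Node()
            a.edge.length = height - ha
            b.edge.length = height - hb
            parent.add_child(a)
            parent.add_child(b)
            lineages = [
                lineages[k] for k in range(len(lineages)) if k not in (i, j)
            ] + [(parent, height)]
        clade_root, h = lineages[0]
        clade_root.edge.length = spec.inter_clade_divergence / 2.0
        root.add_child(clade_root)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    return tree


def random_root_sequence(
    length: int, mask: MotifMask, rng: np.random.Generator,
    forbid_pattern: str | None = None,
) -> str:
    """Background-frequency draw with motif strings overwritten.

    When ``forbid_pattern`` is given, the draw is repeated until the
    pattern occurs nowhere outside the masked positions, so a planted
    Walker A stays the unique anchor.
    """
    masked = mask.positions()
    for _ in range(1000):
        chars = rng.choice(list(AMINO_ACIDS), size=length, p=BACKGROUND)
        seq = mask.apply("".join(chars))
        if forbid_pattern is None:
            return seq
        clashes = [
            m.start()
            for m in re.finditer(forbid_pattern, seq)
            if m.start() not in masked
        ]
        if not clashes:
            return seq
    raise ValidationError("could not draw a root sequence avoiding the pattern")


def evolve_domain(
    tree: dendropy.Tree,
    root_sequence: str,
    mask: MotifMask,
    seed: int,
) -> list[SequenceRecord]:
    """Evolve one domain along the tree; masked positions never change.

    Per branch of length ``t`` each free site is replaced with probability
    ``1 - exp(-t)`` by a residue drawn from the background distribution.
    Returns one ungapped record per leaf, in leaf iteration order.
    """
    if mask.max_end() > len(root_sequence):
        raise ValidationError("mask extends beyond the root sequence")
    rng = np.random.default_rng(seed)
    L = len(root_sequence)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    idx_of = {a: i for i, a in enumerate(AMINO_ACIDS)}
    root_arr = np.array([idx_of[c] for c in root_sequence], dtype=np.int64)
    free = np.array(
        [i not in mask.positions() for i in range(L)], dtype=bool
    )
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_arr}
    records: list[SequenceRecord] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            current = root_arr
        else:
            parent_seq = seqs[id(node.parent_node)]
            t = node.edge.length or 0.0
            current = parent_seq.copy()
            if t > 0:
                p_sub = 1.0 - np.exp(-t)
                hit = (rng.random(L) < p_sub) & free
                nhit = int(hit.sum())
                if nhit:
                    current[hit] = rng.choice(20, size=nhit, p=BACKGROUND)
            seqs[id(node)] = current
        if node.is_leaf():
            residues = aa[current].tobytes().decode()
            records.append(SequenceRecord(node.taxon.label, residues))
    return records


def plant_chimeras(
    nuclease_records: list[SequenceRecord],
    helicase_records: list[SequenceRecord],
    tree: dendropy.Tree,
    fraction: float,
    seed: int,
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Swap helicase domains across clades for a fraction of taxa.

    Exactly ``floor(fraction * n)`` taxa, chosen uniformly, have their
    helicase replaced by the (pre-swap) helicase of a donor taxon drawn
    uniformly from a uniformly chosen different clade.  Full-length records
    are the nuclease+helicase concatenation; the truth table records each
    taxon's domain clades.
    """
    nuc = {r.id: r for r in nuclease_records}
    hel = {r.id: r for r in helicase_records}
    if set(nuc) != set(hel):
        raise ValidationError("nuclease and helicase leaf sets differ")
    ids = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if set(ids) != set(nuc):
        raise ValidationError("tree leaves do not match the records")
    clade_of = {i: i.split("_")[0] for i in ids}
    clades = sorted(set(clade_of.values()))
    if fraction > 0 and len(clades) < 2:
        raise ValidationError("chimeras need at least 2 clades")
    if not 0 <= fraction < 1:
        raise ValidationError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_chim = int(fraction * len(ids))
    chosen = set(
        rng.choice(len(ids), size=n_chim, replace=False).tolist()
    ) if n_chim else set()
    by_clade = {
        c: [i for i in ids if clade_of[i] == c] for c in clades
    }
    records: list[SequenceRecord] = []
    truth: list[TruthRecord] = []
    for pos, taxon in enumerate(ids):
        own = clade_of[taxon]
        if pos in chosen:
            others = [c for c in clades if c != own]
            donor_clade = others[int(rng.integers(0, len(others)))]
            donor = by_clade[donor_clade][
                int(rng.integers(0, len(by_clade[donor_clade])))
            ]
            helicase = hel[donor].residues
            truth.append(TruthRecord(taxon, own, donor_clade, True))
        else:
            helicase = hel[taxon].residues
            truth.append(TruthRecord(taxon, own, own, False))
        records.append(SequenceRecord(taxon, nuc[taxon].residues + helicase))
    return records, truth


def simulate_dataset(
    spec: SimSpec,
) -> tuple[list[SequenceRecord], list[TruthRecord], dendropy.Tree]:
    """Full simulation: guide tree, both domains, planted chimeras.

    Returns full-length (gap-free, hence trivially aligned) records, the
    truth table and the guide tree.  Byte-reproducible for a given spec.
    """
    rng = np.random.default_rng(spec.seed)
    tree = simulate_clade_tree(spec)
    nuc_mask = MotifMask(spec.nuclease_motifs)
    hel_mask = MotifMask(spec.helicase_motifs)
    walker_pattern = "[GA].{4}GK[ST]"
    nuc_root = random_root_sequence(
        spec.nuclease_len, nuc_mask, rng, forbid_pattern=walker_pattern
    )
    hel_root = random_root_sequence(
        spec.helicase_len, hel_mask, rng, forbid_pattern=walker_pattern
    )
    sub_seeds = np.random.SeedSequence(spec.seed).spawn(3)
    nuc_seed = int(sub_seeds[0].generate_state(1)[0] % (2**31))
    hel_seed = int(sub_seeds[1].generate_state(1)[0] % (2**31))
    chi_seed = int(sub_seeds[2].generate_state(1)[0] % (2**31))
    nuc_records = evolve_domain(tree, nuc_root, nuc_mask, nuc_seed)
    hel_records = evolve_domain(tree, hel_root, hel_mask, hel_seed)
    records, truth = plant_chimeras(
        nuc_records, hel_records, tree, spec.chimera_fraction, chi_seed
    )
    return records, truth, tree
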