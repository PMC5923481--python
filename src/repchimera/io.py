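"""Core data types and file I/O.

Sequences travel as :class:`SequenceRecord` / :class:`Alignment`, trees as
dendropy :class:`~dendropy.Tree` objects with branch supports stored as
internal-node labels (percentages, 0-100).  All tabular output in the
package is TSV with a header row; run configuration is a plain-text
``key=value`` file overriding :class:`RunConfig` defaults.
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues legal in a SequenceRecord
ALPHABET = set(AMINO_ACIDS) | {"X", GAP}


class FastaParseError(ValueError):
    """Raised for malformed FASTA input."""


class ValidationError(ValueError):
    """Raised when a domain-type invariant is violated."""


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: an id plus amino-acid residues (possibly gapped)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues.upper()) - ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains illegal residues {sorted(bad)}"
            )

    @property
    def ungapped(self) -> str:
        """Residues with gap characters removed."""
        return self.residues.replace(GAP, "")

    def is_aligned_like(self) -> bool:
        return GAP in self.residues


@dataclasses.dataclass(frozen=True)
class Alignment:
    """An ordered list of equal-length (gapped) sequence records."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 3:
            raise ValidationError("an alignment needs at least 3 records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise ValidationError(
                f"records have unequal lengths: {sorted(lengths)}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record ids: {dupes}")

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)

    def take_columns(self, columns: Sequence[int]) -> "Alignment":
        """New alignment restricted to the given column indices, in order."""
        return Alignment(
            tuple(
                SequenceRecord(
                    r.id,
                    "".join(r.residues[j] for j in columns),
                    r.description,
                )
                for r in self.records
            )
        )

    def subset(self, keep_ids: Iterable[str]) -> "Alignment":
        keep = set(keep_ids)
        return Alignment(tuple(r for r in self.records if r.id in keep))


@dataclasses.dataclass
class RunConfig:
    """Tunable thresholds of the detection pipeline.

    ``top_fraction`` (0.2): fraction of ranked hits kept per domain;
    ``score_threshold`` (0.2): connectedness below this flags a protein;
    ``gap_keep_fraction`` (0.2): minimum non-gap fraction for a column to
    survive trimming; ``support_collapse`` (70): branches with bootstrap
    support below this percentage are collapsed; ``displacement_threshold``
    (0.8): leaf displacement above this flags a protein in the dual-tree
    comparison; ``neighborhood_min`` (5): minimum number of other leaves in
    a displacement neighborhood.
    """

    top_fraction: float = 0.2
    score_threshold: float = 0.2
    gap_keep_fraction: float = 0.2
    support_collapse: int = 70
    bootstrap_reps: int = 100
    seed: int = 0
    displacement_threshold: float = 0.8
    neighborhood_min: int = 5
    min_group_size: int = 5
    denominator: str = "k"  # or "jaccard"
    strict: bool = False
    walker_a_pattern: str = "[GA].{4}GK[ST]"

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValidationError("top_fraction must be in (0, 1]")
        if not 0 <= self.score_threshold <= 1:
            raise ValidationError("score_threshold must be in [0, 1]")
        if not 0 < self.gap_keep_fraction <= 1:
            raise ValidationError("gap_keep_fraction must be in (0, 1]")
        if not 0 <= self.support_collapse <= 100:
            raise ValidationError("support_collapse must be in [0, 100]")
        if self.bootstrap_reps < 1:
            raise ValidationError("bootstrap_reps must be positive")
        if not 0 <= self.displacement_threshold <= 1:
            raise ValidationError("displacement_threshold must be in [0, 1]")
        if self.neighborhood_min < 1:
            raise ValidationError("neighborhood_min must be positive")
        if self.denominator not in ("k", "jaccard"):
            raise ValidationError("denominator must be 'k' or 'jaccard'")


_BOOL_FIELDS = {"strict"}
_INT_FIELDS = {
    "support_collapse",
    "bootstrap_reps",
    "seed",
    "neighborhood_min",
    "min_group_size",
}
_FLOAT_FIELDS = {
    "top_fraction",
    "score_threshold",
    "gap_keep_fraction",
    "displacement_threshold",
}


def read_config(path: str | Path, base: RunConfig | None = None) -> RunConfig:
    """Read ``key=value`` lines, overriding defaults (or ``base``)."""
    values = dataclasses.asdict(base) if base is not None else {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in known:
            raise ValidationError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in _BOOL_FIELDS:
            values[key] = val.lower() in ("1", "true", "yes")
        elif key in _INT_FIELDS:
            values[key] = int(val)
        elif key in _FLOAT_FIELDS:
            values[key] = float(val)
        else:
            values[key] = val
    return RunConfig(**values)


def write_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"{f.name}={getattr(config, f.name)}"
        for f in dataclasses.fields(RunConfig)
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    The id is the header token up to the first whitespace; the remainder is
    stored as the description.  ``.`` gap characters are normalized to
    ``-``.  Duplicate ids are rejected.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first_bad = next(
            i + 1 for i, l in enumerate(text.splitlines()) if l.strip()
        )
        raise FastaParseError(
            f"{path}: line {first_bad}: expected FASTA header starting with '>'"
        )
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace(".", GAP)
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, residues, desc))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> Path:
    """Write records as FASTA, 60-column wrapped, gaps preserved."""
    if not records:
        raise ValidationError("refusing to write an empty FASTA file")
    path = Path(path)
    bio_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(bio_records, handle, "fasta")
    return path


def read_alignment(path: str | Path) -> Alignment:
    return Alignment(tuple(read_fasta(path)))


# ---------------------------------------------------------------------------
# Newick trees (supports as internal-node labels)


class NewickParseError(ValueError):
    pass


def support_of(node: dendropy.Node) -> float | None:
    """Branch support of an internal node, or None when unknown."""
    if node.label is None or node.label == "":
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def set_support(node: dendropy.Node, value: float | None) -> None:
    node.label = None if value is None else format(float(value), "g")


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree; internal-node labels are branch supports.

    Supports given as fractions (every numeric label <= 1, e.g. aBayes
    posteriors) are rescaled to percentages on import.
    """
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"{path}: malformed Newick: {exc}") from exc
    supports = [
        support_of(n) for n in tree.preorder_internal_node_iter()
        if support_of(n) is not None
    ]
    if supports and max(supports) <= 1.0:
        for node in tree.preorder_internal_node_iter():
            s = support_of(node)
            if s is not None:
                set_support(node, s * 100.0)
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> Path:
    path = Path(path)
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return path
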