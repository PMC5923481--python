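"""All-against-all domain similarity ranking and the connectedness score.

Each protein's nuclease and helicase domains are compared against every
other protein's corresponding domain.  For each domain the top fraction
(default 20%) of ranked hits is extracted; the connectedness score is the
number of ids shared between the two top sets divided by the top-set size.
A score near 1 means both domains find the same proteins (co-evolving
domains); a score below the threshold (default 0.2) flags likely
inter-domain recombination.

The default similarity backend is deterministic Smith-Waterman local
alignment with BLOSUM62 and affine gaps.  A profile-search backend using
phmmer (via pyhmmer, when installed) satisfies the same ranking contract;
the statistic only depends on hit order, not on the scoring engine.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .domains import DomainSplit
from .io import RunConfig, SequenceRecord, ValidationError

Domain = Literal["nuclease", "helicase"]

MIN_QUERY_LEN = 10
MIN_DATABASE = 6


@dataclasses.dataclass(frozen=True)
class HitTable:
    """Ranked non-self hits of one query within one domain."""

    query_id: str
    domain: str
    hits: tuple[tuple[str, float, int], ...]  # (subject_id, score, rank)


@dataclasses.dataclass(frozen=True)
class ConnectednessResult:
    query_id: str
    k: int
    nuclease_top: frozenset[str]
    helicase_top: frozenset[str]
    common: int
    score: float
    flagged: bool


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def local_alignment_score(a: str, b: str) -> float:
    """Smith-Waterman score (BLOSUM62, gap open -11 / extend -1)."""
    return float(_ALIGNER.score(a, b))


def similarity_matrix(
    records: Sequence[SequenceRecord], backend: str = "builtin"
) -> np.ndarray:
    """Symmetric all-against-all similarity over ungapped sequences."""
    seqs = [r.ungapped for r in records]
    n = len(seqs)
    mat = np.zeros((n, n))
    if backend == "builtin":
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = local_alignment_score(seqs[i], seqs[j])
    elif backend == "phmmer":
        mat = _phmmer_matrix(records)
    else:
        raise ValidationError(f"unknown similarity backend {backend!r}")
    return mat


def _phmmer_matrix(records: Sequence[SequenceRecord]) -> np.ndarray:
    """phmmer bit scores via pyhmmer; missing hits score 0."""
    import pyhmmer

    alphabet = pyhmmer.easel.Alphabet.amino()
    digital = [
        pyhmmer.easel.TextSequence(
            name=r.id.encode(), sequence=r.ungapped
        ).digitize(alphabet)
        for r in records
    ]
    index = {r.id: i for i, r in enumerate(records)}
    n = len(records)
    mat = np.zeros((n, n))
    for i, hits in enumerate(
        pyhmmer.hmmer.phmmer(digital, digital, cpus=1)
    ):
        for hit in hits:
            name = hit.name
            if isinstance(name, bytes):
                name = name.decode()
            j = index[name]
            if j != i:
                mat[i, j] = float(hit.score)
    # symmetrize so ranking is order-independent
    return np.maximum(mat, mat.T)


def rank_hits(
    query_record: SequenceRecord,
    database_records: Sequence[SequenceRecord],
    domain: str,
    backend: str = "builtin",
) -> HitTable:
    """Rank all non-self database records by similarity to the query.

    Ordering is strictly deterministic: score descending, then subject id
    ascending.  The query id itself never appears among the hits.
    """
    if len(query_record.ungapped) < MIN_QUERY_LEN:
        raise ValidationError(
            f"query {query_record.id!r} shorter than {MIN_QUERY_LEN} residues"
        )
    if len(database_records) < MIN_DATABASE:
        raise ValidationError(
            f"database must hold at least {MIN_DATABASE} records"
        )
    everything = [query_record] + [
        r for r in database_records if r.id != query_record.id
    ]
    mat = similarity_matrix(everything, backend=backend)
    scored = sorted(
        ((r.id, float(mat[0, i + 1])) for i, r in enumerate(everything[1:])),
        key=lambda t: (-t[1], t[0]),
    )
    hits = tuple((sid, s, rank + 1) for rank, (sid, s) in enumerate(scored))
    return HitTable(query_record.id, domain, hits)


def top_fraction(hit_table: HitTable, fraction: float = 0.2) -> frozenset[str]:
    """Ids of the top ``max(1, floor(fraction * H))`` ranked hits."""
    if not hit_table.hits:
        raise ValidationError("empty hit table")
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    k = max(1, int(fraction * len(hit_table.hits)))
    return frozenset(sid for sid, _, _ in hit_table.hits[:k])


def connectedness(
    nuclease_top: frozenset[str] | set[str],
    helicase_top: frozenset[str] | set[str],
    query_id: str = "",
    threshold: float = 0.2,
    denominator: str = "k",
) -> ConnectednessResult:
    """Hit-set overlap score between the two domains' top hits.

    ``score = |nuclease_top & helicase_top| / k`` with ``k`` the top-set
    size (the larger of the two when they differ); the Jaccard variant
    divides by the union size instead.  ``flagged`` is true when the score
    falls below the threshold.
    """
    if not nuclease_top or not helicase_top:
        raise ValidationError("top hit sets must be non-empty")
    nuc = frozenset(nuclease_top)
    hel = frozenset(helicase_top)
    common = len(nuc & hel)
    k = max(len(nuc), len(hel))
    if denominator == "k":
        score = common / k
    elif denominator == "jaccard":
        score = common / len(nuc | hel)
    else:
        raise ValidationError(f"unknown denominator {denominator!r}")
    return ConnectednessResult(
        query_id=query_id,
        k=k,
        nuclease_top=nuc,
        helicase_top=hel,
        common=common,
        score=score,
        flagged=score < threshold,
    )


def _ranked_ids(mat: np.ndarray, ids: Sequence[str], i: int) -> list[str]:
    pairs = sorted(
        ((-float(mat[i, j]), ids[j]) for j in range(len(ids)) if j != i),
    )
    return [sid for _, sid in pairs]


def score_all(
    domain_split: DomainSplit,
    config: RunConfig | None = None,
    backend: str = "builtin",
) -> list[ConnectednessResult]:
    """Connectedness of every protein in a domain split.

    Computes one symmetric similarity matrix per domain over the ungapped
    domain sequences, ranks hits per query, extracts the top fraction and
    scores the overlap.  Deterministic: results depend only on the sequences
    and the configuration, not on record order.
    """
    config = config or RunConfig()
    ids = domain_split.ids
    if len(ids) < 12:
        raise ValidationError("connectedness scoring needs at least 12 records")
    nuc_records = [
        SequenceRecord(r.id, r.ungapped) for r in domain_split.nuclease_block.records
    ]
    hel_records = [
        SequenceRecord(r.id, r.ungapped) for r in domain_split.helicase_block.records
    ]
    # canonical (sorted-id) order so permuting input order cannot change ties
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    ids_c = [ids[i] for i in order]
    nuc_mat = similarity_matrix([nuc_records[i] for i in order], backend=backend)
    hel_mat = similarity_matrix([hel_records[i] for i in order], backend=backend)
    h = len(ids_c) - 1
    k = max(1, int(config.top_fraction * h))
    results = {}
    for i, qid in enumerate(ids_c):
        nuc_top = frozenset(_ranked_ids(nuc_mat, ids_c, i)[:k])
        hel_top = frozenset(_ranked_ids(hel_mat, ids_c, i)[:k])
        results[qid] = connectedness(
            nuc_top,
            hel_top,
            query_id=qid,
            threshold=config.score_threshold,
            denominator=config.denominator,
        )
    return [results[qid] for qid in ids]
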