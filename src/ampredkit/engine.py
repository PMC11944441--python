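"""Seed-and-extend local alignment over peptide databases.

The search follows the classic two-stage design used by high-throughput
protein aligners: sequences are mapped to a reduced alphabet and indexed by
k-mer, candidate pairs sharing at least one seed are then aligned with an
affine-gap Smith-Waterman (Biopython's ``PairwiseAligner``), and hits are
scored with Karlin-Altschul statistics (bitscore and E-value).  An exhaustive
mode aligns every pair and serves as the sensitivity reference for the seeded
mode.

Percent identity is computed as 100 x identical residue pairs / alignment
columns (gap columns included), reported at one decimal -- the convention of
BLAST-style tabular output, and the quantity the redundancy indices consume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

from Bio import Align
from Bio.Align import substitution_matrices

from .alphabet import DIAMOND_11, ReducedAlphabet
from .io import AlignmentHit, HitTable, PeptideRecord, SequenceDatabase

logger = logging.getLogger(__name__)


@dataclass
class AlignmentParams:
    """Scoring and search parameters.

    Defaults mirror common protein-search practice: BLOSUM62 with affine gap
    penalties 11/1, contiguous seeds of 4 reduced symbols, and an E-value
    cutoff of 0.001.  A gap of length L costs ``gap_open + L * gap_extend``.
    ``spaced_seed_mask`` is an optional string of ``1``/``0`` (match/ignore
    positions); the number of ``1``s must equal ``seed_length``.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    seed_length: int = 4
    evalue_cutoff: float = 0.001
    mode: str = "seeded"
    lambda_: float = 0.267
    k_const: float = 0.041
    spaced_seed_mask: str | None = None
    include_self_pairs: bool = True
    alphabet: ReducedAlphabet = field(default_factory=lambda: DIAMOND_11)

    def __post_init__(self) -> None:
        if self.seed_length < 2:
            raise ValueError("seed_length must be >= 2")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.mode not in ("seeded", "exhaustive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.spaced_seed_mask is not None:
            mask = self.spaced_seed_mask
            if set(mask) - {"0", "1"} or mask.count("1") != self.seed_length:
                raise ValueError(
                    "spaced_seed_mask must be a 0/1 string with"
                    f" seed_length={self.seed_length} ones"
                )

    @property
    def mask(self) -> str:
        """Effective seed mask (contiguous when no spaced mask is set)."""
        return self.spaced_seed_mask or "1" * self.seed_length

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(
            self.substitution_matrix
        )
        # first gap residue costs open+extend, each further residue extend
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass
class SeedIndex:
    """Inverted index: reduced k-mer -> postings of (subject id, offset).

    Offsets are 1-based positions of the k-mer window start, consistent with
    the 1-based alignment coordinates used throughout.
    """

    k: int
    mask: str
    table: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    @property
    def n_postings(self) -> int:
        return sum(len(v) for v in self.table.values())

    def candidates(self, reduced_query: str) -> set[str]:
        """Subject ids sharing at least one seed with the reduced query."""
        out: set[str] = set()
        for kmer in iter_seeds(reduced_query, self.mask):
            postings = self.table.get(kmer)
            if postings:
                out.update(sid for sid, _ in postings)
        return out


def iter_seeds(reduced: str, mask: str) -> Iterable[str]:
    """Yield the (possibly spaced) seed words of a reduced sequence."""
    span = len(mask)
    picks = [i for i, m in enumerate(mask) if m == "1"]
    for start in range(len(reduced) - span + 1):
        yield "".join(reduced[start + i] for i in picks)


def build_seed_index(
    db: SequenceDatabase,
    k: int = 4,
    alphabet: ReducedAlphabet = DIAMOND_11,
    mask: str | None = None,
) -> SeedIndex:
    """Index every reduced k-mer of every sequence in the database.

    Sequences shorter than the seed span contribute no postings.
    """
    mask = mask or "1" * k
    index = SeedIndex(k=k, mask=mask)
    for rec in db.records:
        reduced = alphabet.reduce(rec.sequence)
        for pos, kmer in enumerate(iter_seeds(reduced, mask), start=1):
            index.table.setdefault(kmer, []).append((rec.id, pos))
    return index


def _alignment_stats(alignment) -> tuple[int, int, tuple[int, int, int, int]]:
    """(identities, columns, coordinates) of a local alignment."""
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    blocks_q, blocks_s = alignment.aligned
    qstart = int(blocks_q[0][0]) + 1
    qend = int(blocks_q[-1][1])
    sstart = int(blocks_s[0][0]) + 1
    send = int(blocks_s[-1][1])
    return counts.identities, columns, (qstart, qend, sstart, send)


def local_align(
    query: PeptideRecord,
    subject: PeptideRecord,
    params: AlignmentParams | None = None,
    subject_total_residues: int | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> AlignmentHit | None:
    """Optimal local alignment of one pair, or ``None`` below significance.

    bitscore = (lambda * raw - ln K) / ln 2, rounded to one decimal for
    reporting; E-value = m * n * 2^(-bitscore) with m the query length and n
    the subject database's total residue count (the subject's own length when
    no database context is given).  Returns ``None`` when the E-value exceeds
    the cutoff or no positive-scoring local alignment exists.
    """
    if params is None:
        params = AlignmentParams()
    if not query.sequence or not subject.sequence:
        raise ValueError("cannot align empty sequences")
    if aligner is None:
        aligner = params.make_aligner()

    alignments = aligner.align(query.sequence, subject.sequence)
    try:
        best = alignments[0]
    except IndexError:
        return None
    raw = float(best.score)
    if raw <= 0:
        return None

    bitscore = (params.lambda_ * raw - math.log(params.k_const)) / math.log(2)
    n = subject_total_residues if subject_total_residues else subject.length
    evalue = query.length * n * math.pow(2.0, -bitscore)
    if evalue > params.evalue_cutoff:
        return None

    identities, columns, (qstart, qend, sstart, send) = _alignment_stats(best)
    if columns == 0:
        return None
    pident = round(100.0 * identities / columns, 1)
    return AlignmentHit(
        qseqid=query.id,
        sseqid=subject.id,
        pident=pident,
        length=columns,
        evalue=evalue,
        bitscore=round(bitscore, 1),
        qstart=qstart,
        qend=qend,
        sstart=sstart,
        send=send,
    )


def search(
    query_db: SequenceDatabase,
    subject_db: SequenceDatabase,
    params: AlignmentParams | None = None,
) -> HitTable:
    """All-vs-all search of a query database against a subject database.

    In seeded mode only subjects sharing at least one reduced k-mer with the
    query are aligned; in exhaustive mode every pair is.  One best-scoring
    hit per (query, subject) pair is recorded when it passes the E-value
    cutoff.  Self-pairs (same identifier in a self-comparison) are included
    unless ``params.include_self_pairs`` is false.
    """
    if params is None:
        params = AlignmentParams()
    table = HitTable(query_db=query_db.name, subject_db=subject_db.name)
    if not query_db.records or not subject_db.records:
        logger.warning(
            "empty database in search (%s: %d, %s: %d); returning empty table",
            query_db.name,
            len(query_db),
            subject_db.name,
            len(subject_db),
        )
        return table

    self_comparison = query_db.name == subject_db.name
    n_subject_residues = subject_db.total_residues  # frozen at search start
    aligner = params.make_aligner()
    subject_by_id = {rec.id: rec for rec in subject_db.records}
    subject_order = {rec.id: i for i, rec in enumerate(subject_db.records)}

    if params.mode == "seeded":
        index = build_seed_index(
            subject_db, k=params.seed_length, alphabet=params.alphabet,
            mask=params.spaced_seed_mask,
        )

    for query in query_db.records:
        if params.mode == "seeded":
            reduced = params.alphabet.reduce(query.sequence)
            candidate_ids = sorted(
                index.candidates(reduced), key=subject_order.__getitem__
            )
            candidates = (subject_by_id[sid] for sid in candidate_ids)
        else:
            candidates = iter(subject_db.records)
        for subject in candidates:
            if (
                self_comparison
                and not params.include_self_pairs
                and query.id == subject.id
            ):
                continue
            hit = local_align(
                query,
                subject,
                params,
                subject_total_residues=n_subject_residues,
                aligner=aligner,
            )
            if hit is not None:
                table.hits.append(hit)
    return table
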