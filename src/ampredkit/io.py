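"""FASTA databases and tabular hit files.

A peptide collection is read into a :class:`SequenceDatabase`, which tracks the
*theoretical* record count (everything parsed from the file) and, after
:func:`validate_database`, the *obtained* count (records whose sequence uses
only the 20 standard amino-acid letters).  Pairwise comparison results travel
as :class:`HitTable` objects serialized to tab-separated files in the familiar
10-column homology-search layout (qseqid, sseqid, pident, length, evalue,
bitscore, qstart, qend, sstart, send); a 6-column subset without coordinates
is accepted on input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.  Anything else (B, J, O, U, X,
#: Z, gaps, stops, digits) marks a sequence as non-standard and excludes it
#: from comparisons.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA input."""


class HitTableParseError(ValueError):
    """Raised for malformed hit-table rows (carries the 1-based row number)."""


@dataclass(frozen=True)
class PeptideRecord:
    """One sequence entry with its source-database label."""

    id: str
    sequence: str
    db_name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record identifier must be non-empty")
        if "\t" in self.id or "\n" in self.id:
            raise ValueError(f"record identifier contains tab/newline: {self.id!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def is_standard(self) -> bool:
        """True when every residue is one of the 20 standard letters."""
        return all(c in STANDARD_AA for c in self.sequence)


@dataclass
class SequenceDatabase:
    """An ordered peptide collection with theoretical/obtained accounting."""

    name: str
    records: list[PeptideRecord] = field(default_factory=list)
    n_theoretical: int = 0
    n_obtained: int | None = None
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def total_residues(self) -> int:
        return sum(r.length for r in self.records)

    def sequences_by_id(self) -> dict[str, str]:
        return {r.id: r.sequence for r in self.records}

    def lengths_by_id(self) -> dict[str, int]:
        return {r.id: r.length for r in self.records}


@dataclass
class AlignmentHit:
    """One query-subject comparison row.

    ``pident`` is the percentage of identical residue pairs over all alignment
    columns (gap columns included), kept at one-decimal precision.
    Coordinates are 1-based inclusive; they may be ``None`` when a hit came
    from a 6-column legacy file.
    """

    qseqid: str
    sseqid: str
    pident: float
    length: int
    evalue: float
    bitscore: float
    qstart: int | None = None
    qend: int | None = None
    sstart: int | None = None
    send: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"pident out of [0, 100]: {self.pident}")
        if self.length < 1:
            raise ValueError(f"alignment length must be positive: {self.length}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue: {self.evalue}")
        if (self.qstart is None) != (self.qend is None) or (self.sstart is None) != (
            self.send is None
        ):
            raise ValueError("alignment coordinates must be set in start/end pairs")
        if self.qstart is not None and self.qstart > self.qend:
            raise ValueError("qstart > qend")
        if self.sstart is not None and self.sstart > self.send:
            raise ValueError("sstart > send")

    @property
    def has_coordinates(self) -> bool:
        return self.qstart is not None


@dataclass
class HitTable:
    """A collection of hits from one query-db vs subject-db search."""

    query_db: str = ""
    subject_db: str = ""
    hits: list[AlignmentHit] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.hits)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, db_name: str | None = None) -> SequenceDatabase:
    """Read a FASTA file into a :class:`SequenceDatabase`.

    ``n_theoretical`` is set to the parsed record count; validation is *not*
    applied.  Duplicate identifiers are kept and disambiguated with an ordinal
    suffix (``id.2``, ``id.3`` ...) so the theoretical count stays faithful to
    the file.  A record with an empty sequence is a parse error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    name = db_name if db_name is not None else path.stem

    records: list[PeptideRecord] = []
    seen: dict[str, int] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq).strip().upper()
        rid = rec.id
        if not rid:
            raise FastaParseError(f"{path}: record {i} has an empty identifier")
        if not seq:
            raise FastaParseError(
                f"{path}: record {i} ({rid!r}) has an empty sequence"
            )
        n = seen.get(rid, 0) + 1
        seen[rid] = n
        if n > 1:
            logger.warning("duplicate identifier %r in %s; keeping as %r.%d", rid, path, rid, n)
            rid = f"{rid}.{n}"
        records.append(PeptideRecord(id=rid, sequence=seq, db_name=name))

    return SequenceDatabase(name=name, records=records, n_theoretical=len(records))


def write_fasta(db: SequenceDatabase | Iterable[PeptideRecord], path: str | Path) -> None:
    """Write records to a FASTA file (60-column wrapped)."""
    records = db.records if isinstance(db, SequenceDatabase) else list(db)
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def validate_database(db: SequenceDatabase) -> SequenceDatabase:
    """Drop sequences containing non-standard symbols; set ``n_obtained``.

    Sequences are upper-cased before checking (read_fasta already does this,
    but records constructed by hand may not be).  Rejection is the contract,
    not an error; rejected (id, reason) pairs are recorded on the returned
    database and logged.  Idempotent.
    """
    kept: list[PeptideRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec in db.records:
        seq = rec.sequence.strip().upper()
        bad = sorted({c for c in seq if c not in STANDARD_AA})
        if bad:
            reason = "non-standard symbol(s): " + "".join(bad)
            rejected.append((rec.id, reason))
            logger.info("rejected %s: %s", rec.id, reason)
        else:
            kept.append(rec if seq == rec.sequence else replace(rec, sequence=seq))
    return SequenceDatabase(
        name=db.name,
        records=kept,
        n_theoretical=db.n_theoretical,
        n_obtained=len(kept),
        rejected=rejected,
    )


def write_rejected_log(db: SequenceDatabase, path: str | Path) -> None:
    """Write the rejected-sequence log as ``id<TAB>reason`` lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rid, reason in db.rejected:
            fh.write(f"{rid}\t{reason}\n")


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

HIT_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "evalue",
    "bitscore",
    "qstart",
    "qend",
    "sstart",
    "send",
)


def _format_evalue(e: float) -> str:
    # repr of a float is the shortest string that parses back exactly, so
    # write/read round-trips are lossless ("1e-05", "0.001", ...).
    return repr(float(e))


def write_hit_table(table: HitTable, path: str | Path) -> None:
    """Serialize hits as TSV in the fixed 10-column order (no header).

    ``pident`` is written with one decimal.  Hits without coordinates write
    the 6-column subset.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for h in table.hits:
            fields = [
                h.qseqid,
                h.sseqid,
                f"{h.pident:.1f}",
                str(h.length),
                _format_evalue(h.evalue),
                f"{h.bitscore:.1f}",
            ]
            if h.has_coordinates:
                fields += [str(h.qstart), str(h.qend), str(h.sstart), str(h.send)]
            fh.write("\t".join(fields) + "\n")


def read_hit_table(
    path: str | Path, query_db: str = "", subject_db: str = ""
) -> HitTable:
    """Read a 6- or 10-column TSV hit file.

    Non-numeric content in a numeric column raises
    :class:`HitTableParseError` naming the 1-based row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"hit table not found: {path}")
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) not in (6, 10):
                raise HitTableParseError(
                    f"{path}: row {row_no}: expected 6 or 10 columns, got {len(parts)}"
                )
            try:
                pident = float(parts[2])
                length = int(parts[3])
                evalue = float(parts[4])
                bitscore = float(parts[5])
                coords = [int(x) for x in parts[6:10]] if len(parts) == 10 else []
            except ValueError as exc:
                raise HitTableParseError(
                    f"{path}: row {row_no}: non-numeric field ({exc})"
                ) from None
            if math.isnan(evalue) or math.isnan(pident):
                raise HitTableParseError(f"{path}: row {row_no}: NaN field")
            kwargs = dict(zip(("qstart", "qend", "sstart", "send"), coords))
            hits.append(
                AlignmentHit(
                    qseqid=parts[0],
                    sseqid=parts[1],
                    pident=pident,
                    length=length,
                    evalue=evalue,
                    bitscore=bitscore,
                    **kwargs,
                )
            )
    return HitTable(query_db=query_db, subject_db=subject_db, hits=hits)


def hit_table_to_frame(table: HitTable):
    """Return the table as a pandas DataFrame (column order fixed)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "qseqid": h.qseqid,
                "sseqid": h.sseqid,
                "pident": h.pident,
                "length": h.length,
                "evalue": h.evalue,
                "bitscore": h.bitscore,
                "qstart": h.qstart,
                "qend": h.qend,
                "sstart": h.sstart,
                "send": h.send,
            }
            for h in table.hits
        ],
        columns=list(HIT_COLUMNS),
    )
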