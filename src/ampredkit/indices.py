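"""Absolute-identity repeatability indices (DAIRI_d / IDAIRI_d).

Given a hit table from an all-vs-all comparison, the Database
Absolute-Identity Repeatability Index is the percentage of recorded
comparisons at 100% identity:

    DAIRI_d = n_identical / n_total * 100

The inter-database variant rescales the same fraction by the size ratio of
the compared database to the reference database, so a small database full of
copies of the reference is not over-credited and a large one is not
under-credited:

    IDAIRI_d = (n_identical / n_total) * (n_compared / n_reference) * 100

The normalization factor n_compared / n_reference equals 1 for equally sized
databases (IDAIRI_d = DAIRI_d), is < 1 when the compared database is smaller,
and > 1 when it is larger -- in which case IDAIRI_d may exceed 100.  Sequence
counts are the *obtained* (post-validation) counts, since only validated
sequences take part in comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import HitTable, SequenceDatabase


class UndefinedIndexError(ZeroDivisionError):
    """Raised when an index denominator is zero."""


@dataclass(frozen=True)
class ComparisonSummary:
    """Counts feeding the index formulas."""

    n_total: int
    n_identical: int
    n_compared_db: int = 0
    n_reference_db: int = 0

    def __post_init__(self) -> None:
        if min(self.n_total, self.n_identical, self.n_compared_db, self.n_reference_db) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_identical > self.n_total:
            raise ValueError("n_identical cannot exceed n_total")


@dataclass(frozen=True)
class RedundancyReport:
    """DAIRI_d / IDAIRI_d values with their normalization factor."""

    dairi: float
    idairi: float | None = None
    normalization_factor: float | None = None
    n_total: int = 0
    n_identical: int = 0


def count_identical(table: HitTable, min_coverage: float | None = None) -> int:
    """Number of hits at exactly 100.0% identity (one-decimal precision).

    With ``min_coverage`` set, a hit also needs alignment length >= coverage
    x the shorter of the reported alignment spans; off by default, mirroring
    the direct use of the pident column.
    """
    n = 0
    for h in table.hits:
        if round(h.pident, 1) != 100.0:
            continue
        if min_coverage is not None and h.has_coordinates:
            span = min(h.qend - h.qstart + 1, h.send - h.sstart + 1)
            if h.length < min_coverage * span:
                continue
        n += 1
    return n


def compute_dairi(summary: ComparisonSummary) -> float:
    """Percentage of recorded comparisons with 100% identity."""
    if summary.n_total == 0:
        raise UndefinedIndexError("DAIRI is undefined for an empty hit table")
    return 100.0 * summary.n_identical / summary.n_total


def compute_idairi(summary: ComparisonSummary) -> float:
    """Size-normalized inter-database identity percentage."""
    if summary.n_total == 0:
        raise UndefinedIndexError("IDAIRI is undefined for an empty hit table")
    if summary.n_reference_db == 0:
        raise UndefinedIndexError("IDAIRI is undefined with an empty reference database")
    fraction = summary.n_identical / summary.n_total
    return 100.0 * fraction * (summary.n_compared_db / summary.n_reference_db)


def comparison_bound(n_reference: int, n_target: int) -> int:
    """Maximum number of recordable comparisons: the size product.

    Each reference sequence can match every target sequence at most once in
    the recorded table, so 5000 x 3000 sequences bound the table at 15
    million rows.
    """
    if n_reference < 0 or n_target < 0:
        raise ValueError("sequence counts must be non-negative")
    return n_reference * n_target


def self_comparison_report(table: HitTable) -> RedundancyReport:
    """DAIRI_d of a self-comparison hit table."""
    n_identical = count_identical(table)
    summary = ComparisonSummary(n_total=table.n_total, n_identical=n_identical)
    return RedundancyReport(
        dairi=compute_dairi(summary),
        n_total=table.n_total,
        n_identical=n_identical,
    )


def cross_comparison_report(
    table: HitTable,
    n_compared: int | SequenceDatabase,
    n_reference: int | SequenceDatabase,
) -> RedundancyReport:
    """DAIRI_d and IDAIRI_d of a cross-comparison hit table.

    Database arguments use their obtained (validated) counts.
    """

    def _count(x: int | SequenceDatabase) -> int:
        if isinstance(x, SequenceDatabase):
            return x.n_obtained if x.n_obtained is not None else len(x)
        return x

    nc, nr = _count(n_compared), _count(n_reference)
    n_identical = count_identical(table)
    summary = ComparisonSummary(
        n_total=table.n_total,
        n_identical=n_identical,
        n_compared_db=nc,
        n_reference_db=nr,
    )
    return RedundancyReport(
        dairi=compute_dairi(summary),
        idairi=compute_idairi(summary),
        normalization_factor=nc / nr,
        n_total=table.n_total,
        n_identical=n_identical,
    )
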