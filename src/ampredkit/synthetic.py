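"""Synthetic peptide databases and proteomes with known ground truth.

These generators emulate the inputs of the redundancy analysis so every
pipeline stage can be exercised without downloading live databases: peptide
collections with controlled fractions of exact duplicates and of records
corrupted with non-standard symbols, database pairs with a planted overlap
and size ratio, and proteomes whose proteins embed partially mutated copies
of known peptides with trypsin-compatible cleavage motifs planted at (or
deliberately scrubbed from) the domain flanks.

All randomness flows from a single seeded generator, so the same seed yields
byte-identical FASTA output, and every planted fact is recorded in a
:class:`GroundTruth` that can be re-verified by scanning the emitted records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PeptideRecord, SequenceDatabase

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NONSTANDARD = "XBZJUO"
#: residues safe to write into scrubbed flank windows (no K/R, no P)
_NEUTRAL = "GSTANQ"


@dataclass(frozen=True)
class SyntheticDbSpec:
    """Recipe for one synthetic peptide database."""

    n_sequences: int
    length_range: tuple[int, int] = (6, 100)
    duplicate_fraction: float = 0.0
    nonstandard_fraction: float = 0.0
    seed: int = 0
    name: str = "synthetic"
    composition: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_sequences < 0:
            raise ValueError("n_sequences must be non-negative")
        if not (0 <= self.duplicate_fraction <= 1 and 0 <= self.nonstandard_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length range {self.length_range}")


@dataclass
class GroundTruth:
    """Planted facts about a synthetic dataset, for oracle checks."""

    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    corrupted_ids: list[str] = field(default_factory=list)
    # (protein id, peptide id, start, end, target identity)
    planted_domains: list[tuple[str, str, int, int, float]] = field(default_factory=list)
    # (protein id, position, enzyme)
    planted_sites: list[tuple[str, int, str]] = field(default_factory=list)
    # protein id -> expected releasable verdict (proteome generator only)
    releasable: dict[str, bool] = field(default_factory=dict)


def _residue_sampler(rng: np.random.Generator, composition: dict[str, float] | None):
    if composition is None:
        letters = np.array(list(AA20))
        probs = None
    else:
        letters = np.array(list(composition.keys()))
        probs = np.array(list(composition.values()), dtype=float)
        probs = probs / probs.sum()

    def draw(n: int) -> str:
        return "".join(rng.choice(letters, size=n, p=probs))

    return draw


def corrupt_with_nonstandard(sequence: str, rng: np.random.Generator) -> str:
    """Replace one random residue with a non-standard symbol."""
    pos = int(rng.integers(0, len(sequence)))
    bad = NONSTANDARD[int(rng.integers(0, len(NONSTANDARD)))]
    return sequence[:pos] + bad + sequence[pos + 1 :]


def generate_peptide_db(spec: SyntheticDbSpec) -> tuple[SequenceDatabase, GroundTruth]:
    """Generate a peptide database realizing the requested fractions exactly.

    ``round(duplicate_fraction * n)`` records are exact copies of earlier
    records and ``round(nonstandard_fraction * n)`` records (disjoint from
    the duplicate pairs) carry one non-standard symbol.  Reproducible given
    the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sequences
    n_dup = int(round(spec.duplicate_fraction * n))
    n_bad = int(round(spec.nonstandard_fraction * n))
    if n_dup > max(n - 1, 0):
        raise ValueError(
            f"cannot plant {n_dup} duplicates in {n} records (need earlier originals)"
        )
    draw = _residue_sampler(rng, spec.composition)
    lo, hi = spec.length_range

    ids = [f"{spec.name}_{i + 1:05d}" for i in range(n)]
    # duplicate positions: any index > 0; each copies a random earlier original
    dup_positions = set(
        int(i) for i in rng.choice(np.arange(1, n), size=n_dup, replace=False)
    ) if n_dup else set()

    sequences: list[str] = []
    truth = GroundTruth()
    for i in range(n):
        if i in dup_positions:
            originals = [j for j in range(i) if j not in dup_positions]
            # guaranteed non-empty: index 0 is never a duplicate position
            src = originals[int(rng.integers(0, len(originals)))]
            sequences.append(sequences[src])
            truth.duplicate_pairs.append((ids[src], ids[i]))
        else:
            length = int(rng.integers(lo, hi + 1))
            sequences.append(draw(length))

    # corruption targets: records not involved in any duplicate relationship
    involved = set(dup_positions)
    for src_id, _ in truth.duplicate_pairs:
        involved.add(ids.index(src_id))
    eligible = [i for i in range(n) if i not in involved]
    if n_bad > len(eligible):
        raise ValueError(
            f"cannot corrupt {n_bad} records: only {len(eligible)} are outside duplicate pairs"
        )
    if n_bad:
        bad_positions = sorted(
            int(i) for i in rng.choice(np.array(eligible), size=n_bad, replace=False)
        )
        for i in bad_positions:
            sequences[i] = corrupt_with_nonstandard(sequences[i], rng)
            truth.corrupted_ids.append(ids[i])

    records = [
        PeptideRecord(id=ids[i], sequence=sequences[i], db_name=spec.name)
        for i in range(n)
    ]
    db = SequenceDatabase(name=spec.name, records=records, n_theoretical=n)
    return db, truth


def generate_database_pair(
    reference_spec: SyntheticDbSpec,
    overlap_fraction: float,
    size_ratio: float,
    seed: int = 0,
    compared_name: str = "compared",
) -> tuple[SequenceDatabase, SequenceDatabase, GroundTruth]:
    """Generate a (reference, compared) database pair with a planted overlap.

    The compared database holds ``round(size_ratio * n_reference)`` records,
    of which ``floor(overlap_fraction * size)`` are exact copies of distinct
    reference records; the remainder are novel sequences constructed to
    differ from every reference sequence.  Ground-truth duplicate pairs are
    (reference id, compared id).
    """
    if not (0 <= overlap_fraction <= 1):
        raise ValueError("overlap_fraction must lie in [0, 1]")
    if size_ratio <= 0:
        raise ValueError("size_ratio must be positive")

    reference, _ = generate_peptide_db(reference_spec)
    rng = np.random.default_rng(seed)
    draw = _residue_sampler(rng, reference_spec.composition)
    lo, hi = reference_spec.length_range

    n_cmp = int(round(size_ratio * len(reference)))
    n_overlap = int(overlap_fraction * n_cmp)
    if n_overlap > len(reference):
        raise ValueError(
            f"overlap of {n_overlap} exceeds the {len(reference)} reference records"
        )

    ref_seqs = {r.sequence for r in reference.records}
    chosen = sorted(
        int(i) for i in rng.choice(len(reference), size=n_overlap, replace=False)
    )
    truth = GroundTruth()
    records: list[PeptideRecord] = []
    for i in range(n_cmp):
        rid = f"{compared_name}_{i + 1:05d}"
        if i < n_overlap:
            src = reference.records[chosen[i]]
            records.append(PeptideRecord(id=rid, sequence=src.sequence, db_name=compared_name))
            truth.duplicate_pairs.append((src.id, rid))
        else:
            while True:
                seq = draw(int(rng.integers(lo, hi + 1)))
                if seq not in ref_seqs:
                    break
            records.append(PeptideRecord(id=rid, sequence=seq, db_name=compared_name))
    compared = SequenceDatabase(name=compared_name, records=records, n_theoretical=n_cmp)
    return reference, compared, truth


def _mutate_domain(
    peptide: str, identity_target: float, rng: np.random.Generator
) -> str:
    """Point-substitute a copy of the peptide down to the target identity.

    The first and last residues are never touched, so flank-site guarantees
    (cleavage context at the domain boundaries) stay valid.
    """
    plen = len(peptide)
    n_mut = int(round((1.0 - identity_target) * plen))
    mutable = list(range(1, plen - 1))
    n_mut = min(n_mut, len(mutable))
    if n_mut == 0:
        return peptide
    positions = rng.choice(np.array(mutable), size=n_mut, replace=False)
    seq = list(peptide)
    for pos in sorted(int(p) for p in positions):
        choices = [c for c in AA20 if c != seq[pos]]
        seq[pos] = choices[int(rng.integers(0, len(choices)))]
    return "".join(seq)


def generate_proteome_with_domains(
    n_proteins: int,
    amp_db: SequenceDatabase,
    identity_target: float = 1.0,
    flank_site_mode: str = "within-window",
    window: int = 10,
    seed: int = 0,
    protein_length_range: tuple[int, int] = (150, 600),
    name: str = "proteome",
) -> tuple[SequenceDatabase, GroundTruth]:
    """Generate proteins embedding mutated AMP-like domains with known flanks.

    Each protein carries one domain: a copy of a randomly chosen peptide from
    ``amp_db`` point-substituted down to ``identity_target``.  Trypsin-style
    cleavage motifs (K at P1, non-proline at P1') are planted around the
    domain according to ``flank_site_mode``:

    - ``at-flank``: a site directly at (or, where the domain's own boundary
      residue forbids it, one residue outside) each flank;
    - ``within-window``: one site a random 1..window residues outside each
      flank;
    - ``absent``: K/R scrubbed from both flank windows and the residue after
      the domain set to proline, so no trypsin site can release the domain.

    Ground truth records domain spans, planted site positions, and the
    expected releasable verdict under the trypsin rule with this ``window``.
    """
    if not amp_db.records:
        raise ValueError("amp_db must be non-empty")
    if not (0 < identity_target <= 1):
        raise ValueError("identity_target must lie in (0, 1]")
    if flank_site_mode not in ("at-flank", "within-window", "absent"):
        raise ValueError(f"unknown flank_site_mode {flank_site_mode!r}")

    rng = np.random.default_rng(seed)
    lo, hi = protein_length_range
    margin = window + 4  # clearance so flank windows sit inside the protein
    truth = GroundTruth()
    records: list[PeptideRecord] = []

    for i in range(n_proteins):
        pid = f"{name}_{i + 1:05d}"
        peptide = amp_db.records[int(rng.integers(0, len(amp_db.records)))]
        plen = peptide.length
        min_len = plen + 2 * margin
        if min_len > hi:
            raise ValueError(
                f"peptide {peptide.id} ({plen} aa) does not fit a protein of <= {hi} aa"
            )
        length = int(rng.integers(max(lo, min_len), hi + 1))
        seq = list("".join(rng.choice(np.array(list(AA20)), size=length)))

        start = int(rng.integers(margin + 1, length - plen - margin + 1))  # 1-based
        end = start + plen - 1
        domain = _mutate_domain(peptide.sequence, identity_target, rng)
        seq[start - 1 : end] = list(domain)

        def plant_site(p: int) -> None:
            # cleavage between residues p and p+1: K at p, non-P at p+1
            seq[p - 1] = "K"
            if seq[p] == "P":
                seq[p] = "G"
            truth.planted_sites.append((pid, p, "trypsin"))

        if flank_site_mode == "at-flank":
            if domain[0] != "P":
                plant_site(start - 1)
            else:  # a P1' proline blocks the boundary cut; move one residue out
                seq[start - 2] = "G"
                plant_site(start - 2)
            if domain[-1] in "KR":
                if seq[end] == "P":
                    seq[end] = "G"
                truth.planted_sites.append((pid, end, "trypsin"))
            else:
                plant_site(end + 1)
            truth.releasable[pid] = True
        elif flank_site_mode == "within-window":
            d_up = int(rng.integers(1, window + 1))
            d_down = int(rng.integers(1, window + 1))
            plant_site(start - 1 - d_up)
            plant_site(end + d_down)
            truth.releasable[pid] = True
        else:  # absent
            for p in range(start - 1 - window, start):
                if seq[p - 1] in "KR":
                    seq[p - 1] = _NEUTRAL[int(rng.integers(0, len(_NEUTRAL)))]
            seq[end] = "P"  # P1' proline blocks the cut at the C-flank itself
            for p in range(end + 2, end + window + 1):
                if seq[p - 1] in "KR":
                    seq[p - 1] = _NEUTRAL[int(rng.integers(0, len(_NEUTRAL)))]
            truth.releasable[pid] = False

        truth.planted_domains.append((pid, peptide.id, start, end, identity_target))
        records.append(PeptideRecord(id=pid, sequence="".join(seq), db_name=name))

    db = SequenceDatabase(name=name, records=records, n_theoretical=n_proteins)
    return db, truth
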