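# Methods

## The problem

Public antimicrobial-peptide (AMP) databases overlap heavily: curators import
from one another, and popular peptides are deposited many times. Two
questions follow. How internally repetitive is a database, and how much of a
database duplicates a chosen reference once their different sizes are
accounted for? A third, downstream question is whether AMP-like segments
found inside a proteome's proteins could actually be liberated by
proteolysis. `ampredkit` answers all three with explicit, auditable
arithmetic over a standard similarity search.

## Redundancy indices

Both indices operate on a *recorded* hit table: the comparisons a search
actually reported, not the theoretical all-pairs product. With
`n_identical` the number of recorded hits whose percent identity is exactly
100.0 (at the one-decimal precision of the tabular format) and `n_total` the
table size,

    DAIRI_d  = n_identical / n_total * 100
    IDAIRI_d = (n_identical / n_total) * (n_compared / n_reference) * 100

`n_compared` and `n_reference` are the *obtained* (post-validation) sequence
counts of the compared and reference databases, since only validated
sequences participate in comparisons. The normalization factor
`n_compared / n_reference` equals 1 for equally sized databases (then
IDAIRI_d = DAIRI_d exactly), shrinks the index when the compared database is
smaller, and can push IDAIRI_d above 100 when it is larger — a documented
consequence of the formula, not an error. Dividing by an empty table or an
empty reference raises rather than returning a sentinel.

"100% identity" is taken directly from the pident column with no coverage
requirement, mirroring how the tabular output is consumed in practice; an
optional minimum-coverage filter exists (`count_identical(min_coverage=...)`)
but is off by default. The maximum recordable table size for an
`n_r`-sequence reference against an `n_t`-sequence target is `n_r * n_t`
(one best hit per ordered pair), the bound `comparison_bound` computes.

Self-comparisons include self-pairs (a sequence matched against itself) by
default, with a flag to exclude them; with self-pairs included, a
self-comparison's DAIRI_d is at least `100 * n_obtained / n_total`.

## Sequence validation

A sequence is retained iff, after upper-casing and whitespace stripping,
every character is one of the 20 standard amino-acid letters
(ACDEFGHIKLMNPQRSTVWY). B, J, O, U, X, Z, stops, gaps and digits all reject
the record. The database tracks `n_theoretical` (parsed records) and
`n_obtained` (retained records); rejected identifiers are logged as
`id<TAB>reason`. Validation is idempotent. Duplicate identifiers within one
FASTA are kept and disambiguated with an ordinal suffix so `n_theoretical`
stays faithful to the file; dropping them would silently change the
denominator arithmetic.

## The search

The aligner follows the standard two-stage high-throughput design:

1. **Reduced-alphabet seeding.** Residues are mapped onto 11 groups
   ([KREDQN] [C] [G] [H] [ILV] [M] [F] [Y] [W] [P] [STA]); an inverted index
   over reduced k-mers (default k = 4, contiguous; spaced masks via a 0/1
   string) nominates subject sequences sharing at least one seed with the
   query. If query and subject share an exact unreduced substring of length
   ≥ k they necessarily share a reduced k-mer, so seeding can only lose pairs
   whose best alignment contains no such run.
2. **Extension.** Candidates are aligned with affine-gap Smith–Waterman
   (Biopython's `PairwiseAligner`; BLOSUM62, gap of length L costs
   11 + L × 1). Exhaustive mode skips seeding and aligns every pair; it is
   the sensitivity reference, and the test suite checks its optima against an
   independently written three-matrix Gotoh dynamic program.

Percent identity is 100 × identities / alignment columns with gap columns
included, rounded to one decimal — the convention of BLAST-style tabular
output and the exact quantity the indices consume. Scores are converted with
Karlin–Altschul statistics: bitscore = (λ·S − ln K)/ln 2 with λ = 0.267 and
K = 0.041 (the common gapped BLOSUM62/11/1 constants), and
E = m·n·2^(−bitscore) with m the query length and n the subject database's
total residue count, frozen at search start. Composition-based statistics are
not applied. One best-scoring hit per (query, subject) pair is recorded when
E ≤ the cutoff (default 0.001).

**Choosing the E-value cutoff.** The defaults are calibrated for
database-vs-database redundancy accounting. Note the arithmetic at desk
scale: a 100%-identity match needs roughly 12 aligned residues before it is
significant at E ≤ 0.001 against even a few thousand subject residues, and a
15-residue domain mutated to 70% identity sits near E ≈ 4×10⁻³. For proteome
screens whose goal is recall of short, diverged AMP-like domains — where hits
down to ~19% identity are still of interest — a permissive cutoff (E ≤ 1) is
the appropriate setting, and the recall tests use it; the statistical filter
is a reporting choice, not part of the recall property being tested.

**Tie-breaking.** Among co-optimal alignments the aligner's first traceback
is taken. It is deterministic for a fixed input (the requirement the
pipeline needs) but is not guaranteed to be the smallest-coordinate
traceback; enumerating all co-optimal paths to sort them can be exponential.

## Distribution reports

Scatter reports aggregate hits into (query length, pident) points with
multiplicities; histograms bin pident into [lo, hi) bins with the last bin
closed at 100 so exact duplicates are never split off the top (default width
5%). Both are lossless — frequencies and counts each sum to the table size —
and sorted for byte-stable files. Figures scale point area linearly with
frequency under a capped maximum marker size; all numbers are also emitted as
TSV so tests assert on data, never pixels. Lengths on the scatter X-axis are
query-side (the peptide collection) by default since the peptide is the
object whose size distribution is of interest; the mapping is an explicit
argument, so subject-side lengths are a one-line change.

## Similarity networks

A screen's hit table condenses to a strictly bipartite graph: one node per
distinct peptide and protein, one edge per (peptide, protein) pair carrying
the best (maximum-bitscore) hit's pident — the table may hold several rows
per pair, the graph draws one edge. Toxin flags come from a two-column TSV
and default to unknown. Connected components are extracted as a partition
(checked against a flood-fill oracle in tests) and sorted largest-first.
Exports: SIF (`peptide<TAB>similar_to<TAB>protein`), GraphML with
kind/toxin/pident attributes (toxin written only where annotated), and
edge + node TSVs. An optional minimum-pident filter prunes edges before
building; it is off by default rather than guessing an unstated threshold.

## In-silico digestion

Enzyme specificity is a zero-width regular expression evaluated between
residues: lookbehind describes P1 and earlier, lookahead P1' and later, so
trypsin is `(?<=[KR])(?!P)`. Position p (1-based) means cleavage between
residues p and p+1; termini are never sites. The shipped table (a packaged,
user-editable TSV) covers trypsin, Lys-C, Arg-C, Glu-C, high-specificity
chymotrypsin (`(?<=[FYW])(?!P)`), and a simplified pepsin at pH 1.3 (F/L at
P1 — not before proline — or at P1'); the pepsin rule is deliberately
simplified relative to full positional-preference models. `digest` fragments
always reassemble the input exactly.

A matched domain spanning residues s..e is **releasable** when each flank is
either at a protein terminus (already free) or has a cleavage site within the
window: upstream sites at positions s−1−w .. s−1 (a cut at s−1 is directly
flanking), downstream at e .. e+w. The default window w = 10 reflects that a
liberated fragment carrying ≤ 10 extra residues still presents the domain
essentially intact. Releasability is monotone in w — widening the window can
never flip yes to no — and sites from all supplied enzymes are pooled with
per-site attribution.

## Synthetic data: what it emulates and what it does not

The generators emulate the *structure* of the real inputs — peptide
collections of 6–100 residues (defaults; individual experiments may narrow
the range, see below), a controlled fraction of exact duplicates, a
controlled fraction of records corrupted with a non-standard symbol,
database pairs with a planted overlap and size ratio, and 150–600-residue
proteins embedding one mutated AMP-like domain each with trypsin-compatible
motifs planted at, near, or scrubbed from the flanks. Fractions are realized
exactly (rounded to whole records), all randomness flows from one seeded
generator (same seed ⇒ byte-identical FASTA), and every planted fact is
recorded in a ground-truth object that tests re-verify by scanning the
emitted sequences.

Residues are drawn uniformly by default; an optional composition table allows
cationic/hydrophobic bias. Uniform backgrounds mean unrelated records share
no significant local alignment, so a synthetic hit table contains *only* the
planted identity structure — DAIRI_d on such a table is exactly the planted
fraction of the recorded comparisons (typically 100% of them). Passing tests
therefore demonstrate exact accounting and recovery, **not** that the indices
reproduce any real database's values: real collections contain homologous
families that populate the 20–99% identity range, which no uniform-random
generator emulates. Domain mutations never touch the domain's first or last
residue, so flank-site ground truth stays valid; the flank-site guarantees
are scoped to the trypsin rule (the "absent" mode blocks the C-flank cut with
a proline follower and scrubs K/R from both flank windows).

## Numerical and design choices

- **Experiment sizes.** Index-recovery and determinism experiments use
  databases of tens-to-hundreds of 15–50-residue peptides and proteomes of a
  handful of proteins. The 15-residue floor in those experiments follows from
  the significance arithmetic above: shorter planted duplicates would be
  masked by any calibrated E-value cutoff, and chance short exact substrings
  would contaminate the 100%-identity count, so the floor makes exact oracle
  equality a fair check rather than a lottery. The generator's own default
  stays 6–100.
- **Precision.** pident and bitscore are reported at one decimal; E-values
  serialize via shortest-exact float representation so written tables re-read
  bit-identically. Index values print at two decimals.
- **Degenerate inputs.** Empty validated databases yield an empty hit table
  plus a warning (not an error); sequences shorter than the seed span simply
  contribute no postings; an all-negative scoring pair returns no hit.
- **Determinism.** Query and subject iteration order is database order;
  seeded-mode candidates are sorted by subject position; all workflow outputs
  are byte-reproducible from the manifest (inputs + parameters + seed).
- **Coordinates** are 1-based inclusive everywhere (alignment spans, domain
  spans, cleavage positions, seed offsets).

## Known limitations

- The seeded mode guarantees a candidate only when an exact unreduced
  k-substring is shared; strongly gapped or very short homologies can be
  missed relative to exhaustive mode (the containment the tests check is
  one-directional by design).
- Karlin–Altschul parameters are fixed constants, not fitted to the scoring
  system per search; E-values are therefore approximate, which is acceptable
  for redundancy accounting but not for marginal-significance inference.
- The digestion rules are context patterns with single exceptions, not
  cleavage-probability models; PTMs and enzyme kinetics are out of scope.
- Toxin annotation consumes a prepared two-column TSV; no live database
  queries are performed.
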