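# ampredkit

Antimicrobial-peptide (AMP) sequence collections are curated by many
independent groups, and the same peptides reappear across — and within —
databases. `ampredkit` quantifies that redundancy and mines proteomes for
AMP-like domains. It is aimed at researchers who assemble or compare peptide
databases and at teams screening a species' proteome (e.g. a snake-venom
proteome) for candidate antimicrobial peptides hidden inside larger proteins.

## What it computes

**Redundancy indices.** Given an all-vs-all similarity search whose recorded
comparisons number *n*<sub>total</sub>, of which *n*<sub>100%</sub> reached
100% sequence identity, the Database Absolute-Identity Repeatability Index is

&nbsp;&nbsp;&nbsp;&nbsp;DAIRI_d = *n*<sub>100%</sub> / *n*<sub>total</sub> × 100%

and the inter-database variant rescales by the size ratio of the compared
database (*n*<sub>c</sub> sequences) to the reference (*n*<sub>r</sub>):

&nbsp;&nbsp;&nbsp;&nbsp;IDAIRI_d = (*n*<sub>100%</sub> / *n*<sub>total</sub>) × (*n*<sub>c</sub> / *n*<sub>r</sub>) × 100%

When the databases are equally sized the normalization factor is 1 and
IDAIRI_d = DAIRI_d; a reference of 5000 sequences compared against a target
of 3000 can record at most 5000 × 3000 = 15,000,000 comparisons.

**The search.** A seed-and-extend local aligner: sequences are mapped onto an
11-group reduced alphabet ([KREDQN] [C] [G] [H] [ILV] [M] [F] [Y] [W] [P]
[STA]), candidate pairs sharing a reduced k-mer are aligned with affine-gap
Smith–Waterman (BLOSUM62, gap open 11 / extend 1), and hits are reported with
BLAST-style tabular fields (qseqid, sseqid, pident, length, evalue, bitscore,
coordinates) under Karlin–Altschul statistics. An exhaustive mode aligns
every pair and bounds what seeding can miss.

**Proteome mining.** A peptide collection screened against a proteome yields
a strictly bipartite peptide–protein similarity network (exported as GraphML
/ SIF / TSV for Cytoscape, with optional toxin annotations), connected-
component extraction, and — for each matched AMP-like domain — a rule-based
protease digestion test of whether cleavage sites at or near both flanks
(default window: 10 residues) would allow the domain to be released from its
host protein.

**Synthetic data.** Generators produce peptide databases with controlled
duplicate and corrupted-record fractions, database pairs with a planted
overlap and size ratio, and proteomes with embedded, partially mutated
AMP-like domains and planted cleavage motifs — every planted fact is recorded
as ground truth, so the whole pipeline is testable without downloads.

## Worked example

Generate a synthetic database pair (40 + 40 peptides of 15–50 residues, the
reference carrying 20% exact duplicates, half of the compared database copied
from the reference) and run the comparison workflow:

```sh
cat > pair.yaml <<EOF
reference:
  n_sequences: 40
  length_range: [15, 50]
  duplicate_fraction: 0.2
overlap_fraction: 0.5
size_ratio: 1.0
EOF
ampredkit simulate pair --spec pair.yaml --seed 17 --out-dir sim
ampredkit run-comparison --reference sim/reference.fasta \
    --target sim/compared.fasta --mode exhaustive --out-dir out
```

which prints

```
reference	DAIRI_d=100.00	IDAIRI_d=-
compared	DAIRI_d=100.00	IDAIRI_d=-
reference_vs_compared	DAIRI_d=100.00	IDAIRI_d=100.00
```

and writes `out/indices.tsv`:

```
database	dairi	idairi	normalization_factor	n_total	n_identical
reference	100.00			58	58
compared	100.00			44	44
reference_vs_compared	100.00	100.00	1	29	29
```

Reading the numbers: the reference's self-comparison records 58 hits — its 40
self-pairs plus both orientations of the planted duplicate pairs — and every
recorded hit is at 100% identity, so DAIRI_d is 100%. (Unrelated uniform-
random peptides share no statistically significant local alignment at the
default E ≤ 0.001, so unlike a real database of homologous families, a
synthetic table contains *only* the identity structure.) The cross-comparison
records 29 hits, all exact copies; the two databases are equally sized, so
the normalization factor is 1 and IDAIRI_d equals DAIRI_d, the documented
limit of the size normalization. Alongside the TSVs the run writes
similarity-vs-length scatter reports, identity histograms (SVG + TSV), and a
JSON manifest of all parameters.

Release testing from the shell:

```sh
$ ampredkit digest --protein protein.fasta --domain 5:10 --enzymes trypsin --window 0
p	yes	upstream=4:trypsin	downstream=10:trypsin
```

— trypsin sites directly at both flanks, so the 6-residue domain is
releasable even with a zero-residue window.

See `ampredkit --help` for the remaining subcommands (`validate`, `search`,
`indices`, `plots`, `screen`, `network`, `run-mining`, `simulate`).

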