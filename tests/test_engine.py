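"""Reduced alphabet, seeding, and local-alignment correctness.

The exhaustive aligner is checked against an independently written
three-matrix Gotoh dynamic program; the seeded mode is checked for
containment in, and guaranteed-substring sensitivity relative to, the
exhaustive mode.
"""

from __future__ import annotations

import math

import pytest

from ampredkit import (
    AlignmentParams,
    PeptideRecord,
    SequenceDatabase,
    build_seed_index,
    local_align,
    reduce_alphabet,
    search,
    validate_database,
)
from ampredkit.alphabet import DEFAULT_GROUPS, ReducedAlphabet
from ampredkit.engine import iter_seeds

from conftest import random_peptide
from oracles import gotoh_local_score


def _raw_from_bitscore(bitscore: float, params: AlignmentParams) -> float:
    return (bitscore * math.log(2) + math.log(params.k_const)) / params.lambda_


class TestReducedAlphabet:
    def test_group_members_collapse(self):
        assert len(set(reduce_alphabet("ILV"))) == 1
        assert len(set(reduce_alphabet("KREDQN"))) == 1
        assert len(set(reduce_alphabet("STA"))) == 1

    def test_image_has_eleven_symbols(self):
        image = reduce_alphabet("ACDEFGHIKLMNPQRSTVWY")
        assert len(set(image)) == 11

    def test_length_preserved(self, rng):
        seq = random_peptide(rng, 73)
        assert len(reduce_alphabet(seq)) == len(seq)

    def test_partition_enforced(self):
        with pytest.raises(ValueError):
            ReducedAlphabet(groups=("KREDQN", "C"))  # not covering
        with pytest.raises(ValueError):
            ReducedAlphabet(groups=DEFAULT_GROUPS + ("A",))  # overlapping

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError, match="X"):
            reduce_alphabet("ACX")


class TestSeedIndex:
    def _db(self, seqs: dict[str, str]) -> SequenceDatabase:
        recs = [PeptideRecord(id=k, sequence=v) for k, v in seqs.items()]
        return SequenceDatabase(name="d", records=recs, n_theoretical=len(recs))

    def test_homopolymer_postings(self):
        index = build_seed_index(self._db({"a": "KKKK"}), k=3)
        assert len(index.table) == 1
        (postings,) = index.table.values()
        assert postings == [("a", 1), ("a", 2)]

    def test_total_postings_formula(self, rng):
        k = 4
        seqs = {
            f"s{i}": random_peptide(rng, int(rng.integers(2, 30))) for i in range(50)
        }
        index = build_seed_index(self._db(seqs), k=k)
        expected = sum(max(len(s) - k + 1, 0) for s in seqs.values())
        assert index.n_postings == expected

    def test_reduction_equivalent_sequences_share_seeds(self):
        # I/L/V are one group, so these index identically
        index = build_seed_index(self._db({"a": "ILVILV", "b": "VLIVLI"}), k=3)
        for postings in index.table.values():
            assert {sid for sid, _ in postings} == {"a", "b"}

    def test_short_sequence_contributes_nothing(self):
        index = build_seed_index(self._db({"a": "AC"}), k=4)
        assert index.n_postings == 0

    def test_spaced_seed_mask(self):
        words = list(iter_seeds("ABCDE", "101"))
        assert words == ["AC", "BD", "CE"]


class TestLocalAlign:
    def test_identity_pident_and_length(self):
        rec = PeptideRecord(id="a", sequence="ACDEFGHIKLMN")
        hit = local_align(rec, rec, AlignmentParams(evalue_cutoff=10.0))
        assert hit.pident == 100.0
        assert hit.length == 12
        assert (hit.qstart, hit.qend, hit.sstart, hit.send) == (1, 12, 1, 12)

    def test_exhaustive_score_matches_dp_oracle(self, rng, permissive_params):
        checked = 0
        for _ in range(210):
            a = random_peptide(rng, int(rng.integers(6, 61)))
            b = random_peptide(rng, int(rng.integers(6, 61)))
            hit = local_align(
                PeptideRecord(id="a", sequence=a),
                PeptideRecord(id="b", sequence=b),
                permissive_params,
            )
            oracle = gotoh_local_score(a, b)
            if hit is None:
                assert oracle == 0.0
            else:
                raw = _raw_from_bitscore(hit.bitscore, permissive_params)
                assert round(raw) == oracle
                checked += 1
        assert checked >= 200

    def test_score_symmetry(self, rng, permissive_params):
        for _ in range(20):
            a = PeptideRecord(id="a", sequence=random_peptide(rng, 40))
            b = PeptideRecord(id="b", sequence=random_peptide(rng, 40))
            hab = local_align(a, b, permissive_params)
            hba = local_align(b, a, permissive_params)
            assert (hab is None) == (hba is None)
            if hab is not None:
                assert hab.bitscore == hba.bitscore

    def test_compositionally_disjoint_pair_yields_none(self):
        # all-K vs all-G: K/G BLOSUM62 score is negative, no positive cell
        q = PeptideRecord(id="q", sequence="K" * 30)
        s = PeptideRecord(id="s", sequence="G" * 30)
        assert gotoh_local_score(q.sequence, s.sequence) == 0.0
        assert local_align(q, s, AlignmentParams(evalue_cutoff=1e9)) is None

    def test_empty_sequence_is_contract_violation(self):
        with pytest.raises(ValueError):
            PeptideRecord(id="q", sequence="")

    def test_evalue_scales_with_database_size(self):
        rec = PeptideRecord(id="a", sequence="ACDEFGHIKLMN")
        small = local_align(rec, rec, AlignmentParams(evalue_cutoff=1e9),
                            subject_total_residues=100)
        big = local_align(rec, rec, AlignmentParams(evalue_cutoff=1e9),
                          subject_total_residues=100_000)
        assert big.evalue == pytest.approx(small.evalue * 1000)


class TestSearch:
    def test_self_search_identity_hits(self, rng):
        recs = [
            PeptideRecord(id=f"s{i}", sequence=random_peptide(rng, 25), db_name="d")
            for i in range(10)
        ]
        db = validate_database(
            SequenceDatabase(name="d", records=recs, n_theoretical=10)
        )
        table = search(db, db, AlignmentParams(mode="exhaustive"))
        self_hits = {h.qseqid: h for h in table.hits if h.qseqid == h.sseqid}
        assert len(self_hits) == 10
        assert all(h.pident == 100.0 for h in self_hits.values())

    def test_total_bounded_by_size_product(self, small_validated_db, permissive_params):
        table = search(small_validated_db, small_validated_db, permissive_params)
        n = small_validated_db.n_obtained
        assert table.n_total <= n * n

    def test_seeded_hits_subset_of_exhaustive(self, rng):
        recs = [
            PeptideRecord(
                id=f"s{i}", sequence=random_peptide(rng, int(rng.integers(10, 50))),
                db_name="d",
            )
            for i in range(50)
        ]
        db = validate_database(
            SequenceDatabase(name="d", records=recs, n_theoretical=50)
        )
        exhaustive = search(db, db, AlignmentParams(mode="exhaustive", evalue_cutoff=1.0))
        seeded = search(db, db, AlignmentParams(mode="seeded", evalue_cutoff=1.0))
        ex_pairs = {(h.qseqid, h.sseqid): h.bitscore for h in exhaustive.hits}
        sd_pairs = {(h.qseqid, h.sseqid): h.bitscore for h in seeded.hits}
        assert set(sd_pairs) <= set(ex_pairs)
        assert all(ex_pairs[p] == s for p, s in sd_pairs.items())

    def test_shared_substring_guarantees_seeded_candidate(self, rng):
        # planted exact 4-mer in otherwise unrelated sequences
        core = "WCHM"
        a = random_peptide(rng, 20) + core + random_peptide(rng, 20)
        b = random_peptide(rng, 15) + core + random_peptide(rng, 15)
        db = validate_database(SequenceDatabase(
            name="d",
            records=[PeptideRecord(id="b", sequence=b, db_name="d")],
            n_theoretical=1,
        ))
        index = build_seed_index(db, k=4)
        assert "b" in index.candidates(reduce_alphabet(a))

    def test_lowering_cutoff_never_adds_hits(self, small_validated_db):
        loose = search(small_validated_db, small_validated_db,
                       AlignmentParams(mode="exhaustive", evalue_cutoff=10.0))
        strict = search(small_validated_db, small_validated_db,
                        AlignmentParams(mode="exhaustive", evalue_cutoff=1e-6))
        loose_pairs = {(h.qseqid, h.sseqid) for h in loose.hits}
        strict_pairs = {(h.qseqid, h.sseqid) for h in strict.hits}
        assert strict_pairs <= loose_pairs

    def test_exclude_self_pairs_flag(self, small_validated_db, exhaustive_params):
        with_self = search(small_validated_db, small_validated_db, exhaustive_params)
        params = AlignmentParams(mode="exhaustive", include_self_pairs=False)
        without = search(small_validated_db, small_validated_db, params)
        assert all(h.qseqid != h.sseqid for h in without.hits)
        n = small_validated_db.n_obtained
        assert with_self.n_total - without.n_total == n

    def test_empty_database_warns_and_returns_empty(self, small_validated_db, caplog):
        empty = SequenceDatabase(name="e", records=[], n_theoretical=0, n_obtained=0)
        with caplog.at_level("WARNING"):
            table = search(small_validated_db, empty)
        assert table.n_total == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            AlignmentParams(seed_length=1)
        with pytest.raises(ValueError):
            AlignmentParams(gap_open=1, gap_extend=5)
        with pytest.raises(ValueError):
            AlignmentParams(mode="fast")
        with pytest.raises(ValueError):
            AlignmentParams(spaced_seed_mask="1012")
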