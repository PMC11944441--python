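"""Proteome screening and the bipartite similarity network."""

from __future__ import annotations

import networkx as nx
import pytest

from ampredkit import (
    AlignmentHit,
    AlignmentParams,
    HitTable,
    PeptideRecord,
    SequenceDatabase,
    build_network,
    export_network,
    extract_components,
    screen_proteome,
    validate_database,
)
from ampredkit.network import read_annotations
from ampredkit.synthetic import SyntheticDbSpec, generate_peptide_db, generate_proteome_with_domains

from conftest import random_peptide
from oracles import flood_fill_components


def _hit(q: str, s: str, pident: float, bitscore: float = 50.0) -> AlignmentHit:
    return AlignmentHit(q, s, pident, 10, 1e-9, bitscore)


def _table_5_fixture() -> HitTable:
    """Two peptides each hitting the same nineteen proteins."""
    hits = [
        _hit(pep, f"prot{i:02d}", 30.0 + i)
        for pep in ("pepA", "pepB")
        for i in range(19)
    ]
    return HitTable(hits=hits)


@pytest.fixture
def amp_and_proteome():
    amp_spec = SyntheticDbSpec(n_sequences=8, length_range=(15, 40), seed=11, name="amps")
    amps, _ = generate_peptide_db(amp_spec)
    proteome, truth = generate_proteome_with_domains(
        6, amps, identity_target=0.7, flank_site_mode="within-window", seed=5
    )
    return validate_database(amps), validate_database(proteome), truth


class TestScreenProteome:
    def test_exact_embedded_peptide_found_at_100(self, rng):
        pep = PeptideRecord(id="p", sequence=random_peptide(rng, 25), db_name="amps")
        protein = PeptideRecord(
            id="host",
            sequence=random_peptide(rng, 100) + pep.sequence + random_peptide(rng, 80),
            db_name="prot",
        )
        amps = SequenceDatabase(name="amps", records=[pep], n_theoretical=1, n_obtained=1)
        prot = SequenceDatabase(name="prot", records=[protein], n_theoretical=1, n_obtained=1)
        table = screen_proteome(amps, prot, AlignmentParams(mode="exhaustive"))
        hit = next(h for h in table.hits if h.pident == 100.0)
        assert (hit.sstart, hit.send) == (101, 125)
        assert (hit.qstart, hit.qend) == (1, 25)

    def test_mutated_domains_all_recovered(self, amp_and_proteome):
        # short 70%-identity domains are marginally significant, so the recall
        # property is tested with a permissive reporting threshold
        amps, proteome, truth = amp_and_proteome
        table = screen_proteome(
            amps, proteome, AlignmentParams(mode="exhaustive", evalue_cutoff=1.0)
        )
        found = {(h.qseqid, h.sseqid) for h in table.hits}
        for pid, pep_id, start, end, _ in truth.planted_domains:
            assert (pep_id, pid) in found

    def test_hit_coordinates_overlap_planting_record(self, amp_and_proteome):
        amps, proteome, truth = amp_and_proteome
        table = screen_proteome(
            amps, proteome, AlignmentParams(mode="exhaustive", evalue_cutoff=1.0)
        )
        best = {}
        for h in table.hits:
            key = (h.qseqid, h.sseqid)
            if key not in best or h.bitscore > best[key].bitscore:
                best[key] = h
        for pid, pep_id, start, end, _ in truth.planted_domains:
            h = best[(pep_id, pid)]
            # the best match must substantially overlap the planted span
            overlap = min(h.send, end) - max(h.sstart, start) + 1
            assert overlap >= 0.5 * (end - start + 1)

    def test_empty_input_warns(self, amp_and_proteome, caplog):
        amps, _, _ = amp_and_proteome
        empty = SequenceDatabase(name="e", records=[], n_theoretical=0, n_obtained=0)
        with caplog.at_level("WARNING"):
            table = screen_proteome(amps, empty)
        assert table.n_total == 0


class TestBuildNetwork:
    def test_table5_shaped_fixture(self):
        net = build_network(_table_5_fixture())
        assert net.n_nodes == 21
        assert net.n_edges == 38
        comps = extract_components(net)
        assert len(comps) == 1

    def test_empty_table(self):
        net = build_network(HitTable())
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_duplicate_pair_hits_collapse_to_best(self):
        table = HitTable(
            hits=[_hit("p", "x", 40.0, bitscore=30.0), _hit("p", "x", 55.0, bitscore=60.0)]
        )
        net = build_network(table)
        assert net.n_edges == 1
        assert net.edges[0][2] == 55.0

    def test_bipartite_and_annotations(self):
        net = build_network(_table_5_fixture(), annotations={"prot00": True, "prot01": False})
        kinds = {n.id: n.kind for n in net.nodes}
        for pep, prot, _ in net.edges:
            assert kinds[pep] == "peptide" and kinds[prot] == "protein"
        g = net.to_networkx()
        assert nx.is_bipartite(g)
        toxin = {n.id: n.toxin for n in net.nodes}
        assert toxin["prot00"] is True
        assert toxin["prot01"] is False
        assert toxin["prot05"] is None

    def test_min_pident_filter(self):
        net = build_network(_table_5_fixture(), min_pident=40.0)
        assert all(p >= 40.0 for _, _, p in net.edges)


class TestExtractComponents:
    def test_two_planted_clusters(self):
        hits = [_hit("a", "x", 50.0), _hit("a", "y", 60.0), _hit("b", "z", 70.0)]
        comps = extract_components(build_network(HitTable(hits=hits)))
        assert len(comps) == 2
        assert comps[0].n_nodes == 3  # sorted largest first

    def test_partition_conserves_nodes_and_edges(self, rng):
        hits = [
            _hit(f"p{int(rng.integers(0, 15))}", f"x{int(rng.integers(0, 25))}", 50.0)
            for _ in range(60)
        ]
        net = build_network(HitTable(hits=hits))
        comps = extract_components(net)
        assert sum(c.n_nodes for c in comps) == net.n_nodes
        assert sum(c.n_edges for c in comps) == net.n_edges
        ids = [n.id for c in comps for n in c.nodes]
        assert len(ids) == len(set(ids))

    def test_matches_flood_fill_oracle_on_random_graphs(self, rng):
        for trial in range(50):
            n_pep, n_prot = int(rng.integers(1, 12)), int(rng.integers(1, 12))
            hits = [
                _hit(f"p{int(rng.integers(0, n_pep))}", f"x{int(rng.integers(0, n_prot))}", 50.0)
                for _ in range(int(rng.integers(1, 30)))
            ]
            net = build_network(HitTable(hits=hits))
            comps = {frozenset(n.id for n in c.nodes) for c in extract_components(net)}
            oracle = set(
                flood_fill_components(
                    [n.id for n in net.nodes], [(u, v) for u, v, _ in net.edges]
                )
            )
            assert comps == oracle


class TestExportNetwork:
    def test_sif_single_edge(self, tmp_path):
        net = build_network(HitTable(hits=[_hit("p", "x", 50.0)]))
        path = tmp_path / "net.sif"
        export_network(net, "sif", path)
        assert path.read_text() == "p\tsimilar_to\tx\n"

    def test_graphml_round_trip(self, tmp_path):
        net = build_network(_table_5_fixture(), annotations={"prot00": True})
        path = tmp_path / "net.graphml"
        export_network(net, "graphml", path)
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == 21
        assert g.number_of_edges() == 38
        assert g.nodes["prot00"]["toxin"] is True
        assert "toxin" not in g.nodes["prot05"]

    def test_edge_tsv_with_node_attributes(self, tmp_path):
        net = build_network(_table_5_fixture(), annotations={"prot00": True})
        path = tmp_path / "net.edges.tsv"
        export_network(net, "edge-tsv", path)
        assert path.read_text().splitlines()[0] == "qseqid\tsseqid\tpident"
        nodes = (tmp_path / "net.edges.nodes.tsv").read_text().splitlines()
        assert nodes[0] == "id\tkind\ttoxin"
        assert len(nodes) == 22

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(build_network(HitTable()), "dot", tmp_path / "x")


class TestAnnotations:
    def test_two_column_tsv(self, tmp_path):
        p = tmp_path / "tox.tsv"
        p.write_text("id\ttoxin\nA\tyes\nB\tno\n")
        assert read_annotations(p) == {"A": True, "B": False}

    def test_bad_flag_rejected(self, tmp_path):
        p = tmp_path / "tox.tsv"
        p.write_text("A\tmaybe\n")
        with pytest.raises(ValueError, match="row 1"):
            read_annotations(p)
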