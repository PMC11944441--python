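"""Proteome screening and bipartite peptide-protein similarity networks.

A peptide collection is searched against a proteome; the resulting hits are
condensed into a strictly bipartite graph with one node per peptide and per
protein and one identity-weighted edge per (peptide, protein) pair (the best
hit by bitscore).  Protein nodes can carry a toxin annotation taken from a
two-column TSV (identifier, yes/no).  The graph exports to SIF, GraphML and
edge/node TSV, all importable by Cytoscape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx

from .engine import AlignmentParams, search
from .io import AlignmentHit, HitTable, SequenceDatabase

logger = logging.getLogger(__name__)

EXPORT_FORMATS = ("sif", "graphml", "edge-tsv")


@dataclass(frozen=True)
class NetworkNode:
    id: str
    kind: str  # "peptide" | "protein"
    toxin: bool | None = None  # None = unknown; only meaningful for proteins


@dataclass
class SimilarityNetwork:
    """Bipartite peptide-protein graph with identity-weighted edges."""

    nodes: list[NetworkNode] = field(default_factory=list)
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            attrs = {"kind": node.kind}
            if node.toxin is not None:
                attrs["toxin"] = node.toxin
            g.add_node(node.id, **attrs)
        for pep, prot, pident in self.edges:
            g.add_edge(pep, prot, pident=pident)
        return g


def _sanitize(identifier: str) -> str:
    return identifier.replace("\t", " ").replace("\n", " ")


def screen_proteome(
    amp_db: SequenceDatabase,
    proteome: SequenceDatabase,
    params: AlignmentParams | None = None,
) -> HitTable:
    """Search an AMP collection (queries) against a proteome (subjects).

    Match coordinates are populated on every hit so matched-domain spans can
    be reported and tested for proteolytic release.
    """
    if not amp_db.records or not proteome.records:
        logger.warning("empty input to proteome screen; returning empty table")
    return search(amp_db, proteome, params)


def build_network(
    table: HitTable,
    annotations: Mapping[str, bool] | None = None,
    min_pident: float | None = None,
) -> SimilarityNetwork:
    """Condense a screen's hit table into a bipartite similarity network.

    One peptide node per distinct qseqid, one protein node per distinct
    sseqid; duplicate hits for a pair collapse to a single edge carrying the
    best (max-bitscore) hit's pident.  ``annotations`` maps protein ids to a
    toxin flag; unmapped proteins stay unknown.  ``min_pident`` optionally
    drops weaker edges before building.
    """
    annotations = annotations or {}
    best: dict[tuple[str, str], AlignmentHit] = {}
    for h in table.hits:
        if min_pident is not None and h.pident < min_pident:
            continue
        key = (_sanitize(h.qseqid), _sanitize(h.sseqid))
        prev = best.get(key)
        if prev is None or h.bitscore > prev.bitscore:
            best[key] = h

    peptides: dict[str, None] = {}
    proteins: dict[str, None] = {}
    edges: list[tuple[str, str, float]] = []
    for (pep, prot), hit in best.items():
        peptides.setdefault(pep, None)
        proteins.setdefault(prot, None)
        edges.append((pep, prot, hit.pident))

    nodes = [NetworkNode(id=p, kind="peptide") for p in peptides]
    nodes += [
        NetworkNode(id=p, kind="protein", toxin=annotations.get(p)) for p in proteins
    ]
    return SimilarityNetwork(nodes=nodes, edges=edges)


def extract_components(net: SimilarityNetwork) -> list[SimilarityNetwork]:
    """Split into connected components, largest (by node count) first.

    The components partition the node and edge sets exactly.
    """
    g = net.to_networkx()
    components: list[SimilarityNetwork] = []
    for members in nx.connected_components(g):
        sub_nodes = [n for n in net.nodes if n.id in members]
        sub_edges = [e for e in net.edges if e[0] in members]
        components.append(SimilarityNetwork(nodes=sub_nodes, edges=sub_edges))
    components.sort(key=lambda c: (-c.n_nodes, c.nodes[0].id if c.nodes else ""))
    return components


def read_annotations(path: str | Path) -> dict[str, bool]:
    """Read a two-column TSV of protein id -> toxin yes/no."""
    truthy = {"yes", "y", "true", "1"}
    falsy = {"no", "n", "false", "0", "non-toxin", "nontoxin"}
    header_names = {"toxin", "flag", "is_toxin"}
    out: dict[str, bool] = {}
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: row {row_no}: expected two columns")
            if row_no == 1 and parts[1].strip().lower() in header_names:
                continue  # header line
            flag = parts[1].strip().lower()
            if flag in truthy:
                out[parts[0]] = True
            elif flag in falsy:
                out[parts[0]] = False
            else:
                raise ValueError(f"{path}: row {row_no}: unrecognized flag {parts[1]!r}")
    return out


def export_network(
    net: SimilarityNetwork, fmt: str, path: str | Path
) -> None:
    """Write the network as ``sif``, ``graphml``, or ``edge-tsv``.

    SIF lines read ``peptide<TAB>similar_to<TAB>protein``.  The edge-TSV
    format writes ``<path>`` with header qseqid/sseqid/pident plus a node
    attribute file ``<path stem>.nodes.tsv``.  Toxin attributes are exported
    only for annotated nodes.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "sif":
        with open(path, "w") as fh:
            for pep, prot, _ in net.edges:
                fh.write(f"{pep}\tsimilar_to\t{prot}\n")
    elif fmt == "graphml":
        nx.write_graphml(net.to_networkx(), str(path))
    elif fmt == "edge-tsv":
        with open(path, "w") as fh:
            fh.write("qseqid\tsseqid\tpident\n")
            for pep, prot, pident in net.edges:
                fh.write(f"{pep}\t{prot}\t{pident:.1f}\n")
        nodes_path = path.with_suffix(".nodes.tsv")
        with open(nodes_path, "w") as fh:
            fh.write("id\tkind\ttoxin\n")
            for node in net.nodes:
                toxin = "" if node.toxin is None else ("yes" if node.toxin else "no")
                fh.write(f"{node.id}\t{node.kind}\t{toxin}\n")
    else:
        raise ValueError(
            f"unknown export format {fmt!r}; choose one of {EXPORT_FORMATS}"
        )
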