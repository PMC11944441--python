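"""End-to-end workflows: database comparison and proteome mining.

Each workflow reads FASTA inputs, validates them, runs the search, derives
the downstream products (index report, distribution reports, network,
release reports), and writes everything as deterministic TSV/SVG/GraphML
files plus a JSON manifest recording inputs, parameters, and seed.  Stages
communicate only through the documented file formats, so each can also be
run standalone from the CLI on a previous stage's files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .digestion import ProteaseRule, assess_domain_release, get_rule, load_rules
from .engine import AlignmentParams, search
from .indices import RedundancyReport, cross_comparison_report, self_comparison_report
from .io import (
    SequenceDatabase,
    read_fasta,
    validate_database,
    write_hit_table,
    write_rejected_log,
)
from .network import build_network, export_network, extract_components, read_annotations, screen_proteome
from .reports import (
    identity_histogram,
    overlay_report,
    render_histogram,
    render_scatter,
    similarity_by_length,
    write_histogram_tsv,
    write_overlay_scatter_tsv,
    write_scatter_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs beyond its input paths."""

    params: AlignmentParams = field(default_factory=AlignmentParams)
    bin_width: float = 5.0
    min_pident: float | None = None
    enzymes: tuple[str, ...] = ("trypsin",)
    window: int = 10
    min_length_ratio: float = 1.5
    out_dir: Path = Path("ampredkit_out")
    seed: int = 0
    render_figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = AlignmentParams(**raw.pop("alignment", {}))
        if "out_dir" in raw:
            raw["out_dir"] = Path(raw["out_dir"])
        if "enzymes" in raw:
            raw["enzymes"] = tuple(raw["enzymes"])
        return cls(params=params, **raw)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["params"].pop("alphabet", None)
        return d


def _load_validated(path: str | Path, out_dir: Path) -> SequenceDatabase:
    if not Path(path).exists():
        raise FileNotFoundError(f"input FASTA not found: {path}")
    db = validate_database(read_fasta(path))
    logger.info(
        "%s: theoretical %d, obtained %d", db.name, db.n_theoretical, db.n_obtained
    )
    if db.rejected:
        write_rejected_log(db, out_dir / f"rejected_{db.name}.tsv")
    return db


def _write_manifest(out_dir: Path, kind: str, inputs: dict, config: PipelineConfig) -> None:
    manifest = {
        "tool": "ampredkit",
        "version": __version__,
        "workflow": kind,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": config.to_manifest(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_index_report(rows: list[tuple[str, RedundancyReport]], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("database\tdairi\tidairi\tnormalization_factor\tn_total\tn_identical\n")
        for name, rep in rows:
            idairi = "" if rep.idairi is None else f"{rep.idairi:.2f}"
            norm = "" if rep.normalization_factor is None else f"{rep.normalization_factor:.6g}"
            fh.write(
                f"{name}\t{rep.dairi:.2f}\t{idairi}\t{norm}\t{rep.n_total}\t{rep.n_identical}\n"
            )


def run_full_comparison(
    reference: str | Path,
    targets: list[str | Path],
    config: PipelineConfig | None = None,
) -> dict:
    """Self- and cross-compare a reference database against targets.

    Writes per-target self/cross hit tables, a combined index report
    (database, DAIRI_d, IDAIRI_d, normalization factor, counts), overlay
    distribution reports, and a run manifest.  Returns the report objects.
    """
    config = config or PipelineConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ref = _load_validated(reference, out)
    ref_lengths = ref.lengths_by_id()
    ref_self = search(ref, ref, config.params)
    write_hit_table(ref_self, out / f"hits_self_{ref.name}.tsv")

    index_rows: list[tuple[str, RedundancyReport]] = [
        (ref.name, self_comparison_report(ref_self))
    ]
    bundle: dict = {"reference": ref, "self_tables": {ref.name: ref_self}, "cross_tables": {}}

    for target_path in targets:
        tgt = _load_validated(target_path, out)
        if tgt.name == ref.name:
            raise ValueError(
                f"target database name {tgt.name!r} collides with the reference"
            )
        tgt_self = search(tgt, tgt, config.params)
        write_hit_table(tgt_self, out / f"hits_self_{tgt.name}.tsv")
        cross = search(ref, tgt, config.params)
        write_hit_table(cross, out / f"hits_cross_{ref.name}_vs_{tgt.name}.tsv")

        index_rows.append((tgt.name, self_comparison_report(tgt_self)))
        index_rows.append(
            (
                f"{ref.name}_vs_{tgt.name}",
                cross_comparison_report(cross, n_compared=tgt, n_reference=ref),
            )
        )
        bundle["self_tables"][tgt.name] = tgt_self
        bundle["cross_tables"][tgt.name] = cross

        rep = overlay_report(ref_self, cross, ref_lengths, config.bin_width)
        stem = f"{ref.name}_vs_{tgt.name}"
        write_overlay_scatter_tsv(rep, out / f"scatter_{stem}.tsv")
        write_histogram_tsv(rep.cross_hist, out / f"hist_{stem}.tsv", layer="cross")
        if config.render_figures:
            render_scatter(
                [("reference-self", rep.reference_points), ("cross", rep.cross_points)],
                out / f"scatter_{stem}.svg",
                title=stem,
            )
            render_histogram(
                [("reference-self", rep.reference_hist), ("cross", rep.cross_hist)],
                out / f"hist_{stem}.svg",
                title=stem,
            )

    # reference's own distribution report
    ref_points = similarity_by_length(ref_self, ref_lengths)
    write_scatter_tsv(ref_points, out / f"scatter_self_{ref.name}.tsv")
    write_histogram_tsv(
        identity_histogram(ref_self, config.bin_width), out / f"hist_self_{ref.name}.tsv"
    )

    _write_index_report(index_rows, out / "indices.tsv")
    _write_manifest(
        out,
        "run-comparison",
        {"reference": reference, **{f"target_{i}": t for i, t in enumerate(targets)}},
        config,
    )
    bundle["index_rows"] = index_rows
    return bundle


def run_proteome_mining(
    amps: str | Path,
    proteome: str | Path,
    annotations: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Screen a proteome with an AMP collection and mine the results.

    Products: the hit table, the bipartite similarity network (GraphML, SIF,
    edge/node TSV), one GraphML per connected component, and domain-release
    reports for every hit whose protein is at least ``min_length_ratio``
    times the peptide's length.
    """
    config = config or PipelineConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    amp_db = _load_validated(amps, out)
    prot_db = _load_validated(proteome, out)
    annot = read_annotations(annotations) if annotations else {}

    table = screen_proteome(amp_db, prot_db, config.params)
    write_hit_table(table, out / "hits_screen.tsv")

    net = build_network(table, annotations=annot, min_pident=config.min_pident)
    export_network(net, "graphml", out / "network.graphml")
    export_network(net, "sif", out / "network.sif")
    export_network(net, "edge-tsv", out / "network.edges.tsv")

    comp_dir = out / "components"
    comp_dir.mkdir(exist_ok=True)
    components = extract_components(net)
    for i, comp in enumerate(components, start=1):
        export_network(comp, "graphml", comp_dir / f"component_{i:03d}.graphml")

    rule_set = load_rules()
    rules: list[ProteaseRule] = [get_rule(e, rule_set) for e in config.enzymes]
    amp_lengths = amp_db.lengths_by_id()
    proteins = {r.id: r for r in prot_db.records}
    release_rows = []
    for h in table.hits:
        qlen = amp_lengths[h.qseqid]
        protein = proteins[h.sseqid]
        if protein.length < config.min_length_ratio * qlen or not h.has_coordinates:
            continue
        rep = assess_domain_release(
            protein, h.sstart, h.send, rules=rules, window=config.window
        )
        release_rows.append((h.qseqid, rep))

    with open(out / "release_reports.tsv", "w") as fh:
        fh.write(
            "protein_id\tpeptide_id\tdomain_start\tdomain_end\twindow\t"
            "upstream_sites\tdownstream_sites\treleasable\n"
        )
        for qid, rep in release_rows:
            up = ",".join(f"{p}:{e}" for p, e in rep.upstream_sites)
            down = ",".join(f"{p}:{e}" for p, e in rep.downstream_sites)
            fh.write(
                f"{rep.protein_id}\t{qid}\t{rep.domain_start}\t{rep.domain_end}\t"
                f"{rep.window}\t{up}\t{down}\t{'yes' if rep.releasable else 'no'}\n"
            )

    _write_manifest(
        out,
        "run-mining",
        {"amps": amps, "proteome": proteome, "annotations": annotations or ""},
        config,
    )
    return {
        "amp_db": amp_db,
        "proteome": prot_db,
        "hits": table,
        "network": net,
        "components": components,
        "release_reports": release_rows,
    }
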