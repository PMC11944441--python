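"""Similarity-vs-length scatter data and identity histograms.

The scatter report aggregates hits into (query length, percent identity)
points weighted by their multiplicity, so a figure can draw point area
proportional to frequency; the histogram bins percent identity with the last
bin closed at 100 so exact duplicates are never split off the top.  Both
reports are lossless: their frequencies/counts sum to the source table size.
Overlay reports layer a cross-comparison on top of the reference database's
self-comparison, the standard way to judge a database against a reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import HitTable


@dataclass(frozen=True)
class SimilarityPoint:
    """One (length, pident) cell of the scatter report with its multiplicity."""

    length: int
    pident: float
    frequency: int


@dataclass(frozen=True)
class IdentityHistogram:
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]

    @property
    def total(self) -> int:
        return sum(self.counts)


def similarity_by_length(
    table: HitTable, lengths: Mapping[str, int]
) -> list[SimilarityPoint]:
    """Aggregate hits into frequency-weighted (length, pident) points.

    Lengths are looked up per query identifier (the peptide side of the
    comparison); an identifier missing from the mapping is an error.  Output
    is sorted by length, then pident, for deterministic files.
    """
    tally: dict[tuple[int, float], int] = {}
    for h in table.hits:
        if h.qseqid not in lengths:
            raise KeyError(f"no length known for query identifier {h.qseqid!r}")
        key = (lengths[h.qseqid], round(h.pident, 1))
        tally[key] = tally.get(key, 0) + 1
    return [
        SimilarityPoint(length=k[0], pident=k[1], frequency=v)
        for k, v in sorted(tally.items())
    ]


def identity_histogram(table: HitTable, bin_width: float = 5.0) -> IdentityHistogram:
    """Bin hit identities into [lo, hi) bins; the last bin is closed at 100.

    ``bin_width`` must divide 100 evenly.
    """
    n_bins = 100.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin width {bin_width} does not divide 100")
    n_bins = int(round(n_bins))
    edges = [i * bin_width for i in range(n_bins + 1)]
    counts = [0] * n_bins
    for h in table.hits:
        idx = min(int(h.pident // bin_width), n_bins - 1)
        counts[idx] += 1
    return IdentityHistogram(bin_edges=tuple(edges), counts=tuple(counts))


@dataclass(frozen=True)
class OverlayReport:
    """Reference self-comparison layered under a cross-comparison."""

    reference_points: tuple[SimilarityPoint, ...]
    cross_points: tuple[SimilarityPoint, ...]
    reference_hist: IdentityHistogram
    cross_hist: IdentityHistogram
    layer_labels: tuple[str, str] = ("reference-self", "cross")


def overlay_report(
    reference_self: HitTable,
    cross: HitTable,
    lengths: Mapping[str, int],
    bin_width: float = 5.0,
) -> OverlayReport:
    """Build the two-layer scatter/histogram report of a cross-comparison."""
    return OverlayReport(
        reference_points=tuple(similarity_by_length(reference_self, lengths)),
        cross_points=tuple(similarity_by_length(cross, lengths)),
        reference_hist=identity_histogram(reference_self, bin_width),
        cross_hist=identity_histogram(cross, bin_width),
    )


# ---------------------------------------------------------------------------
# TSV and figure output
# ---------------------------------------------------------------------------

def write_scatter_tsv(
    points: Sequence[SimilarityPoint], path: str | Path, layer: str | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        header = "length\tpident\tfrequency"
        fh.write((header + "\tlayer\n") if layer is not None else header + "\n")
        for p in points:
            row = f"{p.length}\t{p.pident:.1f}\t{p.frequency}"
            fh.write((row + f"\t{layer}\n") if layer is not None else row + "\n")


def write_overlay_scatter_tsv(report: OverlayReport, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("length\tpident\tfrequency\tlayer\n")
        for label, points in zip(
            report.layer_labels, (report.reference_points, report.cross_points)
        ):
            for p in points:
                fh.write(f"{p.length}\t{p.pident:.1f}\t{p.frequency}\t{label}\n")


def write_histogram_tsv(
    hist: IdentityHistogram, path: str | Path, layer: str | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        header = "bin_lo\tbin_hi\tcount"
        fh.write((header + "\tlayer\n") if layer is not None else header + "\n")
        for lo, hi, c in zip(hist.bin_edges[:-1], hist.bin_edges[1:], hist.counts):
            row = f"{lo:g}\t{hi:g}\t{c}"
            fh.write((row + f"\t{layer}\n") if layer is not None else row + "\n")


_MAX_MARKER_AREA = 400.0  # points^2; area scales linearly with frequency


def render_scatter(
    layers: Sequence[tuple[str, Sequence[SimilarityPoint]]],
    path: str | Path,
    title: str = "",
) -> None:
    """Draw frequency-weighted scatter layers; later layers draw on top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    max_freq = max(
        (p.frequency for _, pts in layers for p in pts), default=1
    )
    colors = {"reference-self": "0.6", "cross": "tab:blue"}
    for i, (label, pts) in enumerate(layers):
        if not pts:
            continue
        x = [p.length for p in pts]
        y = [p.pident for p in pts]
        area = [max(4.0, _MAX_MARKER_AREA * p.frequency / max_freq) for p in pts]
        ax.scatter(
            x, y, s=area, label=label, alpha=0.6,
            color=colors.get(label), zorder=i + 1,
        )
    ax.set_xlabel("peptide length (aa)")
    ax.set_ylabel("% identity")
    if title:
        ax.set_title(title)
    if len(layers) > 1:
        ax.legend()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path)
    plt.close(fig)


def render_histogram(
    layers: Sequence[tuple[str, IdentityHistogram]],
    path: str | Path,
    title: str = "",
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {"reference-self": "0.6", "cross": "tab:blue"}
    for i, (label, hist) in enumerate(layers):
        edges = np.asarray(hist.bin_edges)
        widths = np.diff(edges)
        ax.bar(
            edges[:-1], hist.counts, width=widths, align="edge",
            label=label, alpha=0.6, color=colors.get(label), zorder=i + 1,
        )
    ax.set_xlabel("% identity")
    ax.set_ylabel("hit counts")
    if title:
        ax.set_title(title)
    if len(layers) > 1:
        ax.legend()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path)
    plt.close(fig)
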