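"""SVG heat maps of binned gene densities plus FASTA/TSV export and re-import.

The heat map draws one row of rectangles per chromosome (one rectangle per
bin) with a linear white-to-hue color ramp scaled to the global maximum of
the plotted value across all tracks; empty bins use a neutral light grey.
Per-bin tooltips are embedded as SVG ``<title>`` elements.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .density import BinGrid, DensityTrack, EnrichmentRow, EnrichmentTable
from .errors import ValidationError
from .genome_model import GenomeIndex, write_fasta
from .query import TaggedSet, write_tagged_tsv

SVG_NS = "http://www.w3.org/2000/svg"

EMPTY_COLOR = "#d9d9d9"
HIGH_RGB = (178, 24, 43)  # saturated red end of the ramp

VALUE_MODES = ("all", "tagged", "relative")


@dataclass
class HeatmapSpec:
    value: str = "relative"      # which per-bin value to plot
    bin_px: int = 12
    row_px: int = 18
    gap_px: int = 6
    label_px: int = 90
    title: str = ""

    def __post_init__(self) -> None:
        if self.value not in VALUE_MODES:
            raise ValidationError(f"value mode must be one of {VALUE_MODES}")


def ramp_color(value: float, vmax: float) -> str:
    """Linear white -> saturated hue; monotone in ``value``."""
    t = 0.0 if vmax <= 0 else min(1.0, max(0.0, value / vmax))
    rgb = tuple(round(255 + (h - 255) * t) for h in HIGH_RGB)
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def _track_values(track: DensityTrack, mode: str) -> np.ndarray:
    if mode == "all":
        return track.all_counts.astype(float)
    if mode == "tagged":
        return track.tagged_counts.astype(float)
    return track.relative


def _panel_height(tracks: list[DensityTrack], spec: HeatmapSpec) -> int:
    return len(tracks) * (spec.row_px + spec.gap_px)


def render_heatmap(
    tracks: list[DensityTrack] | dict[str, list[DensityTrack]],
    spec: HeatmapSpec,
    out: str | Path,
) -> None:
    """Render density tracks to an SVG file.

    ``tracks`` may be a flat list (one panel) or a mapping panel-name ->
    track list (stacked panels sharing the coordinate axis, e.g. one panel
    per gene group).  Raises on an empty track list or unwritable path.
    """
    panels = tracks if isinstance(tracks, dict) else {spec.title or "": tracks}
    flat = [t for ts in panels.values() for t in ts]
    if not flat:
        raise ValidationError("render_heatmap needs at least one track")

    vmax = max(
        (float(_track_values(t, spec.value).max()) for t in flat), default=0.0
    )
    max_bins = max(t.grid.n_bins for t in flat)
    width = spec.label_px + max_bins * spec.bin_px + 20
    legend_h = 50
    title_h = 18
    height = sum(_panel_height(ts, spec) + title_h for ts in panels.values()) + legend_h

    svg = ET.Element("svg", {
        "xmlns": SVG_NS,
        "version": "1.1",
        "width": str(width),
        "height": str(height),
    })

    y = 0
    for panel_name, panel_tracks in panels.items():
        if panel_name:
            txt = ET.SubElement(svg, "text", {
                "x": "4", "y": str(y + 13), "font-size": "12",
                "class": "panel-title",
            })
            txt.text = panel_name
        y += title_h
        for track in panel_tracks:
            grid = track.grid
            label = ET.SubElement(svg, "text", {
                "x": "4", "y": str(y + spec.row_px - 4), "font-size": "11",
            })
            label.text = grid.chromosome
            values = _track_values(track, spec.value)
            for b in range(grid.n_bins):
                fill = (
                    EMPTY_COLOR if track.empty[b]
                    else ramp_color(float(values[b]), vmax)
                )
                rect = ET.SubElement(svg, "rect", {
                    "x": str(spec.label_px + b * spec.bin_px),
                    "y": str(y),
                    "width": str(spec.bin_px),
                    "height": str(spec.row_px),
                    "fill": fill,
                    "stroke": "#ffffff",
                    "stroke-width": "0.5",
                    "class": "bin",
                    "data-chrom": grid.chromosome,
                    "data-bin": str(b),
                })
                title = ET.SubElement(rect, "title")
                title.text = (
                    f"{grid.chromosome} bin {b} ({grid.labels[b]}): "
                    f"{int(track.tagged_counts[b])} tagged / "
                    f"{int(track.all_counts[b])} genes "
                    f"(relative {track.relative[b]:.3f})"
                )
            y += spec.row_px + spec.gap_px

    # legend: 10 swatches from 0 to the global maximum
    n_sw = 10
    for i in range(n_sw):
        ET.SubElement(svg, "rect", {
            "x": str(spec.label_px + i * spec.bin_px),
            "y": str(y + 14),
            "width": str(spec.bin_px),
            "height": "10",
            "fill": ramp_color(vmax * (i + 0.5) / n_sw, vmax),
            "class": "legend",
        })
    lo = ET.SubElement(svg, "text", {
        "x": str(spec.label_px), "y": str(y + 36), "font-size": "10",
    })
    lo.text = "0"
    hi = ET.SubElement(svg, "text", {
        "x": str(spec.label_px + n_sw * spec.bin_px + 4),
        "y": str(y + 36), "font-size": "10",
    })
    hi.text = f"{vmax:g} ({spec.value}, global max)"

    try:
        ET.ElementTree(svg).write(out, xml_declaration=True, encoding="unicode")
    except OSError as exc:
        raise ValidationError(f"cannot write heat map to {out}: {exc}") from exc


# ---------------------------------------------------------------------------
# FASTA export


def export_bin_fasta(
    index: GenomeIndex,
    tagged: TaggedSet,
    chromosome: str,
    bin: int,
    out: str | Path,
) -> list[str]:
    """Write the tagged genes of one bin as FASTA, ordered by (position, id).

    Returns the exported gene ids.  A tagged in-bin gene without a loaded
    sequence is a hard error; an empty bin produces an empty file plus a
    warning.
    """
    chrom = index.chromosomes.get(chromosome)
    if chrom is None:
        raise ValidationError(f"unknown chromosome {chromosome!r}")
    grid = BinGrid(chromosome=chrom.name, width=index.bin_width,
                   length=chrom.length, unit=index.unit)
    if not 0 <= bin < grid.n_bins:
        raise ValidationError(
            f"bin {bin} out of range [0, {grid.n_bins}) for {chromosome}"
        )
    members = [
        g for g in index.genes.values()
        if g.anchored and g.chromosome == chromosome
        and g.gene_id in tagged.gene_ids and grid.bin_of(g.position) == bin
    ]
    members.sort(key=lambda g: (g.position, g.gene_id))
    missing = [g.gene_id for g in members if g.gene_id not in index.sequences]
    if missing:
        raise ValidationError(
            f"no sequence loaded for tagged gene(s) in {chromosome} bin {bin}: "
            + ", ".join(missing)
        )
    if not members:
        warnings.warn(
            f"{chromosome} bin {bin} contains no tagged genes; writing empty FASTA"
        )
    write_fasta({g.gene_id: index.sequences[g.gene_id] for g in members}, out)
    return [g.gene_id for g in members]


# ---------------------------------------------------------------------------
# TSV reports (writers and lossless readers)


def write_density_tsv(tracks: list[DensityTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        if tracks:
            g = tracks[0].grid
            fh.write(f"# unit={g.unit} bin_width={g.width!r}\n")
        fh.write("chromosome\tbin_index\tbin_label\tall_count\ttagged_count\t"
                 "relative\tempty_flag\n")
        for track in tracks:
            grid = track.grid
            fh.write(f"# chromosome={grid.chromosome} length={grid.length!r}\n")
            rel = track.relative
            for b in range(grid.n_bins):
                fh.write(
                    f"{grid.chromosome}\t{b}\t{grid.labels[b]}\t"
                    f"{int(track.all_counts[b])}\t{int(track.tagged_counts[b])}\t"
                    f"{float(rel[b])!r}\t{int(track.empty[b])}\n"
                )


def read_density_tsv(path: str | Path) -> list[DensityTrack]:
    unit = None
    width = None
    lengths: dict[str, float] = {}
    rows: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# unit="):
                parts = dict(p.split("=", 1) for p in line[2:].split(" "))
                unit = parts["unit"]
                width = float(parts["bin_width"])
                continue
            if line.startswith("# chromosome="):
                parts = dict(p.split("=", 1) for p in line[2:].split(" "))
                lengths[parts["chromosome"]] = float(parts["length"])
                continue
            if not line or line.startswith("chromosome\t") or line.startswith("#"):
                continue
            f = line.split("\t")
            rows.setdefault(f[0], []).append((int(f[1]), int(f[3]), int(f[4])))
    if unit is None or width is None:
        raise ValidationError(f"{path}: missing density metadata header")
    tracks = []
    for chrom, entries in rows.items():
        entries.sort()
        grid = BinGrid(chromosome=chrom, width=width,
                       length=lengths[chrom], unit=unit)
        all_counts = np.zeros(grid.n_bins, dtype=int)
        tagged_counts = np.zeros(grid.n_bins, dtype=int)
        for b, a, t in entries:
            all_counts[b] = a
            tagged_counts[b] = t
        tracks.append(DensityTrack(grid=grid, all_counts=all_counts,
                                   tagged_counts=tagged_counts))
    return tracks


def write_enrichment_tsv(table: EnrichmentTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_units_tested={table.n_units_tested}\n")
        fh.write("unit\ttagged_on\ttagged_off\tuntagged_on\tuntagged_off\t"
                 "p_raw\tp_adj\n")
        for r in table.rows:
            fh.write(
                f"{r.unit}\t{r.tagged_on}\t{r.tagged_off}\t{r.untagged_on}\t"
                f"{r.untagged_off}\t{r.p_raw!r}\t{r.p_adj!r}\n"
            )


def read_enrichment_tsv(path: str | Path) -> EnrichmentTable:
    table = EnrichmentTable()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# n_units_tested="):
                table.n_units_tested = int(line.split("=", 1)[1])
                continue
            if not line or line.startswith("unit\t") or line.startswith("#"):
                continue
            f = line.split("\t")
            table.rows.append(EnrichmentRow(
                unit=f[0], tagged_on=int(f[1]), tagged_off=int(f[2]),
                untagged_on=int(f[3]), untagged_off=int(f[4]),
                p_raw=float(f[5]), p_adj=float(f[6]),
            ))
    return table


def export_reports(
    tracks: list[DensityTrack],
    enrichment: Optional[EnrichmentTable],
    tagged: TaggedSet,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write density.tsv / enrichment.tsv / tagged.tsv into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["density"] = out_dir / "density.tsv"
    write_density_tsv(tracks, paths["density"])
    if enrichment is not None:
        paths["enrichment"] = out_dir / "enrichment.tsv"
        write_enrichment_tsv(enrichment, paths["enrichment"])
    paths["tagged"] = out_dir / "tagged.tsv"
    write_tagged_tsv(tagged, paths["tagged"])
    return paths
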