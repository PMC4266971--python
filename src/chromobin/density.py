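"""Bin anchored genes, build all-vs-tagged density tracks, test enrichment.

Bins are half-open ``[b*w, (b+1)*w)`` intervals tiling each chromosome; a
gene sitting exactly at the chromosome length (possible with cM rounding)
is placed in the last bin.  Enrichment of tagged genes per chromosome or
chromosome arm uses a one-sided Fisher's exact test (over-representation)
with Bonferroni adjustment over the units actually tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import TYPE_CHECKING

import numpy as np

from .errors import ValidationError
from .genome_model import GenomeIndex, arm_of

if TYPE_CHECKING:  # pragma: no cover
    from .query import TaggedSet


def bin_index(position: float, width: float) -> int:
    """0-based bin of a position: ``floor(position / width)``."""
    if position < 0:
        raise ValidationError(f"negative position {position}")
    if width <= 0:
        raise ValidationError("bin width must be > 0")
    return int(math.floor(position / width))


def _fmt_scaled(value: float) -> str:
    # "9" not "9.0", but "2.5" stays "2.5"
    if value == int(value):
        return str(int(value))
    return f"{value:g}"


def bin_label(b: int, width: float, unit: str) -> str:
    """Display label of bin ``b``: e.g. "9-10 Mb" for 1 Mb bins, "45-50 cM"."""
    if unit == "bp":
        scale, suffix = 1e6, "Mb"
    else:
        scale, suffix = 1.0, "cM"
    lo = b * width / scale
    hi = (b + 1) * width / scale
    return f"{_fmt_scaled(lo)}-{_fmt_scaled(hi)} {suffix}"


@dataclass
class BinGrid:
    """Non-overlapping bins tiling one chromosome."""

    chromosome: str
    width: float
    length: float
    unit: str

    @property
    def n_bins(self) -> int:
        return max(1, math.ceil(self.length / self.width))

    @property
    def labels(self) -> list[str]:
        return [bin_label(b, self.width, self.unit) for b in range(self.n_bins)]

    def bin_of(self, position: float) -> int:
        """Bin of a position on this chromosome; clamps a position exactly at
        the chromosome length into the last bin."""
        if position > self.length:
            raise ValidationError(
                f"position {position} beyond {self.chromosome} length {self.length}"
            )
        return min(bin_index(position, self.width), self.n_bins - 1)


@dataclass
class DensityTrack:
    """Per-bin counts of all anchored genes vs tagged genes on one chromosome."""

    grid: BinGrid
    all_counts: np.ndarray
    tagged_counts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.tagged_counts > self.all_counts):
            raise ValidationError(
                f"{self.grid.chromosome}: tagged count exceeds total count"
            )

    @property
    def empty(self) -> np.ndarray:
        return self.all_counts == 0

    @property
    def relative(self) -> np.ndarray:
        # empty bins get 0 (flagged via .empty) so heat maps render uniformly
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(
                self.all_counts > 0,
                self.tagged_counts / np.maximum(self.all_counts, 1),
                0.0,
            )
        return rel


def build_density(index: GenomeIndex, tagged: "TaggedSet") -> list[DensityTrack]:
    """One track per declared chromosome.  Unanchored genes are excluded from
    both counts; the tagged-but-unanchored total is available via
    :func:`unanchored_tagged_count`."""
    if tagged.genome_id != index.genome_id:
        raise ValidationError(
            f"tagged set belongs to {tagged.genome_id!r}, not {index.genome_id!r}"
        )
    tag_ids = tagged.gene_ids
    tracks = []
    for chrom in index.chromosomes.values():
        grid = BinGrid(
            chromosome=chrom.name, width=index.bin_width,
            length=chrom.length, unit=index.unit,
        )
        all_counts = np.zeros(grid.n_bins, dtype=int)
        tagged_counts = np.zeros(grid.n_bins, dtype=int)
        for gene in index.genes.values():
            if not gene.anchored or gene.chromosome != chrom.name:
                continue
            b = grid.bin_of(gene.position)
            all_counts[b] += 1
            if gene.gene_id in tag_ids:
                tagged_counts[b] += 1
        tracks.append(DensityTrack(grid=grid, all_counts=all_counts,
                                   tagged_counts=tagged_counts))
    return tracks


def unanchored_tagged_count(index: GenomeIndex, tagged: "TaggedSet") -> int:
    return sum(
        1 for gid in tagged.gene_ids
        if gid in index.genes and not index.genes[gid].anchored
    )


# ---------------------------------------------------------------------------
# enrichment


def fisher_one_sided(tagged_on: int, tagged_off: int,
                     untagged_on: int, untagged_off: int) -> float:
    """One-sided Fisher's exact test for over-representation of tagged genes
    on the unit: ``P(X >= tagged_on)`` under the hypergeometric distribution
    with the table's fixed margins.

    Computed exactly with integer binomial coefficients, then rounded once
    to float.
    """
    counts = (tagged_on, tagged_off, untagged_on, untagged_off)
    if any(c < 0 for c in counts):
        raise ValidationError("contingency counts must be >= 0")
    if all(c == 0 for c in counts):
        raise ValidationError("all-zero contingency table")
    total = sum(counts)
    n_tagged = tagged_on + tagged_off
    n_on = tagged_on + untagged_on
    hi = min(n_tagged, n_on)
    numerator = sum(
        comb(n_tagged, k) * comb(total - n_tagged, n_on - k)
        for k in range(tagged_on, hi + 1)
    )
    return float(Fraction(numerator, comb(total, n_on)))


@dataclass
class EnrichmentRow:
    unit: str
    tagged_on: int
    tagged_off: int
    untagged_on: int
    untagged_off: int
    p_raw: float
    p_adj: float


@dataclass
class EnrichmentTable:
    rows: list[EnrichmentRow] = field(default_factory=list)
    n_units_tested: int = 0

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)


def enrichment_units(index: GenomeIndex, unit: str = "chromosome") -> list[str]:
    """Unit names tested in an enrichment run, in declaration order.  With
    ``unit='arm'``, chromosomes with a declared arm boundary contribute an S
    and an L unit; others are tested whole."""
    if unit not in ("chromosome", "arm"):
        raise ValidationError(f"unit must be 'chromosome' or 'arm', got {unit!r}")
    names: list[str] = []
    for chrom in index.chromosomes.values():
        if unit == "arm" and chrom.arm_boundary is not None:
            names.extend([f"{chrom.name}S", f"{chrom.name}L"])
        else:
            names.append(chrom.name)
    return names


def enrich(index: GenomeIndex, tagged: "TaggedSet",
           unit: str = "chromosome") -> EnrichmentTable:
    """One Fisher test per unit over anchored genes only; Bonferroni over the
    number of units tested; rows sorted by adjusted p, ties by unit name."""
    if not tagged.gene_ids:
        raise ValidationError("tagged set is empty; nothing to test")
    units = enrichment_units(index, unit)
    anchored = [g for g in index.genes.values() if g.anchored]
    if not anchored:
        raise ValidationError("genome has no anchored genes")
    tag_ids = tagged.gene_ids

    gene_unit: dict[str, str] = {}
    for gene in anchored:
        chrom = index.chromosomes[gene.chromosome]
        gene_unit[gene.gene_id] = (
            arm_of(gene, chrom) if unit == "arm" else chrom.name
        )

    n_total = len(anchored)
    n_tagged = sum(1 for g in anchored if g.gene_id in tag_ids)
    k = len(units)
    rows = []
    for name in units:
        on = [g for g in anchored if gene_unit[g.gene_id] == name]
        tagged_on = sum(1 for g in on if g.gene_id in tag_ids)
        untagged_on = len(on) - tagged_on
        tagged_off = n_tagged - tagged_on
        untagged_off = n_total - n_tagged - untagged_on
        p_raw = fisher_one_sided(tagged_on, tagged_off, untagged_on, untagged_off)
        rows.append(EnrichmentRow(
            unit=name,
            tagged_on=tagged_on, tagged_off=tagged_off,
            untagged_on=untagged_on, untagged_off=untagged_off,
            p_raw=p_raw, p_adj=min(1.0, p_raw * k),
        ))
    rows.sort(key=lambda r: (r.p_adj, r.unit))
    return EnrichmentTable(rows=rows, n_units_tested=k)
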