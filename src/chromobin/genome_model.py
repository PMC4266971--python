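"""Data model and readers/validators for genomes, anchored genes, sequences and terms.

A genome is a set of gene models, each optionally *anchored* to a chromosome
at a physical (bp) or genetic (cM) position.  All chromosomes of one genome
share a single coordinate unit.  Positions are 1-based in files for bp
genomes and converted to 0-based integers internally; cM positions are kept
as-is (genetic distances are measured from 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import ConfigError, ValidationError

UNITS = ("bp", "cM")

ANCHOR_COLUMNS = ["gene_id", "chromosome", "arm", "position", "anchored"]


@dataclass(frozen=True)
class Coordinate:
    """A non-negative position or length in a fixed unit (bp or cM)."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(f"unknown coordinate unit {self.unit!r}")
        if self.value < 0:
            raise ValidationError(f"coordinate value must be >= 0, got {self.value}")


@dataclass
class ChromosomeDef:
    """A chromosome with a length and an optional centromere/arm boundary.

    Positions strictly below ``arm_boundary`` belong to the short arm ("S"),
    positions at or above it to the long arm ("L").
    """

    name: str
    length: float
    arm_boundary: Optional[float] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"chromosome {self.name}: length must be > 0")
        if self.arm_boundary is not None and not (0 < self.arm_boundary < self.length):
            raise ValidationError(
                f"chromosome {self.name}: arm boundary {self.arm_boundary} "
                f"outside (0, {self.length})"
            )


@dataclass
class AnchoredGene:
    """One gene model; anchored iff both chromosome and position are known."""

    gene_id: str
    chromosome: Optional[str] = None
    position: Optional[float] = None
    anchored: bool = False
    terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        has_coords = self.chromosome is not None and self.position is not None
        if self.anchored != has_coords:
            raise ValidationError(
                f"gene {self.gene_id}: anchored flag inconsistent with coordinates"
            )
        if self.position is not None and self.position < 0:
            raise ValidationError(f"gene {self.gene_id}: negative position")


@dataclass
class GenomeIndex:
    """Validated collection of genes, chromosome definitions and bin policy."""

    genome_id: str
    unit: str
    bin_width: float
    chromosomes: dict[str, ChromosomeDef] = field(default_factory=dict)
    genes: dict[str, AnchoredGene] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}")
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be > 0")

    # -- counts -----------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_anchored(self) -> int:
        return sum(1 for g in self.genes.values() if g.anchored)

    @property
    def n_unanchored(self) -> int:
        return self.n_genes - self.n_anchored

    def anchored_genes(self) -> Iterable[AnchoredGene]:
        return (g for g in self.genes.values() if g.anchored)

    def add_gene(self, gene: AnchoredGene, row: Optional[int] = None) -> None:
        where = f" (row {row})" if row is not None else ""
        if gene.gene_id in self.genes:
            raise ValidationError(f"duplicate gene id {gene.gene_id!r}{where}")
        if gene.anchored:
            chrom = self.chromosomes.get(gene.chromosome)
            if chrom is None:
                raise ValidationError(
                    f"gene {gene.gene_id}: unknown chromosome {gene.chromosome!r}{where}"
                )
            # bp positions are 0-based internally: valid range [0, length);
            # real-valued cM positions may sit exactly at the map length
            beyond = (gene.position >= chrom.length if self.unit == "bp"
                      else gene.position > chrom.length)
            if beyond:
                raise ValidationError(
                    f"gene {gene.gene_id}: position {gene.position} beyond "
                    f"chromosome {chrom.name} length {chrom.length}{where}"
                )
        self.genes[gene.gene_id] = gene


@dataclass
class LoadReport:
    """Non-fatal findings of a loader: unknown ids, rejected rows, orphans."""

    unknown_ids: list[str] = field(default_factory=list)
    rejected_rows: list[tuple[int, str]] = field(default_factory=list)
    orphan_sequences: dict[str, str] = field(default_factory=dict)

    @property
    def n_warnings(self) -> int:
        return len(self.unknown_ids) + len(self.rejected_rows)


def arm_of(gene: AnchoredGene, chrom: ChromosomeDef) -> str:
    """Arm unit of an anchored gene: ``<chrom>S`` / ``<chrom>L`` or the bare
    chromosome name when no arm boundary is declared.  The boundary position
    itself belongs to the long arm."""
    if not gene.anchored:
        raise ValidationError(f"gene {gene.gene_id} is unanchored; no arm unit")
    if gene.chromosome != chrom.name:
        raise ValidationError(
            f"gene {gene.gene_id} is on {gene.chromosome}, not {chrom.name}"
        )
    if chrom.arm_boundary is None:
        return chrom.name
    return f"{chrom.name}S" if gene.position < chrom.arm_boundary else f"{chrom.name}L"


# ---------------------------------------------------------------------------
# genome config


def load_genome_config(path: str | Path) -> GenomeIndex:
    """Read a genome header (YAML or JSON) into an empty :class:`GenomeIndex`.

    Expected keys: ``genome_id``, ``unit`` (bp|cM), ``bin_width``,
    ``chromosomes`` (list of name/length/optional arm_boundary).  An optional
    ``files`` mapping (anchors/fasta/annotations/...) is preserved on the
    returned index as ``index.files`` with paths resolved relative to the
    config file.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: genome config must be a mapping")
    for key in ("genome_id", "unit", "bin_width", "chromosomes"):
        if key not in cfg:
            raise ConfigError(f"{path}: missing required key {key!r}")
    if cfg["unit"] not in UNITS:
        raise ConfigError(f"{path}: unit must be one of {UNITS}")
    index = GenomeIndex(
        genome_id=str(cfg["genome_id"]),
        unit=cfg["unit"],
        bin_width=float(cfg["bin_width"]),
    )
    for entry in cfg["chromosomes"]:
        try:
            chrom = ChromosomeDef(
                name=str(entry["name"]),
                length=float(entry["length"]),
                arm_boundary=(
                    float(entry["arm_boundary"])
                    if entry.get("arm_boundary") is not None
                    else None
                ),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: bad chromosome entry {entry!r}: {exc}") from exc
        if chrom.name in index.chromosomes:
            raise ConfigError(f"{path}: duplicate chromosome {chrom.name!r}")
        index.chromosomes[chrom.name] = chrom
    files = {
        kind: str((path.parent / p).resolve())
        for kind, p in (cfg.get("files") or {}).items()
    }
    index.files = files  # type: ignore[attr-defined]
    return index


def write_genome_config(index: GenomeIndex, path: str | Path,
                        files: Optional[dict[str, str]] = None) -> None:
    cfg = {
        "genome_id": index.genome_id,
        "unit": index.unit,
        "bin_width": index.bin_width,
        "chromosomes": [
            {
                "name": c.name,
                "length": c.length,
                **({"arm_boundary": c.arm_boundary} if c.arm_boundary is not None else {}),
            }
            for c in index.chromosomes.values()
        ],
    }
    if files:
        cfg["files"] = files
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# anchor tables


def _position_to_internal(raw: str, unit: str) -> float:
    # bp positions are 1-based integers in files; cM are real and 0-based.
    if unit == "bp":
        return int(raw) - 1
    return float(raw)


def _position_to_file(pos: float, unit: str) -> str:
    if unit == "bp":
        return str(int(pos) + 1)
    return repr(float(pos))


def _parse_bool(raw: str, row: int) -> bool:
    val = raw.strip().lower()
    if val in ("1", "true", "yes"):
        return True
    if val in ("0", "false", "no", ""):
        return False
    raise ValidationError(f"row {row}: cannot parse anchored flag {raw!r}")


def load_anchor_table(path: str | Path, genome_config: GenomeIndex) -> GenomeIndex:
    """Load a TSV anchor table into a fresh index sharing the config's header.

    Unanchored rows (empty chromosome/position) are retained with
    ``anchored=False``.  Duplicate ids, unknown chromosomes and out-of-range
    positions are hard errors naming the offending row.
    """
    index = GenomeIndex(
        genome_id=genome_config.genome_id,
        unit=genome_config.unit,
        bin_width=genome_config.bin_width,
        chromosomes=dict(genome_config.chromosomes),
    )
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ANCHOR_COLUMNS:
            raise ValidationError(
                f"{path}: expected header {ANCHOR_COLUMNS}, got {header}"
            )
        for row_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(ANCHOR_COLUMNS):
                raise ValidationError(
                    f"{path}: row {row_no}: expected {len(ANCHOR_COLUMNS)} "
                    f"columns, got {len(fields)}"
                )
            gene_id, chrom, _arm, position, anchored_raw = fields
            anchored = _parse_bool(anchored_raw, row_no)
            has_coords = chrom != "" and position != ""
            if anchored != has_coords:
                raise ValidationError(
                    f"{path}: row {row_no}: anchored flag inconsistent with "
                    f"chromosome/position columns"
                )
            try:
                pos = _position_to_internal(position, index.unit) if has_coords else None
            except ValueError as exc:
                raise ValidationError(f"{path}: row {row_no}: bad position {position!r}") from exc
            if pos is not None and pos < 0:
                raise ValidationError(f"{path}: row {row_no}: non-positive position")
            gene = AnchoredGene(
                gene_id=gene_id,
                chromosome=chrom if has_coords else None,
                position=pos,
                anchored=anchored,
            )
            index.add_gene(gene, row=row_no)
    return index


def write_anchor_table(index: GenomeIndex, path: str | Path) -> None:
    """Inverse of :func:`load_anchor_table`; bp positions are written 1-based."""
    with open(path, "w") as fh:
        fh.write("\t".join(ANCHOR_COLUMNS) + "\n")
        for gene in index.genes.values():
            if gene.anchored:
                chrom_def = index.chromosomes[gene.chromosome]
                arm = arm_of(gene, chrom_def)
                arm_token = arm[len(gene.chromosome):]  # "S"/"L" or ""
                row = [
                    gene.gene_id,
                    gene.chromosome,
                    arm_token,
                    _position_to_file(gene.position, index.unit),
                    "1",
                ]
            else:
                row = [gene.gene_id, "", "", "", "0"]
            fh.write("\t".join(row) + "\n")


def load_anchor_gff3(path: str | Path, genome_config: GenomeIndex) -> GenomeIndex:
    """Alternative anchor reader: GFF3 ``gene`` features, id from the ``ID=``
    attribute, position = feature midpoint rounded down.  All genes from a
    GFF3 file are anchored by construction."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    index = GenomeIndex(
        genome_id=genome_config.genome_id,
        unit=genome_config.unit,
        bin_width=genome_config.bin_width,
        chromosomes=dict(genome_config.chromosomes),
    )
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        midpoint_1based = (feat.start + feat.end) // 2
        gene = AnchoredGene(
            gene_id=feat.id,
            chromosome=feat.seqid,
            position=midpoint_1based - 1,
            anchored=True,
        )
        index.add_gene(gene)
    return index


# ---------------------------------------------------------------------------
# annotations and sequences


def load_annotations(path: str | Path, index: GenomeIndex) -> LoadReport:
    """Merge a two-column ``gene_id<TAB>term`` table into the index.

    Unknown gene ids and empty terms are reported, never silently dropped.
    The index is modified in place; the report is returned.
    """
    report = LoadReport()
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                report.rejected_rows.append((row_no, "expected 2 columns"))
                continue
            gene_id, term = fields
            if term.strip() == "":
                report.rejected_rows.append((row_no, "empty term"))
                continue
            gene = index.genes.get(gene_id)
            if gene is None:
                report.unknown_ids.append(gene_id)
                continue
            gene.terms.add(term)
    return report


def write_annotations(index: GenomeIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in index.genes.values():
            for term in sorted(gene.terms):
                fh.write(f"{gene.gene_id}\t{term}\n")


def load_fasta(path: str | Path, index: GenomeIndex) -> LoadReport:
    """Attach sequences to genes; id is the first token of the FASTA header.

    Records without a matching gene id go into the orphan-sequences report.
    A duplicate FASTA id is a hard error.
    """
    report = LoadReport()
    seen: set[str] = set()
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            seq_id = header.split()[0] if header.split() else header
            if seq_id in seen:
                raise ValidationError(f"{path}: duplicate FASTA id {seq_id!r}")
            seen.add(seq_id)
            if seq_id in index.genes:
                index.sequences[seq_id] = seq
            else:
                report.orphan_sequences[seq_id] = seq
    return report


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in sequences.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
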