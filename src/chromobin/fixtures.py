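"""Deterministic synthetic-data generator for self-contained workflows.

Generates genomes (anchor tables, sequences, annotation terms), ortholog
hit-table pairs with planted ground truth, and expression uploads.  Every
quantity is drawn from a named pseudo-random stream derived from the spec
seed (one stream per sub-generator), so adding a generator never reshuffles
the output of another, and the same spec always produces byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigError, ValidationError
from .expression import (DEGList, ExpressionMatrix, GroupMap,
                         write_deg_list, write_expression_tsv, write_group_map)
from .genome_model import (AnchoredGene, ChromosomeDef, GenomeIndex, arm_of,
                           write_anchor_table, write_annotations,
                           write_fasta, write_genome_config)
from .homology import AlignmentHit, HitTable, write_tabular_hits
from .query import TaggedSet

# pseudo-random stream ids (order is part of the on-disk contract)
_STREAM_POSITIONS = 0
_STREAM_UNANCHORED = 1
_STREAM_TERMS = 2
_STREAM_SEQUENCES = 3
_STREAM_TAGGING = 4
_STREAM_HITS = 5
_STREAM_EXPRESSION = 6

DEFAULT_TERM_VOCAB = (
    "GO:0043565", "GO:0006355", "GO:0016758", "GO:0009607",
    "PF00001", "PF00201", "PF02458", "PF03106",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: int, stream: int, *extra: int | str) -> np.random.Generator:
    key = [stream]
    for item in extra:
        key.append(zlib.crc32(item.encode()) if isinstance(item, str) else item)
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset; same spec -> identical bytes."""

    seed: int
    n_chromosomes: int = 3
    chromosome_length: float = 30_000_000
    unit: str = "bp"
    n_genes: int = 300
    bin_width: float = 1_000_000
    unanchored_fraction: float = 0.1
    arm_fraction: Optional[float] = 0.45
    planted_cluster: Optional[tuple[str, int, int]] = None  # (chrom, bin, n)
    planted_enriched_unit: Optional[tuple[str, int]] = None  # (unit, n extra)
    planted_ortholog_pairs: int = 0
    planted_decoy_paralogs: int = 0
    ortholog_identity_range: tuple[float, float] = (0.70, 1.00)
    n_conditions: int = 4
    lognorm_location: float = 1.0
    lognorm_scale: float = 0.5
    fraction_constant_genes: float = 0.1
    make_sequences: bool = True
    seq_length_range: tuple[int, int] = (300, 3000)
    term_vocabulary: tuple[str, ...] = DEFAULT_TERM_VOCAB

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("fixture spec: missing required field 'seed'")
        if self.n_genes <= 0 or self.n_chromosomes <= 0:
            raise ConfigError("fixture spec: n_genes and n_chromosomes must be > 0")
        if self.planted_cluster and self.planted_cluster[2] > self.n_genes:
            raise ConfigError("fixture spec: planted cluster larger than n_genes")
        if self.planted_ortholog_pairs > self.n_genes:
            raise ConfigError("fixture spec: more planted pairs than genes")
        if not 0 <= self.unanchored_fraction <= 1:
            raise ConfigError("fixture spec: unanchored_fraction outside [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "FixtureSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: fixture spec must be a mapping")
        if "seed" not in raw:
            raise ConfigError(f"{path}: missing required field 'seed'")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown field(s) {sorted(unknown)}")
        for name in ("planted_cluster", "planted_enriched_unit",
                     "ortholog_identity_range", "seq_length_range",
                     "term_vocabulary"):
            if isinstance(raw.get(name), list):
                raw[name] = tuple(raw[name])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _gene_ids(spec: FixtureSpec, genome_id: str) -> list[str]:
    width = max(5, len(str(spec.n_genes)))
    return [f"{genome_id}_g{i:0{width}d}" for i in range(1, spec.n_genes + 1)]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def make_genome(spec: FixtureSpec, genome_id: str = "synth") -> GenomeIndex:
    """A genome with uniformly placed genes (plus an optional planted
    cluster), a configurable unanchored fraction, random sequences and
    annotation terms from a small vocabulary."""
    chrom_names = [f"chr{i}" for i in range(1, spec.n_chromosomes + 1)]
    length = float(spec.chromosome_length)
    boundary = (
        spec.arm_fraction * length if spec.arm_fraction is not None else None
    )
    index = GenomeIndex(genome_id=genome_id, unit=spec.unit,
                        bin_width=float(spec.bin_width))
    for name in chrom_names:
        index.chromosomes[name] = ChromosomeDef(
            name=name, length=length, arm_boundary=boundary
        )

    ids = _gene_ids(spec, genome_id)
    rng_pos = _rng(spec.seed, _STREAM_POSITIONS, genome_id)
    chrom_idx = rng_pos.integers(0, spec.n_chromosomes, size=spec.n_genes)
    if spec.unit == "bp":
        positions = rng_pos.integers(0, int(length), size=spec.n_genes).astype(float)
    else:
        positions = rng_pos.uniform(0, length, size=spec.n_genes)

    cluster_ids: set[str] = set()
    if spec.planted_cluster is not None:
        c_chrom, c_bin, c_n = spec.planted_cluster
        if c_chrom not in index.chromosomes:
            raise ConfigError(f"planted cluster chromosome {c_chrom!r} not declared")
        lo = c_bin * spec.bin_width
        hi = min((c_bin + 1) * spec.bin_width, length)
        if lo >= length:
            raise ConfigError(f"planted cluster bin {c_bin} beyond chromosome")
        cluster_pos = rng_pos.uniform(lo, hi, size=c_n)
        if spec.unit == "bp":
            cluster_pos = np.floor(cluster_pos)
        for i in range(c_n):  # first c_n genes form the cluster
            chrom_idx[i] = chrom_names.index(c_chrom)
            positions[i] = cluster_pos[i]
            cluster_ids.add(ids[i])

    rng_un = _rng(spec.seed, _STREAM_UNANCHORED, genome_id)
    n_unanchored = int(math.floor(spec.unanchored_fraction * spec.n_genes))
    eligible = [i for i, gid in enumerate(ids) if gid not in cluster_ids]
    unanchored_idx = set(
        rng_un.choice(eligible, size=min(n_unanchored, len(eligible)),
                      replace=False).tolist()
    ) if n_unanchored else set()

    rng_terms = _rng(spec.seed, _STREAM_TERMS, genome_id)
    vocab = list(spec.term_vocabulary)
    for i, gid in enumerate(ids):
        n_terms = int(rng_terms.integers(0, 4))
        terms = set(
            rng_terms.choice(vocab, size=min(n_terms, len(vocab)),
                             replace=False).tolist()
        )
        if i in unanchored_idx:
            gene = AnchoredGene(gene_id=gid, anchored=False, terms=terms)
        else:
            gene = AnchoredGene(
                gene_id=gid,
                chromosome=chrom_names[chrom_idx[i]],
                position=float(positions[i]),
                anchored=True,
                terms=terms,
            )
        index.add_gene(gene)

    if spec.make_sequences:
        rng_seq = _rng(spec.seed, _STREAM_SEQUENCES, genome_id)
        lo, hi = spec.seq_length_range
        for gid in ids:
            index.sequences[gid] = _random_sequence(
                rng_seq, int(rng_seq.integers(lo, hi + 1))
            )
    return index


def planted_cluster_ids(spec: FixtureSpec, genome_id: str = "synth") -> list[str]:
    if spec.planted_cluster is None:
        return []
    return _gene_ids(spec, genome_id)[: spec.planted_cluster[2]]


def _unit_of(index: GenomeIndex, gene: AnchoredGene) -> str:
    return arm_of(gene, index.chromosomes[gene.chromosome])


def plant_tagged(index: GenomeIndex, spec: FixtureSpec,
                 background_fraction: float = 0.05) -> TaggedSet:
    """Tagged set with a uniform background plus extra tagged genes planted
    on ``spec.planted_enriched_unit`` (matched by arm unit or chromosome)."""
    rng = _rng(spec.seed, _STREAM_TAGGING, index.genome_id)
    all_ids = sorted(index.genes)
    tagged = {
        gid for gid in all_ids if rng.random() < background_fraction
    }
    if spec.planted_enriched_unit is not None:
        unit_name, n_extra = spec.planted_enriched_unit
        on_unit = sorted(
            g.gene_id for g in index.anchored_genes()
            if _unit_of(index, g) == unit_name or g.chromosome == unit_name
        )
        pool = [gid for gid in on_unit if gid not in tagged]
        take = min(n_extra, len(pool))
        tagged.update(rng.choice(pool, size=take, replace=False).tolist())
    return TaggedSet(
        genome_id=index.genome_id,
        gene_ids=frozenset(tagged),
        provenance={"mode": "fixture", "seed": spec.seed,
                    "background_fraction": background_fraction},
    )


# ---------------------------------------------------------------------------
# ortholog hit tables


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if n_mut:
        sites = rng.choice(len(arr), size=n_mut, replace=False)
        for site in sites:
            choices = _BASES[_BASES != arr[site]]
            arr[site] = rng.choice(choices)
    return bytes(arr).decode()


def make_ortholog_hit_tables(
    genome_a: GenomeIndex, genome_b: GenomeIndex, spec: FixtureSpec
):
    """Plant 1:1 ortholog pairs between two genomes and emit forward/reverse
    12-column hit tables.

    Planted partners in genome B receive a mutated copy of their A partner's
    sequence (identity drawn from ``ortholog_identity_range``) and the
    top-scoring reciprocal hits; decoy paralog hits get strictly lower
    scores.  Returns (forward, reverse, planted pairs).
    """
    p = spec.planted_ortholog_pairs
    rng = _rng(spec.seed, _STREAM_HITS, genome_a.genome_id, genome_b.genome_id)
    fwd = HitTable(direction="forward")
    rev = HitTable(direction="reverse")
    if p == 0:
        return fwd, rev, []
    a_pool = sorted(gid for gid in genome_a.genes if gid in genome_a.sequences)
    b_pool = sorted(genome_b.genes)
    if p > min(len(a_pool), len(b_pool)):
        raise ValidationError("not enough genes with sequences to plant pairs")
    a_ids = rng.choice(a_pool, size=p, replace=False).tolist()
    b_ids = rng.choice(b_pool, size=p, replace=False).tolist()

    m_total = sum(len(s) for s in genome_a.sequences.values()) or 1
    n_total = sum(len(s) for s in genome_b.sequences.values()) or 1

    def _evalue(score: float) -> float:
        try:
            return m_total * n_total * 2.0 ** (-score)
        except OverflowError:
            return 0.0

    pairs = []
    scores = []
    lo_id, hi_id = spec.ortholog_identity_range
    for a, b in zip(a_ids, b_ids):
        seq = genome_a.sequences[a]
        L = len(seq)
        target = rng.uniform(lo_id, hi_id)
        n_mut = int(round((1.0 - target) * L))
        genome_b.sequences[b] = _mutate(rng, seq, n_mut)
        identity = 100.0 * (L - n_mut) / L
        score = float(L - 3 * n_mut)  # +1 match / -2 mismatch, ungapped
        common = dict(pct_identity=identity, aln_length=L, mismatches=n_mut,
                      gap_opens=0, q_start=1, q_end=L, s_start=1, s_end=L,
                      evalue=_evalue(score), bitscore=score)
        fwd.hits.append(AlignmentHit(query_id=a, subject_id=b, **common))
        rev.hits.append(AlignmentHit(query_id=b, subject_id=a, **common))
        pairs.append((a, b))
        scores.append(score)

    for _ in range(spec.planted_decoy_paralogs):
        i = int(rng.integers(0, p))
        j = int(rng.integers(0, p - 1))
        if j >= i:
            j += 1
        a, b = a_ids[i], b_ids[j]
        score = math.floor(0.5 * min(scores[i], scores[j]))
        L = len(genome_a.sequences[a])
        identity = float(rng.uniform(55.0, 69.5))
        aln = max(1, int(L * 0.6))
        common = dict(pct_identity=identity, aln_length=aln,
                      mismatches=int(aln * (1 - identity / 100.0)),
                      gap_opens=0, q_start=1, q_end=aln, s_start=1, s_end=aln,
                      evalue=_evalue(score), bitscore=float(score))
        fwd.hits.append(AlignmentHit(query_id=a, subject_id=b, **common))
        rev.hits.append(AlignmentHit(query_id=b, subject_id=a, **common))
    return fwd, rev, pairs


# ---------------------------------------------------------------------------
# expression uploads


def make_expression(spec: FixtureSpec, index: GenomeIndex):
    """Log-normal expression values; a designated subset (genes on the
    planted enriched unit, else a random 10%) gets a high-variance spike and
    DEG membership; groups put the designated subset into its own module.

    Returns (ExpressionMatrix, DEGList, GroupMap).
    """
    rng = _rng(spec.seed, _STREAM_EXPRESSION, index.genome_id)
    ids = sorted(index.genes)
    loc, scale = spec.lognorm_location, spec.lognorm_scale
    ncond = spec.n_conditions

    if spec.planted_enriched_unit is not None:
        unit_name = spec.planted_enriched_unit[0]
        designated = [
            g.gene_id for g in index.anchored_genes()
            if _unit_of(index, g) == unit_name or g.chromosome == unit_name
        ]
    else:
        n_des = max(1, len(ids) // 10)
        designated = rng.choice(ids, size=n_des, replace=False).tolist()
    designated = sorted(designated)

    if spec.fraction_constant_genes >= 1.0:
        constant = set(ids)
        designated = []
    else:
        pool = sorted(set(ids) - set(designated))
        n_const = min(int(round(spec.fraction_constant_genes * len(ids))),
                      len(pool))
        constant = set(
            rng.choice(pool, size=n_const, replace=False).tolist()
        ) if n_const else set()

    designated_set = set(designated)
    values: dict[str, np.ndarray] = {}
    for gid in ids:
        if gid in constant:
            values[gid] = np.full(ncond, rng.lognormal(loc, scale))
        elif gid in designated_set:
            base = rng.lognormal(loc, scale)
            vec = np.full(ncond, base)
            vec[int(rng.integers(0, ncond))] *= 20.0  # high-CV spike
            values[gid] = vec
        else:
            values[gid] = rng.lognormal(loc, scale, size=ncond)

    matrix = ExpressionMatrix(
        conditions=[f"cond{i}" for i in range(1, ncond + 1)], values=values
    )
    deg = DEGList(gene_ids=frozenset(designated))
    mapping = {}
    for gid in ids:
        if gid in designated_set:
            mapping[gid] = "module1"
        else:
            mapping[gid] = f"module{int(rng.integers(2, 5))}"
    return matrix, deg, GroupMap(mapping=mapping)


# ---------------------------------------------------------------------------
# fixture directory


def write_fixture_dir(spec: FixtureSpec, out_dir: str | Path,
                      genome_id: str = "synth") -> dict[str, Path]:
    """Write a complete, self-describing fixture directory loadable by the
    CLI: genome config + anchors + FASTA + annotations + expression uploads,
    and (when ortholog pairs are planted) a second genome with forward and
    reverse hit tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = make_genome(spec, genome_id=genome_id)

    paths: dict[str, Path] = {}
    second = spec.planted_ortholog_pairs > 0
    if second:
        index_b = make_genome(spec, genome_id=f"{genome_id}_b")
        fwd, rev, _pairs = make_ortholog_hit_tables(index_b, index, spec)
        # forward table maps the second genome's genes onto the primary one

    matrix, deg, groups = make_expression(spec, index)

    paths["anchors"] = out_dir / "anchors.tsv"
    write_anchor_table(index, paths["anchors"])
    paths["annotations"] = out_dir / "annotations.tsv"
    write_annotations(index, paths["annotations"])
    if spec.make_sequences:
        paths["fasta"] = out_dir / "genes.fasta"
        write_fasta(index.sequences, paths["fasta"])
    paths["expression"] = out_dir / "expression.tsv"
    write_expression_tsv(matrix, paths["expression"])
    paths["deg"] = out_dir / "deg.txt"
    write_deg_list(deg, paths["deg"])
    paths["groups"] = out_dir / "groups.tsv"
    write_group_map(groups, paths["groups"])

    files = {k: p.name for k, p in paths.items()}
    if second:
        paths["hits_fwd"] = out_dir / "hits_fwd.tsv"
        write_tabular_hits(fwd, paths["hits_fwd"])
        paths["hits_rev"] = out_dir / "hits_rev.tsv"
        write_tabular_hits(rev, paths["hits_rev"])
        paths["anchors_b"] = out_dir / "anchors_b.tsv"
        write_anchor_table(index_b, paths["anchors_b"])
        if spec.make_sequences:
            paths["fasta_b"] = out_dir / "genes_b.fasta"
            write_fasta(index_b.sequences, paths["fasta_b"])
        files.update(hits_fwd="hits_fwd.tsv", hits_rev="hits_rev.tsv")
        write_genome_config(
            index_b, out_dir / "genome_b.yaml",
            files={"anchors": "anchors_b.tsv",
                   **({"fasta": "genes_b.fasta"} if spec.make_sequences else {})},
        )
        paths["config_b"] = out_dir / "genome_b.yaml"

    paths["config"] = out_dir / "genome.yaml"
    write_genome_config(index, paths["config"], files=files)
    paths["spec"] = out_dir / "fixture.json"
    with open(paths["spec"], "w") as fh:
        json.dump(spec.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
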