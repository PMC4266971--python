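"""Produce "tagged gene" sets from id lists, annotation terms or homology hits.

Every query mode returns a :class:`TaggedSet` whose provenance record fully
reconstructs the query (mode, parameters, thresholds, misses).  Expression
constraints are applied afterwards with :func:`intersect_filters`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .errors import ValidationError
from .genome_model import GenomeIndex
from .homology import HitTable, filter_hits, reciprocal_best_hits


@dataclass
class TaggedSet:
    genome_id: str
    gene_ids: frozenset[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    @property
    def provenance_hash(self) -> str:
        canonical = json.dumps(self.provenance, sort_keys=True, default=sorted)
        return hashlib.sha1(canonical.encode()).hexdigest()[:12]


def query_by_ids(index: GenomeIndex, ids: Iterable[str]) -> TaggedSet:
    """Intersect a list of gene ids with the genome; unknown ids are recorded
    in provenance as misses, not fatal."""
    requested = list(ids)
    present = frozenset(i for i in requested if i in index.genes)
    misses = sorted(set(requested) - present)
    return TaggedSet(
        genome_id=index.genome_id,
        gene_ids=present,
        provenance={
            "mode": "ids",
            "n_requested": len(requested),
            "misses": misses,
        },
    )


def query_by_annotation(index: GenomeIndex, term: str) -> TaggedSet:
    """All genes (anchored and unanchored) carrying the exact term.  The
    provenance reports anchored vs total counts, e.g. "3 (5)"."""
    if not term:
        raise ValidationError("annotation term must be non-empty")
    carriers = frozenset(
        g.gene_id for g in index.genes.values() if term in g.terms
    )
    n_anchored = sum(1 for gid in carriers if index.genes[gid].anchored)
    return TaggedSet(
        genome_id=index.genome_id,
        gene_ids=carriers,
        provenance={
            "mode": "annotation",
            "term": term,
            "n_anchored": n_anchored,
            "n_total": len(carriers),
            "dual_count": f"{n_anchored} ({len(carriers)})",
        },
    )


def query_by_homology(
    index: GenomeIndex,
    forward: HitTable,
    reverse: Optional[HitTable],
    evalue_max: float,
    identity_min: float,
    bbh: bool,
) -> TaggedSet:
    """Tag SUBJECT genes of thresholded hits; with ``bbh=True`` only subjects
    of reciprocal best-hit pairs survive (requires the reverse table)."""
    if bbh and reverse is None:
        raise ValidationError("BBH filtering requested but no reverse hit table given")
    fwd = filter_hits(forward, evalue_max, identity_min)
    if bbh:
        rev = filter_hits(reverse, evalue_max, identity_min)
        subjects = {b for (_a, b) in reciprocal_best_hits(fwd, rev)}
    else:
        subjects = {h.subject_id for h in fwd.hits}
    present = frozenset(s for s in subjects if s in index.genes)
    misses = sorted(subjects - present)
    return TaggedSet(
        genome_id=index.genome_id,
        gene_ids=present,
        provenance={
            "mode": "homology",
            "evalue_max": evalue_max,
            "identity_min": identity_min,
            "bbh": bbh,
            "misses": misses,
        },
    )


def intersect_filters(tagged: TaggedSet, predicates: Iterable) -> TaggedSet:
    """Intersect a tagged set with gene-set predicates (expression module),
    extending the provenance chain.  Zero predicates is the identity."""
    ids = set(tagged.gene_ids)
    applied = []
    for pred in predicates:
        ids &= set(pred.accepted)
        applied.append(pred.name)
    return TaggedSet(
        genome_id=tagged.genome_id,
        gene_ids=frozenset(ids),
        provenance={**tagged.provenance, "filters":
                    tagged.provenance.get("filters", []) + applied},
    )


def write_tagged_tsv(tagged: TaggedSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tprovenance\n")
        for gid in sorted(tagged.gene_ids):
            fh.write(f"{gid}\t{tagged.provenance_hash}\n")


def read_tagged_tsv(path: str | Path, genome_id: str) -> TaggedSet:
    ids = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:1] != ["gene_id"]:
            raise ValidationError(f"{path}: not a tagged-set TSV")
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return TaggedSet(
        genome_id=genome_id,
        gene_ids=frozenset(ids),
        provenance={"mode": "imported", "path": str(path)},
    )
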