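"""Validation of user-supplied expression data and derived gene-set predicates.

Mirrors an upload "data manager": expression matrices, lists of
differentially expressed genes (DEGs) and gene-to-group mappings are
validated against a genome before they unlock the corresponding filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import UploadError
from .genome_model import GenomeIndex
from .query import TaggedSet

UNGROUPED = "ungrouped"


@dataclass
class ExpressionMatrix:
    conditions: list[str]
    values: dict[str, np.ndarray]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values


@dataclass
class DEGList:
    gene_ids: frozenset[str]


@dataclass
class GroupMap:
    mapping: dict[str, str]

    def group_of(self, gene_id: str) -> Optional[str]:
        return self.mapping.get(gene_id)


@dataclass
class UploadReport:
    unknown_ids: list[str] = field(default_factory=list)
    malformed: list[tuple[int, str]] = field(default_factory=list)
    n_matched: int = 0


@dataclass
class GenePredicate:
    """A named gene-set predicate: a gene passes iff it is in ``accepted``."""

    name: str
    accepted: frozenset[str]

    def __call__(self, gene_id: str) -> bool:
        return gene_id in self.accepted


# ---------------------------------------------------------------------------
# statistics


def cv(values) -> Optional[float]:
    """Coefficient of variation: sample standard deviation (n-1 denominator)
    divided by the sample mean.  Undefined (None) when the mean is 0; genes
    with undefined CV fail every CV filter."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise UploadError("CV needs at least two conditions")
    mean = float(arr.mean())
    if mean == 0.0:
        return None
    return float(arr.std(ddof=1)) / mean


# ---------------------------------------------------------------------------
# upload validation


def _parse_expression(path: Path, index: GenomeIndex):
    report = UploadReport()
    values: dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "gene_id":
            raise UploadError(
                f"{path}: expression header must be gene_id<TAB>cond1<TAB>cond2..."
            )
        conditions = header[1:]
        n_rows = 0
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise UploadError(
                    f"{path}: line {line_no}: expected {len(header)} columns, "
                    f"got {len(fields)}"
                )
            gene_id = fields[0]
            try:
                vec = np.array([float(x) for x in fields[1:]])
            except ValueError:
                report.malformed.append((line_no, "non-numeric expression value"))
                continue
            if np.any(vec < 0) or not np.all(np.isfinite(vec)):
                report.malformed.append((line_no, "negative or non-finite value"))
                continue
            n_rows += 1
            if gene_id not in index.genes:
                report.unknown_ids.append(gene_id)
                continue
            values[gene_id] = vec
        if n_rows == 0:
            raise UploadError(f"{path}: expression matrix has no data rows")
    report.n_matched = len(values)
    return ExpressionMatrix(conditions=conditions, values=values), report


def _parse_deg(path: Path, index: GenomeIndex):
    report = UploadReport()
    matched = set()
    with open(path) as fh:
        for line in fh:
            gid = line.strip()
            if not gid or gid.startswith("#"):
                continue
            if gid in index.genes:
                matched.add(gid)
            else:
                report.unknown_ids.append(gid)
    report.n_matched = len(matched)
    return DEGList(gene_ids=frozenset(matched)), report


def _parse_groups(path: Path, index: GenomeIndex):
    report = UploadReport()
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[1].strip():
                report.malformed.append((line_no, "expected gene_id<TAB>group"))
                continue
            gene_id, group = fields[0], fields[1].strip()
            if gene_id in mapping and mapping[gene_id] != group:
                raise UploadError(
                    f"{path}: line {line_no}: gene {gene_id!r} mapped to both "
                    f"{mapping[gene_id]!r} and {group!r}"
                )
            if gene_id not in index.genes:
                report.unknown_ids.append(gene_id)
                continue
            mapping[gene_id] = group
    report.n_matched = len(mapping)
    return GroupMap(mapping=mapping), report


def validate_upload(path: str | Path, kind: str, index: GenomeIndex):
    """Validate an upload of the given kind against the genome.

    kind: ``expression`` | ``deg`` | ``groups``.  Returns (typed object,
    :class:`UploadReport`).  An upload with zero ids matching the genome is
    rejected outright.
    """
    path = Path(path)
    parsers = {"expression": _parse_expression, "deg": _parse_deg,
               "groups": _parse_groups}
    if kind not in parsers:
        raise UploadError(f"unknown upload kind {kind!r}")
    obj, report = parsers[kind](path, index)
    if report.n_matched == 0:
        raise UploadError(f"{path}: no overlap with genome {index.genome_id!r}")
    return obj, report


# ---------------------------------------------------------------------------
# predicates


def filter_cv(matrix: ExpressionMatrix, min_cv: float) -> GenePredicate:
    """Genes whose expression varies across conditions: defined CV >= min_cv.
    Genes absent from the matrix are rejected."""
    if min_cv < 0:
        raise UploadError("min_cv must be >= 0")
    accepted = frozenset(
        gid for gid, vec in matrix.values.items()
        if (c := cv(vec)) is not None and c >= min_cv
    )
    return GenePredicate(name=f"cv>={min_cv:g}", accepted=accepted)


def filter_min_expression(matrix: ExpressionMatrix, threshold: float) -> GenePredicate:
    """Genes whose expression strictly surpasses the threshold in at least
    one condition."""
    if threshold < 0:
        raise UploadError("expression threshold must be >= 0")
    accepted = frozenset(
        gid for gid, vec in matrix.values.items() if float(vec.max()) > threshold
    )
    return GenePredicate(name=f"min_expr>{threshold:g}", accepted=accepted)


def filter_deg(deg: DEGList) -> GenePredicate:
    return GenePredicate(name="deg", accepted=frozenset(deg.gene_ids))


def group_partition(tagged: TaggedSet, groups: GroupMap) -> dict[str, TaggedSet]:
    """Split a tagged set by group; genes without a group go to the reserved
    "ungrouped" label.  Empty buckets are omitted, so the result is a true
    partition of the input."""
    buckets: dict[str, set[str]] = {}
    for gid in tagged.gene_ids:
        group = groups.group_of(gid) or UNGROUPED
        buckets.setdefault(group, set()).add(gid)
    return {
        group: TaggedSet(
            genome_id=tagged.genome_id,
            gene_ids=frozenset(ids),
            provenance={**tagged.provenance, "group": group},
        )
        for group, ids in sorted(buckets.items())
    }


# ---------------------------------------------------------------------------
# writers (used by the fixture generator and the CLI)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.conditions) + "\n")
        for gid in sorted(matrix.values):
            vals = "\t".join(f"{v:.6g}" for v in matrix.values[gid])
            fh.write(f"{gid}\t{vals}\n")


def write_deg_list(deg: DEGList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(deg.gene_ids):
            fh.write(gid + "\n")


def write_group_map(groups: GroupMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(groups.mapping):
            fh.write(f"{gid}\t{groups.mapping[gid]}\n")
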