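"""Pairwise alignment hit tables: parsing, thresholding, best-bidirectional hits.

The production path consumes precomputed 12-column tabular hit files
(the classic BLAST ``-outfmt 6`` dialect).  A lightweight built-in
nucleotide search (:func:`naive_search`) is provided so the test suite and
the self-contained workflows need no external aligner; its e-values are a
crude ungapped surrogate and are NOT comparable to BLAST e-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .errors import ValidationError

TABULAR_COLUMNS = 12

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: identity "
                f"{self.pct_identity} outside [0, 100]"
            )
        if self.evalue < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: negative e-value"
            )
        if self.aln_length <= 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: non-positive length"
            )


@dataclass
class HitTable:
    hits: list[AlignmentHit] = field(default_factory=list)
    direction: str = "forward"
    warnings: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)


def parse_tabular_hits(path: str | Path, direction: str = "forward") -> HitTable:
    """Parse a whitespace/tab-separated 12-column hit file.

    ``#``-prefixed lines are ignored; malformed rows (wrong column count,
    non-numeric numeric fields) are rejected and reported with their line
    number in ``table.warnings``.
    """
    table = HitTable(direction=direction)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != TABULAR_COLUMNS:
                table.warnings.append(
                    (line_no, f"expected {TABULAR_COLUMNS} columns, got {len(fields)}")
                )
                continue
            try:
                hit = AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except (ValueError, ValidationError) as exc:
                table.warnings.append((line_no, str(exc)))
                continue
            table.hits.append(hit)
    return table


def write_tabular_hits(table: HitTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in table.hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t"
                f"{h.aln_length}\t{h.mismatches}\t{h.gap_opens}\t"
                f"{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t"
                f"{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def filter_hits(table: HitTable, evalue_max: float, identity_min: float) -> HitTable:
    """Keep hits with ``evalue <= evalue_max`` and ``identity >= identity_min``
    (inclusive thresholds), preserving order."""
    if evalue_max <= 0:
        raise ValidationError("evalue_max must be > 0")
    if not 0.0 <= identity_min <= 100.0:
        raise ValidationError("identity_min must be in [0, 100]")
    kept = [
        h for h in table.hits
        if h.evalue <= evalue_max and h.pct_identity >= identity_min
    ]
    return HitTable(hits=kept, direction=table.direction)


def _hit_rank(hit: AlignmentHit) -> tuple:
    # maximal bitscore; ties by lower evalue, higher identity, smallest subject
    return (-hit.bitscore, hit.evalue, -hit.pct_identity, hit.subject_id)


def best_hit_per_query(table: HitTable) -> dict[str, AlignmentHit]:
    """For each query, the hit with maximal bitscore; deterministic tie-break
    by (lower e-value, higher identity, lexicographically smallest subject)."""
    best: dict[str, AlignmentHit] = {}
    for hit in table.hits:
        current = best.get(hit.query_id)
        if current is None or _hit_rank(hit) < _hit_rank(current):
            best[hit.query_id] = hit
    return best


def reciprocal_best_hits(forward: HitTable, reverse: HitTable) -> set[tuple[str, str]]:
    """Pairs (a, b) where b is a's best forward hit and a is b's best reverse
    hit.  The result is a one-to-one partial matching."""
    fwd_best = best_hit_per_query(forward)
    rev_best = best_hit_per_query(reverse)
    pairs = set()
    for a, hit in fwd_best.items():
        b = hit.subject_id
        back = rev_best.get(b)
        if back is not None and back.subject_id == a:
            pairs.add((a, b))
    return pairs


# ---------------------------------------------------------------------------
# built-in nucleotide search


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_nucleotides(name: str, seq: str) -> None:
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise ValidationError(
            f"sequence {name}: non-IUPAC nucleotide residue(s) {sorted(bad)}"
        )


def _best_segment_on_diagonal(q: str, t: str, diag: int,
                              match: int = 1, mismatch: int = -2):
    """Best-scoring contiguous segment of the q/t overlap on one diagonal
    (Kadane's maximum-subarray over +match/-mismatch scores).

    Returns (score, q_lo, q_hi_exclusive, n_matches) or None.
    """
    lo = max(0, -diag)
    hi = min(len(q), len(t) - diag)
    if hi <= lo:
        return None
    best_score = 0
    best = None
    run_score = 0
    run_start = lo
    for i in range(lo, hi):
        is_match = q[i] == t[i + diag] and q[i] != "N"
        run_score += match if is_match else mismatch
        if run_score <= 0:
            run_score = 0
            run_start = i + 1
        elif run_score > best_score:
            best_score = run_score
            best = (run_start, i + 1)
    if best is None:
        return None
    b_lo, b_hi = best
    n_matches = sum(
        1 for i in range(b_lo, b_hi) if q[i] == t[i + diag] and q[i] != "N"
    )
    return best_score, b_lo, b_hi, n_matches


def naive_search(
    queries: dict[str, str],
    subjects: dict[str, str],
    k: int = 11,
    min_identity: float = 0.0,
) -> HitTable:
    """Exact k-mer seeded, ungapped nucleotide search on both strands.

    One best local hit per (query, subject) pair, scored +1/-2; the e-value
    is the surrogate ``m * n * 2**(-score)`` with m, n the total query and
    subject lengths.  Minus-strand hits are reported with s_start > s_end.
    """
    if k < 8:
        raise ValidationError("seed length k must be >= 8")
    queries = {name: seq.upper() for name, seq in queries.items()}
    subjects = {name: seq.upper() for name, seq in subjects.items()}
    for name, seq in list(queries.items()) + list(subjects.items()):
        _validate_nucleotides(name, seq)

    m_total = sum(len(s) for s in queries.values())
    n_total = sum(len(s) for s in subjects.values())

    # index: kmer -> list of (subject_id, strand, pos in stranded sequence)
    stranded: dict[tuple[str, str], str] = {}
    kmer_index: dict[str, list[tuple[str, str, int]]] = {}
    for sid, seq in subjects.items():
        for strand, sseq in (("+", seq), ("-", reverse_complement(seq))):
            stranded[(sid, strand)] = sseq
            for pos in range(len(sseq) - k + 1):
                kmer = sseq[pos:pos + k]
                if "N" in kmer:
                    continue
                kmer_index.setdefault(kmer, []).append((sid, strand, pos))

    table = HitTable(direction="forward")
    for qid in sorted(queries):
        qseq = queries[qid]
        # distinct diagonals with at least one shared seed, per (subject, strand)
        diagonals: dict[tuple[str, str], set[int]] = {}
        for qpos in range(len(qseq) - k + 1):
            kmer = qseq[qpos:qpos + k]
            if "N" in kmer:
                continue
            for sid, strand, spos in kmer_index.get(kmer, ()):
                diagonals.setdefault((sid, strand), set()).add(spos - qpos)

        best_per_subject: dict[str, tuple] = {}
        for (sid, strand), diags in sorted(diagonals.items()):
            tseq = stranded[(sid, strand)]
            for diag in sorted(diags):
                seg = _best_segment_on_diagonal(qseq, tseq, diag)
                if seg is None:
                    continue
                score, q_lo, q_hi, n_matches = seg
                cand = (score, strand == "+", -q_lo, sid, strand, diag,
                        q_lo, q_hi, n_matches)
                prev = best_per_subject.get(sid)
                if prev is None or cand[:3] > prev[:3]:
                    best_per_subject[sid] = cand

        for sid in sorted(best_per_subject):
            (score, _, _, _, strand, diag, q_lo, q_hi, n_matches) = \
                best_per_subject[sid]
            aln_len = q_hi - q_lo
            identity = 100.0 * n_matches / aln_len
            if identity < min_identity:
                continue
            t_lo, t_hi = q_lo + diag, q_hi + diag  # 0-based, exclusive end
            slen = len(subjects[sid])
            if strand == "+":
                s_start, s_end = t_lo + 1, t_hi
            else:
                # map coordinates on the reverse complement back to the
                # original subject; s_start > s_end flags the minus strand
                s_start, s_end = slen - t_lo, slen - t_hi + 1
            evalue = m_total * n_total * 2.0 ** (-score)
            table.hits.append(AlignmentHit(
                query_id=qid,
                subject_id=sid,
                pct_identity=identity,
                aln_length=aln_len,
                mismatches=aln_len - n_matches,
                gap_opens=0,
                q_start=q_lo + 1,
                q_end=q_hi,
                s_start=s_start,
                s_end=s_end,
                evalue=evalue,
                bitscore=float(score),
            ))
    return table
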