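import numpy as np
import pytest

from chromobin.genome_model import AnchoredGene, ChromosomeDef, GenomeIndex
from chromobin.homology import AlignmentHit, HitTable
from chromobin.query import TaggedSet


@pytest.fixture
def toy_index() -> GenomeIndex:
    """Two chromosomes (one with an arm boundary), 5 genes, 1 unanchored."""
    index = GenomeIndex(genome_id="toy", unit="bp", bin_width=10)
    index.chromosomes["3B"] = ChromosomeDef("3B", length=100, arm_boundary=50)
    index.chromosomes["5B"] = ChromosomeDef("5B", length=100)
    rows = [
        ("g1", "3B", 5.0, {"GO:0043565", "PF00001"}),
        ("g2", "3B", 50.0, {"GO:0043565"}),
        ("g3", "3B", 95.0, set()),
        ("g4", "5B", 10.0, {"GO:0043565"}),
    ]
    for gid, chrom, pos, terms in rows:
        index.add_gene(AnchoredGene(gene_id=gid, chromosome=chrom,
                                    position=pos, anchored=True, terms=terms))
    index.add_gene(AnchoredGene(gene_id="g5", anchored=False,
                                terms={"GO:0043565"}))
    return index


def make_tagged(index: GenomeIndex, ids) -> TaggedSet:
    return TaggedSet(genome_id=index.genome_id, gene_ids=frozenset(ids),
                     provenance={"mode": "test"})


def make_hit(q, s, bitscore=100.0, evalue=1e-20, identity=90.0,
             aln_length=100) -> AlignmentHit:
    return AlignmentHit(
        query_id=q, subject_id=s, pct_identity=identity,
        aln_length=aln_length, mismatches=0, gap_opens=0,
        q_start=1, q_end=aln_length, s_start=1, s_end=aln_length,
        evalue=evalue, bitscore=bitscore,
    )


def random_hit_tables(rng: np.random.Generator, n_a=6, n_b=6, density=0.6):
    """A random forward/reverse hit-table pair over small id sets."""
    a_ids = [f"a{i}" for i in range(n_a)]
    b_ids = [f"b{i}" for i in range(n_b)]
    fwd, rev = HitTable(direction="forward"), HitTable(direction="reverse")
    for a in a_ids:
        for b in b_ids:
            if rng.random() < density:
                fwd.hits.append(make_hit(a, b, bitscore=float(rng.integers(1, 30)),
                                         evalue=float(rng.choice([1e-30, 1e-10, 1e-5]))))
            if rng.random() < density:
                rev.hits.append(make_hit(b, a, bitscore=float(rng.integers(1, 30)),
                                         evalue=float(rng.choice([1e-30, 1e-10, 1e-5]))))
    return fwd, rev


def brute_force_rbh(forward: HitTable, reverse: HitTable) -> set:
    """Independent oracle: exhaustive check of the reciprocal condition over
    all (a, b) pairs, using explicit rank scans rather than best-hit maps."""
    def rank(h):
        return (-h.bitscore, h.evalue, -h.pct_identity, h.subject_id)

    def is_best(table, query, subject):
        mine = [h for h in table.hits if h.query_id == query]
        if not mine:
            return False
        best = min(mine, key=rank)
        return best.subject_id == subject

    a_ids = {h.query_id for h in forward.hits}
    b_ids = {h.query_id for h in reverse.hits} | {h.subject_id for h in forward.hits}
    return {
        (a, b) for a in a_ids for b in b_ids
        if is_best(forward, a, b) and is_best(reverse, b, a)
    }
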