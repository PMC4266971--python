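import filecmp
from pathlib import Path

import numpy as np
import pytest

from chromobin.density import build_density, enrich
from chromobin.errors import ConfigError
from chromobin.expression import cv, filter_cv
from chromobin.fixtures import (FixtureSpec, make_expression, make_genome,
                                make_ortholog_hit_tables, plant_tagged,
                                planted_cluster_ids, write_fixture_dir)
from chromobin.genome_model import load_anchor_table, load_annotations, \
    load_fasta, load_genome_config
from chromobin.homology import filter_hits, parse_tabular_hits, \
    reciprocal_best_hits
from chromobin.query import TaggedSet

from conftest import brute_force_rbh, make_tagged

SMALL = dict(n_genes=60, n_chromosomes=2, chromosome_length=5_000_000,
             bin_width=1_000_000)


class TestMakeGenome:
    def test_seed_determinism(self, tmp_path):
        spec = FixtureSpec(seed=1, **SMALL)
        a = make_genome(spec)
        b = make_genome(spec)
        assert a.genes == b.genes
        assert a.sequences == b.sequences

    def test_zero_unanchored_fraction(self):
        spec = FixtureSpec(seed=1, unanchored_fraction=0.0, **SMALL)
        index = make_genome(spec)
        assert index.n_unanchored == 0

    def test_unanchored_fraction_respected(self):
        spec = FixtureSpec(seed=1, unanchored_fraction=0.25, **SMALL)
        index = make_genome(spec)
        assert index.n_unanchored == 15

    def test_planted_cluster_fills_bin(self):
        spec = FixtureSpec(seed=2, planted_cluster=("chr1", 2, 20), **SMALL)
        index = make_genome(spec)
        tagged = TaggedSet(genome_id=index.genome_id, gene_ids=frozenset())
        track = next(t for t in build_density(index, tagged)
                     if t.grid.chromosome == "chr1")
        assert track.all_counts[2] >= 20
        assert len(planted_cluster_ids(spec)) == 20

    def test_too_large_cluster_errors(self):
        with pytest.raises(ConfigError):
            FixtureSpec(seed=1, planted_cluster=("chr1", 0, 1000), **SMALL)

    def test_outputs_parse_through_production_readers(self, tmp_path):
        spec = FixtureSpec(seed=3, **SMALL)
        paths = write_fixture_dir(spec, tmp_path)
        config = load_genome_config(paths["config"])
        index = load_anchor_table(paths["anchors"], config)
        assert index.n_genes == spec.n_genes
        report = load_annotations(paths["annotations"], index)
        assert report.n_warnings == 0
        report = load_fasta(paths["fasta"], index)
        assert not report.orphan_sequences
        assert len(index.sequences) == spec.n_genes


class TestOrthologTables:
    def test_bbh_recovers_exactly_planted_pairs(self):
        spec = FixtureSpec(seed=4, planted_ortholog_pairs=10,
                           planted_decoy_paralogs=5, **SMALL)
        a = make_genome(spec, genome_id="ga")
        b = make_genome(spec, genome_id="gb")
        fwd, rev, pairs = make_ortholog_hit_tables(a, b, spec)
        assert len(pairs) == 10
        got = reciprocal_best_hits(fwd, rev)
        assert got == set(pairs)
        assert got == brute_force_rbh(fwd, rev)  # independent oracle

    def test_zero_pairs_empty(self):
        spec = FixtureSpec(seed=4, **SMALL)
        a = make_genome(spec, genome_id="ga")
        b = make_genome(spec, genome_id="gb")
        fwd, rev, pairs = make_ortholog_hit_tables(a, b, spec)
        assert pairs == [] and len(fwd) == 0 and len(rev) == 0

    def test_identity_100_survives_strict_filter(self):
        spec = FixtureSpec(seed=4, planted_ortholog_pairs=5,
                           planted_decoy_paralogs=3,
                           ortholog_identity_range=(1.0, 1.0), **SMALL)
        a = make_genome(spec, genome_id="ga")
        b = make_genome(spec, genome_id="gb")
        fwd, rev, pairs = make_ortholog_hit_tables(a, b, spec)
        kept = filter_hits(fwd, 1e-5, 100.0)
        assert {(h.query_id, h.subject_id) for h in kept.hits} == set(pairs)

    def test_mutated_partner_identity_in_range(self):
        spec = FixtureSpec(seed=5, planted_ortholog_pairs=8, **SMALL)
        a = make_genome(spec, genome_id="ga")
        b = make_genome(spec, genome_id="gb")
        fwd, _rev, pairs = make_ortholog_hit_tables(a, b, spec)
        for hit in list(fwd.hits)[:8]:
            assert 69.0 <= hit.pct_identity <= 100.0
            # realized identity matches the mutated sequence pair
            sa, sb = a.sequences[hit.query_id], b.sequences[hit.subject_id]
            matches = sum(1 for x, y in zip(sa, sb) if x == y)
            assert hit.pct_identity == pytest.approx(100.0 * matches / len(sa))


class TestMakeExpression:
    def test_all_constant_gives_cv_zero(self):
        spec = FixtureSpec(seed=6, fraction_constant_genes=1.0, **SMALL)
        index = make_genome(spec)
        matrix, _deg, _groups = make_expression(spec, index)
        assert all(cv(v) == 0.0 for v in matrix.values.values())

    def test_planted_high_cv_separable(self):
        spec = FixtureSpec(seed=7, fraction_constant_genes=0.9,
                           planted_enriched_unit=("chr1S", 10),
                           unanchored_fraction=0.0, **SMALL)
        index = make_genome(spec)
        matrix, deg, _groups = make_expression(spec, index)
        # oracle: CVs computable directly from the generated values
        high = {g for g, v in matrix.values.items() if cv(v) and cv(v) > 0.5}
        assert high == set(deg.gene_ids)
        pred = filter_cv(matrix, 0.5)
        assert pred.accepted == frozenset(deg.gene_ids)

    def test_module_genes_enrich_their_unit(self):
        spec = FixtureSpec(seed=8, n_genes=400, n_chromosomes=3,
                           make_sequences=False,
                           planted_enriched_unit=("chr1S", 25))
        index = make_genome(spec)
        _matrix, _deg, groups = make_expression(spec, index)
        module = frozenset(g for g, grp in groups.mapping.items()
                           if grp == "module1")
        tagged = make_tagged(index, module & {g.gene_id
                                              for g in index.anchored_genes()})
        table = enrich(index, tagged, unit="arm")
        assert table.rows[0].unit == "chr1S"

    def test_group_map_is_function(self):
        spec = FixtureSpec(seed=6, **SMALL)
        index = make_genome(spec)
        _m, _d, groups = make_expression(spec, index)
        assert set(groups.mapping) == set(index.genes)


class TestFixtureDir:
    def test_byte_identical_per_seed(self, tmp_path):
        spec = FixtureSpec(seed=9, planted_ortholog_pairs=4, **SMALL)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_fixture_dir(spec, d1)
        p2 = write_fixture_dir(spec, d2)
        assert sorted(p.name for p in d1.iterdir()) == \
               sorted(p.name for p in d2.iterdir())
        for f in d1.iterdir():
            assert filecmp.cmp(f, d2 / f.name, shallow=False), f.name

    def test_different_seeds_differ(self, tmp_path):
        p1 = write_fixture_dir(FixtureSpec(seed=1, **SMALL), tmp_path / "a")
        p2 = write_fixture_dir(FixtureSpec(seed=2, **SMALL), tmp_path / "b")
        assert Path(p1["anchors"]).read_text() != Path(p2["anchors"]).read_text()

    def test_hit_tables_parse_and_bbh_holds(self, tmp_path):
        spec = FixtureSpec(seed=10, planted_ortholog_pairs=6, **SMALL)
        paths = write_fixture_dir(spec, tmp_path)
        fwd = parse_tabular_hits(paths["hits_fwd"])
        rev = parse_tabular_hits(paths["hits_rev"])
        assert not fwd.warnings and not rev.warnings
        pairs = reciprocal_best_hits(fwd, rev)
        assert len(pairs) == 6

    def test_spec_from_file_missing_seed(self, tmp_path):
        f = tmp_path / "spec.yaml"
        f.write_text("n_genes: 10\n")
        with pytest.raises(ConfigError, match="seed"):
            FixtureSpec.from_file(f)

    def test_spec_from_file_unknown_field(self, tmp_path):
        f = tmp_path / "spec.yaml"
        f.write_text("seed: 1\nbogus: 2\n")
        with pytest.raises(ConfigError, match="bogus"):
            FixtureSpec.from_file(f)


class TestPlantTagged:
    def test_planted_unit_receives_extra_tags(self):
        spec = FixtureSpec(seed=12, n_genes=500, make_sequences=False,
                           planted_enriched_unit=("chr2L", 20))
        index = make_genome(spec)
        tagged = plant_tagged(index, spec)
        from chromobin.genome_model import arm_of
        on_unit = sum(
            1 for g in index.anchored_genes()
            if g.gene_id in tagged.gene_ids
            and arm_of(g, index.chromosomes[g.chromosome]) == "chr2L"
        )
        assert on_unit >= 20
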