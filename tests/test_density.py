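import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from chromobin.density import (BinGrid, bin_index, bin_label, build_density,
                               enrich, enrichment_units, fisher_one_sided,
                               unanchored_tagged_count)
from chromobin.errors import ValidationError

from conftest import make_tagged


class TestBinIndex:
    def test_use_case_convention(self):
        # a gene at 9.5 Mb under 1 Mb binning sits in bin 9, "9-10 Mb"
        assert bin_index(9_500_000, 1_000_000) == 9
        assert bin_label(9, 1_000_000, "bp") == "9-10 Mb"

    def test_position_zero(self):
        assert bin_index(0, 1_000_000) == 0

    def test_exact_boundary_goes_up(self):
        assert bin_index(10_000_000, 1_000_000) == 10

    def test_negative_position_errors(self):
        with pytest.raises(ValidationError):
            bin_index(-1, 10)

    def test_cm_labels(self):
        assert bin_label(3, 5.0, "cM") == "15-20 cM"

    def test_grid_clamps_chromosome_end_into_last_bin(self):
        grid = BinGrid(chromosome="c", width=5.0, length=100.0, unit="cM")
        assert grid.n_bins == 20
        assert grid.bin_of(100.0) == 19


class TestBuildDensity:
    def test_relative_arithmetic(self, toy_index):
        # 3B bin 0 holds only g1; tagging g1 makes it 1/1
        tracks = build_density(toy_index, make_tagged(toy_index, {"g1"}))
        t3b = next(t for t in tracks if t.grid.chromosome == "3B")
        assert t3b.all_counts[0] == 1
        assert t3b.tagged_counts[0] == 1
        assert t3b.relative[0] == 1.0

    def test_quarter_relative(self):
        from chromobin.genome_model import AnchoredGene, ChromosomeDef, GenomeIndex
        index = GenomeIndex(genome_id="g", unit="bp", bin_width=100)
        index.chromosomes["c"] = ChromosomeDef("c", length=100)
        for i in range(4):
            index.add_gene(AnchoredGene(gene_id=f"g{i}", chromosome="c",
                                        position=float(10 + i), anchored=True))
        tracks = build_density(index, make_tagged(index, {"g0"}))
        assert tracks[0].all_counts[0] == 4
        assert tracks[0].relative[0] == 0.25

    def test_empty_tagged_set(self, toy_index):
        tracks = build_density(toy_index, make_tagged(toy_index, set()))
        for t in tracks:
            assert t.tagged_counts.sum() == 0
            assert np.all(t.relative == 0)

    def test_saturation(self, toy_index):
        all_ids = set(toy_index.genes)
        tracks = build_density(toy_index, make_tagged(toy_index, all_ids))
        for t in tracks:
            assert np.all(t.relative[~t.empty] == 1.0)

    def test_conservation(self, toy_index):
        tracks = build_density(toy_index, make_tagged(toy_index, set()))
        per_chrom = {t.grid.chromosome: int(t.all_counts.sum()) for t in tracks}
        for chrom, count in per_chrom.items():
            expected = sum(1 for g in toy_index.anchored_genes()
                           if g.chromosome == chrom)
            assert count == expected

    def test_unanchored_excluded_but_counted(self, toy_index):
        tagged = make_tagged(toy_index, {"g1", "g5"})
        tracks = build_density(toy_index, tagged)
        assert sum(int(t.tagged_counts.sum()) for t in tracks) == 1
        assert unanchored_tagged_count(toy_index, tagged) == 1

    def test_empty_bins_flagged_not_nan(self, toy_index):
        tracks = build_density(toy_index, make_tagged(toy_index, {"g1"}))
        for t in tracks:
            assert not np.any(np.isnan(t.relative))
            assert np.all(t.relative[t.empty] == 0)


def oracle_tail(a, b, c, d):
    """Independent oracle: enumerate every table with the observed margins and
    sum the point probabilities of those at least as enriched."""
    N, K, n = a + b + c + d, a + b, a + c
    fact = math.factorial
    total = 0.0
    tail = 0.0
    for k in range(0, min(K, n) + 1):
        if n - k > N - K:
            continue
        p = (fact(K) / (fact(k) * fact(K - k))) * \
            (fact(N - K) / (fact(n - k) * fact(N - K - n + k))) / \
            (fact(N) / (fact(n) * fact(N - n)))
        total += p
        if k >= a:
            tail += p
    return tail / total


class TestFisher:
    def test_zero_tagged_on_unit_is_one(self):
        for t, u, v in [(1, 2, 3), (5, 0, 5), (0, 7, 1)]:
            assert fisher_one_sided(0, t, u, v) == 1.0

    def test_five_zero_zero_five(self):
        assert fisher_one_sided(5, 0, 0, 5) == pytest.approx(1 / math.comb(10, 5),
                                                             rel=1e-14)

    def test_three_one_one_three(self):
        # N=8, K=4, n=4: P(X>=3) = (16 + 1) / 70
        assert fisher_one_sided(3, 1, 1, 3) == pytest.approx(17 / 70, rel=1e-14)

    def test_all_zero_errors(self):
        with pytest.raises(ValidationError):
            fisher_one_sided(0, 0, 0, 0)

    def test_negative_count_errors(self):
        with pytest.raises(ValidationError):
            fisher_one_sided(-1, 1, 1, 1)

    @pytest.mark.parametrize("table", [
        (3, 1, 1, 3), (5, 0, 0, 5), (2, 8, 4, 16), (1, 1, 1, 1),
        (0, 3, 9, 2), (7, 3, 2, 8), (4, 0, 6, 10),
    ])
    def test_matches_enumeration_oracle(self, table):
        assert fisher_one_sided(*table) == pytest.approx(oracle_tail(*table),
                                                         rel=1e-12)

    def test_matches_scipy_sf(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, size=4)
            if a + b + c + d == 0:
                continue
            N, K, n = a + b + c + d, a + b, a + c
            expected = hypergeom.sf(a - 1, N, K, n)
            assert fisher_one_sided(a, b, c, d) == pytest.approx(expected,
                                                                 rel=1e-9)

    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15),
           st.integers(1, 15))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_tagged_on(self, a, b, c, d):
        # moving one tagged gene onto the unit (from off-unit, margins on the
        # unit fixed) never increases p
        if b == 0 or c == 0:
            return
        p_before = fisher_one_sided(a, b, c, d)
        p_after = fisher_one_sided(a + 1, b - 1, c - 1, d + 1)
        assert p_after <= p_before + 1e-15


class TestEnrich:
    def test_units_chromosome_vs_arm(self, toy_index):
        assert enrichment_units(toy_index, "chromosome") == ["3B", "5B"]
        assert enrichment_units(toy_index, "arm") == ["3BS", "3BL", "5B"]

    def test_counts_sum_to_anchored(self, toy_index):
        table = enrich(toy_index, make_tagged(toy_index, {"g1", "g5"}), "arm")
        for row in table:
            assert (row.tagged_on + row.tagged_off + row.untagged_on +
                    row.untagged_off) == toy_index.n_anchored

    def test_all_tagged_no_contrast(self, toy_index):
        table = enrich(toy_index, make_tagged(toy_index, set(toy_index.genes)))
        for row in table:
            assert row.p_raw == 1.0

    def test_bonferroni_cap(self):
        from chromobin.genome_model import AnchoredGene, ChromosomeDef, GenomeIndex
        index = GenomeIndex(genome_id="g", unit="bp", bin_width=10)
        index.chromosomes["c1"] = ChromosomeDef("c1", length=100)
        index.chromosomes["c2"] = ChromosomeDef("c2", length=100)
        for i in range(6):
            index.add_gene(AnchoredGene(
                gene_id=f"g{i}", chromosome="c1" if i < 3 else "c2",
                position=float(i), anchored=True))
        table = enrich(index, make_tagged(index, {"g0", "g3"}))
        assert table.n_units_tested == 2
        for row in table:
            assert row.p_adj == min(1.0, row.p_raw * 2)
            assert row.p_raw <= row.p_adj <= 1.0

    def test_planted_arm_ranks_first(self):
        from chromobin.fixtures import FixtureSpec, make_genome, plant_tagged
        spec = FixtureSpec(seed=11, n_genes=500, make_sequences=False,
                           planted_enriched_unit=("chr1S", 20))
        index = make_genome(spec)
        tagged = plant_tagged(index, spec)
        table = enrich(index, tagged, unit="arm")
        assert table.rows[0].unit == "chr1S"
        assert table.rows[0].p_adj < 0.05
        # oracle: direct hypergeometric computation for the planted unit
        r = table.rows[0]
        N = r.tagged_on + r.tagged_off + r.untagged_on + r.untagged_off
        expected = hypergeom.sf(r.tagged_on - 1, N, r.tagged_on + r.tagged_off,
                                r.tagged_on + r.untagged_on)
        assert r.p_raw == pytest.approx(expected, rel=1e-9)

    def test_empty_tagged_errors(self, toy_index):
        with pytest.raises(ValidationError):
            enrich(toy_index, make_tagged(toy_index, set()))

    def test_rows_sorted_by_p_adj(self, toy_index):
        table = enrich(toy_index, make_tagged(toy_index, {"g1"}), "arm")
        p_adjs = [r.p_adj for r in table]
        assert p_adjs == sorted(p_adjs)
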