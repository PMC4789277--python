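"""The synthetic-study generator: determinism, structure, distributions."""
import numpy as np
import pytest

from mbdscan.annotation import promoter_interval
from mbdscan.intervals import GenomicInterval
from mbdscan.synth import (
    GenerationError,
    TruthConfig,
    make_annotations,
    make_design,
    make_genome,
    plant_truth,
    simulate_counts,
    simulate_expression,
    simulate_study,
)


class TestMakeGenome:
    def test_single_chromosome(self):
        g = make_genome(1, 1000)
        assert g.chromosomes == (("chr1", 1000),)

    def test_total_length(self):
        assert make_genome(2, 5_000_000, seed=1).total_length == 10_000_000

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            make_genome(0, 1000)
        with pytest.raises(ValueError):
            make_genome(1, 0)


class TestMakeAnnotations:
    def test_no_genes_gives_empty_set(self):
        genome = make_genome(1, 100_000)
        genes, islands = make_annotations(genome, 0, 5, seed=3)
        assert genes == []

    def test_genes_are_valid_and_non_overlapping(self):
        genome = make_genome(2, 5_000_000)
        genes, _ = make_annotations(genome, 50, 0, seed=4)
        assert len(genes) == 50
        by_chrom: dict = {}
        for g in genes:  # GeneModel construction already validates exon structure
            by_chrom.setdefault(g.chrom, []).append((g.tx_start, g.tx_end))
        for spans in by_chrom.values():
            spans.sort()
            for a, b in zip(spans, spans[1:]):
                assert a[1] <= b[0]

    def test_reproducible_given_seed(self):
        genome = make_genome(1, 2_000_000)
        a = make_annotations(genome, 20, 10, seed=9)
        b = make_annotations(genome, 20, 10, seed=9)
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_all_islands_in_promoters_when_fraction_is_one(self):
        genome = make_genome(1, 3_000_000)
        genes, islands = make_annotations(
            genome, 30, 15, seed=5, fraction_islands_in_promoters=1.0
        )
        promoters = [promoter_interval(g, chrom_length=3_000_000) for g in genes]
        for isl in islands:
            assert any(isl.overlaps(p) for p in promoters)


class TestPlantTruth:
    GENOME = make_genome(2, 2_000_000)

    def _truth(self, cfg, seed=7):
        genes, _ = make_annotations(self.GENOME, 40, 0, seed=seed)
        return plant_truth(self.GENOME, genes, make_design(3), cfg, seed)

    def test_zero_regions(self):
        truth = self._truth(TruthConfig(0, 0, 0, 0))
        assert truth.regions == []

    def test_requested_kind_counts(self):
        truth = self._truth(TruthConfig(n_sharp01=30, n_sharp10=25, n_shared=10))
        assert len(truth.regions_of_kind("sharp01")) == 30
        assert len(truth.regions_of_kind("sharp10")) == 25
        assert len(truth.regions_of_kind("shared_methylated")) == 10

    def test_regions_never_overlap(self):
        truth = self._truth(TruthConfig(n_sharp01=60, n_sharp10=60, n_shared=30))
        ivs = sorted(
            (r.interval for r in truth.regions), key=lambda i: (i.chrom, i.start)
        )
        for a, b in zip(ivs, ivs[1:]):
            assert not a.overlaps(b)

    def test_inverse_genes_pair_promoter_dmr_with_opposite_expression(self):
        genes, _ = make_annotations(self.GENOME, 40, 0, seed=7)
        truth = plant_truth(
            self.GENOME, genes, make_design(3),
            TruthConfig(n_sharp01=20, n_sharp10=20, n_inverse_genes=10), 7,
        )
        assert len(truth.inverse_genes) == 10
        by_gene = {g.gene_id: g for g in genes}
        for gid in truth.inverse_genes:
            prom = promoter_interval(by_gene[gid], chrom_length=2_000_000)
            sharp = [
                r
                for r in truth.regions_of_kind("sharp01", "sharp10")
                if r.interval.overlaps(prom)
            ]
            assert len(sharp) == 1  # exactly one planted promoter sharp region
            fold, padj = truth.de_genes[gid]
            assert padj < 0.05
            if sharp[0].kind == "sharp01":
                assert fold < 1  # hypermethylated promoter, expression down
            else:
                assert fold > 1

    def test_infeasible_placement_raises(self):
        tiny = make_genome(1, 2_000)
        with pytest.raises(GenerationError):
            plant_truth(tiny, [], make_design(2), TruthConfig(n_sharp01=500), 1)

    def test_size_factors_positive_and_in_range(self):
        truth = self._truth(TruthConfig(n_sharp01=5, n_sharp10=5))
        assert all(0.7 <= v <= 1.4 for v in truth.size_factors.values())


class TestSimulateCounts:
    def test_all_zero_rates_give_all_zero_counts(self):
        genome = make_genome(1, 100_000)
        truth = plant_truth(
            genome, [], make_design(2), TruthConfig(0, 0, 0, 0), 1
        )
        m = simulate_counts(genome, truth, make_design(2), seed=1, background_rate=0.0)
        assert m.counts.sum() == 0

    def test_background_mean_within_three_se(self):
        genome = make_genome(1, 5_000_000)  # 100k windows
        design = make_design(2)
        truth = plant_truth(genome, [], design, TruthConfig(0, 0, 0, 0), 2)
        m = simulate_counts(genome, truth, design, seed=2, background_rate=0.3)
        for j, s in enumerate(m.samples):
            mu = 0.3 * truth.size_factors[s]
            se = np.sqrt(mu / m.grid.n_windows)
            assert abs(m.counts[:, j].mean() - mu) < 3 * se

    def test_group_a_sees_background_at_sharp01_regions(self):
        genome = make_genome(1, 2_000_000)
        design = make_design(3)
        truth = plant_truth(
            genome, [], design,
            TruthConfig(n_sharp01=100, n_sharp10=0, n_shared=0, region_windows=8), 3,
        )
        m = simulate_counts(genome, truth, design, seed=3)
        starts = m.grid.windows["start"].to_numpy()
        in_region = np.zeros(m.grid.n_windows, dtype=bool)
        for r in truth.regions:
            in_region |= (starts >= r.interval.start) & (starts < r.interval.end)
        a_cols = [j for j, s in enumerate(m.samples) if design[s] == "A"]
        region_mean = m.counts[np.ix_(in_region, a_cols)].mean()
        assert region_mean < 1.0  # background, nowhere near the methylated rate

    def test_determinism(self):
        genome = make_genome(1, 500_000)
        design = make_design(2)
        truth = plant_truth(genome, [], design, TruthConfig(10, 10), 5)
        a = simulate_counts(genome, truth, design, seed=9)
        b = simulate_counts(genome, truth, design, seed=9)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_single_sample_group_rejected(self):
        genome = make_genome(1, 100_000)
        truth = plant_truth(genome, [], {"A1": "A", "B1": "B", "B2": "B"},
                            TruthConfig(0, 0), 1)
        with pytest.raises(ValueError, match=">= 2 samples"):
            simulate_counts(genome, truth, {"A1": "A", "B1": "B", "B2": "B"})


class TestSimulateExpression:
    def _setup(self, n_inverse=5):
        genome = make_genome(1, 3_000_000)
        genes, _ = make_annotations(genome, 30, 0, seed=11)
        truth = plant_truth(
            genome, genes, make_design(3),
            TruthConfig(n_sharp01=10, n_sharp10=10, n_inverse_genes=n_inverse), 11,
        )
        return genes, truth

    def test_no_planted_de_genes_none_significant(self):
        genes, truth = self._setup(n_inverse=0)
        table = simulate_expression(genes, truth, seed=1)
        assert (table["padj"] >= 0.05).all()

    def test_planted_fold_changes_carried_exactly(self):
        genes, truth = self._setup()
        gid = truth.inverse_genes[0]
        truth.de_genes[gid] = (0.19, 0.0)  # a hypermethylated, downregulated gene
        table = simulate_expression(genes, truth, seed=1).set_index("gene")
        assert table.loc[gid, "fold_change"] == 0.19
        assert table.loc[gid, "padj"] < 0.05

    def test_unknown_gene_id_rejected(self):
        genes, truth = self._setup()
        truth.de_genes["nonexistent"] = (2.0, 0.01)
        with pytest.raises(ValueError, match="unknown gene"):
            simulate_expression(genes, truth, seed=1)


class TestSimulateStudy:
    def test_bit_identical_under_same_seed(self):
        a = simulate_study(3, n_chroms=1, chrom_length=300_000, n_genes=10,
                           n_islands=5, config=TruthConfig(5, 5))
        b = simulate_study(3, n_chroms=1, chrom_length=300_000, n_genes=10,
                           n_islands=5, config=TruthConfig(5, 5))
        np.testing.assert_array_equal(a.matrix.counts, b.matrix.counts)
        assert a.truth.size_factors == b.truth.size_factors
        assert a.expression.equals(b.expression)

    def test_different_seed_changes_counts(self):
        a = simulate_study(3, n_chroms=1, chrom_length=300_000, n_genes=10,
                           n_islands=5, config=TruthConfig(5, 5))
        b = simulate_study(4, n_chroms=1, chrom_length=300_000, n_genes=10,
                           n_islands=5, config=TruthConfig(5, 5))
        assert (a.matrix.counts != b.matrix.counts).any()
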