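"""Gene-feature and CpG-island context annotation."""
import numpy as np
import pandas as pd
import pytest

from mbdscan.annotation import (
    GeneModel,
    annotate_dmrs,
    build_feature_index,
    classify_cgi_context,
    classify_feature,
    context_proportions,
    promoter_interval,
    three_prime_interval,
)
from mbdscan.intervals import GenomicInterval, merge_intervals

PRIORITY = {"promoter": 0, "three_prime": 1, "exon": 2, "intron": 3, "intergenic": 4}


def per_base_oracle(region, genes, chrom_len):
    """Label every base by every feature it falls in; take the top priority
    label overlapped by the region."""
    labels = [[] for _ in range(chrom_len)]

    def paint(start, end, label):
        for b in range(max(0, start), min(end, chrom_len)):
            labels[b].append(label)

    for g in genes:
        if g.chrom != region.chrom:
            continue
        p = promoter_interval(g, chrom_length=chrom_len)
        t = three_prime_interval(g, chrom_length=chrom_len)
        paint(p.start, p.end, "promoter")
        paint(t.start, t.end, "three_prime")
        for s, e in g.exons:
            paint(s, e, "exon")
        for s, e in g.introns():
            paint(s, e, "intron")
    hit = [
        lab
        for b in range(region.start, min(region.end, chrom_len))
        for lab in labels[b]
    ]
    if not hit:
        return "intergenic"
    return min(hit, key=PRIORITY.get)


def cgi_oracle(region, islands):
    if not islands:
        return "open_sea", float("inf")
    best = float("inf")
    for isl in islands:
        if isl.chrom != region.chrom:
            continue
        if region.start < isl.end and isl.start < region.end:
            return "island", 0.0
        best = min(best, max(region.start, isl.start) - min(region.end, isl.end))
    if best == float("inf"):
        return "open_sea", best
    if best == 0:  # edge-to-edge touching: zero distance labels as island
        return "island", 0.0
    if best <= 2000:
        return "shore", best
    if best <= 4000:
        return "shelf", best
    return "open_sea", best


def random_gene(rng, chrom, chrom_len, gid):
    length = int(rng.integers(2000, 8000))
    start = int(rng.integers(0, chrom_len - length))
    strand = "+" if rng.random() < 0.5 else "-"
    n_ex = int(rng.integers(1, 4))
    bounds = np.linspace(start, start + length, n_ex + 1).astype(int)
    exons = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        w = int(rng.integers(100, max(101, (hi - lo) // 2)))
        exons.append((int(lo), int(lo) + min(w, hi - lo)))
    exons[-1] = (exons[-1][0], start + length)
    return GeneModel(gid, gid, chrom, strand, start, start + length, tuple(exons))


class TestPromoterWindows:
    def test_plus_strand_promoter(self):
        g = GeneModel("g", "g", "chr1", "+", 10_000, 20_000, ((10_000, 20_000),))
        iv = promoter_interval(g)
        assert (iv.start, iv.end) == (9_000, 10_500)

    def test_minus_strand_promoter_mirrors(self):
        g = GeneModel("g", "g", "chr1", "-", 8_000, 20_000, ((8_000, 20_000),))
        iv = promoter_interval(g)
        assert (iv.start, iv.end) == (19_500, 21_000)

    def test_clipped_at_chromosome_start(self):
        g = GeneModel("g", "g", "chr1", "+", 300, 5_000, ((300, 5_000),))
        iv = promoter_interval(g)
        assert (iv.start, iv.end) == (0, 800)

    def test_promoter_contains_tss_after_clipping(self):
        g = GeneModel("g", "g", "chr1", "-", 100, 900, ((100, 900),))
        iv = promoter_interval(g, chrom_length=1000)
        assert iv.start <= g.tss - 1 < iv.end  # TSS base inside window

    def test_three_prime_plus_strand(self):
        g = GeneModel("g", "g", "chr1", "+", 10_000, 50_000, ((10_000, 50_000),))
        iv = three_prime_interval(g)
        assert (iv.start, iv.end) == (49_000, 51_000)

    def test_three_prime_minus_strand(self):
        g = GeneModel("g", "g", "chr1", "-", 8_000, 20_000, ((8_000, 20_000),))
        iv = three_prime_interval(g)
        assert (iv.start, iv.end) == (7_000, 9_000)

    def test_three_prime_clip(self):
        g = GeneModel("g", "g", "chr1", "-", 500, 2_000, ((500, 2_000),))
        iv = three_prime_interval(g)
        assert (iv.start, iv.end) == (0, 1_500)


class TestClassifyFeature:
    def test_promoter_beats_intron(self):
        ga = GeneModel("a", "a", "chr1", "+", 10_000, 20_000, ((10_000, 20_000),))
        gb = GeneModel(
            "b", "b", "chr1", "+", 5_000, 9_800, ((5_000, 5_200), (9_600, 9_800))
        )
        idx = build_feature_index([ga, gb])
        call = classify_feature(GenomicInterval("chr1", 9_300, 9_500), idx)
        assert call.category == "promoter" and call.gene_ids == ("a",)

    def test_no_overlap_is_intergenic(self):
        g = GeneModel("a", "a", "chr1", "+", 10_000, 20_000, ((10_000, 20_000),))
        idx = build_feature_index([g])
        assert classify_feature(GenomicInterval("chr1", 500, 600), idx).category == (
            "intergenic"
        )

    def test_matches_per_base_oracle_on_random_fixtures(self, rng):
        chrom_len = 60_000
        genes = [random_gene(rng, "chr1", chrom_len, f"g{i}") for i in range(12)]
        idx = build_feature_index(genes, chrom_sizes={"chr1": chrom_len})
        for _ in range(250):
            start = int(rng.integers(0, chrom_len - 400))
            region = GenomicInterval("chr1", start, start + int(rng.integers(50, 400)))
            got = classify_feature(region, idx).category
            assert got == per_base_oracle(region, genes, chrom_len)


class TestCgiContext:
    ISLANDS = [GenomicInterval("chr1", 10_000, 10_600)]

    @pytest.mark.parametrize(
        "start,end,expected,dist",
        [
            (10_200, 10_300, "island", 0),
            (8_400, 8_500, "shore", 1500),  # 1.5 kb from the island edge
            (12_600, 12_650, "shore", 2000),  # exactly 2 kb still shore
            (12_700, 12_800, "shelf", 2100),
            (15_100, 15_200, "open_sea", 4500),
        ],
    )
    def test_distance_bands(self, start, end, expected, dist):
        call = classify_cgi_context(GenomicInterval("chr1", start, end), self.ISLANDS)
        assert (call.context, call.distance) == (expected, dist)

    def test_empty_island_set_is_open_sea(self):
        call = classify_cgi_context(GenomicInterval("chr1", 0, 100), [])
        assert call.context == "open_sea" and call.distance == float("inf")

    def test_matches_brute_force_on_random_fixtures(self, rng):
        islands = merge_intervals(
            [
                GenomicInterval(
                    "chr1", s := int(rng.integers(0, 90_000)), s + int(rng.integers(200, 1000))
                )
                for _ in range(15)
            ]
        )
        for _ in range(300):
            start = int(rng.integers(0, 99_000))
            region = GenomicInterval("chr1", start, start + int(rng.integers(50, 500)))
            call = classify_cgi_context(region, islands)
            exp_ctx, exp_d = cgi_oracle(region, islands)
            assert (call.context, call.distance) == (exp_ctx, exp_d)


class TestAnnotateAndSummarize:
    def test_each_dmr_gets_one_category_and_context(self, rng):
        genes = [random_gene(rng, "chr1", 50_000, f"g{i}") for i in range(5)]
        islands = [GenomicInterval("chr1", 20_000, 20_500)]
        dmrs = pd.DataFrame(
            {
                "chrom": ["chr1"] * 10,
                "start": rng.integers(0, 49_000, 10),
                "direction": ["01"] * 5 + ["10"] * 5,
            }
        )
        dmrs["end"] = dmrs["start"] + 200
        out = annotate_dmrs(dmrs, genes, islands)
        assert out["category"].notna().all() and out["cgi_context"].notna().all()
        assert len(out) == 10

    def test_proportions_sum_to_100_per_direction(self):
        annotated = pd.DataFrame(
            {
                "direction": ["01", "01", "01", "01", "10", "10"],
                "category": ["promoter", "promoter", "intron", "intergenic",
                             "exon", "intron"],
            }
        )
        props = context_proportions(annotated)
        for _, sub in props.groupby("direction"):
            assert sub["percent"].sum() == pytest.approx(100.0, abs=0.1)
        p01 = props[props["direction"] == "01"].set_index("category")["percent"]
        assert p01["promoter"] == pytest.approx(50.0)
        assert p01["intron"] == pytest.approx(25.0)

    def test_single_dmr_is_100_percent(self):
        props = context_proportions(
            pd.DataFrame({"direction": ["01"], "category": ["exon"]})
        )
        assert props["percent"].tolist() == [100.0]

    def test_empty_input_gives_empty_summary(self):
        assert context_proportions(pd.DataFrame(columns=["direction", "category"])).empty
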