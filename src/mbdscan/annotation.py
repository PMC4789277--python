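"""Genomic-context annotation of DMRs.

Each region gets exactly one gene-model category, chosen by the priority
promoter > 3' end > exon > intron > intergenic over everything it overlaps,
and one CpG-island context (island / shore / shelf / open sea) from its
edge-to-edge distance to the nearest island.

Defaults: promoters span 1000 bp upstream to 500 bp downstream of the TSS,
3' ends +/-1000 bp around the transcription termination site, shores reach
2 kb from an island, shelves 2-4 kb, open sea beyond 4 kb.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, merge_intervals

FEATURE_PRIORITY = ["promoter", "three_prime", "exon", "intron", "intergenic"]
_PRIORITY_RANK = {c: i for i, c in enumerate(FEATURE_PRIORITY)}


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: span, strand and exon structure (BED12-style).

    Exons are half-open intervals inside ``[tx_start, tx_end)``, sorted and
    non-overlapping. Introns are the complement of the exons within the span.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"gene {self.gene_id}: invalid transcript span")
        prev_end = self.tx_start
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: needs >= 1 exon")
        for s, e in self.exons:
            if s < prev_end or e <= s or e > self.tx_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be sorted, non-overlapping "
                    "and inside the transcript span"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tts(self) -> int:
        """Transcription termination site (strand-aware)."""
        return self.tx_end if self.strand == "+" else self.tx_start

    def introns(self) -> list[tuple[int, int]]:
        out = []
        prev = self.tx_start
        for s, e in self.exons:
            if s > prev:
                out.append((prev, s))
            prev = e
        if self.tx_end > prev:
            out.append((prev, self.tx_end))
        return out


@dataclass(frozen=True)
class FeatureCall:
    dmr_id: str
    category: str
    gene_ids: tuple[str, ...]


@dataclass(frozen=True)
class CGIContextCall:
    dmr_id: str
    context: str
    distance: float  # bp to nearest island; 0 if overlapping, inf if none


def promoter_interval(
    gene: GeneModel,
    upstream: int = 1000,
    downstream: int = 500,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped to the chromosome.

    With defaults, a + strand TSS at 10,000 gives [9000, 10500).
    """
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def three_prime_interval(
    gene: GeneModel, flank: int = 1000, chrom_length: int | None = None
) -> GenomicInterval:
    """Symmetric window of +/-flank bp around the TTS, clipped."""
    start = max(0, gene.tts - flank)
    end = gene.tts + flank
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(gene.chrom, start, end, gene.strand)


class _FeatureIndex:
    """Interval trees of gene features, one per (chrom, category)."""

    def __init__(
        self,
        genes: list[GeneModel],
        promoter_upstream: int = 1000,
        promoter_downstream: int = 500,
        three_prime_flank: int = 1000,
        chrom_sizes: dict[str, int] | None = None,
    ) -> None:
        self.trees: dict[tuple[str, str], IntervalTree] = {}
        for g in genes:
            clen = chrom_sizes.get(g.chrom) if chrom_sizes else None
            prom = promoter_interval(g, promoter_upstream, promoter_downstream, clen)
            tp = three_prime_interval(g, three_prime_flank, clen)
            self._add(g.chrom, "promoter", prom.start, prom.end, g.gene_id)
            self._add(g.chrom, "three_prime", tp.start, tp.end, g.gene_id)
            for s, e in g.exons:
                self._add(g.chrom, "exon", s, e, g.gene_id)
            for s, e in g.introns():
                self._add(g.chrom, "intron", s, e, g.gene_id)

    def _add(self, chrom: str, cat: str, start: int, end: int, gid: str) -> None:
        if end <= start:
            return
        self.trees.setdefault((chrom, cat), IntervalTree()).addi(start, end, gid)

    def overlapping(self, region: GenomicInterval, cat: str) -> set[str]:
        tree = self.trees.get((region.chrom, cat))
        if tree is None:
            return set()
        return {hit.data for hit in tree.overlap(region.start, region.end)}


def classify_feature(
    region: GenomicInterval,
    index: "_FeatureIndex",
    dmr_id: str = "",
) -> FeatureCall:
    """Single highest-priority gene-feature category overlapped by a region.

    All overlapping genes contribute to the pooled overlap set; the call
    reports the genes supporting the winning category.
    """
    for cat in FEATURE_PRIORITY[:-1]:
        gids = index.overlapping(region, cat)
        if gids:
            return FeatureCall(dmr_id, cat, tuple(sorted(gids)))
    return FeatureCall(dmr_id, "intergenic", ())


def build_feature_index(
    genes: list[GeneModel],
    promoter_upstream: int = 1000,
    promoter_downstream: int = 500,
    three_prime_flank: int = 1000,
    chrom_sizes: dict[str, int] | None = None,
) -> _FeatureIndex:
    return _FeatureIndex(
        genes, promoter_upstream, promoter_downstream, three_prime_flank, chrom_sizes
    )


def classify_cgi_context(
    region: GenomicInterval,
    islands: list[GenomicInterval],
    dmr_id: str = "",
    shore_bp: int = 2000,
    shelf_bp: int = 2000,
) -> CGIContextCall:
    """CpG-island context from edge distance to the nearest (merged) island.

    Bands are half-open: shore (0, shore_bp], shelf (shore_bp, shore_bp +
    shelf_bp], open sea beyond. An empty island set gives open_sea at
    infinite distance.
    """
    if not islands:
        return CGIContextCall(dmr_id, "open_sea", float("inf"))
    d = min(region.distance(isl) for isl in islands)
    if d == 0:
        context = "island"
    elif d <= shore_bp:
        context = "shore"
    elif d <= shore_bp + shelf_bp:
        context = "shelf"
    else:
        context = "open_sea"
    return CGIContextCall(dmr_id, context, d)


def annotate_dmrs(
    dmrs: pd.DataFrame,
    genes: list[GeneModel],
    islands: list[GenomicInterval],
    promoter_upstream: int = 1000,
    promoter_downstream: int = 500,
    three_prime_flank: int = 1000,
    shore_bp: int = 2000,
    shelf_bp: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Add feature category, CGI context and gene ids to a DMR table.

    ``dmrs`` needs columns chrom/start/end; a ``dmr_id`` column is created
    if absent. Islands are merged before distance computation.
    """
    dmrs = dmrs.copy()
    if "dmr_id" not in dmrs.columns:
        dmrs["dmr_id"] = [f"dmr_{i}" for i in range(len(dmrs))]
    index = build_feature_index(
        genes, promoter_upstream, promoter_downstream, three_prime_flank, chrom_sizes
    )
    merged = merge_intervals(islands)
    cats, gids, ctxs, dists = [], [], [], []
    for row in dmrs.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        fc = classify_feature(iv, index, row.dmr_id)
        cc = classify_cgi_context(iv, merged, row.dmr_id, shore_bp, shelf_bp)
        cats.append(fc.category)
        gids.append(",".join(fc.gene_ids))
        ctxs.append(cc.context)
        dists.append(cc.distance)
    dmrs["category"] = cats
    dmrs["gene_ids"] = gids
    dmrs["cgi_context"] = ctxs
    dmrs["island_distance"] = dists
    return dmrs


def context_proportions(
    annotated: pd.DataFrame, column: str = "category"
) -> pd.DataFrame:
    """Percentage of DMRs per category, separately for hyper (01) and hypo (10).

    Returns a tidy frame (direction, category, count, percent); percentages
    within each direction sum to 100.
    """
    if annotated.empty:
        return pd.DataFrame(columns=["direction", column, "count", "percent"])
    rows = []
    for direction, sub in annotated.groupby("direction"):
        counts = sub[column].value_counts()
        total = counts.sum()
        for cat, n in counts.items():
            rows.append(
                {
                    "direction": direction,
                    column: cat,
                    "count": int(n),
                    "percent": 100.0 * n / total,
                }
            )
    return pd.DataFrame(rows).sort_values(["direction", column]).reset_index(drop=True)
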