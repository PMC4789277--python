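"""Synthetic MBD-seq studies with planted ground truth.

Generates toy genomes, non-overlapping gene models and CpG islands, a truth
table of planted methylation regions, per-sample window counts drawn from
the generative model the deconvolution assumes (independent Poisson counts
at a region rate scaled by a per-sample size factor), and a differential-
expression table whose planted "inverse" genes pair a promoter sharp region
with an opposite-direction expression change.

Region kinds mirror what the pipeline must distinguish:

* ``sharp01`` — background rate in group A, methylated rate in group B
  (hypermethylated in the fibrotic group);
* ``sharp10`` — the converse;
* ``quantitative`` — methylated in both groups at different rates;
* ``shared_methylated`` — methylated identically in both groups (decoys the
  differential test must not call);
* everything else is background.

Defaults (background 0.3, methylated 25, quantitative 25 vs 60 counts per
window; size factors log-uniform in [0.7, 1.4]) separate the mixture
components cleanly at desk scale; all are configurable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel, promoter_interval
from .coverage import WindowCountMatrix, tile_windows
from .intervals import GenomicInterval, ToyGenome

REGION_KINDS = ("sharp01", "sharp10", "quantitative", "shared_methylated")


class GenerationError(RuntimeError):
    """Requested synthetic structure cannot be placed."""


@dataclass(frozen=True)
class TruthRegion:
    interval: GenomicInterval
    kind: str
    rate_a: float
    rate_b: float

    def __post_init__(self) -> None:
        if self.rate_a < 0 or self.rate_b < 0:
            raise ValueError("rates must be >= 0")
        if self.kind not in REGION_KINDS + ("background",):
            raise ValueError(f"unknown region kind {self.kind}")


@dataclass
class TruthTable:
    """Planted truth: regions, per-sample size factors, and the DE plan.

    ``de_genes`` maps gene id -> (planted linear fold change B vs A,
    planted adjusted-p surrogate); ``inverse_genes`` is the subset whose
    promoter carries a sharp region of the opposite direction.
    """

    regions: list[TruthRegion]
    size_factors: dict[str, float]
    de_genes: dict[str, tuple[float, float]]
    inverse_genes: list[str]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.size_factors.values()):
            raise ValueError("size factors must be positive")
        if not set(self.inverse_genes) <= set(self.de_genes):
            raise ValueError("inverse genes must be planted DE genes")
        ivs = sorted(
            (r.interval for r in self.regions),
            key=lambda iv: (iv.chrom, iv.start),
        )
        for a, b in zip(ivs, ivs[1:]):
            if a.overlaps(b):
                raise ValueError("truth regions must not overlap")

    def regions_of_kind(self, *kinds: str) -> list[TruthRegion]:
        return [r for r in self.regions if r.kind in kinds]


@dataclass
class TruthConfig:
    """Knobs of the planted study; defaults are the package's study conditions."""

    n_sharp01: int = 100
    n_sharp10: int = 100
    n_quantitative: int = 0
    n_shared: int = 50
    n_inverse_genes: int = 0
    n_concordant_genes: int = 0
    n_de_only_genes: int = 0
    region_windows: int = 5  # width of each planted region, in windows
    window: int = 50  # bp
    background_rate: float = 0.3
    methylated_rate: float = 25.0
    quant_rate_a: float = 25.0
    quant_rate_b: float = 60.0
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    max_retries: int = 2000


def make_genome(n_chroms: int, chrom_length: int, seed: int = 0) -> ToyGenome:
    """A toy genome of equal-length chromosomes named chr1..chrN."""
    if n_chroms < 1 or chrom_length < 1:
        raise ValueError("n_chroms and chrom_length must be positive")
    return ToyGenome(
        tuple((f"chr{i + 1}", chrom_length) for i in range(n_chroms))
    )


def make_annotations(
    genome: ToyGenome,
    n_genes: int,
    n_islands: int,
    seed: int,
    gene_length: tuple[int, int] = (5_000, 30_000),
    n_exons: tuple[int, int] = (2, 8),
    island_length: tuple[int, int] = (300, 1_500),
    fraction_islands_in_promoters: float = 0.3,
) -> tuple[list[GeneModel], list[GenomicInterval]]:
    """Place non-overlapping genes (BED12-valid) and CpG islands.

    A configurable fraction of islands is dropped inside gene promoters
    (1 kb upstream / 500 bp downstream of the TSS); the rest land anywhere
    islands do not already sit.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}
    for i in range(n_genes):
        length = int(rng.integers(gene_length[0], gene_length[1] + 1))
        chrom, start = _place(genome, occupied, length, rng, pad=2000)
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _random_exons(start, start + length, int(rng.integers(*n_exons)), rng)
        genes.append(
            GeneModel(f"g{i}", f"GENE{i}", chrom, strand, start, start + length, exons)
        )
        occupied[chrom].append((start, start + length))
    islands: list[GenomicInterval] = []
    isl_occ: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}
    promoters = [promoter_interval(g, chrom_length=genome.sizes[g.chrom]) for g in genes]
    # without genes there are no promoters to target; all islands go anywhere
    n_in_prom = (
        int(round(fraction_islands_in_promoters * n_islands)) if promoters else 0
    )
    for i in range(n_islands):
        length = int(rng.integers(island_length[0], island_length[1] + 1))
        if i < n_in_prom:
            for _ in range(200):
                prom = promoters[int(rng.integers(len(promoters)))]
                w = min(length, len(prom))
                offset = int(rng.integers(0, len(prom) - w + 1))
                chrom, start, length = prom.chrom, prom.start + offset, w
                if not any(
                    start < e and s < start + length for s, e in isl_occ[chrom]
                ):
                    break
            else:
                raise GenerationError("could not place an island in a promoter")
        else:
            chrom, start = _place(genome, isl_occ, length, rng, pad=100)
        islands.append(GenomicInterval(chrom, start, start + length))
        isl_occ[chrom].append((start, start + length))
    return genes, islands


def _place(
    genome: ToyGenome,
    occupied: dict[str, list[tuple[int, int]]],
    length: int,
    rng: np.random.Generator,
    pad: int = 0,
    max_retries: int = 2000,
    chrom: str | None = None,
) -> tuple[str, int]:
    """Rejection-sample a free (chrom, start) slot; pad keeps neighbours apart."""
    names = [chrom] if chrom else genome.names
    for _ in range(max_retries):
        c = names[int(rng.integers(len(names)))]
        limit = genome.sizes[c] - length
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        if all(
            start >= e + pad or s >= start + length + pad for s, e in occupied[c]
        ):
            return c, start
    raise GenerationError(
        f"could not place a {length}-bp feature after {max_retries} retries"
    )


def _random_exons(
    start: int, end: int, n: int, rng: np.random.Generator
) -> tuple[tuple[int, int], ...]:
    span = end - start
    n = max(1, min(n, span // 200))
    # carve n exons from n 'slots' of the transcript, leaving intron gaps
    bounds = np.linspace(start, end, n + 1).astype(int)
    exons = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        width = int(rng.integers(100, max(101, (hi - lo) // 2)))
        width = min(width, hi - lo)
        exons.append((int(lo), int(lo) + width))
    exons[0] = (start, exons[0][1])  # first exon starts at the TSS-side boundary
    last = exons[-1]
    exons[-1] = (last[0], end) if last[1] > end - 100 else last
    if exons[-1][1] < end:  # ensure the span ends in an exon (BED12 convention)
        exons.append((max(exons[-1][1] + 1, end - 100), end))
    return tuple(exons)


def plant_truth(
    genome: ToyGenome,
    genes: list[GeneModel],
    design: dict[str, str],
    config: TruthConfig,
    seed: int,
) -> TruthTable:
    """Plant non-overlapping truth regions and the DE plan.

    ``n_inverse_genes`` genes get a sharp region inside their promoter with
    a planted expression fold change in the opposite direction (alternating
    01/down and 10/up); ``n_concordant_genes`` get a same-direction pair;
    these promoter regions count toward the sharp totals. Remaining regions
    land away from all promoters so the planted inverse set stays exact.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    width_bp = cfg.region_windows * cfg.window
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}
    promoters = {
        g.gene_id: promoter_interval(g, chrom_length=genome.sizes[g.chrom])
        for g in genes
    }
    for p in promoters.values():  # block promoters for generic placement
        occupied[p.chrom].append((p.start, p.end))

    regions: list[TruthRegion] = []
    de_genes: dict[str, tuple[float, float]] = {}
    inverse_genes: list[str] = []
    n01_left, n10_left = cfg.n_sharp01, cfg.n_sharp10

    special = cfg.n_inverse_genes + cfg.n_concordant_genes + cfg.n_de_only_genes
    if special > len(genes):
        raise GenerationError("not enough genes for the requested DE plan")
    chosen = list(rng.choice([g.gene_id for g in genes], size=special, replace=False))
    inv_ids = chosen[: cfg.n_inverse_genes]
    conc_ids = chosen[cfg.n_inverse_genes : cfg.n_inverse_genes + cfg.n_concordant_genes]
    de_only_ids = chosen[cfg.n_inverse_genes + cfg.n_concordant_genes :]

    def promoter_region(gene_id: str, kind: str) -> TruthRegion:
        prom = promoters[gene_id]
        # window-aligned slot inside the promoter
        lo = (prom.start // cfg.window + 1) * cfg.window
        hi = prom.end - width_bp
        if hi < lo:
            raise GenerationError(f"promoter of {gene_id} too short for a region")
        start = lo + int(rng.integers(0, (hi - lo) // cfg.window + 1)) * cfg.window
        iv = GenomicInterval(prom.chrom, start, start + width_bp)
        ra, rb = (
            (cfg.background_rate, cfg.methylated_rate)
            if kind == "sharp01"
            else (cfg.methylated_rate, cfg.background_rate)
        )
        return TruthRegion(iv, kind, ra, rb)

    for i, gid in enumerate(inv_ids + conc_ids):
        if n01_left == 0 and n10_left == 0:
            raise GenerationError("sharp region budget smaller than the DE plan")
        kind = "sharp01" if i % 2 == 0 else "sharp10"
        if kind == "sharp01" and n01_left == 0:
            kind = "sharp10"
        if kind == "sharp10" and n10_left == 0:
            kind = "sharp01"
        regions.append(promoter_region(gid, kind))
        if kind == "sharp01":
            n01_left -= 1
        else:
            n10_left -= 1
        inverse = gid in inv_ids
        if (kind == "sharp01") == inverse:
            fold = float(np.exp(rng.uniform(np.log(0.1), np.log(0.5))))  # down
        else:
            fold = float(np.exp(rng.uniform(np.log(2.0), np.log(10.0))))  # up
        de_genes[gid] = (fold, float(rng.uniform(0.0, 0.04)))
        if inverse:
            inverse_genes.append(gid)
    for gid in de_only_ids:
        up = rng.random() < 0.5
        fold = float(
            np.exp(rng.uniform(np.log(2.0), np.log(10.0)))
            if up
            else np.exp(rng.uniform(np.log(0.1), np.log(0.5)))
        )
        de_genes[gid] = (fold, float(rng.uniform(0.0, 0.04)))

    plan = (
        [("sharp01", n01_left), ("sharp10", n10_left)]
        + [("quantitative", cfg.n_quantitative), ("shared_methylated", cfg.n_shared)]
    )
    rates = {
        "sharp01": (cfg.background_rate, cfg.methylated_rate),
        "sharp10": (cfg.methylated_rate, cfg.background_rate),
        "quantitative": (cfg.quant_rate_a, cfg.quant_rate_b),
        "shared_methylated": (cfg.methylated_rate, cfg.methylated_rate),
    }
    for r in regions:  # promoter regions also block space
        occupied[r.interval.chrom].append((r.interval.start, r.interval.end))
    for kind, n in plan:
        for _ in range(n):
            chrom, start = _place(
                genome, occupied, width_bp, rng,
                pad=4 * cfg.window, max_retries=cfg.max_retries,
            )
            start = (start // cfg.window) * cfg.window  # window-aligned
            if start + width_bp > genome.sizes[chrom]:
                start -= cfg.window
            occupied[chrom].append((start, start + width_bp))
            ra, rb = rates[kind]
            regions.append(
                TruthRegion(GenomicInterval(chrom, start, start + width_bp), kind, ra, rb)
            )

    lo, hi = cfg.size_factor_range
    size_factors = {
        s: float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) for s in design
    }
    return TruthTable(regions, size_factors, de_genes, inverse_genes)


def simulate_counts(
    genome: ToyGenome,
    truth: TruthTable,
    design: dict[str, str],
    window: int = 50,
    seed: int = 0,
    background_rate: float = 0.3,
) -> WindowCountMatrix:
    """Draw count(w, s) ~ Poisson(size_factor_s * rate_group(s)(w)).

    Windows under a truth region take that region's group rate; all other
    windows take the background rate.
    """
    groups = set(design.values())
    for g in groups:
        if sum(1 for v in design.values() if v == g) < 2:
            raise ValueError("each group needs >= 2 samples")
    rng = np.random.default_rng(seed)
    grid = tile_windows(genome, window)
    n = grid.n_windows
    rate_a = np.full(n, background_rate)
    rate_b = np.full(n, background_rate)
    offsets = {}
    pos = 0
    for name, length in genome.chromosomes:
        offsets[name] = pos
        pos += -(-length // window)
    starts = grid.windows["start"].to_numpy()
    for r in truth.regions:
        off = offsets[r.interval.chrom]
        w0 = off + r.interval.start // window
        w1 = off + -(-r.interval.end // window)
        rate_a[w0:w1] = r.rate_a
        rate_b[w0:w1] = r.rate_b
    samples = list(design)
    counts = np.empty((n, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        rate = rate_b if design[s] == "B" else rate_a
        counts[:, j] = rng.poisson(truth.size_factors[s] * rate)
    return WindowCountMatrix(grid, samples, dict(design), counts)


def simulate_expression(
    genes: list[GeneModel], truth: TruthTable, seed: int = 0
) -> pd.DataFrame:
    """A DE table (gene, fold_change, padj) honouring the planted plan.

    Planted DE genes carry their planted fold change and an adjusted p
    below 0.05; every other gene gets a fold change near 1 and padj drawn
    from [0.05, 1).
    """
    known = {g.gene_id for g in genes}
    unknown = set(truth.de_genes) - known
    if unknown:
        raise ValueError(f"unknown gene ids in truth DE plan: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for g in genes:
        if g.gene_id in truth.de_genes:
            fold, padj = truth.de_genes[g.gene_id]
        else:
            fold = float(np.exp(rng.normal(0.0, 0.05)))
            padj = float(rng.uniform(0.05, 1.0))
        rows.append(
            {"gene": g.gene_id, "symbol": g.symbol, "fold_change": fold, "padj": padj}
        )
    return pd.DataFrame(rows, columns=["gene", "symbol", "fold_change", "padj"])


def truth_regions_bed(truth: TruthTable) -> pd.DataFrame:
    rows = []
    for r in truth.regions:
        ratio = (r.rate_b + 1e-9) / (r.rate_a + 1e-9)
        rows.append(
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "name": r.kind,
                "score": round(ratio, 3),
                "strand": ".",
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


@dataclass
class SyntheticStudy:
    """A complete simulated study: inputs plus the planted truth."""

    genome: ToyGenome
    genes: list[GeneModel]
    islands: list[GenomicInterval]
    truth: TruthTable
    matrix: WindowCountMatrix
    expression: pd.DataFrame
    design: dict[str, str]


def simulate_study(
    seed: int,
    n_chroms: int = 2,
    chrom_length: int = 5_000_000,
    n_genes: int = 100,
    n_islands: int = 60,
    n_per_group: int = 3,
    config: TruthConfig | None = None,
) -> SyntheticStudy:
    """Generate genome, annotations, truth, counts and DE table in one call.

    Sub-seeds for each generation step are derived deterministically from
    ``seed``, so the whole study reproduces bit-identically.
    """
    cfg = config or TruthConfig()
    sub = [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(4)]
    genome = make_genome(n_chroms, chrom_length, sub[0])
    genes, islands = make_annotations(genome, n_genes, n_islands, sub[0])
    design = make_design(n_per_group)
    truth = plant_truth(genome, genes, design, cfg, sub[1])
    matrix = simulate_counts(
        genome, truth, design, cfg.window, sub[2], cfg.background_rate
    )
    expression = simulate_expression(genes, truth, sub[3])
    return SyntheticStudy(genome, genes, islands, truth, matrix, expression, design)


def make_design(n_per_group: int = 3) -> dict[str, str]:
    """Sample design: A1..An normal (group A), B1..Bn fibrotic (group B)."""
    d = {f"A{i + 1}": "A" for i in range(n_per_group)}
    d.update({f"B{i + 1}": "B" for i in range(n_per_group)})
    return d
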