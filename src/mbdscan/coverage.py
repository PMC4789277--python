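"""From aligned fragments to a filtered window-count matrix.

MBD capture enriches densely methylated fragments, so methylation is read
out as local fragment depth. Reads are extended to the average fragment
length from their 5' end, the genome is tiled in fixed-width non-overlapping
windows (50 bp by default), each window scores the rounded average per-base
coverage, and windows that no sample lifts above an even-coverage Poisson
false-discovery threshold are dropped before model fitting.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, ToyGenome


@dataclass(frozen=True)
class WindowGrid:
    """Fixed-width tiling of a genome; last window per chromosome may be short."""

    genome: ToyGenome
    width: int
    windows: pd.DataFrame  # columns chrom, start, end, in genome order

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.windows["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class WindowCountMatrix:
    """Integer window x sample counts on a grid, with group labels."""

    grid: WindowGrid
    samples: list[str]
    groups: dict[str, str]
    counts: np.ndarray  # shape (n_windows, n_samples), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.grid.n_windows, len(self.samples)):
            raise ValueError("count matrix shape inconsistent with grid x samples")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.windows.copy()
        for j, s in enumerate(self.samples):
            df[s] = self.counts[:, j]
        return df

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, genome: ToyGenome, width: int, groups: dict[str, str]
    ) -> "WindowCountMatrix":
        samples = [c for c in df.columns if c not in ("chrom", "start", "end")]
        grid = WindowGrid(genome, width, df[["chrom", "start", "end"]].copy())
        return cls(grid, samples, groups, df[samples].to_numpy(dtype=np.int64))


@dataclass(frozen=True)
class FilterResult:
    """Outcome of the even-coverage Poisson false-discovery filter."""

    retained: np.ndarray  # sorted indices into the grid
    rates: dict[str, float]  # per-sample genome-wide mean count lambda-hat
    thresholds: dict[str, int]  # per-sample minimal significant count c_s
    alpha: float


def extend_fragments(
    fragments: list[GenomicInterval],
    target_length: int,
    chrom_sizes: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """Resize each fragment to ``target_length``, anchored at its 5' end.

    ``+`` fragments keep their start, ``-`` fragments their end; results are
    clipped to chromosome bounds when sizes are given. Unstranded fragments
    are only legal if already at the target length (direction is ambiguous).
    """
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    out = []
    for f in fragments:
        if f.strand == "+":
            start, end = f.start, f.start + target_length
        elif f.strand == "-":
            start, end = f.end - target_length, f.end
        else:
            if len(f) != target_length:
                raise ValueError(
                    f"unstranded fragment {f.chrom}:{f.start}-{f.end} cannot be "
                    "extended: direction is ambiguous"
                )
            start, end = f.start, f.end
        start = max(0, start)
        if chrom_sizes is not None:
            if f.chrom not in chrom_sizes:
                raise ValueError(f"fragment on unknown chromosome {f.chrom}")
            end = min(end, chrom_sizes[f.chrom])
        out.append(GenomicInterval(f.chrom, start, end, f.strand))
    return out


def tile_windows(genome: ToyGenome, width: int = 50) -> WindowGrid:
    """Non-overlapping ``width``-bp windows covering every chromosome exactly.

    The terminal window of a chromosome is truncated rather than dropped, so
    the tiling covers the entire genome.
    """
    if width < 1:
        raise ValueError("window width must be >= 1")
    chroms, starts, ends = [], [], []
    for name, length in genome.chromosomes:
        s = np.arange(0, length, width, dtype=np.int64)
        e = np.minimum(s + width, length)
        chroms.extend([name] * len(s))
        starts.append(s)
        ends.append(e)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.concatenate(starts) if starts else [],
            "end": np.concatenate(ends) if ends else [],
        }
    )
    return WindowGrid(genome, width, df)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # round half away from zero; counts are non-negative so this is floor(x+0.5)
    return np.floor(x + 0.5).astype(np.int64)


def count_coverage(
    grid: WindowGrid,
    fragments_per_sample: dict[str, list[GenomicInterval]],
    groups: dict[str, str] | None = None,
) -> WindowCountMatrix:
    """Rounded average per-base coverage of each window, per sample.

    Depth is accumulated base-by-base via a difference array, averaged over
    the window's actual width (truncated terminal windows use their true
    width) and rounded half away from zero.
    """
    sizes = grid.genome.sizes
    samples = list(fragments_per_sample)
    counts = np.zeros((grid.n_windows, len(samples)), dtype=np.int64)
    widths = (grid.windows["end"] - grid.windows["start"]).to_numpy()
    for j, sample in enumerate(samples):
        per_chrom: dict[str, np.ndarray] = {}
        for f in fragments_per_sample[sample]:
            if f.chrom not in sizes:
                raise ValueError(f"fragment on unknown chromosome {f.chrom}")
            diff = per_chrom.setdefault(f.chrom, np.zeros(sizes[f.chrom] + 1))
            diff[f.start] += 1
            diff[min(f.end, sizes[f.chrom])] -= 1
        for chrom, diff in per_chrom.items():
            depth = np.cumsum(diff[:-1])
            sl = grid.chrom_slice(chrom)
            starts = grid.windows["start"].to_numpy()[sl]
            sums = np.add.reduceat(depth, starts)
            counts[sl, j] = _round_half_up(sums / widths[sl])
    return WindowCountMatrix(grid, samples, groups or {}, counts)


def poisson_filter(matrix: WindowCountMatrix, alpha: float = 0.05) -> FilterResult:
    """Drop windows no sample covers above an even-coverage Poisson threshold.

    Under even coverage each sample's window counts would be Poisson with
    rate lambda-hat = total count / n_windows. A window survives if at least
    one sample's count reaches that sample's minimal count c with upper-tail
    probability <= alpha / n_windows (Bonferroni over windows).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    n = matrix.grid.n_windows
    if n == 0:
        raise ValueError("empty count matrix")
    per_test = alpha / n
    rates, thresholds = {}, {}
    keep = np.zeros(n, dtype=bool)
    for j, s in enumerate(matrix.samples):
        lam = matrix.counts[:, j].sum() / n
        if lam == 0:
            warnings.warn(f"sample {s} has no reads; it cannot retain windows")
            c = 1
        else:
            # smallest c with P(Poisson(lam) >= c) <= alpha/n; sf(c-1) is that tail
            c = 1
            while stats.poisson.sf(c - 1, lam) > per_test:
                c += 1
        rates[s] = float(lam)
        thresholds[s] = int(c)
        keep |= matrix.counts[:, j] >= c
    return FilterResult(np.flatnonzero(keep), rates, thresholds, alpha)


def filter_report(result: FilterResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": list(result.rates),
            "lambda_hat": list(result.rates.values()),
            "threshold": [result.thresholds[s] for s in result.rates],
        }
    )
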