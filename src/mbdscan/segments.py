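"""Scan-based segmentation of binary methylation statuses into regions.

Per sample, maximal runs of methylated windows are merged across short
gaps (a fixed-composition scan over the binary status track) and kept when
they contain enough methylated windows. Segments from all samples are then
unioned into candidate regions — the units the differential test sees — and
each sample gets a methylated/unmethylated status over each candidate by a
window-majority rule.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MethylationSegment:
    """A gap-tolerant run of methylated windows in one sample.

    Window indices are positions in the chromosome-local status vector;
    ``members`` are the methylated ones, ``start``/``end`` the spanned
    window range (half-open).
    """

    sample: str
    start: int  # first window index
    end: int  # one past last window index
    members: tuple[int, ...]  # methylated window indices
    n_gap_windows: int

    @property
    def n_methylated(self) -> int:
        return len(self.members)


def scan_segments(
    status: np.ndarray,
    max_gap: int = 2,
    min_windows: int = 2,
    sample: str = "",
) -> list[MethylationSegment]:
    """Merge methylated runs separated by <= ``max_gap`` unmethylated windows.

    The input is one chromosome's genome-ordered binary status vector for
    one sample. Merged runs with fewer than ``min_windows`` methylated
    members are discarded. Never call this across a chromosome boundary.
    """
    status = np.asarray(status, dtype=bool)
    meth = np.flatnonzero(status)
    if meth.size == 0:
        return []
    segments: list[MethylationSegment] = []
    cur = [int(meth[0])]
    for idx in meth[1:]:
        if idx - cur[-1] - 1 <= max_gap:
            cur.append(int(idx))
        else:
            segments.append(_make_segment(sample, cur))
            cur = [int(idx)]
    segments.append(_make_segment(sample, cur))
    return [s for s in segments if s.n_methylated >= min_windows]


def _make_segment(sample: str, members: list[int]) -> MethylationSegment:
    span = members[-1] - members[0] + 1
    return MethylationSegment(
        sample=sample,
        start=members[0],
        end=members[-1] + 1,
        members=tuple(members),
        n_gap_windows=span - len(members),
    )


@dataclass(frozen=True)
class CandidateRegion:
    """Union of overlapping per-sample segments, with a per-sample status.

    ``start``/``end`` are window indices (chromosome-local, half-open);
    ``status`` maps every sample to True (methylated over the candidate)
    or False.
    """

    chrom: str
    start: int
    end: int
    status: dict[str, bool]

    @property
    def n_windows(self) -> int:
        return self.end - self.start

    def window_indices(self) -> np.ndarray:
        return np.arange(self.start, self.end)


def candidate_regions(
    segments_by_sample: dict[str, list[MethylationSegment]],
    status_matrix: np.ndarray,
    samples: list[str],
    chrom: str = "",
    majority: float = 0.5,
) -> list[CandidateRegion]:
    """Union segments across samples into maximal candidate intervals.

    ``status_matrix`` is the (windows x samples) binary matrix for this
    chromosome; a sample is methylated over a candidate when at least
    ``majority`` of the candidate's windows are methylated in it.
    """
    spans = sorted(
        (seg.start, seg.end)
        for segs in segments_by_sample.values()
        for seg in segs
    )
    if not spans:
        return []
    merged: list[list[int]] = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        frac = status_matrix[s:e].mean(axis=0)
        status = {
            samp: bool(frac[j] >= majority) for j, samp in enumerate(samples)
        }
        out.append(CandidateRegion(chrom, s, e, status))
    return out


def segments_to_bed(
    segments_by_chrom: dict[str, dict[str, list[MethylationSegment]]],
    window_starts: dict[str, np.ndarray],
    window_ends: dict[str, np.ndarray],
) -> pd.DataFrame:
    rows = []
    for chrom, by_sample in segments_by_chrom.items():
        for sample, segs in by_sample.items():
            for seg in segs:
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(window_starts[chrom][seg.start]),
                        "end": int(window_ends[chrom][seg.end - 1]),
                        "name": sample,
                        "score": seg.n_methylated,
                        "strand": ".",
                    }
                )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
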