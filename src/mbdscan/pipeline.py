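"""End-to-end orchestration: count -> filter -> fit -> scan -> test ->
annotate -> integrate, with one config object and a reproducible manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .annotation import GeneModel, annotate_dmrs, context_proportions
from .coverage import (
    FilterResult,
    WindowCountMatrix,
    filter_report,
    poisson_filter,
)
from .integration import integrate, read_expression_table
from .intervals import GenomicInterval
from .mixture import DegenerateFitError, ThreePoissonMixture, fit_report
from .segments import candidate_regions, scan_segments, segments_to_bed
from .testing import count_by_chromosome, heatmap_matrix, test_candidates


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the package defaults.

    Window width 50 bp, FDR 0.05, promoter 1000/500, 3' flank 1000 and CGI
    bands 2000/2000 follow the study design this pipeline implements; the
    remaining knobs (filter alpha, mixture tolerances, scan gap limits,
    majority threshold, pseudocount) are framework parameters with
    conservative defaults.
    """

    window: int = 50
    filter_alpha: float = 0.05
    tau: float = 0.5
    max_iter: int = 500
    tol: float = 1e-8
    weight_floor: float = 1e-6
    rate_floor: float = 1e-6
    max_gap: int = 2
    min_windows: int = 2
    majority: float = 0.5
    fdr: float = 0.05
    pseudocount: float = 0.5
    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    three_prime_flank: int = 1000
    shore_bp: int = 2000
    shelf_bp: int = 2000
    de_alpha: float = 0.05
    group_a: str = "A"
    group_b: str = "B"
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.window >= 1, "window >= 1"),
            (0 < self.filter_alpha < 1, "filter_alpha in (0,1)"),
            (0 < self.tau < 1, "tau in (0,1)"),
            (0 < self.fdr < 1, "fdr in (0,1)"),
            (0 < self.de_alpha < 1, "de_alpha in (0,1)"),
            (self.max_gap >= 0, "max_gap >= 0"),
            (self.min_windows >= 1, "min_windows >= 1"),
            (0 < self.majority <= 1, "majority in (0,1]"),
            (self.pseudocount >= 0, "pseudocount >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: require {msg}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DmrCallResult:
    """Everything the core caller produces, before annotation."""

    filter_result: FilterResult
    fits: dict
    posteriors: pd.DataFrame  # retained windows x samples p_meth
    status: np.ndarray  # full-grid binary status, windows x samples
    segments_bed: pd.DataFrame
    candidates: pd.DataFrame  # all tested candidates with class/reason
    dmrs: pd.DataFrame  # significant, classified rows only
    heatmap: pd.DataFrame
    chrom_summary: pd.DataFrame


def call_dmrs(matrix: WindowCountMatrix, config: PipelineConfig) -> DmrCallResult:
    """Run filter -> mixture fit -> scan -> differential test on a matrix."""
    cfg = config
    filt = poisson_filter(matrix, cfg.filter_alpha)
    retained = filt.retained
    samples = matrix.samples
    n_windows = matrix.grid.n_windows
    status = np.zeros((n_windows, len(samples)), dtype=bool)
    fits = {}
    post = {}
    for j, s in enumerate(samples):
        counts = matrix.counts[retained, j]
        try:
            fit = ThreePoissonMixture(counts, sample=s).fit(
                max_iter=cfg.max_iter,
                tol=cfg.tol,
                weight_floor=cfg.weight_floor,
                rate_floor=cfg.rate_floor,
            )
        except (DegenerateFitError, ValueError) as exc:
            warnings.warn(f"sample {s}: mixture fit degenerate ({exc}); "
                          "all windows called unmethylated")
            post[s] = np.zeros(len(retained))
            continue
        fits[s] = fit
        p = fit.methylation_probability(counts)
        post[s] = p
        status[retained, j] = p >= cfg.tau

    posteriors = matrix.grid.windows.iloc[retained].reset_index(drop=True).copy()
    for s in samples:
        posteriors[s] = post[s]

    # scan per chromosome, union candidates across samples
    cand_tuples = []
    seg_rows: dict[str, dict] = {}
    window_starts = matrix.grid.windows["start"].to_numpy()
    window_ends = matrix.grid.windows["end"].to_numpy()
    chrom_col = matrix.grid.windows["chrom"].to_numpy()
    for chrom, _ in matrix.grid.genome.chromosomes:
        sl = matrix.grid.chrom_slice(chrom)
        if sl.stop == sl.start:
            continue
        sub_status = status[sl]
        segs = {
            s: scan_segments(
                sub_status[:, j], cfg.max_gap, cfg.min_windows, sample=s
            )
            for j, s in enumerate(samples)
        }
        seg_rows[chrom] = segs
        for cand in candidate_regions(segs, sub_status, samples, chrom, cfg.majority):
            g0, g1 = sl.start + cand.start, sl.start + cand.end
            cand_tuples.append(
                (
                    cand,
                    matrix.counts[g0:g1],
                    int(window_starts[g0]),
                    int(window_ends[g1 - 1]),
                )
            )
    segments_bed = segments_to_bed(
        {c: seg_rows[c] for c in seg_rows},
        {c: window_starts[matrix.grid.chrom_slice(c)] for c in seg_rows},
        {c: window_ends[matrix.grid.chrom_slice(c)] for c in seg_rows},
    )
    candidates = test_candidates(
        cand_tuples,
        samples,
        matrix.groups,
        cfg.group_a,
        cfg.group_b,
        fdr=cfg.fdr,
        pseudocount=cfg.pseudocount,
    )
    dmrs = candidates[candidates["dmr_class"].notna()].reset_index(drop=True)
    if not dmrs.empty:
        dmrs = dmrs.copy()
        dmrs.insert(0, "dmr_id", [f"dmr_{i}" for i in range(len(dmrs))])
        # post-hoc direction consistency on raw counts
        _assert_directions(dmrs, matrix, cfg)
    sharp = dmrs[dmrs["dmr_class"] == "sharp"] if not dmrs.empty else dmrs
    heat_counts, heat_ids = [], []
    for row in sharp.itertuples(index=False):
        mask = (
            (chrom_col == row.chrom)
            & (window_starts >= row.start)
            & (window_ends <= row.end)
        )
        heat_counts.append(matrix.counts[mask])
        heat_ids.append(row.dmr_id)
    heat = heatmap_matrix(heat_counts, samples, heat_ids) if heat_counts else (
        pd.DataFrame(columns=samples)
    )
    summary = count_by_chromosome(sharp)
    return DmrCallResult(
        filt, fits, posteriors, status, segments_bed, candidates, dmrs, heat, summary
    )


def _assert_directions(
    dmrs: pd.DataFrame, matrix: WindowCountMatrix, cfg: PipelineConfig
) -> None:
    a_cols = [j for j, s in enumerate(matrix.samples)
              if matrix.groups[s] == cfg.group_a]
    b_cols = [j for j, s in enumerate(matrix.samples)
              if matrix.groups[s] == cfg.group_b]
    starts = matrix.grid.windows["start"].to_numpy()
    ends = matrix.grid.windows["end"].to_numpy()
    chroms = matrix.grid.windows["chrom"].to_numpy()
    for row in dmrs.itertuples(index=False):
        mask = (chroms == row.chrom) & (starts >= row.start) & (ends <= row.end)
        mean_a = matrix.counts[np.ix_(mask, a_cols)].mean()
        mean_b = matrix.counts[np.ix_(mask, b_cols)].mean()
        ok = mean_b > mean_a if row.direction == "01" else mean_b < mean_a
        if not ok:
            raise AssertionError(
                f"direction {row.direction} inconsistent with raw counts at "
                f"{row.chrom}:{row.start}-{row.end}"
            )


def run_pipeline(
    matrix: WindowCountMatrix,
    config: PipelineConfig,
    outdir,
    genes: list[GeneModel] | None = None,
    islands: list[GenomicInterval] | None = None,
    expression: pd.DataFrame | None = None,
) -> dict:
    """Run every stage, write all stage outputs + a manifest, return paths.

    Annotation runs when gene models/islands are given; integration when an
    expression table is also given. Identical config and inputs produce
    byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = call_dmrs(matrix, config)
    files = {}

    def emit(name: str, df: pd.DataFrame, header=True, index=False) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", header=header, index=index)
        files[name] = path

    emit("counts.tsv", matrix.to_frame())
    emit("filter_report.tsv", filter_report(result.filter_result))
    emit("retained_posteriors.tsv", result.posteriors)
    emit("mixture_fits.tsv", fit_report(result.fits))
    emit("segments.bed", result.segments_bed, header=False)
    emit("candidates.tsv", result.candidates)
    emit("dmrs.tsv", result.dmrs)
    emit("heatmap_matrix.tsv", result.heatmap, index=True)
    emit("chromosome_summary.tsv", result.chrom_summary)

    annotated = None
    if genes is not None and islands is not None:
        annotated = annotate_dmrs(
            result.dmrs,
            genes,
            islands,
            promoter_upstream=config.promoter_upstream,
            promoter_downstream=config.promoter_downstream,
            three_prime_flank=config.three_prime_flank,
            shore_bp=config.shore_bp,
            shelf_bp=config.shelf_bp,
            chrom_sizes=matrix.grid.genome.sizes,
        )
        emit("dmrs_annotated.tsv", annotated)
        emit("context_proportions.tsv", context_proportions(annotated))
        if expression is not None:
            hits = integrate(annotated, expression, de_alpha=config.de_alpha)
            emit("integration.tsv", hits)

    manifest = {
        "config": config.to_dict(),
        "stage_counts": {
            "windows": int(matrix.grid.n_windows),
            "windows_retained": int(len(result.filter_result.retained)),
            "segments": int(len(result.segments_bed)),
            "candidates": int(len(result.candidates)),
            "dmrs": int(len(result.dmrs)),
        },
        "files": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in files.items()
        },
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return {"result": result, "annotated": annotated, "files": files,
            "manifest": manifest}
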