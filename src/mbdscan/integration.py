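"""Methylome-transcriptome integration at promoters.

Joins promoter-annotated sharp DMRs with a differential-expression table
(produced externally; consumed, never computed) and flags the genes whose
promoter methylation change runs opposite to their expression change:
promoter hypermethylation (01) with decreased expression (fold change < 1),
or hypomethylation (10) with increased expression.
"""
from __future__ import annotations

import pandas as pd

REQUIRED_COLUMNS = ("gene", "fold_change", "padj")


def read_expression_table(path) -> pd.DataFrame:
    """Read and validate a DE table TSV (gene, fold_change, padj [, symbol]).

    Rows with non-positive fold changes, p-values outside [0, 1] or missing
    values are rejected with their line numbers; duplicated gene ids are an
    error (the downstream join would be ambiguous).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing columns: {missing}")
    bad_lines = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            fc, p = float(row["fold_change"]), float(row["padj"])
        except (TypeError, ValueError):
            bad_lines.append(line)
            continue
        if pd.isna(fc) or pd.isna(p) or fc <= 0 or not (0 <= p <= 1):
            bad_lines.append(line)
    if bad_lines:
        raise ValueError(
            f"invalid expression rows at lines {bad_lines}: require "
            "fold_change > 0 and padj in [0, 1]"
        )
    dupes = df.loc[df["gene"].duplicated(), "gene"].tolist()
    if dupes:
        raise ValueError(f"duplicated gene ids in expression table: {dupes}")
    return df


def integrate(
    annotated_dmrs: pd.DataFrame,
    expression: pd.DataFrame,
    de_alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes with a significant expression change and a promoter sharp DMR.

    ``annotated_dmrs`` must carry ``category``, ``direction``, ``gene_ids``
    (comma-separated) and coordinates. The output has one row per gene,
    sorted by gene id, with:

    * ``direction`` — promoter methylation direction, or "discordant" when
      both 01 and 10 promoter DMRs hit the same gene (excluded from the
      inverse list);
    * ``inverse`` — True iff (01 and fold < 1) or (10 and fold > 1).
    """
    sharp_prom = annotated_dmrs[
        (annotated_dmrs.get("dmr_class") == "sharp")
        & (annotated_dmrs["category"] == "promoter")
    ]
    by_gene: dict[str, dict] = {}
    for row in sharp_prom.itertuples(index=False):
        for gid in str(row.gene_ids).split(","):
            if not gid:
                continue
            rec = by_gene.setdefault(
                gid, {"directions": set(), "dmrs": [], "coords": []}
            )
            rec["directions"].add(row.direction)
            rec["dmrs"].append(row.dmr_id)
            rec["coords"].append(f"{row.chrom}:{row.start}-{row.end}")
    expr = expression.set_index("gene")
    rows = []
    for gid in sorted(by_gene):
        if gid not in expr.index:
            continue
        e = expr.loc[gid]
        if float(e["padj"]) >= de_alpha:
            continue
        dirs = by_gene[gid]["directions"]
        direction = dirs.pop() if len(dirs) == 1 else "discordant"
        fc = float(e["fold_change"])
        inverse = (direction == "01" and fc < 1) or (direction == "10" and fc > 1)
        rows.append(
            {
                "gene": gid,
                "symbol": e.get("symbol", gid),
                "direction": direction,
                "fold_change": fc,
                "padj": float(e["padj"]),
                "expression_direction": "up" if fc > 1 else "down",
                "inverse": inverse,
                "dmr_ids": ",".join(by_gene[gid]["dmrs"]),
                "dmr_coords": ",".join(by_gene[gid]["coords"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "symbol", "direction", "fold_change", "padj",
            "expression_direction", "inverse", "dmr_ids", "dmr_coords",
        ],
    )


def inverse_genes(hits: pd.DataFrame) -> set[str]:
    if hits.empty:
        return set()
    return set(hits.loc[hits["inverse"], "gene"])
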