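"""Region-level differential testing and DMR classification.

Each candidate region is tested for a between-group difference with a
linear mixed-effects model on log2(count+1) at window level — fixed group
effect, random per-sample intercept, REML fit, Wald t-test on the group
coefficient with between-within degrees of freedom (n_samples − 2) —
falling back to a Welch t-test on per-sample region means when the mixed
fit is singular or fails. The t reference matters: windows within a sample
are not independent replicates of the group effect, and a 1-df chi-square
likelihood-ratio reference is badly anti-conservative at three samples per
group. P-values are Benjamini-Hochberg adjusted across
candidates; significant regions are classified from the per-sample
methylation statuses:

* sharp 01 — every fibrotic/B sample methylated, every A unmethylated
  (hypermethylation in B);
* sharp 10 — the converse (hypomethylation in B);
* quantitative — all samples in both groups methylated but counts differ;
* anything else is excluded as "inconsistent".

Fold change is reported on the linear count scale as the ratio of group
mean region counts (with a pseudocount).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .segments import CandidateRegion


@dataclass(frozen=True)
class TestResult:
    fold_change: float
    p_raw: float
    method: str  # "lmm" or "welch"


def test_region(
    region_counts: np.ndarray,
    samples: list[str],
    groups: dict[str, str],
    group_a: str,
    group_b: str,
    pseudocount: float = 0.5,
) -> TestResult:
    """Between-group test of one region's (windows x samples) raw counts.

    Returns the linear-scale fold change of group-B over group-A mean
    region counts and the raw p-value.
    """
    region_counts = np.asarray(region_counts, dtype=float)
    if region_counts.ndim != 2 or region_counts.shape[0] < 1:
        raise ValueError("region needs >= 1 window of counts")
    labels = [groups[s] for s in samples]
    a_idx = [j for j, g in enumerate(labels) if g == group_a]
    b_idx = [j for j, g in enumerate(labels) if g == group_b]
    if not a_idx or not b_idx:
        raise ValueError("both groups must have samples")
    sample_means = region_counts.mean(axis=0)
    fold = (sample_means[b_idx].mean() + pseudocount) / (
        sample_means[a_idx].mean() + pseudocount
    )
    y = np.log2(region_counts + 1.0)
    p, method = _wald_mixed(y, labels, group_b)
    if p is None:
        p = _welch(y[:, a_idx].mean(axis=0), y[:, b_idx].mean(axis=0))
        method = "welch"
    return TestResult(float(fold), float(p), method)


def _wald_mixed(
    y: np.ndarray, labels: list[str], group_b: str
) -> tuple[float | None, str]:
    n_windows, n_samples = y.shape
    if n_windows < 2:
        return None, "welch"  # one obs per sample: random intercept unidentifiable
    endog = y.ravel()  # window-major; each column is one sample
    if np.allclose(endog, endog[0]):
        return 1.0, "lmm"  # constant response: no effect, degenerate variance
    sample_ids = np.tile(np.arange(n_samples), n_windows)
    is_b = np.tile(
        np.array([1.0 if g == group_b else 0.0 for g in labels]), n_windows
    )
    exog = np.column_stack([np.ones_like(is_b), is_b])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = MixedLM(endog, exog, groups=sample_ids).fit(reml=True)
        if not (np.isfinite(fit.params[1]) and np.isfinite(fit.bse[1])):
            return None, "welch"
        if float(np.asarray(fit.cov_re).ravel()[0]) < 1e-10:
            return None, "welch"  # random-effect variance on the boundary
        t = fit.params[1] / fit.bse[1]
        # between-within df: N samples minus 2 group means
        return float(2.0 * stats.t.sf(abs(t), df=n_samples - 2)), "lmm"
    except (np.linalg.LinAlgError, ValueError):
        return None, "welch"


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(b, a, equal_var=False).pvalue)


def adjust_pvalues(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_dmr(
    candidate: CandidateRegion,
    fold_change: float,
    p_adj: float,
    groups: dict[str, str],
    group_a: str,
    group_b: str,
    fdr: float = 0.05,
) -> tuple[str | None, str | None, str]:
    """Classify a significant candidate; returns (class, direction, reason).

    Non-significant candidates give (None, None, "not_significant"); status
    patterns matching neither the sharp nor the quantitative definition give
    (None, None, "inconsistent").
    """
    if p_adj >= fdr:
        return None, None, "not_significant"
    a_status = [candidate.status[s] for s in candidate.status if groups[s] == group_a]
    b_status = [candidate.status[s] for s in candidate.status if groups[s] == group_b]
    if all(b_status) and not any(a_status):
        return "sharp", "01", "ok"
    if all(a_status) and not any(b_status):
        return "sharp", "10", "ok"
    if all(a_status) and all(b_status):
        return "quantitative", "01" if fold_change > 1 else "10", "ok"
    return None, None, "inconsistent"


def test_candidates(
    candidates: list[tuple[CandidateRegion, np.ndarray, int, int]],
    samples: list[str],
    groups: dict[str, str],
    group_a: str,
    group_b: str,
    fdr: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Test, BH-adjust and classify a list of candidates.

    Each entry is (candidate, raw window x sample counts, bp start, bp end).
    Returns one row per candidate, including excluded ones (audit trail);
    emitted DMRs are the rows with a non-null ``dmr_class``.
    """
    rows = []
    for cand, counts, bp_start, bp_end in candidates:
        res = test_region(counts, samples, groups, group_a, group_b, pseudocount)
        rows.append(
            {
                "chrom": cand.chrom,
                "start": bp_start,
                "end": bp_end,
                "n_windows": cand.n_windows,
                "fold_change": res.fold_change,
                "p_raw": res.p_raw,
                "test_method": res.method,
                **{f"status_{s}": int(cand.status[s]) for s in samples},
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=[
                "chrom", "start", "end", "n_windows", "fold_change",
                "p_raw", "p_adj", "dmr_class", "direction", "reason",
            ]
        )
    df["p_adj"] = adjust_pvalues(df["p_raw"].to_numpy())
    classes, directions, reasons = [], [], []
    for (cand, _, _, _), p_adj, fold in zip(
        candidates, df["p_adj"], df["fold_change"]
    ):
        c, d, r = classify_dmr(cand, fold, p_adj, groups, group_a, group_b, fdr)
        classes.append(c)
        directions.append(d)
        reasons.append(r)
    df["dmr_class"] = classes
    df["direction"] = directions
    df["reason"] = reasons
    return df


def heatmap_matrix(
    dmr_window_counts: list[np.ndarray], samples: list[str], dmr_ids=None
) -> pd.DataFrame:
    """Square-root window-normalized read counts, one row per DMR.

    value(dmr, sample) = sqrt(total count in DMR / n_windows); the display
    statistic behind the standard sharp-DMR heatmap.
    """
    rows = [
        np.sqrt(np.asarray(c, dtype=float).sum(axis=0) / c.shape[0])
        for c in dmr_window_counts
    ]
    idx = dmr_ids if dmr_ids is not None else range(len(rows))
    return pd.DataFrame(rows, columns=samples, index=idx)


def count_by_chromosome(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Hyper (01) and hypo (10) sharp-DMR counts per chromosome."""
    if dmrs.empty:
        return pd.DataFrame(columns=["chrom", "hyper", "hypo"])
    out = (
        dmrs.assign(
            hyper=(dmrs["direction"] == "01").astype(int),
            hypo=(dmrs["direction"] == "10").astype(int),
        )
        .groupby("chrom", as_index=False)[["hyper", "hypo"]]
        .sum()
    )
    return out
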