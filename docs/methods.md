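# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical edge cases.

## Coordinates and formats

All coordinates are 0-based half-open, matching BED, so interval files
round-trip without shifting. Gene models are BED12 (name field
`gene_id|symbol`), CpG islands BED3, fragments BED6 (strand required for
extension), and all tables TSV with a header.

## Window counts

Fragments are resized to the average fragment length anchored at their 5′
end (`+`: keep start; `−`: keep end) and clipped to chromosome bounds.
Resizing an unstranded fragment is refused — the extension direction would
be ambiguous. The genome is tiled in fixed 50-bp windows; the terminal
window of each chromosome is truncated, not dropped, so the tiling covers
the genome exactly. A window's count is the average per-base depth over its
*actual* width, rounded half away from zero (0.5 → 1). Conservation holds
by construction: summed window counts times width match total base depth to
within half a count per window.

## Even-coverage Poisson filter

If reads were spread evenly, sample *s*'s window counts would be
Poisson(λ̂ₛ), λ̂ₛ = total count / n_windows. The minimal "surprising" count
is cₛ = min{c ≥ 1 : P(Pois(λ̂ₛ) ≥ c) ≤ α/n_windows}; a window is retained
when any sample reaches its cₛ. The per-window level α/n_windows is a
Bonferroni correction at α = 0.05 — deliberately conservative, since the
filter's job is only to discard the genome-wide background before model
fitting. A sample with zero reads gets λ̂ = 0, cₛ = 1 and contributes no
retained windows (with a warning). "Reaches" is ≥ cₛ, where cₛ is the
smallest significant count.

## Three-Poisson deconvolution

Counts in an enrichment library mix background noise, ambient/partial
signal and genuine methylation; the model is a mixture of three Poisson
components with rates λ₁ ≤ λ₂ ≤ λ₃ and weights π. Fitting is EM to a MAP
estimate under weak conjugate priors — Gamma(1, 10⁻³) on each rate and
Dirichlet(1) on weights — which coincides with maximum likelihood as the
priors vanish; the Gamma prior's only practical effect is to keep rate
updates finite when a component empties. A full posterior sampler would add
nothing: only the per-window posterior membership is consumed downstream.

* Initialization is deterministic (rates at the 25th/75th/99th count
  percentiles + 0.1, weights 0.6/0.3/0.1), so fits reproduce without a
  seed.
* EM runs on the aggregated empirical distribution (unique count values
  with multiplicities), making each iteration O(#distinct values).
* Convergence: relative log-likelihood change < 10⁻⁸, max 500 iterations;
  floors 10⁻⁶ on rates and weights.
* The methylated state is the single highest-rate component; the middle
  component is ambient, i.e. unmethylated. Consequently a sample whose
  retained windows really occupy three distinct enrichment levels will
  call only the top level methylated — a deliberate, conservative choice.
* **Model-order fallback.** The filter usually removes the background, so a
  sample's retained counts often carry only two modes (leaked background +
  methylated), or one (everything methylated). Forcing three components
  then splits a mode into interchangeable halves and the top-component
  posterior collapses toward its weight. The fit is therefore computed at
  orders 3, 2 and 1 and the best by BIC is kept, flagged `degenerate` when
  reduced. A one-component fit assigns methylation probability 1 to every
  window: its windows are one population already far above the
  even-coverage background the filter removed. Counts with fewer than two
  distinct values cannot identify any mixture and raise an error; the
  pipeline then calls that sample entirely unmethylated with a warning.

The posterior p(c) = π₃Pois(c; λ₃)/Σₖ πₖPois(c; λₖ) is evaluated in
log-space; posteriors over components sum to one to ≈10⁻¹⁴ and p(c) is
non-decreasing in c whenever λ₃ is strictly maximal. Binary status is
p ≥ τ with τ = 0.5 (ties count as methylated).

## Scan segmentation and candidates

For binary statuses, a scan over fixed-composition windows reduces to
gap-tolerant run merging: maximal runs of methylated windows are merged
when separated by ≤ 2 unmethylated windows (100 bp) and kept when they
contain ≥ 2 methylated windows, never across chromosome boundaries. These
per-sample segments are unioned across samples into maximal candidate
intervals; a sample is methylated over a candidate when ≥ 50 % of the
candidate's windows are methylated in it. Both the gap limit and the
majority threshold are configurable; the defaults are the smallest values
that tolerate isolated posterior flips without bridging distinct regions
(the generator keeps planted regions ≥ 4 windows apart for the same
reason).

## Differential testing and classification

Each candidate's window-level counts are modelled as
log2(count + 1) ~ group, with a random per-sample intercept, fit by REML
(statsmodels `MixedLM`). The group effect is tested with a Wald t-statistic
on **between-within degrees of freedom, n_samples − 2**. The df choice is
load-bearing: windows within a sample are not independent replicates of
the group effect, and a 1-df χ² likelihood-ratio reference rejects at ≈11 %
under a null with real per-sample effects at three samples per group
(measured by simulation), whereas the between-within t holds ≈3.5 % —
slightly conservative, never anti-conservative. When the random-effect
variance estimate hits zero, the fit fails, or the candidate has a single
window, the test falls back to a Welch t-test on per-sample region means
(flagged per region in the output).

Fold change is reported on the linear count scale:
(mean_B + 0.5)/(mean_A + 0.5) of per-sample region-mean counts; the 0.5
pseudocount keeps sharp regions (near-zero one side) finite and is
configurable. P-values are Benjamini–Hochberg adjusted across candidates;
regions pass at adjusted p < 0.05.

Classification uses the per-sample statuses: sharp 01 = all group-B
methylated and all group-A unmethylated; sharp 10 = converse; quantitative
= all samples methylated (direction from the fold change). Any other
pattern matches no definition and is excluded with reason `inconsistent`,
retained in the candidate table for audit. A post-hoc assertion checks
every emitted direction against raw group means. The heatmap statistic is
sqrt(region count / n_windows) per sample, and per-chromosome summaries
count hyper (01) and hypo (10) sharp DMRs.

## Annotation

Promoters span 1000 bp upstream to 500 bp downstream of the TSS
(strand-aware, clipped; the conventional asymmetric promoter window — the
configuration accepts any (upstream, downstream) pair). 3′-end windows are
±1000 bp around the TTS. Introns are the transcript span minus exons. A DMR
overlapping several genes pools all overlapped categories and takes the
highest priority: promoter > 3′ end > exon > intron > intergenic. CpG
island context uses edge-to-edge distance to the nearest merged island with
half-open bands — island (d = 0, which includes exact adjacency), shore
(0 < d ≤ 2000), shelf (2000 < d ≤ 4000), open sea (d > 4000) — so every
locus gets exactly one label; with no islands everything is open sea at
infinite distance. Distance is measured from region edges, not midpoints.

## Expression integration

Genes, not DMRs, are the output unit. A gene qualifies with ≥ 1 sharp DMR
whose priority category is promoter and an expression adjusted p < 0.05;
it is *inverse* when direction 01 pairs with fold change < 1 or 10 with
fold change > 1. A gene hit by both 01 and 10 promoter DMRs is marked
`discordant` and excluded from the inverse list. Expression tables are
validated on read (positive fold changes, p in [0, 1], unique gene ids)
with offending line numbers reported.

## Synthetic studies

The generator emulates exactly the generative process the deconvolution
assumes: per-window counts are independent Poisson draws at
size_factor × rate, where the rate is the planted region's group rate or
the background. Defaults define the study conditions: background 0.3 and
methylated 25 counts/window (quantitative pairs 25 vs 60), regions 5
windows wide, per-sample size factors log-uniform on [0.7, 1.4], three
samples per group. These rates separate the mixture components cleanly at
desk scale; the true dynamic range of MBD enrichment varies by protocol,
so they are chosen for testability, not realism. Planted region kinds are
sharp01/sharp10 (background one group, methylated the other),
quantitative, and shared-methylated decoys. Inverse genes get one sharp
region inside their promoter and an opposite-direction planted fold
change; concordant and DE-only genes exercise the negative paths. All
other regions avoid promoters so the planted inverse set is exact, and
regions keep ≥ 4 windows of separation so the scan cannot bridge them.
DE adjusted p-values are planted surrogates — the pipeline consumes, never
computes, expression statistics.

Not emulated: read-level artifacts (duplicates, mapping ambiguity, GC
bias), fragment-length variation (counts are drawn at window level;
extension/counting is exercised separately on hand-built fragment
fixtures), per-CpG resolution, overdispersion beyond Poisson, and copy
number variation. Passing tests therefore demonstrate correctness of the
statistical machinery under its own model, plus exact agreement of the
deterministic stages with brute-force oracles — not robustness to
real-data artifacts the model does not represent (the sharp-site focus
mitigates, but does not test, CNV confounding).

## Problem sizes and determinism

The test suite and the acceptance script run studies of 1–10 Mb (20k–400k
windows, 200–250 planted regions), sizes at which every planted effect is
comfortably detectable and a full run takes well under a minute per study.
All randomness flows from explicit seeds (sub-seeds derived via
`numpy.random.SeedSequence`), mixture initialization is deterministic, and
two runs with the same config and seed produce byte-identical output files
(verified by manifest checksums).

## Known limitations

* The mixed model assumes a common within-group variance on the log2
  scale; strongly heteroscedastic regions rely on the Welch fallback.
* Sharp classification requires unanimity of per-sample statuses; a single
  noisy sample demotes a true sharp region to `inconsistent` rather than
  miscalling it (visible in the candidate table).
* The middle mixture component is always unmethylated; data with three
  genuine enrichment levels per sample will under-call the middle level.
* Candidate unification across samples is interval union; two directly
  abutting opposite-direction regions would merge if their segments ever
  overlap (the generator's spacing avoids this; real data may not).
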