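# Methods

## Overview

jointnet reconstructs, per sample, a directed weighted TF → gene network
from three evidence layers — PWM motif hits in open chromatin within a
gene's regulatory regions, TF expression, and peak intensity — and
summarizes TF importance by personalized PageRank. Group-level analysis
then proceeds on (i) consensus edges shared across a group's samples,
(ii) Wilcoxon differential statistics on PageRank scores, expression and
peak intensities, and (iii) two bespoke permutation statistics on marker
panels. A synthetic cohort generator provides planted ground truth for
validation.

## Network construction

**Regulatory regions.** Promoter = [tss − up, tss + down) on the plus
strand and the mirrored [tss − down, tss + up) on the minus strand, with
up = 5000 bp and down = 1000 bp by default — a common regulatory-window
convention; both are configurable. Enhancers come from a user-supplied
BEDPE of enhancer → gene interactions (e.g. the most confident predictions
of an interaction model). Without a BEDPE, a fallback attaches any peak
within `enhancer_max_dist` (default 50 kb) of the TSS, excluding peaks
already inside the promoter window; this keeps the pipeline runnable at the
cost of much denser candidate regions.

**Motif scanning.** Log-odds score in bits, Σⱼ log2(fⱼ,b / qb), at every
offset on both strands; per offset the better strand is kept (ties favor
'+'). The relative score normalizes by the PWM's attainable range,
(s − smin)/(smax − smin), and hits with relative score ≥ 0.8 (default) are
retained. Ambiguous bases (N) contribute zero log-odds. PWM frequencies
are floored at a pseudofrequency of 1e-3 and renormalized at load time so
no cell has −∞ log-odds. Relative-score thresholding (rather than a
p-value threshold) was chosen because it is scale-free across PWMs of
different lengths and information content; the threshold is exposed in
`NetworkParams`.

**Edge weights.** The three components — best relative motif score, TF
expression, peak intensity — are each mapped to (0, 1] and combined by
geometric mean (configurable to product or arithmetic mean). Expression
and intensity enter as within-sample rank/n rather than raw values: ranks
are invariant to the upstream normalization choice and match the
nonparametric spirit of the downstream tests. Rank ties are broken
lexicographically by feature id, making networks fully deterministic. The
geometric mean makes any zero component (unexpressed TF, zero-intensity
peak) remove the edge, and keeps the three scales comparable. Multiple
candidate edges for one (TF, gene) collapse to the maximum weight —
the strongest single piece of regulatory evidence.

**Node weights** are the sample's normalized expression values as given;
the reader records the declared unit but imposes no specific normalization
beyond non-negativity.

## Personalized PageRank

The score vector solves s = (1 − d)·v + d·(Wᵀs + m·v), where W is the
out-edge weight matrix row-normalized per source, v the personalization
vector (node weights + 1e-12, normalized to sum 1; the epsilon guards
all-zero expression), and m the mass on dangling nodes. Redistributing
dangling mass through v (rather than uniformly) preserves both probability
conservation (Σs = 1 to 1e-9) and the personalized semantics: a gene with
no outgoing edges returns its walk mass preferentially to highly expressed
genes. Defaults d = 0.85, L1 tolerance 1e-10, max 1000 iterations —
canonical PageRank settings; non-convergence raises an error carrying the
residual rather than returning silently. Power iteration on a sparse
matrix is exact to the dense linear solve (I − d(Wᵀ + v·1ᵈᵀ))s = (1 − d)v,
which the test suite verifies to 1e-8 on random digraphs. A log1p scaling
of the personalization is available by flag for heavy-tailed expression.

## Consensus and regulator ranking

Consensus edges within a (group, condition) require occurrence in
**strictly more than** a configurable fraction of samples (default 0.7) —
the strict inequality reads "> 70 %" literally. Per-gene regulator ranking
uses the **inclusive** threshold "at least" 20 % of samples and sorts by
median edge weight (ties by TF id). The two filters deliberately differ in
strictness; both fractions are parameters.

## Differential analysis

All two-group tests use the Wilcoxon rank-sum statistic: exact null
distribution when the pooled size is ≤ 12 with no ties, tie-corrected
normal approximation otherwise (backed by scipy's Mann–Whitney
implementation; an exhaustive rank-enumeration oracle in the test suite
pins the exact branch). Fold changes are log2 of group **medians** with
pseudocount c = 1, matching the median-based summaries used elsewhere.

* DEGs: called at raw p < 0.05 and |log2FC| > 0.58.
* DARs: per-sample peak intensities are summed into consensus peaks
  (intervals merged at ≥ 1 bp overlap), normalized by total signal per
  sample (a library-size analog; no read-count dispersion model is
  attempted), and called at BH FDR < 0.05 and |log2FC| > 0.58.
* Differential TFs: Wilcoxon on personalized-PageRank rows at raw
  p < 0.05, with direction = sign of the median difference; TFs scoring
  zero everywhere are skipped and logged.

The raw-p/FDR asymmetry between DEGs and DARs is intentional and
configurable. Calling rules are pure functions of (p or FDR, log2FC);
changing a threshold never recomputes a statistic.

Regulatee profiles intersect each differential TF's consensus targets
(union of the two compared (group, condition) consensus sets) with called
DEGs (by gene id) and called DARs (mapped to genes through the regulatory
region map; unassigned peaks are excluded). Enrichment of the union
(TFs ∪ regulatees) uses the hypergeometric upper tail P(X ≥ k) with BH
across sets. The default universe is all annotated genes — the most
conservative choice when the expressed subset is not separately defined —
and is configurable.

## Permutation tests

*Activation ratio.* Each activated/resting marker is assigned to the group
with the greatest median expression; exact ties exclude the marker
(logged). Ratio_g = (#activated won)/(#resting won), computed plainly when
both counts are positive and with pseudocount 0.5 added to both counts
otherwise (so a group winning nothing scores the neutral ratio 1). The
statistic is Ratio_i − Ratio_j; the null permutes the per-marker winner
labels across markers, M = 5000 by default.

*Cumulative induction.* Statistic Σ_genes median_i − Σ_genes median_j over
a cytokine/MMP list on the declared normalized scale; the null shuffles
sample-level group labels, stratified within condition. The two tests
deliberately permute different units (marker labels vs sample labels),
reflecting how each statistic is constructed.

*P-values.* p = #{null ≥ observed}/M by default (one-sided, ties counted,
granularity exactly 1/M). The literal rule #{null < observed}/M — which
approaches 1, not 0, for extreme positive statistics — is preserved
verbatim behind `direction="literal_less"` rather than silently
corrected; `less` and `two_sided` are also available. No add-one
(Phipson–Smyth) correction is applied by default, so p = 0 is reportable;
the correction is available by flag.

## Synthetic cohort generator

The generator emulates a 3-group × 2-condition design with 10 subjects per
group (60 samples), 300 genes of which 30 are TFs, on a 500 kb single-chrom
genome — large enough for enrichment statistics, small enough for fast
iteration. Genes are laid out non-overlapping with alternating strands;
each gene gets a fixed 500 bp TSS-centered promoter peak.

* **Counts**: negative binomial with var = μ + μ²·φ, φ = 0.05 (typical
  RNA-seq biological dispersion for cell lines), baseline means log-uniform
  in [30, 300], per-sample library-size factors log-normal (σ = 0.15).
  Normalization is median-of-ratios (DESeq-style), chosen over total-count
  scaling so that planted fold changes are not distorted by composition
  bias.
* **Peak intensities**: log-normal (baseline σ = 0.5 across peaks,
  per-sample noise σ = 0.25).
* **Planted programs** (one per group by default): the TF gains +1 log2
  expression in its target group; its 15 target genes carry the TF's
  consensus motif in their promoter peak (planted into the shared genome),
  gain +1 log2 expression (`target_expr_log2fc`, making them true DEGs, as
  a TF program upregulating its regulatees) and have peak intensity ×2 in
  the target group. The first program also plants distal enhancer peaks
  linked by BEDPE, exercising the interaction path.
* **Marker panels**: disjoint activated/resting/cytokine-MMP gene sets;
  activated markers are elevated in the first group, resting markers in
  the third, and the cytokine/MMP panel is TNF-induced with group-specific
  log2 magnitudes (2.0 / 1.5 / 1.0), mirroring an amplified response in
  the first group without claiming real effect sizes.

All randomness flows from one `numpy` Generator seeded by the config, so a
seed fully determines every output byte. Truth tables record all planted
TFs, edges, motif positions, expression effects and peak multipliers.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level noise and peak-calling artifacts,
batch effects, peak coordinates that vary across samples (coordinates are
fixed per gene; only intensities vary), correlated co-regulation beyond
the planted programs, realistic motif databases (PWMs are synthetic
8-mers with 0.85 consensus weight), and genome sequence composition.
Recovery rates measured here are upper bounds on what identical settings
would achieve on real cohorts.

## Pipeline

One YAML config drives simulate/load → networks → PageRank → consensus →
differential → regulatee/enrichment → permutation. A master seed generates
per-stage seeds by stable hashing of (seed, stage name). Stages cache on a
content hash of parameters and upstream hashes, so reruns skip completed
work. The run manifest records the package version, config hash, seeds and
an SHA-256 per output file — and deliberately no wall-clock state, so two
runs with identical inputs produce byte-identical manifests. Motif scans
are memoized per (interval, TF) across samples of a cohort, which is exact
because the genome is shared.

## Validation problem sizes

The test suite validates the PageRank solver against a dense linear-solve
oracle on 50 random digraphs of up to 100 nodes; permutation-test
calibration on 200 exchangeable-null cohorts at M = 200 (KS uniformity at
α = 0.01) plus exhaustive-enumeration agreement on instances with ≤ 7
permutable units; and planted-program recovery over 20 replicate default
cohorts (60 samples each). These sizes give stable Monte-Carlo estimates
(KS critical deviation ≈ 0.115 at n = 200 vs the ≈ 0.035 discreteness of
the ratio statistic) while keeping the full suite fast.

## Known limitations

* The DAR stand-in tests normalized signalValue intensities, not
  re-counted reads; it is not a replacement for count-model tools when
  read data are available.
* The edge-weight functional form (geometric mean of rank-normalized
  components) is one defensible choice among several; product and
  arithmetic mean are provided, and conclusions that depend on the choice
  should be checked under all three.
* The enhancer distance fallback attaches all nearby peaks to a gene and
  can create many weak candidate edges in gene-dense regions; supplying
  real interaction predictions is strongly preferred.
* With ties counted and no add-one correction, permutation p-values are
  slightly conservative under discrete statistics; the activation-ratio
  statistic is discrete by construction.
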