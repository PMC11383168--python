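"""Differential statistics between sample groups.

Differentially expressed genes (DEGs) are called by the Wilcoxon rank-sum
test on normalized expression at raw p < 0.05 with |log2 fold change| >
0.58 (fold changes use group medians with a pseudocount of 1).
Differentially accessible regions (DARs) apply the same statistic to
library-size-normalized peak intensities over a merged consensus peak set,
but gate on Benjamini-Hochberg FDR < 0.05 instead of raw p — the asymmetry
between the two rules is deliberate and configurable. Differential TF
importance applies the Wilcoxon test to personalized-PageRank rows.
Regulatee profiling intersects a differential TF's consensus targets with
called DEGs/DARs, and pathway enrichment of the resulting union uses the
hypergeometric upper tail with BH adjustment across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, JointnetError, PeakSet, SampleMetadata, warn_logged
from .network import RegulatoryRegionMap
from .pagerank import ConsensusEdgeSet, PageRankTable


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    statistic: float
    degenerate: bool = False


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> WilcoxonResult:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when the pooled size is at most 12 and
    there are no ties; otherwise the tie-corrected normal approximation.
    Two constant, identical groups are degenerate and return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise JointnetError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return WilcoxonResult(1.0, len(x) * len(y) / 2.0, degenerate=True)
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not ties) else "asymptotic"
    res = st.mannwhitneyu(x, y, alternative=alternative, method=method)
    return WilcoxonResult(float(res.pvalue), float(res.statistic))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _select_samples(
    metadata: SampleMetadata,
    group: str,
    condition: str | None,
    available: Sequence[str],
) -> list[str]:
    ids = [s for s in metadata.samples_in(group=group, condition=condition) if s in set(available)]
    if group not in set(metadata.table["group"]):
        raise JointnetError(f"unknown group label '{group}'")
    return ids


def _two_group_table(
    values: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-feature medians, log2 fold change and Wilcoxon p over two groups."""
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise JointnetError("need >= 2 samples per group")
    a = values[list(samples_a)].to_numpy(dtype=float)
    b = values[list(samples_b)].to_numpy(dtype=float)
    med_a = np.median(a, axis=1)
    med_b = np.median(b, axis=1)
    lfc = np.log2((med_a + pseudocount) / (med_b + pseudocount))
    rows = []
    for i in range(len(values)):
        r = wilcoxon_rank_sum(a[i], b[i])
        rows.append((r.p_value, r.degenerate))
    p, degen = zip(*rows) if rows else ((), ())
    return pd.DataFrame({
        "feature_id": values.index,
        "median_a": med_a,
        "median_b": med_b,
        "log2fc": lfc,
        "p_value": np.asarray(p, dtype=float),
        "degenerate": np.asarray(degen, dtype=bool),
    })


def call_degs(
    expression: ExpressionMatrix,
    metadata: SampleMetadata,
    group_a: str,
    group_b: str,
    condition: str | None = None,
    p_thresh: float = 0.05,
    lfc_thresh: float = 0.58,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential expression between two groups (raw p and |log2FC| gates)."""
    sa = _select_samples(metadata, group_a, condition, expression.sample_ids)
    sb = _select_samples(metadata, group_b, condition, expression.sample_ids)
    tab = _two_group_table(expression.values, sa, sb, pseudocount)
    tab["fdr"] = bh_adjust(tab["p_value"])
    tab["called"] = (tab["p_value"] < p_thresh) & (tab["log2fc"].abs() > lfc_thresh)
    tab.insert(1, "group_a", group_a)
    tab.insert(2, "group_b", group_b)
    return tab


def build_peak_matrix(peaksets: Sequence[PeakSet]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge per-sample peaks (>=1 bp overlap) into a consensus intensity matrix.

    Returns (matrix, consensus) where ``matrix`` is consensus-peak x sample
    raw intensity (intensities of a sample's peaks falling in one merged
    interval are summed) and ``consensus`` holds chrom/start/end per row.
    """
    if not peaksets:
        raise JointnetError("no peak sets given")
    all_iv = pd.concat(
        [ps.records[["chrom", "start", "end"]] for ps in peaksets], ignore_index=True
    ).sort_values(["chrom", "start"], kind="stable")
    merged: list[list] = []
    for r in all_iv.itertuples(index=False):
        if merged and merged[-1][0] == r.chrom and r.start < merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], r.end)
        else:
            merged.append([r.chrom, r.start, r.end])
    consensus = pd.DataFrame(merged, columns=["chrom", "start", "end"])
    consensus["peak_id"] = [
        f"{c}:{s}-{e}" for c, s, e in zip(consensus["chrom"], consensus["start"], consensus["end"])
    ]
    consensus = consensus.set_index("peak_id")

    # merged intervals are sorted and disjoint per chrom: locate each sample
    # peak by binary search on the merged starts
    by_chrom = {
        c: (sub["start"].to_numpy(), sub["end"].to_numpy(),
            np.nonzero((consensus["chrom"] == c).to_numpy())[0])
        for c, sub in consensus.groupby("chrom")
    }
    arr = np.zeros((len(consensus), len(peaksets)))
    for j, ps in enumerate(peaksets):
        for r in ps.records.itertuples(index=False):
            starts, ends, rows = by_chrom[r.chrom]
            lo = np.searchsorted(starts, r.start, side="right") - 1
            hi = np.searchsorted(starts, r.end, side="left")
            for k in range(max(lo, 0), hi):
                if starts[k] < r.end and ends[k] > r.start:
                    arr[rows[k], j] += r.intensity
    mat = pd.DataFrame(arr, index=consensus.index, columns=[ps.sample_id for ps in peaksets])
    return mat, consensus.reset_index()


def normalize_peak_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample by total signal (library-size analog), preserving the mean scale."""
    totals = matrix.sum(axis=0)
    if (totals <= 0).any():
        raise JointnetError("sample with zero total peak signal")
    return matrix / totals * totals.mean()


def call_dars(
    peak_matrix: pd.DataFrame,
    metadata: SampleMetadata,
    group_a: str,
    group_b: str,
    condition: str | None = None,
    fdr_thresh: float = 0.05,
    lfc_thresh: float = 0.58,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential accessibility on a consensus peak matrix (BH FDR gate)."""
    norm = normalize_peak_matrix(peak_matrix)
    sa = _select_samples(metadata, group_a, condition, norm.columns)
    sb = _select_samples(metadata, group_b, condition, norm.columns)
    tab = _two_group_table(norm, sa, sb, pseudocount)
    tab["fdr"] = bh_adjust(tab["p_value"])
    tab["called"] = (tab["fdr"] < fdr_thresh) & (tab["log2fc"].abs() > lfc_thresh)
    tab.insert(1, "group_a", group_a)
    tab.insert(2, "group_b", group_b)
    return tab


def differential_pagerank(
    table: PageRankTable,
    metadata: SampleMetadata,
    group_a: str,
    group_b: str,
    condition: str | None = None,
    p_thresh: float = 0.05,
) -> pd.DataFrame:
    """Differentially ranked TFs between two groups (Wilcoxon on PageRank rows).

    TFs scoring zero in every sample of both groups are skipped (logged).
    ``direction`` is the sign of median_a - median_b.
    """
    scores = table.scores
    sa = _select_samples(metadata, group_a, condition, scores.columns)
    sb = _select_samples(metadata, group_b, condition, scores.columns)
    sub = scores[list(sa) + list(sb)]
    nonzero = sub.abs().sum(axis=1) > 0
    n_skipped = int((~nonzero).sum())
    if n_skipped:
        warn_logged(f"skipping {n_skipped} all-zero TF rows")
    tab = _two_group_table(scores.loc[nonzero], sa, sb, pseudocount=0.0)
    tab["fdr"] = bh_adjust(tab["p_value"])
    tab["called"] = tab["p_value"] < p_thresh
    tab["direction"] = np.sign(tab["median_a"] - tab["median_b"]).astype(int)
    tab.insert(1, "group_a", group_a)
    tab.insert(2, "group_b", group_b)
    return tab


def assign_peaks_to_genes(
    consensus_peaks: pd.DataFrame, region_map: RegulatoryRegionMap
) -> dict[str, list[str]]:
    """Map consensus peak ids to genes whose regulatory regions they overlap."""
    out: dict[str, list[str]] = {}
    for r in consensus_peaks.itertuples(index=False):
        genes = []
        for gene, regions in region_map.items():
            for reg in regions:
                if reg.chrom == r.chrom and reg.start < r.end and reg.end > r.start:
                    genes.append(gene)
                    break
        if genes:
            out[r.peak_id] = sorted(genes)
    return out


@dataclass
class RegulateeProfile:
    """Differential TFs with their DEG/DAR-overlapping consensus regulatees."""

    diff_tfs: list[str]
    deg_overlap: dict[str, set[str]]    # tf -> regulatee genes that are called DEGs
    dar_overlap: dict[str, set[str]]    # tf -> regulatee genes owning a called DAR
    union: set[str]                     # TFs + all differential regulatees

    def regulatees_of(self, tf: str) -> set[str]:
        return self.deg_overlap.get(tf, set()) | self.dar_overlap.get(tf, set())


def regulatee_profiles(
    diff_tfs: Sequence[str],
    consensus: ConsensusEdgeSet | Sequence[ConsensusEdgeSet],
    deg_table: pd.DataFrame,
    dar_table: pd.DataFrame,
    region_gene_map: Mapping[str, Sequence[str]] | None = None,
) -> RegulateeProfile:
    """Intersect each differential TF's consensus targets with called DEGs/DARs.

    ``region_gene_map`` maps DAR feature ids to gene ids; without it DAR
    overlap is empty. ``consensus`` may be one edge set or several (targets
    are unioned), e.g. the two compared (group, condition) sets.
    """
    sets = [consensus] if isinstance(consensus, ConsensusEdgeSet) else list(consensus)
    called_degs = set(deg_table.loc[deg_table["called"], "feature_id"])
    dar_genes: set[str] = set()
    if region_gene_map is not None and len(dar_table):
        for pid in dar_table.loc[dar_table["called"], "feature_id"]:
            dar_genes.update(region_gene_map.get(pid, []))
    deg_overlap: dict[str, set[str]] = {}
    dar_overlap: dict[str, set[str]] = {}
    union: set[str] = set(diff_tfs)
    for tf in diff_tfs:
        targets: set[str] = set()
        for cs in sets:
            targets |= cs.targets_of(tf)
        deg_overlap[tf] = targets & called_degs
        dar_overlap[tf] = targets & dar_genes
        union |= deg_overlap[tf] | dar_overlap[tf]
    return RegulateeProfile(list(diff_tfs), deg_overlap, dar_overlap, union)


def hypergeometric_enrichment(
    query_genes: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query_genes`` in each set.

    p = P(X >= k) for k = |query ∩ set|, drawing n = |query| from a
    universe of N genes containing K set members; sets are intersected with
    the universe first. BH adjustment across sets.
    """
    uni = set(universe)
    query = set(query_genes) & uni
    if not uni:
        raise JointnetError("empty universe")
    if not query:
        raise JointnetError("empty query after universe intersection")
    N, n = len(uni), len(query)
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & uni
        K = len(members)
        k = len(query & members)
        p = float(st.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((set_id, k, n, K, N, min(p, 1.0)))
    tab = pd.DataFrame(rows, columns=["set_id", "overlap", "query_size", "set_size", "universe_size", "p_value"])
    tab["fdr"] = bh_adjust(tab["p_value"])
    return tab


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (set, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            fh.write("\t".join([name, "jointnet"] + list(gene_sets[name])) + "\n")
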