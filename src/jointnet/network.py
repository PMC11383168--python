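"""Per-sample TF->gene regulatory network construction.

A gene's regulatory regions (strand-aware promoter window around the TSS,
plus enhancers from supplied enhancer-promoter interactions or a distance
fallback) are intersected with the sample's open-chromatin peaks; the
overlap sequence is scanned with every TF's PWM on both strands. A retained
motif hit for an expressed TF yields a directed edge TF -> gene weighted by
combining the relative motif score, the TF's within-sample expression rank
and the peak's within-sample intensity rank (geometric mean by default, so
a zero component removes the edge). Multiple candidate edges for the same
(TF, gene) collapse to the maximum weight. Nodes carry the sample's
normalized expression as node weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    EPInteractions,
    ExpressionMatrix,
    GenomeAnnotation,
    JointnetError,
    MotifLibrary,
    PeakSet,
    ValidationError,
    warn_logged,
)

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    kind: str      # promoter | enhancer
    source: str    # window | interaction


@dataclass
class RegulatoryRegionMap:
    """gene_id -> candidate regulatory intervals; every gene appears."""

    regions: dict[str, list[Region]]

    def __getitem__(self, gene_id: str) -> list[Region]:
        return self.regions[gene_id]

    def items(self):
        return self.regions.items()


@dataclass(frozen=True)
class MotifHit:
    start: int            # offset within the scanned sequence
    strand: str           # + or -
    log_odds_score: float  # bits
    rel_score: float      # (score - min) / (max - min), in [0, 1]
    tf_id: str = ""
    chrom: str = ""


@dataclass(frozen=True)
class NetworkParams:
    promoter_upstream: int = 5000
    promoter_downstream: int = 1000
    enhancer_max_dist: int = 50_000
    rel_threshold: float = 0.8
    edge_combine: str = "geometric"  # geometric | product | arithmetic


@dataclass
class RegulatoryNetwork:
    """One sample's directed weighted TF->gene network."""

    sample_id: str
    nodes: pd.Series                   # gene_id -> node weight (normalized expression)
    edges: pd.DataFrame                # tf, gene, weight, peak, hit_pos, hit_strand, rel_score

    EDGE_COLUMNS = ["tf", "gene", "weight", "peak", "hit_pos", "hit_strand", "rel_score"]

    def __post_init__(self) -> None:
        if len(self.edges) and (self.edges["weight"] <= 0).any():
            raise ValidationError("edge weights must be > 0")
        if (self.nodes < 0).any():
            raise ValidationError("node weights must be >= 0")

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["tf"], self.edges["gene"]))

    def edge_weights(self) -> pd.Series:
        return self.edges.set_index(["tf", "gene"])["weight"]


def assign_regulatory_regions(
    annotation: GenomeAnnotation,
    interactions: EPInteractions | None = None,
    promoter_window: tuple[int, int] = (5000, 1000),
    peaks: PeakSet | None = None,
    enhancer_max_dist: int = 50_000,
) -> RegulatoryRegionMap:
    """Map each gene to its promoter window and enhancer intervals.

    The promoter is ``[tss-up, tss+down)`` on the plus strand and the
    mirrored ``[tss-down, tss+up)`` on the minus strand. Enhancers come
    from ``interactions``; with no interactions and ``peaks`` given, any
    peak within ``enhancer_max_dist`` of the TSS (and not overlapping the
    promoter) is attached as a fallback enhancer. Interactions that target
    unknown genes are skipped with a logged count.
    """
    up, down = promoter_window
    regions: dict[str, list[Region]] = {}
    t = annotation.table
    for gid, row in t.iterrows():
        tss = int(row["tss"])
        if row["strand"] == "+":
            s, e = tss - up, tss + down
        else:
            s, e = tss - down, tss + up
        regions[gid] = [Region(row["chrom"], max(0, s), e, "promoter", "window")]

    if interactions is not None and len(interactions):
        skipped = 0
        for r in interactions.table.itertuples(index=False):
            if r.gene_id not in regions:
                skipped += 1
                continue
            regions[r.gene_id].append(
                Region(r.chrom, int(r.start), int(r.end), "enhancer", "interaction")
            )
        if skipped:
            warn_logged(f"skipped {skipped} interactions targeting unknown genes")
    elif peaks is not None and len(peaks):
        pk = peaks.records
        for gid, row in t.iterrows():
            tss = int(row["tss"])
            prom = regions[gid][0]
            near = pk[
                (pk["chrom"] == row["chrom"])
                & (pk["start"] < tss + enhancer_max_dist)
                & (pk["end"] > tss - enhancer_max_dist)
            ]
            for p in near.itertuples(index=False):
                if p.start < prom.end and p.end > prom.start:
                    continue  # already inside the promoter window
                regions[gid].append(Region(p.chrom, int(p.start), int(p.end), "enhancer", "window"))
    return RegulatoryRegionMap(regions)


def _encode(sequence: str) -> np.ndarray:
    return _ENC[np.frombuffer(sequence.encode(), dtype=np.uint8)]


def _logodds(pwm: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Per-position log2(frequency/background) with a zero column for N."""
    lo = np.log2(pwm / background[None, :])
    return np.column_stack([lo, np.zeros(len(pwm))])


def scan_motifs(
    sequence: str,
    pwm: np.ndarray,
    background: np.ndarray | None = None,
    rel_threshold: float = 0.8,
) -> list[MotifHit]:
    """Score a PWM at every offset of ``sequence`` on both strands.

    Returns hits whose relative score (log-odds min-max normalized over the
    PWM's attainable range) reaches ``rel_threshold``; at each offset only
    the better strand is kept (ties favor '+'). Ambiguous bases (N)
    contribute a log-odds of zero. A sequence shorter than the motif yields
    no hits.
    """
    if background is None:
        background = np.full(4, 0.25)
    pwm = np.asarray(pwm, dtype=float)
    L = len(pwm)
    enc = _encode(sequence)
    if len(enc) < L:
        return []
    lo_f = _logodds(pwm, background)
    lo_r = _logodds(pwm[::-1, ::-1], background)  # reverse complement
    smin, smax = lo_f[:, :4].min(axis=1).sum(), lo_f[:, :4].max(axis=1).sum()
    denom = smax - smin if smax > smin else 1.0

    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    idx = np.arange(L)
    score_f = lo_f[idx[None, :], windows].sum(axis=1)
    score_r = lo_r[idx[None, :], windows].sum(axis=1)
    best = np.maximum(score_f, score_r)
    rel = (best - smin) / denom
    hits = []
    for off in np.nonzero(rel >= rel_threshold)[0]:
        strand = "+" if score_f[off] >= score_r[off] else "-"
        hits.append(MotifHit(int(off), strand, float(best[off]), float(min(rel[off], 1.0))))
    return hits


def compute_edge_weight(
    rel_motif_score: float,
    tf_expr_norm: float,
    peak_intensity_norm: float,
    method: str = "geometric",
) -> float:
    """Combine the three edge evidence components, each in [0, 1]."""
    comps = (rel_motif_score, tf_expr_norm, peak_intensity_norm)
    for c in comps:
        if not (0.0 <= c <= 1.0):
            raise JointnetError(f"edge-weight component {c} outside [0, 1]")
    prod = rel_motif_score * tf_expr_norm * peak_intensity_norm
    if method == "geometric":
        return float(prod ** (1.0 / 3.0)) if prod > 0 else 0.0
    if method == "product":
        return float(prod)
    if method == "arithmetic":
        return float(sum(comps) / 3.0)
    raise JointnetError(f"unknown edge combine method '{method}'")


def _rank_scale(values: pd.Series) -> pd.Series:
    """Ranks scaled to (0, 1]; ties broken lexicographically by id."""
    order = sorted(values.index, key=lambda g: (values[g], g))
    n = len(order)
    return pd.Series({g: (i + 1) / n for i, g in enumerate(order)})


def candidate_edges(
    peaks: PeakSet,
    region_map: RegulatoryRegionMap,
    motif_library: MotifLibrary,
    genome: Mapping[str, str],
    params: NetworkParams = NetworkParams(),
    cache: dict | None = None,
) -> pd.DataFrame:
    """Sample-independent candidate edges: motif hits in region/peak overlaps.

    One row per (gene, TF, peak) whose region-peak overlap contains a
    retained hit, carrying the best hit's position, strand and relative
    score. Depends only on peak coordinates (not intensities), so with
    ``cache`` shared across samples the result is memoized per distinct
    coordinate set and individual scans are memoized per
    (chrom, start, end, tf).
    """
    cache = cache if cache is not None else {}
    pk = peaks.records
    coord_key = ("skeleton", tuple(map(tuple, pk[["chrom", "start", "end", "name"]].to_numpy())))
    if coord_key in cache:
        return cache[coord_key]

    tf_ids = sorted(motif_library.pwms)
    bg = motif_library.background
    rows = []
    for gene, regions in region_map.items():
        for region in regions:
            sub = pk[(pk["chrom"] == region.chrom)
                     & (pk["start"] < region.end) & (pk["end"] > region.start)]
            for p in sub.itertuples(index=False):
                ov_s, ov_e = max(region.start, int(p.start)), min(region.end, int(p.end))
                for tf in tf_ids:
                    if ov_e - ov_s < len(motif_library.pwms[tf]):
                        continue
                    key = (region.chrom, ov_s, ov_e, tf)
                    if key not in cache:
                        seq = genome[region.chrom][ov_s:ov_e]
                        cache[key] = scan_motifs(
                            seq, motif_library.pwms[tf], bg, params.rel_threshold
                        )
                    hits = cache[key]
                    if not hits:
                        continue
                    top = max(hits, key=lambda h: (h.rel_score, -h.start))
                    rows.append((gene, tf, p.name, ov_s + top.start, top.strand, top.rel_score))
    out = pd.DataFrame(rows, columns=["gene", "tf", "peak", "hit_pos", "hit_strand", "rel_score"])
    cache[coord_key] = out
    return out


def build_network(
    sample_id: str,
    expression: ExpressionMatrix,
    peaks: PeakSet,
    region_map: RegulatoryRegionMap,
    motif_library: MotifLibrary,
    genome: Mapping[str, str],
    params: NetworkParams = NetworkParams(),
    hit_cache: dict | None = None,
) -> RegulatoryNetwork:
    """Build the sample's regulatory network.

    ``hit_cache`` (optional) memoizes motif scans and the candidate-edge
    skeleton; safe to share across samples of one cohort because the genome
    is fixed.
    """
    if sample_id not in expression.sample_ids:
        raise JointnetError(f"sample '{sample_id}' not in expression matrix")
    expr = expression.values[sample_id]

    tf_ids = sorted(t for t in motif_library.pwms if t in expr.index)
    if not tf_ids:
        raise JointnetError("no motif maps to a gene in the expression matrix")
    tf_rank = _rank_scale(expr[tf_ids])

    pk = peaks.records
    peak_rank_by_name = _rank_scale(pk.set_index("name")["intensity"]) if len(pk) else pd.Series(dtype=float)

    cand = candidate_edges(peaks, region_map, motif_library, genome, params, hit_cache)
    cand = cand[cand["tf"].isin(tf_ids) & cand["gene"].isin(expr.index)]
    if len(cand):
        cand = cand[cand["tf"].map(expr) > 0]
    if len(cand):
        cand = cand.copy()
        m = cand["rel_score"].to_numpy(dtype=float)
        e = cand["tf"].map(tf_rank).to_numpy(dtype=float)
        pnorm = cand["peak"].map(peak_rank_by_name).to_numpy(dtype=float)
        prod = m * e * pnorm
        if params.edge_combine == "geometric":
            w = np.where(prod > 0, prod ** (1.0 / 3.0), 0.0)
        elif params.edge_combine == "product":
            w = prod
        elif params.edge_combine == "arithmetic":
            w = (m + e + pnorm) / 3.0
        else:
            raise JointnetError(f"unknown edge combine method '{params.edge_combine}'")
        cand["weight"] = w
        cand = cand[cand["weight"] > 0]
    if len(cand):
        # collapse multiple candidates per (tf, gene) to the maximum weight;
        # deterministic tie-break by peak name then position
        cand = cand.sort_values(
            ["tf", "gene", "weight", "peak", "hit_pos"],
            ascending=[True, True, False, True, True], kind="stable",
        )
        cand = cand.drop_duplicates(["tf", "gene"], keep="first")
        edges = cand[RegulatoryNetwork.EDGE_COLUMNS].reset_index(drop=True)
    else:
        edges = pd.DataFrame(columns=RegulatoryNetwork.EDGE_COLUMNS)
        warn_logged(f"sample {sample_id}: network has no edges")
    return RegulatoryNetwork(sample_id, expr.copy(), edges)


def network_to_tables(net: RegulatoryNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    nodes = net.nodes.rename("node_weight").rename_axis("gene").reset_index()
    return net.edges.copy(), nodes


def network_from_tables(sample_id: str, edges: pd.DataFrame, nodes: pd.DataFrame) -> RegulatoryNetwork:
    return RegulatoryNetwork(
        sample_id,
        nodes.set_index("gene")["node_weight"],
        edges.reindex(columns=RegulatoryNetwork.EDGE_COLUMNS),
    )
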