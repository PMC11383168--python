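"""Personalized PageRank TF importance and cross-sample edge consensus.

TF importance is the stationary distribution of a random walk with restart
on the sample's directed weighted network, where the restart
(personalization) vector is proportional to node weights (normalized gene
expression). Dangling-node mass is redistributed proportionally to the
personalization vector, preserving both probability conservation and the
personalized semantics. Scores over all nodes sum to one; the TF rows of
the full vector form the per-sample importance profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import JointnetError
from .network import RegulatoryNetwork


@dataclass
class PageRankTable:
    """TF x sample matrix of personalized PageRank scores."""

    scores: pd.DataFrame         # tf_ids x sample_ids
    damping: float
    tol: float
    iterations: dict[str, int]   # per sample


def _personalization(node_weights: pd.Series, log_scale: bool, eps: float = 1e-12) -> np.ndarray:
    w = node_weights.to_numpy(dtype=float)
    if log_scale:
        w = np.log1p(w)
    v = w + eps
    return v / v.sum()


def personalized_pagerank(
    network: RegulatoryNetwork,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
    log_scale_personalization: bool = False,
) -> pd.Series:
    """Full node-score vector of the personalized PageRank walk.

    Iterates ``s = (1-d) v + d (W^T s + dangling_mass * v)`` where W is the
    row-normalized (out-edge) weight matrix and v the expression-derived
    personalization vector, until the L1 change drops below ``tol``.
    """
    if not (0.0 < damping < 1.0):
        raise JointnetError("damping must be in (0, 1)")
    if len(network.nodes) == 0:
        raise JointnetError("empty network")
    nodes = list(network.nodes.index)
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    v = _personalization(network.nodes, log_scale_personalization)

    e = network.edges
    if len(e):
        src = np.fromiter((index[t] for t in e["tf"]), dtype=np.int64, count=len(e))
        dst = np.fromiter((index[g] for g in e["gene"]), dtype=np.int64, count=len(e))
        w = e["weight"].to_numpy(dtype=float)
        out = np.zeros(n)
        np.add.at(out, src, w)
        wn = w / out[src]
        # transpose: column j of W^T receives from source j
        WT = sp.csr_matrix((wn, (dst, src)), shape=(n, n))
        dangling = out == 0
    else:
        WT = sp.csr_matrix((n, n))
        dangling = np.ones(n, dtype=bool)

    s = v.copy()
    for it in range(1, max_iter + 1):
        dangling_mass = s[dangling].sum()
        s_new = (1.0 - damping) * v + damping * (WT @ s + dangling_mass * v)
        delta = np.abs(s_new - s).sum()
        s = s_new
        if delta < tol:
            personalized_pagerank.last_iterations = it
            return pd.Series(s, index=nodes)
    raise JointnetError(f"PageRank did not converge in {max_iter} iterations (residual {delta:.3g})")


def pagerank_table(
    networks: list[RegulatoryNetwork],
    tf_ids: list[str] | None = None,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
    log_scale_personalization: bool = False,
) -> PageRankTable:
    """Per-sample personalized PageRank, projected onto the TF rows."""
    if not networks:
        raise JointnetError("no networks given")
    if tf_ids is None:
        tf_ids = sorted({t for net in networks for t in net.edges["tf"]})
    cols = {}
    iters = {}
    for net in networks:
        s = personalized_pagerank(net, damping, tol, max_iter, log_scale_personalization)
        cols[net.sample_id] = s.reindex(tf_ids).fillna(0.0)
        iters[net.sample_id] = personalized_pagerank.last_iterations
    return PageRankTable(pd.DataFrame(cols, index=tf_ids), damping, tol, iters)


@dataclass
class ConsensusEdgeSet:
    """Edges shared by more than ``min_fraction`` of a group's samples."""

    group_key: tuple[str, str]
    edges: pd.DataFrame          # tf, gene, fraction, median_weight
    min_fraction: float
    n_samples: int

    def targets_of(self, tf_id: str) -> set[str]:
        sub = self.edges[self.edges["tf"] == tf_id]
        return set(sub["gene"])


def _edge_stats(networks: list[RegulatoryNetwork]) -> pd.DataFrame:
    """Occurrence fraction and median weight of every edge over the networks."""
    per_net = [net.edge_weights().astype(float) for net in networks]
    nonempty = [w for w in per_net if len(w)]
    if not nonempty:
        return pd.DataFrame(columns=["tf", "gene", "fraction", "median_weight"])
    all_w = pd.concat(nonempty, keys=range(len(nonempty)), names=["_net"])
    g = all_w.groupby(level=["tf", "gene"])
    stats = pd.DataFrame({
        "fraction": g.size() / len(networks),
        "median_weight": g.median(),
    }).reset_index()
    return stats.sort_values(["tf", "gene"], kind="stable").reset_index(drop=True)


def consensus_edges(
    networks_in_group: list[RegulatoryNetwork],
    min_fraction: float = 0.7,
    group_key: tuple[str, str] = ("", ""),
) -> ConsensusEdgeSet:
    """Keep edges present in strictly more than ``min_fraction`` of samples."""
    if not networks_in_group:
        raise JointnetError("empty sample group for consensus")
    stats = _edge_stats(networks_in_group)
    kept = stats[stats["fraction"] > min_fraction].reset_index(drop=True)
    return ConsensusEdgeSet(group_key, kept, min_fraction, len(networks_in_group))


def rank_gene_regulators(
    networks_in_group: list[RegulatoryNetwork],
    gene_id: str,
    min_fraction: float = 0.2,
) -> pd.DataFrame:
    """Rank the TFs regulating one gene by median edge weight.

    TFs with an edge to ``gene_id`` in at least ``min_fraction`` of samples
    (inclusive) are retained and sorted by median edge weight descending,
    ties broken by TF id. Returns columns tf, support_fraction, median_edge_weight.
    """
    if not networks_in_group:
        raise JointnetError("empty sample group")
    stats = _edge_stats(networks_in_group)
    sub = stats[(stats["gene"] == gene_id) & (stats["fraction"] >= min_fraction)]
    sub = sub.sort_values(
        ["median_weight", "tf"], ascending=[False, True], kind="stable"
    )
    return pd.DataFrame({
        "tf": sub["tf"].to_numpy(),
        "support_fraction": sub["fraction"].to_numpy(),
        "median_edge_weight": sub["median_weight"].to_numpy(),
    })
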