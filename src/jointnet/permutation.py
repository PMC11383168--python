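"""Resampling tests for marker-state enrichment and cytokine/MMP induction.

Two statistics, each compared between a pair of sample groups i and j:

* activation ratio — every activated/resting marker is assigned to the
  group with the greatest median expression; the statistic is
  Ratio_i - Ratio_j where Ratio_g = (#activated markers won by g) /
  (#resting markers won by g). The null shuffles the per-marker winner
  labels across markers.
* cumulative induction — the statistic is the summed per-gene group median
  of a cytokine/MMP gene list, group i minus group j. The null shuffles
  sample-level group labels (within condition strata).

Empirical p-values use the plain #/M formula on M label shuffles. The
default direction is one-sided 'greater' (large statistic = enrichment in
group i, with ties counted); the literal printed inequality
#{null < observed}/M is available as direction='literal_less'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, JointnetError, SampleMetadata, warn_logged


@dataclass
class MarkerPanel:
    """Activated/resting/cytokine-MMP gene panels (activated ∩ resting = ∅)."""

    activated: list[str]
    resting: list[str]
    cytokine_mmp: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.activated) & set(self.resting)
        if overlap:
            raise JointnetError(f"activated/resting panels overlap: {sorted(overlap)[:5]}")

    @classmethod
    def from_dict(cls, panels: Mapping[str, Sequence[str]]) -> "MarkerPanel":
        return cls(
            activated=list(panels.get("activated", [])),
            resting=list(panels.get("resting", [])),
            cytokine_mmp=list(panels.get("cytokine_mmp", [])),
        )


@dataclass(frozen=True)
class PermutationConfig:
    M: int = 5000
    seed: int = 0
    direction: str = "greater"   # greater | less | two_sided | literal_less
    marker_subset: str = "all"   # all | degs_only

    def __post_init__(self) -> None:
        if self.M < 1:
            raise JointnetError("M must be >= 1")


@dataclass
class PermutationResult:
    observed: float
    null_stats: np.ndarray
    p_value: float
    groups: tuple[str, str]
    config: PermutationConfig
    detail: dict = field(default_factory=dict)


def permutation_pvalue(observed: float, null_stats, direction: str = "greater") -> float:
    """Empirical p over the null draws with granularity 1/M.

    greater: #{null >= observed}/M (ties count); less: #{null <= observed}/M;
    two_sided: #{|null| >= |observed|}/M; literal_less: #{null < observed}/M,
    the printed formula applied verbatim.
    """
    null = np.asarray(null_stats, dtype=float)
    if len(null) == 0:
        raise JointnetError("empty null distribution")
    if direction == "greater":
        return float((null >= observed).sum() / len(null))
    if direction == "less":
        return float((null <= observed).sum() / len(null))
    if direction == "two_sided":
        return float((np.abs(null) >= abs(observed)).sum() / len(null))
    if direction == "literal_less":
        return float((null < observed).sum() / len(null))
    raise JointnetError(f"unknown direction '{direction}'")


def _present_markers(expression: ExpressionMatrix, markers: Sequence[str]) -> list[str]:
    idx = set(expression.gene_ids)
    present = [m for m in markers if m in idx]
    missing = [m for m in markers if m not in idx]
    if missing:
        warn_logged(f"dropping {len(missing)} markers absent from expression matrix")
    return present


def max_joint_assignment(
    expression: ExpressionMatrix,
    metadata: SampleMetadata,
    markers: Sequence[str],
    condition: str | None = None,
) -> pd.Series:
    """Winning group per marker: argmax of per-group median expression.

    Markers tied for the maximum are excluded (logged). Markers absent from
    the matrix are dropped with a warning.
    """
    groups = sorted(set(metadata.table["group"]))
    if len(groups) < 2:
        raise JointnetError("need >= 2 groups")
    markers = _present_markers(expression, markers)
    cols = {g: [s for s in metadata.samples_in(group=g, condition=condition)
                if s in expression.sample_ids] for g in groups}
    med = pd.DataFrame(
        {g: expression.values.loc[markers, cols[g]].median(axis=1) for g in groups}
    )
    winners = {}
    n_ties = 0
    for m in markers:
        row = med.loc[m]
        top = row.max()
        best = [g for g in groups if row[g] == top]
        if len(best) > 1:
            n_ties += 1
            continue
        winners[m] = best[0]
    if n_ties:
        warn_logged(f"excluding {n_ties} markers with tied group medians")
    return pd.Series(winners, dtype=object)


def activation_ratio(
    assignments: pd.Series,
    panel: MarkerPanel,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-group ratio of activated to resting markers won.

    The pseudocount enters only when a group's resting (denominator) or
    activated count is zero, preserving plain A/R arithmetic otherwise; a
    group that wins nothing gets the neutral ratio 1.
    """
    activated = set(panel.activated)
    resting = set(panel.resting)
    groups = sorted(set(assignments.values))
    out = {}
    for g in groups:
        won = assignments[assignments == g].index
        a = sum(1 for m in won if m in activated)
        r = sum(1 for m in won if m in resting)
        if a > 0 and r > 0:
            out[g] = a / r
        else:
            out[g] = (a + pseudocount) / (r + pseudocount)
    return pd.Series(out)


def _ratio_stat_vectorized(
    winner_codes: np.ndarray,      # (M, n_markers) int codes
    is_activated: np.ndarray,      # (n_markers,) bool
    code_i: int,
    code_j: int,
    pseudocount: float,
) -> np.ndarray:
    stats = np.empty(len(winner_codes))
    for idx, code in enumerate((code_i, code_j)):
        won = winner_codes == code
        a = (won & is_activated[None, :]).sum(axis=1).astype(float)
        r = (won & ~is_activated[None, :]).sum(axis=1).astype(float)
        plain = a > 0
        plain &= r > 0
        ratio = np.where(plain, a / np.where(r > 0, r, 1.0),
                         (a + pseudocount) / (r + pseudocount))
        stats = stats - ratio if idx == 1 else ratio.copy()
    return stats


def activation_ratio_test(
    expression: ExpressionMatrix,
    metadata: SampleMetadata,
    panel: MarkerPanel,
    group_i: str,
    group_j: str,
    config: PermutationConfig = PermutationConfig(),
    condition: str | None = None,
    restrict_to: Sequence[str] | None = None,
    pseudocount: float = 0.5,
) -> PermutationResult:
    """Permutation test of Ratio_i - Ratio_j on activated/resting markers.

    The null permutes the observed per-marker winner labels across markers;
    ``restrict_to`` (e.g. called DEGs for marker_subset='degs_only')
    restricts the panels first.
    """
    if group_i == group_j:
        raise JointnetError("group_i and group_j must differ")
    activated, resting = panel.activated, panel.resting
    if restrict_to is not None:
        keep = set(restrict_to)
        activated = [m for m in activated if m in keep]
        resting = [m for m in resting if m in keep]
    markers = list(activated) + list(resting)
    assignments = max_joint_assignment(expression, metadata, markers, condition=condition)
    if len(assignments) < 2:
        raise JointnetError("fewer than 2 markers with a unique winning group")

    sub_panel = MarkerPanel(activated=activated, resting=resting)
    ratios = activation_ratio(assignments, sub_panel, pseudocount)
    obs = float(ratios.get(group_i, 1.0) - ratios.get(group_j, 1.0))

    groups = sorted(set(metadata.table["group"]))
    code = {g: k for k, g in enumerate(groups)}
    winner_codes = np.array([code[g] for g in assignments.values])
    is_activated = np.array([m in set(activated) for m in assignments.index])

    rng = np.random.default_rng(config.seed)
    perms = rng.permuted(np.tile(winner_codes, (config.M, 1)), axis=1)
    null = _ratio_stat_vectorized(perms, is_activated, code[group_i], code[group_j], pseudocount)
    p = permutation_pvalue(obs, null, config.direction)
    return PermutationResult(obs, null, p, (group_i, group_j), config,
                             detail={"ratios": ratios.to_dict(),
                                     "n_markers": len(assignments)})


def _exhaustive_ratio_null(
    winner_codes: np.ndarray,
    is_activated: np.ndarray,
    code_i: int,
    code_j: int,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """All distinct orderings of the winner-label multiset (small inputs only)."""
    from itertools import permutations

    perms = np.array(sorted(set(permutations(winner_codes.tolist()))))
    return _ratio_stat_vectorized(perms, is_activated, code_i, code_j, pseudocount)


def _stratified_shuffle(labels: np.ndarray, strata: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = labels.copy()
    for s in np.unique(strata):
        idx = np.nonzero(strata == s)[0]
        out[idx] = labels[idx][rng.permutation(len(idx))]
    return out


def cumulative_induction_test(
    expression: ExpressionMatrix,
    metadata: SampleMetadata,
    gene_list: Sequence[str],
    group_i: str,
    group_j: str,
    config: PermutationConfig = PermutationConfig(),
    condition: str | None = None,
) -> PermutationResult:
    """Permutation test of summed per-gene group medians, group i minus j.

    The null shuffles sample-level group labels; when samples span several
    conditions the shuffle is stratified within condition. ``condition``
    restricts the test to that condition's samples first.
    """
    if group_i == group_j:
        raise JointnetError("group_i and group_j must differ")
    genes = _present_markers(expression, gene_list)
    if not genes:
        raise JointnetError("gene list empty after intersection with expression matrix")
    meta = metadata.table
    samples = [s for s in expression.sample_ids if s in meta.index]
    if condition is not None:
        samples = [s for s in samples if meta.loc[s, "condition"] == condition]
    labels = meta.loc[samples, "group"].to_numpy()
    strata = meta.loc[samples, "condition"].to_numpy()
    for g in (group_i, group_j):
        if (labels == g).sum() < 2:
            raise JointnetError(f"group '{g}' has < 2 samples")
    vals = expression.values.loc[genes, samples].to_numpy(dtype=float)

    def stat(lab: np.ndarray) -> float:
        mi = np.median(vals[:, lab == group_i], axis=1).sum()
        mj = np.median(vals[:, lab == group_j], axis=1).sum()
        return float(mi - mj)

    obs = stat(labels)
    rng = np.random.default_rng(config.seed)
    null = np.array([stat(_stratified_shuffle(labels, strata, rng)) for _ in range(config.M)])
    p = permutation_pvalue(obs, null, config.direction)
    return PermutationResult(obs, null, p, (group_i, group_j), config,
                             detail={"n_genes": len(genes), "n_samples": len(samples)})


def _exhaustive_induction_null(
    values: np.ndarray, labels: np.ndarray, group_i: str, group_j: str
) -> np.ndarray:
    """Statistic over all distinct label orderings (small inputs only)."""
    from itertools import permutations

    stats = []
    for perm in sorted(set(permutations(labels.tolist()))):
        lab = np.array(perm)
        mi = np.median(values[:, lab == group_i], axis=1).sum()
        mj = np.median(values[:, lab == group_j], axis=1).sum()
        stats.append(mi - mj)
    return np.array(stats)
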