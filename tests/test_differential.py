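from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from jointnet.differential import (
    assign_peaks_to_genes,
    bh_adjust,
    build_peak_matrix,
    call_dars,
    call_degs,
    differential_pagerank,
    hypergeometric_enrichment,
    normalize_peak_matrix,
    regulatee_profiles,
    wilcoxon_rank_sum,
)
from jointnet.io import ExpressionMatrix, JointnetError, PeakSet, SampleMetadata
from jointnet.pagerank import ConsensusEdgeSet, PageRankTable


# --- Wilcoxon rank-sum ---

def exact_wilcoxon_two_sided(x, y):
    """Oracle: enumerate all rank assignments of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    rx = ranks[: len(x)].sum()
    nx = len(x)
    stats = [sum(c) for c in combinations(ranks, nx)]
    stats = np.asarray(stats)
    mu = stats.mean()
    p = (np.abs(stats - mu) >= abs(rx - mu) - 1e-12).mean()
    return p


def test_wilcoxon_textbook_example():
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]).p_value == pytest.approx(0.1)


@pytest.mark.parametrize("nx,ny,seed", [(2, 2, 0), (3, 2, 1), (3, 3, 2), (4, 3, 3),
                                        (4, 4, 4), (5, 4, 5), (5, 5, 6)])
def test_wilcoxon_matches_exhaustive_enumeration(nx, ny, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=nx)
    y = rng.normal(1.0, size=ny)   # tie-free with probability 1
    got = wilcoxon_rank_sum(x, y).p_value
    assert got == pytest.approx(exact_wilcoxon_two_sided(x, y), abs=1e-12)


def test_wilcoxon_degenerate_constant_groups():
    r = wilcoxon_rank_sum([5, 5, 5], [5, 5, 5])
    assert r.p_value == 1.0 and r.degenerate


def test_wilcoxon_two_sided_symmetry():
    x, y = [1.2, 3.4, 2.2, 8.0], [4.1, 5.0, 0.3]
    assert wilcoxon_rank_sum(x, y).p_value == pytest.approx(wilcoxon_rank_sum(y, x).p_value)


def test_wilcoxon_requires_two_per_group():
    with pytest.raises(JointnetError):
        wilcoxon_rank_sum([1.0], [2.0, 3.0])


# --- BH adjustment ---

def test_bh_worked_example():
    # step-up with monotonicity: (.01,.02,.04,.8) -> (.04,.04,.05333...,.8)
    adj = bh_adjust([0.01, 0.02, 0.04, 0.8])
    assert np.allclose(adj, [0.04, 0.04, 0.16 / 3, 0.8])


from hypothesis import given, settings
from hypothesis import strategies as hst


@settings(max_examples=50, derandomize=True, deadline=None)
@given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_bh_properties_hold_for_any_pvector(p):
    adj = bh_adjust(p)
    assert ((adj >= np.asarray(p) - 1e-12) & (adj <= 1.0 + 1e-12)).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_bh_monotone_and_dominating():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=40)
    adj = bh_adjust(p)
    assert (adj >= p - 1e-15).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-15).all()


# --- hypergeometric enrichment ---

def test_hypergeometric_closed_form():
    # N=10, K=5, n=3, k=3: p = C(5,3)/C(10,3) = 1/12
    uni = [f"g{i}" for i in range(10)]
    tab = hypergeometric_enrichment(uni[:3], {"S": uni[:5]}, uni)
    assert tab["p_value"].iloc[0] == pytest.approx(1 / 12)
    assert tab["overlap"].iloc[0] == 3


def test_hypergeometric_full_set_and_zero_overlap():
    uni = [f"g{i}" for i in range(10)]
    tab = hypergeometric_enrichment(uni[:4], {"ALL": uni, "NONE": uni[6:]}, uni)
    assert tab.set_index("set_id").loc["ALL", "p_value"] == pytest.approx(1.0)
    # k = 0: P(X >= 0) = 1
    tab0 = hypergeometric_enrichment(uni[:4], {"DISJ": uni[4:6]}, uni[:6])
    assert tab0["p_value"].iloc[0] <= 1.0
    none_row = tab.set_index("set_id").loc["NONE"]
    assert none_row["overlap"] == 0 and none_row["p_value"] == pytest.approx(1.0)


def test_hypergeometric_rejects_empty():
    with pytest.raises(JointnetError):
        hypergeometric_enrichment([], {"S": ["a"]}, ["a"])
    with pytest.raises(JointnetError):
        hypergeometric_enrichment(["a"], {"S": ["a"]}, [])


# --- DEG calling ---

def _toy_meta(groups, condition="unstim"):
    rows = [(f"{g}{i}", g, condition, f"{g}{i}") for g in groups for i in range(4)]
    return SampleMetadata(pd.DataFrame(
        rows, columns=["sample_id", "group", "condition", "subject_id"]).set_index("sample_id"))


def test_deg_fold_change_gate_blocks_small_effects():
    meta = _toy_meta(["a", "b"])
    rng = np.random.default_rng(1)
    # |log2fc| ~ 0.49 < 0.58 with clearly separated groups
    a_vals = 100 * 2**0.5 + rng.normal(0, 0.5, 4)
    b_vals = 100 + rng.normal(0, 0.5, 4)
    values = pd.DataFrame([np.concatenate([a_vals, b_vals])],
                          index=["g1"], columns=meta.sample_ids)
    expr = ExpressionMatrix(values)
    tab = call_degs(expr, meta, "a", "b")
    assert tab["p_value"].iloc[0] < 0.05
    assert abs(tab["log2fc"].iloc[0]) < 0.58
    assert not tab["called"].iloc[0]


def test_deg_constant_gene_not_called():
    meta = _toy_meta(["a", "b"])
    expr = ExpressionMatrix(pd.DataFrame(
        [[7.0] * 8], index=["g1"], columns=meta.sample_ids))
    tab = call_degs(expr, meta, "a", "b")
    assert not tab["called"].iloc[0] and tab["p_value"].iloc[0] == 1.0


def test_deg_unknown_group_rejected(small_bundle):
    with pytest.raises(JointnetError, match="unknown group"):
        call_degs(small_bundle.expression, small_bundle.metadata, "elbow", "hip")


def test_planted_degs_recovered(small_bundle):
    b = small_bundle
    tab = call_degs(b.expression, b.metadata, "hand", "hip", condition="unstim")
    eff = b.truth["expression_effects"]
    planted = set(eff[(eff.group == "hand") & (eff.condition == "*")].gene_id)
    called = set(tab.loc[tab.called, "feature_id"])
    assert len(planted & called) / len(planted) >= 0.8


# --- DAR calling ---

def _peakset(sid, rows):
    return PeakSet(sid, pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "intensity", "summit_offset"]))


def test_peak_matrix_merges_overlapping_intervals():
    ps1 = _peakset("s1", [("chr1", 100, 200, "a", 2.0, -1), ("chr1", 400, 500, "b", 1.0, -1)])
    ps2 = _peakset("s2", [("chr1", 150, 260, "c", 3.0, -1)])
    mat, cons = build_peak_matrix([ps1, ps2])
    assert list(cons["start"]) == [100, 400] and list(cons["end"]) == [260, 500]
    assert mat.loc["chr1:100-260", "s1"] == 2.0
    assert mat.loc["chr1:100-260", "s2"] == 3.0
    assert mat.loc["chr1:400-500", "s2"] == 0.0


def test_normalize_peak_matrix_equalizes_totals():
    mat = pd.DataFrame({"s1": [1.0, 3.0], "s2": [4.0, 12.0]}, index=["p1", "p2"])
    norm = normalize_peak_matrix(mat)
    assert np.allclose(norm.sum(axis=0), norm.sum(axis=0).iloc[0])


def test_identical_intensity_profiles_yield_no_dars(small_bundle):
    meta = _toy_meta(["a", "b"])
    mat = pd.DataFrame(
        np.tile([[10.0], [5.0], [2.0]], (1, 8)), index=["p1", "p2", "p3"],
        columns=meta.sample_ids)
    tab = call_dars(mat, meta, "a", "b")
    assert not tab["called"].any()


def test_planted_dars_recovered(small_bundle):
    b = small_bundle
    mat, cons = build_peak_matrix(b.peaksets)
    tab = call_dars(mat, b.metadata, "hand", "hip", condition="unstim")
    truth = b.truth["peaks"]
    hand_peaks = set(truth.loc[truth.group == "hand", "peak_name"])
    # map planted peak names to consensus ids via coordinates
    coords = {ps_name: None for ps_name in hand_peaks}
    rec = b.peaksets[0].records.set_index("name")
    called = set(tab.loc[tab.called, "feature_id"])
    hits = 0
    for name in hand_peaks:
        r = rec.loc[name]
        pid = cons[(cons["chrom"] == r["chrom"]) & (cons["start"] <= r["start"])
                   & (cons["end"] >= r["end"])]["peak_id"]
        if len(pid) and pid.iloc[0] in called:
            hits += 1
    assert hits / len(hand_peaks) >= 0.8


# --- differential PageRank ---

def test_identical_pagerank_scores_not_called():
    meta = _toy_meta(["a", "b"])
    scores = pd.DataFrame(np.tile([[0.3], [0.2]], (1, 8)),
                          index=["TF1", "TF2"], columns=meta.sample_ids)
    tab = differential_pagerank(PageRankTable(scores, 0.85, 1e-10, {}), meta, "a", "b")
    assert not tab["called"].any()


def test_all_zero_tf_rows_skipped():
    meta = _toy_meta(["a", "b"])
    scores = pd.DataFrame(
        np.vstack([np.zeros(8), np.linspace(0.1, 0.8, 8)]),
        index=["DEAD", "LIVE"], columns=meta.sample_ids)
    with pytest.warns(UserWarning, match="all-zero"):
        tab = differential_pagerank(PageRankTable(scores, 0.85, 1e-10, {}), meta, "a", "b")
    assert tab["feature_id"].tolist() == ["LIVE"]


def test_planted_tf_differential_direction(small_bundle, small_networks):
    from jointnet.pagerank import pagerank_table

    b = small_bundle
    tab = pagerank_table(list(small_networks.values()), tf_ids=sorted(b.motifs.pwms))
    d = differential_pagerank(tab, b.metadata, "hand", "hip", condition="unstim")
    row = d.set_index("feature_id").loc["TF001"]
    assert row["called"] and row["direction"] == 1


# --- regulatee profiles ---

def _consensus(edges):
    return ConsensusEdgeSet(("g", "c"), pd.DataFrame(
        edges, columns=["tf", "gene", "fraction", "median_weight"]), 0.7, 10)


def _result_table(features, called):
    return pd.DataFrame({"feature_id": features, "called": [f in called for f in features]})


def test_regulatee_deg_intersection():
    cs = _consensus([("TF1", "g1", 0.8, 0.5), ("TF1", "g2", 0.9, 0.4), ("TF1", "g3", 1.0, 0.3)])
    deg = _result_table(["g1", "g2", "g3"], {"g1", "g2"})
    prof = regulatee_profiles(["TF1"], cs, deg, _result_table([], set()))
    assert prof.deg_overlap["TF1"] == {"g1", "g2"}
    assert prof.union == {"TF1", "g1", "g2"}


def test_regulatee_dar_overlap_via_region_map():
    cs = _consensus([("TF1", "g1", 0.8, 0.5)])
    dar = _result_table(["chr1:0-100"], {"chr1:0-100"})
    prof = regulatee_profiles(["TF1"], cs, _result_table([], set()), dar,
                              region_gene_map={"chr1:0-100": ["g1"]})
    assert prof.dar_overlap["TF1"] == {"g1"}


def test_tf_without_called_regulatees_contributes_itself():
    cs = _consensus([("TF1", "g1", 0.8, 0.5)])
    prof = regulatee_profiles(["TF1"], cs, _result_table(["g1"], set()),
                              _result_table([], set()))
    assert prof.union == {"TF1"}


def test_empty_diff_tf_list_gives_empty_profile():
    prof = regulatee_profiles([], _consensus([]), _result_table([], set()),
                              _result_table([], set()))
    assert prof.union == set() and prof.deg_overlap == {}


def test_assign_peaks_to_genes(small_bundle):
    from jointnet.network import assign_regulatory_regions

    b = small_bundle
    rm = assign_regulatory_regions(b.annotation, b.interactions)
    mat, cons = build_peak_matrix(b.peaksets)
    mapping = assign_peaks_to_genes(cons, rm)
    # every promoter peak maps back to (at least) its own gene
    rec = b.peaksets[0].records
    prom = rec[rec["name"].str.endswith("_prom")]
    for r in prom.itertuples(index=False):
        pid = cons[(cons["chrom"] == r.chrom) & (cons["start"] <= r.start)
                   & (cons["end"] >= r.end)]["peak_id"].iloc[0]
        assert r.name.removesuffix("_prom") in mapping[pid]
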