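import warnings

import numpy as np
import pandas as pd
import pytest

from jointnet.io import (
    EPInteractions,
    ExpressionMatrix,
    GenomeAnnotation,
    JointnetError,
    MotifLibrary,
    PeakSet,
)
from jointnet.network import (
    NetworkParams,
    assign_regulatory_regions,
    build_network,
    compute_edge_weight,
    scan_motifs,
)

RC = str.maketrans("ACGT", "TGCA")


def _one_hot(seq: str, major: float = 0.997) -> np.ndarray:
    minor = (1.0 - major) / 3.0
    pwm = np.full((len(seq), 4), minor)
    for i, b in enumerate(seq):
        pwm[i, "ACGT".index(b)] = major
    return pwm


def _annot(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "is_tf"])
    return GenomeAnnotation(df.set_index("gene_id"))


# --- regulatory region assignment ---

def test_promoter_window_plus_strand():
    ann = _annot([("g", "chr1", 10_000, 10_600, "+", False)])
    rm = assign_regulatory_regions(ann, promoter_window=(5000, 1000))
    (prom,) = rm["g"]
    assert (prom.start, prom.end, prom.kind) == (5000, 11_000, "promoter")


def test_promoter_window_minus_strand_mirrored():
    # tss = end - 1 = 10000; promoter = [tss-down, tss+up)
    ann = _annot([("g", "chr1", 9_500, 10_001, "-", False)])
    rm = assign_regulatory_regions(ann, promoter_window=(5000, 1000))
    (prom,) = rm["g"]
    assert (prom.start, prom.end) == (9_000, 15_000)


def test_interaction_enhancer_attached_to_target():
    ann = _annot([("G", "chr1", 100_000, 100_600, "+", False)])
    ep = EPInteractions(pd.DataFrame(
        [("chr1", 5000, 6000, "G", 1.0)],
        columns=["chrom", "start", "end", "gene_id", "confidence"]))
    rm = assign_regulatory_regions(ann, ep)
    kinds = {(r.kind, r.source) for r in rm["G"]}
    assert ("enhancer", "interaction") in kinds
    enh = [r for r in rm["G"] if r.kind == "enhancer"][0]
    assert (enh.start, enh.end) == (5000, 6000)


def test_interaction_to_unknown_gene_skipped_with_warning():
    ann = _annot([("G", "chr1", 100_000, 100_600, "+", False)])
    ep = EPInteractions(pd.DataFrame(
        [("chr1", 5000, 6000, "NOPE", 1.0)],
        columns=["chrom", "start", "end", "gene_id", "confidence"]))
    with pytest.warns(UserWarning, match="skipped 1"):
        rm = assign_regulatory_regions(ann, ep)
    assert all(r.kind == "promoter" for r in rm["G"])


def test_distance_fallback_attaches_nearby_peaks():
    ann = _annot([("G", "chr1", 100_000, 100_600, "+", False)])
    peaks = PeakSet("s", pd.DataFrame(
        [("chr1", 70_000, 70_400, "near", 5.0, -1),
         ("chr1", 900_000, 900_400, "far", 5.0, -1)],
        columns=["chrom", "start", "end", "name", "intensity", "summit_offset"]))
    rm = assign_regulatory_regions(ann, None, peaks=peaks, enhancer_max_dist=50_000)
    enh = [r for r in rm["G"] if r.kind == "enhancer"]
    assert [(r.start, r.end) for r in enh] == [(70_000, 70_400)]


# --- motif scanning ---

def test_scan_perfect_match_forward():
    hits = scan_motifs("ACGT", _one_hot("ACGT"), rel_threshold=0.8)
    assert len(hits) == 1
    h = hits[0]
    assert (h.start, h.strand) == (0, "+")
    assert h.rel_score == pytest.approx(1.0)


def test_scan_perfect_match_reverse_strand():
    # AAAC on the minus strand of GTTT
    hits = scan_motifs("GTTT", _one_hot("AAAC"), rel_threshold=0.8)
    assert len(hits) == 1
    assert hits[0].strand == "-"
    assert hits[0].rel_score == pytest.approx(1.0)


def test_scan_short_or_ambiguous_sequence():
    pwm = _one_hot("ACGT")
    assert scan_motifs("NN", pwm) == []
    assert scan_motifs("ACG", pwm) == []


def _brute_force_scan(seq, pwm, background, rel_threshold):
    """Independent oracle: per-offset, per-strand log-odds by explicit loops."""
    L = len(pwm)
    lo = np.log2(pwm / background[None, :])
    smin = sum(min(lo[j, :4]) for j in range(L))
    smax = sum(max(lo[j, :4]) for j in range(L))

    def score(sub):
        s = 0.0
        for j, b in enumerate(sub):
            s += 0.0 if b == "N" else lo[j, "ACGT".index(b)]
        return s

    out = []
    for off in range(len(seq) - L + 1):
        sub = seq[off:off + L]
        fwd = score(sub)
        rev = score(sub.translate(RC)[::-1])
        best, strand = (fwd, "+") if fwd >= rev else (rev, "-")
        rel = (best - smin) / (smax - smin)
        if rel >= rel_threshold:
            out.append((off, strand, round(best, 9)))
    return out


@pytest.mark.parametrize("seed", range(5))
def test_scan_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=200))
    pwm = np.asarray(rng.dirichlet(np.full(4, 0.5), size=6))
    pwm = np.maximum(pwm, 1e-3)
    pwm /= pwm.sum(axis=1, keepdims=True)
    bg = np.full(4, 0.25)
    expected = _brute_force_scan(seq, pwm, bg, 0.7)
    got = [(h.start, h.strand, round(h.log_odds_score, 9))
           for h in scan_motifs(seq, pwm, bg, 0.7)]
    assert got == expected


# --- edge weights ---

@pytest.mark.parametrize("comps,expected", [
    ((1.0, 1.0, 1.0), 1.0),
    ((0.0, 0.9, 0.9), 0.0),
    ((0.5, 0.5, 0.5), 0.5),
])
def test_edge_weight_geometric(comps, expected):
    assert compute_edge_weight(*comps) == pytest.approx(expected)


def test_edge_weight_rejects_out_of_range():
    with pytest.raises(JointnetError):
        compute_edge_weight(1.2, 0.5, 0.5)


def test_edge_weight_alternative_combiners():
    assert compute_edge_weight(0.5, 0.5, 0.5, method="product") == pytest.approx(0.125)
    assert compute_edge_weight(0.2, 0.4, 0.6, method="arithmetic") == pytest.approx(0.4)


# --- network assembly on a constructed fixture ---

@pytest.fixture
def tiny_fixture():
    """One TF with a planted consensus motif in gene G's open promoter."""
    consensus = "ACGTACGT"
    genome = {"chr1": "T" * 9_000 + consensus + "T" * 25_000}
    ann = _annot([
        ("TF_A", "chr1", 500, 1_100, "+", True),
        ("G", "chr1", 9_500, 10_100, "+", False),    # tss 9500, motif at 9000
        ("LONER", "chr1", 30_000, 30_400, "+", False),  # no peak near its promoter
    ])
    motifs = MotifLibrary({"TF_A": _one_hot(consensus)})
    peaks = PeakSet("s1", pd.DataFrame(
        [("chr1", 8_900, 9_300, "pkG", 7.0, -1)],
        columns=["chrom", "start", "end", "name", "intensity", "summit_offset"]))
    expr = ExpressionMatrix(pd.DataFrame(
        {"s1": [10.0, 5.0, 3.0]}, index=["TF_A", "G", "LONER"]))
    rm = assign_regulatory_regions(ann, promoter_window=(5000, 1000))
    return genome, ann, motifs, peaks, expr, rm


def test_planted_edge_is_found(tiny_fixture):
    genome, ann, motifs, peaks, expr, rm = tiny_fixture
    net = build_network("s1", expr, peaks, rm, motifs, genome)
    assert net.edge_set() == {("TF_A", "G")}
    e = net.edges.iloc[0]
    assert e["peak"] == "pkG" and e["hit_pos"] == 9_000 and e["hit_strand"] == "+"
    assert 0 < e["weight"] <= 1


def test_zero_expression_tf_makes_no_edges(tiny_fixture):
    genome, ann, motifs, peaks, expr, rm = tiny_fixture
    expr0 = ExpressionMatrix(expr.values.copy())
    expr0.values.loc["TF_A", "s1"] = 0.0
    with pytest.warns(UserWarning, match="no edges"):
        net = build_network("s1", expr0, peaks, rm, motifs, genome)
    assert net.edge_set() == set()


def test_gene_without_open_region_is_isolated_node(tiny_fixture):
    genome, ann, motifs, peaks, expr, rm = tiny_fixture
    net = build_network("s1", expr, peaks, rm, motifs, genome)
    assert net.nodes["LONER"] == 3.0
    assert "LONER" not in set(net.edges["gene"])


def test_raising_peak_intensity_never_decreases_its_edges(small_bundle):
    b = small_bundle
    from jointnet.network import assign_regulatory_regions as arr

    rm = arr(b.annotation, b.interactions)
    ps = b.peaksets[0]
    cache = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net0 = build_network(ps.sample_id, b.expression, ps, rm, b.motifs, b.genome,
                             NetworkParams(), cache)
        bumped = ps.records.copy()
        target_peak = net0.edges["peak"].iloc[0]
        bumped.loc[bumped["name"] == target_peak, "intensity"] *= 10
        ps2 = PeakSet(ps.sample_id, bumped)
        net1 = build_network(ps.sample_id, b.expression, ps2, rm, b.motifs, b.genome,
                             NetworkParams(), cache)
    w0 = net0.edges[net0.edges["peak"] == target_peak].set_index(["tf", "gene"])["weight"]
    w1 = net1.edges.set_index(["tf", "gene"])["weight"]
    joined = w1.reindex(w0.index)
    assert (joined >= w0 - 1e-12).all()


def test_planted_program_edges_exist_in_target_group(small_bundle, small_networks):
    b = small_bundle
    truth = b.truth["edges"]
    meta = b.metadata.table
    for group in ("hand", "hip", "knee"):
        planted = set(zip(truth.loc[truth.target_group == group, "tf_id"],
                          truth.loc[truth.target_group == group, "gene_id"]))
        for sid in meta.index[(meta["group"] == group)]:
            assert planted <= small_networks[sid].edge_set()


def test_networks_deterministic(small_bundle):
    b = small_bundle
    rm = assign_regulatory_regions(b.annotation, b.interactions)
    ps = b.peaksets[0]
    n1 = build_network(ps.sample_id, b.expression, ps, rm, b.motifs, b.genome)
    n2 = build_network(ps.sample_id, b.expression, ps, rm, b.motifs, b.genome)
    pd.testing.assert_frame_equal(n1.edges, n2.edges)
    pd.testing.assert_series_equal(n1.nodes, n2.nodes)
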