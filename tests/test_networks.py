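"""Peak-to-gene assignment, GRN construction and network comparisons."""

import numpy as np
import pandas as pd
import pytest

import grnrewire as gr
from grnrewire.diff import CountMatrix
from grnrewire.intervals import GeneModels, PeakSet
from grnrewire.networks import (
    GRN,
    assign_peaks_to_genes,
    build_grn,
    degree_and_delta,
    network_overlap,
    summarize_tfs,
    tf_tf_projection,
)
from grnrewire.simulate import replace, simulate_study

from conftest import GRN_CFG, edge_f1


def _genes(rows):
    return GeneModels(pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tes"]))


def _peaks(rows):
    return PeakSet("p", pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "summit"]))


# ---------------------------------------------------------------- assignment


def test_summit_at_tss_assigns_with_zero_distance():
    genes = _genes([("g1", "chr1", "+", 5000, 9000)])
    peaks = _peaks([("chr1", 4800, 5200, "pk", 5000)])
    out = assign_peaks_to_genes(peaks, genes)
    assert out.iloc[0]["gene"] == "g1"
    assert out.iloc[0]["distance"] == 0
    assert out.iloc[0]["assignment"] == "promoter"


def test_promoter_boundary_is_half_open():
    genes = _genes([("g1", "chr1", "+", 50_000, 55_000)])
    for summit, expected in ((50_000 - 3000, "promoter"), (50_000 + 2999, "promoter"),
                             (50_000 + 3000, "distal"), (50_000 + 3001, "distal")):
        peaks = _peaks([("chr1", summit - 100, summit + 100, "pk", summit)])
        assert assign_peaks_to_genes(peaks, genes).iloc[0]["assignment"] == expected


def test_far_peak_unassigned():
    genes = _genes([("g1", "chr1", "+", 5000, 9000)])
    peaks = _peaks([("chr1", 150_000, 150_400, "pk", 150_200)])
    out = assign_peaks_to_genes(peaks, genes, max_distal=100_000)
    assert out.iloc[0]["assignment"] == "unassigned"
    assert pd.isna(out.iloc[0]["gene"])


@pytest.mark.parametrize("seed", range(5))
def test_assignment_matches_brute_force_all_pairs(seed):
    rng = np.random.default_rng(seed)
    genes = _genes([
        (f"g{i}", "chr1", "+", int(t), int(t) + 2000)
        for i, t in enumerate(np.sort(rng.choice(500_000, 30, replace=False)))
    ])
    summits = rng.integers(0, 500_000, 80)
    peaks = _peaks([
        ("chr1", s - 50, s + 50, f"pk{i}", int(s)) for i, s in enumerate(summits)
    ])
    got = assign_peaks_to_genes(peaks, genes).set_index("peak")
    tss = genes.df["tss"].values
    ids = genes.df["gene_id"].values
    for name, s in zip(peaks.df["name"], peaks.summits):
        d = np.abs(tss - s)
        j = int(d.argmin())
        row = got.loc[name]
        if tss[j] - 3000 <= s < tss[j] + 3000:
            assert row["assignment"] == "promoter" and row["gene"] == ids[j]
        elif d[j] <= 100_000:
            assert row["assignment"] == "distal" and row["gene"] == ids[j]
        else:
            assert row["assignment"] == "unassigned"


# ---------------------------------------------------------------- build_grn


def _tiny_inputs(corr_sign=1.0):
    """TF and target perfectly co-expressed, one linking peak, perfect hit."""
    samples = pd.DataFrame(
        {"condition": ["CON"] * 4, "replicate": [1, 2, 3, 4], "block": ["B1"] * 4},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
    )
    tf = np.array([10, 40, 160, 640])
    target = tf if corr_sign > 0 else tf[::-1]
    rna = CountMatrix(
        pd.DataFrame([tf, target, [7, 7, 7, 7]], index=["TF", "TG", "other"],
                     columns=samples.index),
        samples,
    )
    atac = CountMatrix(
        pd.DataFrame([[50, 50, 50, 50], [5, 5, 5, 5]], index=["pk1", "pk2"],
                     columns=samples.index),
        samples,
    )
    hits = pd.DataFrame(
        {"peak": ["pk1"], "motif": ["M"], "strand": ["+"], "offset": [0],
         "score": [10.0], "match_fraction": [1.0]}
    )
    p2g = pd.DataFrame({"peak": ["pk1", "pk2"], "gene": ["TG", "other"],
                        "distance": [0, 0], "assignment": ["promoter", "promoter"]})
    return rna, atac, hits, p2g


def test_perfect_edge_scores_one_and_is_retained():
    rna, atac, hits, p2g = _tiny_inputs()
    grn = build_grn(rna, atac, hits, p2g, {"TF": "M"}, "CON")
    assert len(grn) == 1
    e = grn.edges.iloc[0]
    assert (e["tf"], e["target"], e["peak"]) == ("TF", "TG", "pk1")
    assert e["score"] == pytest.approx(1.0)
    assert e["corr"] == pytest.approx(1.0)


def test_low_correlation_edge_dropped():
    rna, atac, hits, p2g = _tiny_inputs()
    # overwrite the target with a constant profile (zero variance -> corr 0)
    rna.counts.loc["TG"] = [100, 100, 100, 100]
    grn = build_grn(rna, atac, hits, p2g, {"TF": "M"}, "CON")
    assert len(grn) == 0


def test_fewer_than_three_samples_is_an_error():
    rna, atac, hits, p2g = _tiny_inputs()
    rna2 = CountMatrix(rna.counts.iloc[:, :2], rna.samples.iloc[:2])
    atac2 = CountMatrix(atac.counts.iloc[:, :2], atac.samples.iloc[:2])
    with pytest.raises(ValueError):
        build_grn(rna2, atac2, hits, p2g, {"TF": "M"}, "CON")


def test_retained_edges_satisfy_thresholds(grn_bundle):
    _, _, _, grns = grn_bundle
    for grn in grns.values():
        assert (grn.edges["score"] > 0.5).all()
        assert (grn.edges["corr"].abs() > 0.3).all()
        assert (grn.edges["tf"] != grn.edges["target"]).all()


def test_edge_recovery_f1(grn_bundle):
    b, _, _, grns = grn_bundle
    for cond in ("CON", "IND"):
        assert edge_f1(grns[cond], b.truth.true_edges[cond]) >= 0.8


def test_raising_thresholds_never_adds_edges(grn_bundle):
    b, hits, p2g, grns = grn_bundle
    stricter = build_grn(b.rna, b.atac, hits, p2g, b.truth.tf2motif, "CON",
                         score_threshold=0.65, corr_threshold=0.5)
    assert stricter.edge_keys() <= grns["CON"].edge_keys()


# ---------------------------------------------------------------- degrees


def _grn_from(edges, condition="CON"):
    df = pd.DataFrame(edges, columns=["tf", "target"])
    df["peak"] = "pk"
    df["score"] = 0.9
    df["corr"] = 0.9
    df["condition"] = condition
    return GRN(condition, df[["tf", "target", "peak", "score", "corr", "condition"]])


def test_degree_hand_computed_on_toy_network():
    # 5 nodes: t1 -> {a, b, c}, t2 -> {a}
    grn = _grn_from([("t1", "a"), ("t1", "b"), ("t1", "c"), ("t2", "a")])
    deg = degree_and_delta(grn, grn)
    assert deg.loc["t1", "degree_con"] == pytest.approx(3 / 4)
    assert deg.loc["t2", "degree_con"] == pytest.approx(1 / 4)
    assert np.allclose(deg["delta_degree"], 0.0)


def test_fully_connected_tf_has_degree_one():
    grn = _grn_from([("hub", t) for t in ("a", "b", "c")])
    deg = degree_and_delta(grn, GRN("IND"))
    assert deg.loc["hub", "degree_con"] == pytest.approx(1.0)
    assert deg.loc["hub", "degree_ind"] == 0.0  # absent -> 0, delta defined


def test_degree_invariant_under_node_relabelling():
    grn = _grn_from([("t1", "a"), ("t1", "b"), ("t2", "b"), ("t3", "c")])
    relabel = {n: f"x_{n}" for n in grn.nodes}
    df = grn.edges.copy()
    df["tf"] = df["tf"].map(relabel)
    df["target"] = df["target"].map(relabel)
    deg1 = degree_and_delta(grn, grn)["degree_con"]
    deg2 = degree_and_delta(GRN("CON", df), GRN("CON", df))["degree_con"]
    assert sorted(deg1.values) == sorted(deg2.values)


def test_replicate_networks_average_degrees():
    g1 = _grn_from([("t1", "a"), ("t1", "b"), ("t2", "c")])
    g2 = _grn_from([("t1", "a")])
    deg = degree_and_delta([g1, g2], g1)
    # g1: t1 -> 2/4; g2: t1 -> 1/1 (nodes t1, a only)
    assert deg.loc["t1", "degree_con"] == pytest.approx((2 / 4 + 1 / 1) / 2)


# ---------------------------------------------------------------- projection


def test_projection_weights_shared_targets():
    grn = _grn_from([("t1", "a"), ("t1", "b"), ("t2", "a"), ("t2", "b"), ("t3", "z")])
    g = tf_tf_projection(grn)
    assert g["t1"]["t2"]["weight"] == 2
    assert not g.has_edge("t1", "t3")


@pytest.mark.parametrize("seed", range(3))
def test_projection_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    edges = {(f"t{rng.integers(6)}", f"g{rng.integers(30)}") for _ in range(120)}
    grn = _grn_from(sorted(edges))
    g = tf_tf_projection(grn)
    targets = {}
    for tf, tg in edges:
        targets.setdefault(tf, set()).add(tg)
    for u in targets:
        for v in targets:
            if u < v:
                w = len(targets[u] & targets[v])
                assert (g.has_edge(u, v) and g[u][v]["weight"] == w) or w == 0


# ---------------------------------------------------------------- overlap


def test_overlap_identical_disjoint_and_arithmetic():
    a = _grn_from([("t", f"g{i}") for i in range(10)])
    assert network_overlap(a, a)["shared_fraction"] == pytest.approx(1.0)
    b = _grn_from([("t", f"h{i}") for i in range(10)])
    assert network_overlap(a, b)["shared_fraction"] == 0.0
    c = _grn_from([("t", f"g{i}") for i in range(5)] + [("t", f"h{i}") for i in range(5)])
    out = network_overlap(a, c)
    assert out["shared_fraction"] == pytest.approx(5 / 15)
    assert out["fraction_of_a"] == pytest.approx(0.5)
    assert out["fraction_of_b"] == pytest.approx(0.5)
    # symmetry of the union fraction
    assert network_overlap(c, a)["shared_fraction"] == out["shared_fraction"]


def test_overlap_of_empty_networks_is_undefined():
    with pytest.warns(UserWarning):
        out = network_overlap(GRN("CON"), GRN("IND"))
    assert np.isnan(out["shared_fraction"])


# ---------------------------------------------------------------- summaries


def test_tf_summary_grouping_and_missing_modalities():
    degrees = degree_and_delta(
        _grn_from([("t1", "a"), ("t2", "b")]), _grn_from([("t1", "a")], "IND")
    )
    diff_table = pd.DataFrame(
        {"log2fc": [2.5, -1.4], "padj": [0.001, 0.02], "status": ["up", "down"]},
        index=pd.Index(["t1", "t2"], name="feature"),
    )
    footcalls = pd.DataFrame({"motif": ["t1"], "delta": [0.4]})
    out = summarize_tfs(diff_table, footcalls, degrees)
    assert out.loc["t1", "group"] == "Activated"
    assert out.loc["t2", "group"] == "Repressed"
    assert out.loc["t1", "footprint_delta"] == 0.4
    assert "t2" in out.index and pd.isna(out.loc["t2", "footprint_delta"])


def test_rewired_tfs_have_larger_degree_shifts_across_replicates():
    """Mean |delta degree| of rewired TFs exceeds that of stable TFs over
    seeded replicate simulations."""
    rew, stable = [], []
    for seed in range(30, 40):
        cfg = replace(GRN_CFG, n_samples_per_condition=12, seed=seed)
        b = simulate_study(cfg, with_fragments=False)
        hits = gr.scan_peaks(b.pwms, b.genome, b.peaks, mode="best_central")
        p2g = assign_peaks_to_genes(b.peaks, b.genes)
        grns = {c: build_grn(b.rna, b.atac, hits, p2g, b.truth.tf2motif, c)
                for c in ("CON", "IND")}
        deg = degree_and_delta(grns["CON"], grns["IND"])
        absd = deg["delta_degree"].abs()
        rew += [absd.get(tf, 0.0) for tf in b.truth.rewired_tfs]
        stable += [absd.get(tf, 0.0) for tf in set(b.truth.tf2motif) - b.truth.rewired_tfs]
    assert np.mean(rew) > np.mean(stable)
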