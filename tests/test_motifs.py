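"""PWM construction, scanning rules, positional density, enrichment and
family clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import grnrewire as gr
from grnrewire.intervals import PeakSet
from grnrewire.motifs import (
    PWM,
    build_pwm,
    cluster_motifs,
    enrich_peakset,
    positional_density,
    pwm_similarity,
    read_jaspar,
    scan_peaks,
    scan_sequence,
    write_jaspar,
)
from grnrewire.simulate import default_pwm_panel


def _onehot_pfm(consensus: str, count: int = 100) -> np.ndarray:
    pfm = np.zeros((4, len(consensus)))
    for i, b in enumerate(consensus):
        pfm["ACGT".index(b), i] = count
    return pfm


def _genome_of(seqs: dict[str, str]) -> dict[str, str]:
    return seqs


def _peakset(names_and_centres, width=400, chrom="chr1"):
    rows = [
        (chrom, c - width // 2, c + width // 2, n, c) for n, c in names_and_centres
    ]
    return PeakSet("fg", pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "summit"]))


# ---------------------------------------------------------------- build_pwm


def test_uniform_pfm_gives_zero_logodds():
    pwm = build_pwm(np.full((4, 6), 25.0))
    assert np.allclose(pwm.logodds, 0.0)


def test_onehot_logodds_approach_two_bits_as_pseudocount_vanishes():
    pwm = build_pwm(_onehot_pfm("ACGT"), pseudocount=1e-9)
    hot = pwm.logodds.max(axis=0)
    assert np.allclose(hot, 2.0, atol=1e-6)


def test_zero_sum_column_rejected():
    pfm = _onehot_pfm("ACGT")
    pfm[:, 2] = 0
    with pytest.raises(ValueError):
        build_pwm(pfm)


def test_jaspar_round_trip(tmp_path):
    pwms = default_pwm_panel(4, width=10, seed=12)
    path = tmp_path / "panel.jaspar"
    write_jaspar(pwms, path)
    back = read_jaspar(str(path))
    assert [p.motif_id for p in back] == [p.motif_id for p in pwms]
    for a, b in zip(pwms, back):
        assert np.allclose(a.counts, b.counts)
        assert np.allclose(a.ppm, b.ppm)


# ---------------------------------------------------------------- scanning


def test_consensus_at_window_centre_is_single_central_hit():
    pwm = build_pwm(_onehot_pfm("ACGTACGTAC"))
    rng = np.random.default_rng(5)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, 400))
    mid = 200 - pwm.width // 2
    seq[mid : mid + pwm.width] = pwm.consensus()
    genome = _genome_of({"chr1": "".join(seq)})
    peaks = _peakset([("p1", 200)])
    hits = scan_peaks(pwm, genome, peaks, mode="best_central", threshold=0.99)
    assert len(hits) == 1
    assert hits.iloc[0]["offset"] == 0
    assert hits.iloc[0]["match_fraction"] == pytest.approx(1.0)


def test_absent_motif_at_full_threshold_gives_no_hits():
    pwm = build_pwm(_onehot_pfm("AAAAAAAAAA"))
    genome = _genome_of({"chr1": "CGTCGT" * 200})
    peaks = _peakset([("p1", 400)])
    assert len(scan_peaks(pwm, genome, peaks, threshold=1.0, mode="all")) == 0


def test_reverse_complement_scan_is_mirrored():
    from Bio.Seq import Seq

    pwm = default_pwm_panel(1, width=9, seed=3)[0]
    rng = np.random.default_rng(8)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
    rc = str(Seq(seq).reverse_complement())
    h_fwd = scan_sequence(pwm, seq, threshold=0.5)
    h_rev = scan_sequence(pwm, rc, threshold=0.5)
    L, w = len(seq), pwm.width
    fwd = {(p, s, round(sc, 9)) for p, s, sc in zip(h_fwd["pos"], h_fwd["strand"], h_fwd["score"])}
    mirrored = {
        (L - w - p, {"+": "-", "-": "+"}[s], round(sc, 9))
        for p, s, sc in zip(h_rev["pos"], h_rev["strand"], h_rev["score"])
    }
    assert fwd == mirrored and fwd


def test_match_fraction_invariant_to_column_shift():
    pwm = default_pwm_panel(1, width=8, seed=6)[0]
    seq = "".join("ACGT"[i] for i in np.random.default_rng(4).integers(0, 4, 60))
    base = scan_sequence(pwm, seq, threshold=0.0)
    shifted = PWM(pwm.motif_id, pwm.ppm.copy())
    shifted.logodds = pwm.logodds + 0.7  # constant added to every column
    after = scan_sequence(shifted, seq, threshold=0.0)
    assert np.allclose(
        np.sort(base["match_fraction"].values), np.sort(after["match_fraction"].values)
    )


def test_best_central_is_subset_of_all_and_prefers_centre(small_bundle):
    b = small_bundle
    all_hits = scan_peaks(b.pwms, b.genome, b.peaks, mode="all", threshold=0.7)
    best = scan_peaks(b.pwms, b.genome, b.peaks, mode="best_central", threshold=0.7)
    key = ["peak", "motif", "strand", "offset"]
    all_keys = set(map(tuple, all_hits[key].values))
    best_keys = set(map(tuple, best[key].values))
    assert best_keys <= all_keys
    # per peak x motif, kept hit minimises |offset|
    min_off = all_hits.assign(a=all_hits["offset"].abs()).groupby(["peak", "motif"])["a"].min()
    for rec in best.itertuples():
        assert abs(rec.offset) == min_off.loc[(rec.peak, rec.motif)]
    assert (best["match_fraction"] >= 0.7).all()
    assert (best["offset"].abs() <= 200).all()


# ---------------------------------------------------------------- density


def test_positional_density_mass_and_conservation():
    hits = pd.DataFrame({"offset": [0, 0, 5, -190, 199]})
    dens = positional_density(hits, n_peaks=10)
    assert dens.loc[0] == pytest.approx(0.3)  # offsets 0, 0, 5 in [0, 20)
    assert dens.sum() == pytest.approx(len(hits) / 10)
    assert list(dens.index) == list(range(-200, 200, 20))


def test_positional_density_uniform_offsets_are_flat():
    rng = np.random.default_rng(10)
    hits = pd.DataFrame({"offset": rng.integers(-200, 200, 4000)})
    dens = positional_density(hits, n_peaks=100)
    expected = 4000 / 20 / 100
    ci = 3 * np.sqrt(4000 * (1 / 20) * (19 / 20)) / 100
    assert ((dens - expected).abs() < ci).all()


# ---------------------------------------------------------------- enrichment


def test_enrichment_zero_when_background_equals_foreground():
    rng = np.random.default_rng(11)
    genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, 60_000))}
    peaks = _peakset([(f"p{i}", 300 + 600 * i) for i in range(30)], width=500)
    pwms = default_pwm_panel(3, width=10, seed=2)
    out = enrich_peakset(pwms, peaks, genome, bg_peaks=peaks)
    assert np.allclose(out["log2_enrichment"], 0.0)
    assert np.allclose(out["pvalue"], 1.0)


def test_planted_foreground_is_strongly_enriched():
    pwm = build_pwm(_onehot_pfm("ACGTACGTACGT"))
    rng = np.random.default_rng(12)
    chrom = list("ACGT"[i] for i in rng.integers(0, 4, 140_000))
    fg, bg = [], []
    for i in range(50):
        c = 500 + 1000 * i
        chrom[c - 6 : c + 6] = pwm.consensus()
        fg.append((f"fg{i}", c))
    for i in range(50):
        bg.append((f"bg{i}", 70_500 + 1000 * i))
    genome = {"chr1": "".join(chrom)}
    out = enrich_peakset(
        [pwm], _peakset(fg, width=500), genome, bg_peaks=_peakset(bg, width=500),
        threshold=0.95,
    )
    assert out.iloc[0]["log2_enrichment"] > 0
    assert out.iloc[0]["pvalue"] < 1e-6


def test_fisher_p_matches_hypergeometric_enumeration():
    """The 2x2 test on (40/10 vs 10/40) equals a brute-force two-sided
    hypergeometric enumeration."""
    hit_fg, miss_fg, hit_bg, miss_bg = 40, 10, 10, 40
    n, K, N = hit_fg + miss_fg, hit_fg + hit_bg, 100
    probs = hypergeom.pmf(np.arange(0, K + 1), N, K, n)
    p_obs = hypergeom.pmf(hit_fg, N, K, n)
    expected = probs[probs <= p_obs * (1 + 1e-9)].sum()
    from scipy.stats import fisher_exact

    _, got = fisher_exact([[hit_fg, miss_fg], [hit_bg, miss_bg]], alternative="two-sided")
    assert got == pytest.approx(expected, rel=1e-6)


# ---------------------------------------------------------------- clustering


def test_similarity_self_and_reverse_complement_are_one():
    pwm = default_pwm_panel(1, width=8, seed=7)[0]
    assert pwm_similarity(pwm, pwm) == pytest.approx(1.0)
    assert pwm_similarity(pwm, pwm.reverse_complement()) == pytest.approx(1.0)


def test_disjoint_onehots_are_anticorrelated_and_split():
    a = build_pwm(_onehot_pfm("AAAA"), motif_id="polyA")
    c = build_pwm(_onehot_pfm("CCCC"), motif_id="polyC")
    sim = pwm_similarity(a, c)
    assert sim < 0
    fams, order = cluster_motifs([a, c], similarity_threshold=0.8)
    assert fams.set_index("motif")["family"]["polyA"] != fams.set_index("motif")["family"]["polyC"]
    assert sorted(order) == ["polyA", "polyC"]


def test_cluster_groups_near_identical_motifs():
    base = default_pwm_panel(3, width=10, seed=9)
    twin = PWM(base[0].motif_id + "_rc", base[0].reverse_complement().ppm)
    fams, _ = cluster_motifs(base + [twin], similarity_threshold=0.8)
    by = fams.set_index("motif")["family"]
    assert by[base[0].motif_id] == by[twin.motif_id]


def test_cluster_rejects_tiny_input():
    pwm = default_pwm_panel(1, width=8, seed=1)[0]
    with pytest.raises(ValueError):
        cluster_motifs([pwm])
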