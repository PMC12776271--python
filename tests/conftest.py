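"""Shared simulation fixtures.

The heavier study scenarios are session-scoped so that module tests and the
acceptance suite reuse one generation each. Every scenario is fully
deterministic under its config seed.
"""

import warnings

import pandas as pd
import pytest

import grnrewire as gr
from grnrewire.simulate import SimConfig, simulate_study, truth_sites

warnings.filterwarnings("ignore", category=UserWarning)

# study scenario configs (fixed; see docs/methods.md for the rationale)
GRN_CFG = SimConfig(
    n_chroms=2, chrom_len=400_000, n_genes=90, n_peaks=140, n_tfs=8,
    n_samples_per_condition=16, rewire_fraction=0.25, targets_per_tf=8,
    de_fraction=0.0, dar_fraction=0.0, seed=5,
)
REWIRE_CFG = SimConfig(
    n_chroms=2, chrom_len=600_000, n_genes=110, n_peaks=160, n_tfs=10,
    n_samples_per_condition=16, rewire_fraction=0.1, targets_per_tf=6,
    de_fraction=0.0, dar_fraction=0.0, seed=8,
)
FOOTPRINT_CFG = SimConfig(
    n_chroms=2, chrom_len=600_000, n_genes=60, n_peaks=200, n_tfs=5,
    rewire_fraction=0.2, targets_per_tf=5, extra_sites_per_tf=35,
    n_unbound_tfs=3, n_samples_per_condition=2, footprint_protection=0.8,
    de_fraction=0.0, dar_fraction=0.0, frags_per_peak=200, seed=3,
)
DE_CFG = SimConfig(
    n_chroms=4, chrom_len=2_000_000, n_genes=1000, n_peaks=50, n_tfs=0,
    promoter_peak_fraction=1.0, de_fraction=0.1, de_lfc=2.0, dar_fraction=0.0,
    n_samples_per_condition=6, seed=13,
)
NULL_CFG = SimConfig(
    n_chroms=4, chrom_len=2_000_000, n_genes=2000, n_peaks=50, n_tfs=0,
    promoter_peak_fraction=1.0, de_fraction=0.0, dar_fraction=0.0,
    n_samples_per_condition=10, seed=11,
)
SMALL_CFG = SimConfig(
    n_chroms=1, chrom_len=200_000, n_genes=24, n_peaks=40, n_tfs=3,
    targets_per_tf=3, n_samples_per_condition=4, frags_per_peak=60, seed=1,
)


def footprint_profiles(bundle):
    """Per-condition insertion profiles over every planted motif site."""
    sites = truth_sites(bundle.truth, bundle.peaks)
    profiles = {c: {} for c in ("CON", "IND")}
    for cond in profiles:
        frags = bundle.fragments[bundle.fragments["condition"] == cond]
        for motif, sub in sites.groupby("motif"):
            profiles[cond][motif] = gr.insertion_profile(
                frags, sub, motif, condition=cond, motif_width=int(sub["width"].iloc[0])
            )
    return profiles


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_study(SMALL_CFG)


@pytest.fixture(scope="session")
def grn_bundle():
    b = simulate_study(GRN_CFG, with_fragments=False)
    hits = gr.scan_peaks(b.pwms, b.genome, b.peaks, mode="best_central")
    p2g = gr.assign_peaks_to_genes(b.peaks, b.genes)
    grns = {
        c: gr.build_grn(b.rna, b.atac, hits, p2g, b.truth.tf2motif, c)
        for c in ("CON", "IND")
    }
    return b, hits, p2g, grns


@pytest.fixture(scope="session")
def rewire_bundle():
    b = simulate_study(REWIRE_CFG, with_fragments=False)
    hits = gr.scan_peaks(b.pwms, b.genome, b.peaks, mode="best_central")
    p2g = gr.assign_peaks_to_genes(b.peaks, b.genes)
    grns = {
        c: gr.build_grn(b.rna, b.atac, hits, p2g, b.truth.tf2motif, c)
        for c in ("CON", "IND")
    }
    return b, grns


@pytest.fixture(scope="session")
def footprint_bundle():
    b = simulate_study(FOOTPRINT_CFG)
    return b, footprint_profiles(b)


@pytest.fixture(scope="session")
def de_bundle():
    return simulate_study(DE_CFG, with_fragments=False)


@pytest.fixture(scope="session")
def null_bundle():
    return simulate_study(NULL_CFG, with_fragments=False)


def edge_f1(grn, true_edges) -> float:
    pred = grn.edge_keys()
    tp = len(pred & true_edges)
    prec = tp / max(len(pred), 1)
    rec = tp / max(len(true_edges), 1)
    return 2 * prec * rec / max(prec + rec, 1e-12)


def toy_peakset(rng, n, name, chrom_len=100_000, max_len=400) -> gr.PeakSet:
    starts = rng.integers(0, chrom_len - max_len, n)
    lengths = rng.integers(50, max_len, n)
    return gr.PeakSet(
        name,
        pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts,
                "end": starts + lengths,
                "name": [f"{name}_{i}" for i in range(n)],
            }
        ),
    )
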