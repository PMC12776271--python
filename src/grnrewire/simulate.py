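"""Synthetic multi-omic study generator with planted ground truth.

Emulates a two-condition (CON vs IND), two-block (cell line) inducible-TF
experiment: a toy genome with gene models and non-overlapping peaks, PWM
consensus sites planted inside peaks, NB count matrices for RNA and ATAC with
planted differential features and block baseline offsets, ATAC fragment files
with protein-protected footprints over bound motifs, and a per-condition
ground-truth TF -> target network that rewires between conditions. Everything
is deterministic under the config seed; truth cardinalities follow the config
fractions exactly (first ceil(fraction * n) after a seeded shuffle, not
Bernoulli draws).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)

import numpy as np
import pandas as pd

from .diff import CountMatrix
from .intervals import GeneModels, PeakSet
from .motifs import BASES, PWM, build_pwm
from .networks import assign_peaks_to_genes

CONDITIONS = ("CON", "IND")


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters for the simulator.

    Fractions are exact assignment fractions (deterministic, not sampled);
    ``nb_dispersion`` is the NB alpha (variance = m + alpha m^2);
    ``footprint_protection`` is the fractional depletion of Tn5 insertions
    over bound motif spans; ``coexpr_log2_sd`` the SD of the shared
    per-sample log2-normal latent factor linking a TF to its active targets.
    """

    n_chroms: int = 2
    chrom_len: int = 300_000
    n_genes: int = 80
    n_peaks: int = 120
    n_tfs: int = 8
    n_samples_per_condition: int = 6
    n_blocks: int = 2
    nb_mean_log_range: tuple[float, float] = (3.0, 9.0)
    nb_dispersion: float = 0.05
    de_fraction: float = 0.1
    de_lfc: float = 2.0
    dar_fraction: float = 0.1
    dar_lfc: float = 2.0
    footprint_protection: float = 0.8
    rewire_fraction: float = 0.25
    promoter_peak_fraction: float = 0.4
    targets_per_tf: int = 6
    extra_sites_per_tf: int = 0
    n_unbound_tfs: int = 0
    peak_width: int = 400
    frags_per_peak: int = 200
    block_log2_sd: float = 0.5
    depth_log2_halfwidth: float = 0.5
    coexpr_log2_sd: float = 0.8
    bound_peak_boost: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fraction", "dar_fraction", "footprint_protection",
                     "rewire_fraction", "promoter_peak_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chroms", "chrom_len", "n_genes", "n_peaks",
                     "n_samples_per_condition", "n_blocks", "peak_width",
                     "frags_per_peak"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_tfs < 0 or self.targets_per_tf < 0 or self.extra_sites_per_tf < 0:
            raise ValueError("n_tfs / targets_per_tf / extra_sites_per_tf must be >= 0")
        if self.n_samples_per_condition < self.n_blocks:
            raise ValueError("need at least one sample per block per condition")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthSet:
    """Planted ground truth for recovery tests.

    ``de_genes``/``dars`` map feature id -> signed planted log2FC;
    ``true_edges`` and ``bound_motifs`` are per-condition; bound motif entries
    are (peak, motif, offset, width) with the offset the motif midpoint
    relative to the peak summit.
    """

    de_genes: dict[str, float] = field(default_factory=dict)
    dars: dict[str, float] = field(default_factory=dict)
    true_edges: dict[str, set[tuple[str, str]]] = field(
        default_factory=lambda: {c: set() for c in CONDITIONS}
    )
    bound_motifs: dict[str, list[tuple[str, str, int, int]]] = field(
        default_factory=lambda: {c: [] for c in CONDITIONS}
    )
    rewired_tfs: set[str] = field(default_factory=set)
    tf2motif: dict[str, str] = field(default_factory=dict)
    tf_targets: dict[str, list[str]] = field(default_factory=dict)
    unbound_sites: list[tuple[str, str, int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "de_genes": self.de_genes,
            "dars": self.dars,
            "true_edges": {c: sorted(map(list, e)) for c, e in self.true_edges.items()},
            "bound_motifs": {c: sorted(map(list, b)) for c, b in self.bound_motifs.items()},
            "rewired_tfs": sorted(self.rewired_tfs),
            "unbound_sites": sorted(map(list, self.unbound_sites)),
            "tf2motif": self.tf2motif,
            "tf_targets": self.tf_targets,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthSet":
        return cls(
            de_genes=dict(d["de_genes"]),
            dars=dict(d["dars"]),
            true_edges={c: {tuple(e) for e in v} for c, v in d["true_edges"].items()},
            bound_motifs={c: [tuple(b) for b in v] for c, v in d["bound_motifs"].items()},
            rewired_tfs=set(d["rewired_tfs"]),
            tf2motif=dict(d["tf2motif"]),
            tf_targets={k: list(v) for k, v in d["tf_targets"].items()},
            unbound_sites=[tuple(b) for b in d.get("unbound_sites", [])],
        )


# ---------------------------------------------------------------- reference


def make_reference(cfg: SimConfig) -> tuple[dict[str, str], GeneModels, PeakSet]:
    """Random genome, gene models and a non-overlapping mixed peak set.

    Peaks are a mix of promoter-proximal (summit within +/- 1 kb of a TSS,
    hence inside the +/- 3 kb promoter window) and distal (>= 3.5 kb from any
    TSS) sites; the promoter fraction matches the config exactly by
    construction.
    """
    rng = cfg.rng(0)
    margin = 5000
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    genome = {
        c: "".join(np.array(list(BASES))[rng.integers(0, 4, cfg.chrom_len)])
        for c in chroms
    }

    # genes: evenly spaced TSS with jitter, round-robin over chromosomes
    per_chrom = [cfg.n_genes // cfg.n_chroms + (i < cfg.n_genes % cfg.n_chroms)
                 for i in range(cfg.n_chroms)]
    span = cfg.chrom_len - 2 * margin
    rows = []
    gid = 0
    for c, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        spacing = span / n
        if spacing < 500:
            raise ValueError("chromosome too short to host the requested genes")
        base = margin + spacing * (np.arange(n) + 0.5)
        jitter = rng.integers(-200, 201, n)
        tss = np.round(base).astype(int) + jitter
        for t in tss:
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(2000, 10001))
            if strand == "+":
                tes = min(t + length, cfg.chrom_len - 1)
            else:
                tes = max(t - length, 0)
            rows.append((f"G{gid:04d}", c, strand, int(t), int(tes)))
            gid += 1
    genes = GeneModels(pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tes"]))
    if genes.df.duplicated(subset=["chrom", "tss"]).any():
        raise ValueError("TSS collision; increase chromosome length")

    # peaks
    n_prom = math.ceil(cfg.promoter_peak_fraction * cfg.n_peaks)
    half = cfg.peak_width // 2
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    tss_by_chrom = {c: genes.df.loc[genes.df["chrom"] == c, "tss"].values for c in chroms}

    def free(chrom: str, s: int, e: int) -> bool:
        return all(e <= a or s >= b for a, b in occupied[chrom])

    peak_rows = []

    def place(chrom: str, summit: int) -> bool:
        s, e = summit - half, summit + half
        if s < margin // 2 or e > cfg.chrom_len - margin // 2:
            return False
        if not free(chrom, s, e):
            return False
        occupied[chrom].append((s, e))
        peak_rows.append((chrom, s, e, f"peak{len(peak_rows):04d}", summit))
        return True

    gene_order = rng.permutation(len(genes.df))
    attempts = 0
    placed = 0
    gi = 0
    while placed < n_prom:
        attempts += 1
        if attempts > 200 * cfg.n_peaks:
            raise ValueError("could not place promoter peaks; chromosomes too short")
        row = genes.df.iloc[gene_order[gi % len(gene_order)]]
        gi += 1
        summit = int(row["tss"] + rng.integers(-1000, 1001))
        if place(row["chrom"], summit):
            placed += 1
    while placed < cfg.n_peaks:
        attempts += 1
        if attempts > 500 * cfg.n_peaks:
            raise ValueError("could not place distal peaks; chromosomes too short")
        chrom = chroms[int(rng.integers(0, cfg.n_chroms))]
        summit = int(rng.integers(margin, cfg.chrom_len - margin))
        tss = tss_by_chrom[chrom]
        if len(tss) and np.abs(tss - summit).min() < 3500:
            continue
        if place(chrom, summit):
            placed += 1
    peaks = PeakSet("peaks", pd.DataFrame(
        peak_rows, columns=["chrom", "start", "end", "name", "summit"]
    ))
    return genome, genes, peaks


# ---------------------------------------------------------------- motif panel


def default_pwm_panel(n: int, width: int = 18, seed: int = 99, sharpness: int = 91) -> list[PWM]:
    """Sharp, information-rich random PFMs, one per TF (consensus base gets
    ``sharpness`` of 100 counts per column)."""
    rng = np.random.default_rng(seed)
    pwms = []
    seen = set()
    while len(pwms) < n:
        cons = rng.integers(0, 4, width)
        key = tuple(cons)
        if key in seen:
            continue
        seen.add(key)
        off = (100 - sharpness) / 3
        pfm = np.full((4, width), off)
        pfm[cons, np.arange(width)] = sharpness
        pwms.append(build_pwm(pfm, motif_id=f"M{len(pwms):02d}"))
    return pwms


# ---------------------------------------------------------------- truth


def plant_motifs_and_truth(
    cfg: SimConfig,
    genome: dict[str, str],
    genes: GeneModels,
    peaks: PeakSet,
    pwms: list[PWM],
) -> tuple[dict[str, str], TruthSet]:
    """Write PWM consensus sites into peaks and derive the ground truth.

    The first ``n_tfs`` genes act as TF genes, each mapped to one PWM. Each TF
    regulates ``targets_per_tf`` disjoint target genes through a consensus
    site planted in a peak assigned to the target; rewired TFs are bound (and
    their edges exist) in exactly one condition, alternating IND/CON. DE genes
    and DARs are the first ceil(fraction * n) features after a seeded shuffle,
    with alternating signs.
    """
    rng = cfg.rng(1)
    truth = TruthSet()
    mutable = {c: bytearray(s, "ascii") for c, s in genome.items()}

    gene_ids = list(genes.df["gene_id"])
    shuffled_genes = [str(g) for g in np.array(gene_ids)[rng.permutation(len(gene_ids))]]
    n_de = math.ceil(cfg.de_fraction * len(gene_ids))
    truth.de_genes = {
        g: cfg.de_lfc * (1 if i % 2 == 0 else -1) for i, g in enumerate(shuffled_genes[:n_de])
    }
    peak_ids = list(peaks.df["name"])
    shuffled_peaks = [str(p) for p in np.array(peak_ids)[rng.permutation(len(peak_ids))]]
    n_dar = math.ceil(cfg.dar_fraction * len(peak_ids))
    truth.dars = {
        p: cfg.dar_lfc * (1 if i % 2 == 0 else -1) for i, p in enumerate(shuffled_peaks[:n_dar])
    }

    if cfg.n_tfs == 0 and cfg.n_unbound_tfs == 0:
        return {c: bytes(b).decode() for c, b in mutable.items()}, truth
    if not pwms:
        raise ValueError("pwms must be non-empty when motifs are to be planted")
    if len(pwms) < cfg.n_tfs + cfg.n_unbound_tfs:
        raise ValueError("need one PWM per TF (bound and unbound)")

    tf_ids = gene_ids[: cfg.n_tfs]
    truth.tf2motif = {tf: pwms[i].motif_id for i, tf in enumerate(tf_ids)}
    pwm_of_tf = {tf: pwms[i] for i, tf in enumerate(tf_ids)}

    order = [str(t) for t in np.array(tf_ids)[rng.permutation(cfg.n_tfs)]]
    n_rw = math.ceil(cfg.rewire_fraction * cfg.n_tfs)
    truth.rewired_tfs = set(order[:n_rw])
    bound_in = {
        tf: ({("IND" if k % 2 == 0 else "CON")} if tf in truth.rewired_tfs else set(CONDITIONS))
        for k, tf in enumerate(order)
    }

    peak_df = peaks.df.set_index("name")
    p2g = assign_peaks_to_genes(peaks, genes)
    peaks_of_gene: dict[str, list[str]] = {}
    for rec in p2g.dropna(subset=["gene"]).itertuples():
        peaks_of_gene.setdefault(rec.gene, []).append(rec.peak)

    candidates = [g for g in shuffled_genes if g in peaks_of_gene and g not in tf_ids]
    need = cfg.n_tfs * cfg.targets_per_tf
    if len(candidates) < need:
        raise ValueError(
            f"not enough peak-linked target genes ({len(candidates)}) for "
            f"{cfg.n_tfs} TFs x {cfg.targets_per_tf} targets"
        )
    used_spans: dict[str, list[tuple[int, int]]] = {p: [] for p in peak_ids}

    def plant(peak: str, pwm: PWM) -> int | None:
        row = peak_df.loc[peak]
        w = pwm.width
        if w > row["end"] - row["start"]:
            raise ValueError(f"motif {pwm.motif_id} longer than peak {peak}")
        for _ in range(60):
            g_start = int(rng.integers(row["start"], row["end"] - w + 1))
            # keep the site comfortably inside the scan window
            mid = g_start + w // 2
            if abs(mid - row["summit"]) > cfg.peak_width // 2 - w:
                continue
            if all(g_start + w <= a or g_start >= b for a, b in used_spans[peak]):
                used_spans[peak].append((g_start, g_start + w))
                mutable[row["chrom"]][g_start : g_start + w] = pwm.consensus().encode()
                return mid - int(row["summit"])
        return None

    ci = 0
    for tf in tf_ids:
        pwm = pwm_of_tf[tf]
        targets = []
        while len(targets) < cfg.targets_per_tf:
            gene = candidates[ci]
            ci += 1
            peak = peaks_of_gene[gene][0]
            off = plant(peak, pwm)
            if off is None:
                continue
            targets.append(gene)
            for cond in bound_in[tf]:
                truth.true_edges[cond].add((tf, gene))
                truth.bound_motifs[cond].append((peak, pwm.motif_id, off, pwm.width))
        truth.tf_targets[tf] = targets
        extra = 0
        tries = 0
        while extra < cfg.extra_sites_per_tf:
            tries += 1
            if tries > 50 * max(cfg.extra_sites_per_tf, 1):
                raise ValueError("could not place extra motif sites; too few peaks")
            peak = peak_ids[int(rng.integers(0, len(peak_ids)))]
            off = plant(peak, pwm)
            if off is None:
                continue
            extra += 1
            for cond in bound_in[tf]:
                truth.bound_motifs[cond].append((peak, pwm.motif_id, off, pwm.width))

    # never-bound decoy motifs: sites exist in the genome but carry no
    # protection, no accessibility boost and no edges in either condition
    for pwm in pwms[cfg.n_tfs : cfg.n_tfs + cfg.n_unbound_tfs]:
        placed = 0
        tries = 0
        while placed < cfg.extra_sites_per_tf:
            tries += 1
            if tries > 50 * max(cfg.extra_sites_per_tf, 1):
                raise ValueError("could not place unbound motif sites; too few peaks")
            peak = peak_ids[int(rng.integers(0, len(peak_ids)))]
            off = plant(peak, pwm)
            if off is None:
                continue
            placed += 1
            truth.unbound_sites.append((peak, pwm.motif_id, off, pwm.width))
    return {c: bytes(b).decode() for c, b in mutable.items()}, truth


def truth_sites(truth: TruthSet, peaks: PeakSet) -> pd.DataFrame:
    """All planted motif sites (bound in either condition plus never-bound
    decoys) as footprint-profiling input: motif, chrom, center, width."""
    entries = set(truth.unbound_sites)
    for c in CONDITIONS:
        entries |= set(truth.bound_motifs[c])
    pk = peaks.df.set_index("name")
    rows = [
        (m, pk.loc[p, "chrom"], int(pk.loc[p, "summit"]) + off, w)
        for p, m, off, w in sorted(entries)
    ]
    return pd.DataFrame(rows, columns=["motif", "chrom", "center", "width"])


# ---------------------------------------------------------------- counts


def _sample_sheet(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for cond in CONDITIONS:
        for i in range(cfg.n_samples_per_condition):
            block = f"B{i % cfg.n_blocks + 1}"
            rep = i // cfg.n_blocks + 1
            rows.append((f"{cond}_{block}_R{rep}", cond, rep, block))
    return pd.DataFrame(
        rows, columns=["sample", "condition", "replicate", "block"]
    ).set_index("sample")


def _draw_nb(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    cfg: SimConfig, genes: GeneModels, peaks: PeakSet, truth: TruthSet
) -> tuple[CountMatrix, CountMatrix]:
    """NB count matrices for RNA (genes) and ATAC (peaks).

    Counts ~ NB(mean, alpha) with per-feature baselines, per-feature x block
    offsets, per-sample depth factors, planted condition effects
    (mean x 2^(+/- lfc) in IND), a shared TF/target latent factor carrying
    the planted co-expression, and an accessibility boost on bound peaks.
    """
    rng = cfg.rng(2)
    samples = _sample_sheet(cfg)
    n_s = len(samples)
    cond = samples["condition"].values
    block_idx = samples["block"].map(
        {f"B{b + 1}": b for b in range(cfg.n_blocks)}
    ).values
    depth = 2.0 ** rng.uniform(
        -cfg.depth_log2_halfwidth, cfg.depth_log2_halfwidth, n_s
    )

    def base_matrix(features: list[str], planted: dict[str, float]) -> np.ndarray:
        n_f = len(features)
        lo, hi = cfg.nb_mean_log_range
        base = 2.0 ** rng.uniform(lo, hi, n_f)
        block_eff = 2.0 ** rng.normal(0.0, cfg.block_log2_sd, (n_f, cfg.n_blocks))
        mean = base[:, None] * block_eff[:, block_idx]
        fpos = {f: i for i, f in enumerate(features)}
        for f, lfc in planted.items():
            mean[fpos[f], cond == "IND"] *= 2.0**lfc
        return mean

    gene_ids = list(genes.df["gene_id"])
    mean_rna = base_matrix(gene_ids, truth.de_genes)

    # shared latent factor: TF expression co-varies with its active targets
    gpos = {g: i for i, g in enumerate(gene_ids)}
    for tf in sorted(truth.tf2motif):
        u = rng.normal(0.0, cfg.coexpr_log2_sd, n_s)
        factor = 2.0**u
        mean_rna[gpos[tf]] *= factor
        for c in CONDITIONS:
            cmask = cond == c
            for t_tf, target in sorted(truth.true_edges[c]):
                if t_tf == tf:
                    mean_rna[gpos[target], cmask] *= factor[cmask]

    peak_ids = list(peaks.df["name"])
    mean_atac = base_matrix(peak_ids, truth.dars)
    ppos = {p: i for i, p in enumerate(peak_ids)}
    # bound regulatory elements are accessible: a static baseline factor for
    # any motif-carrying peak, plus a condition boost where the motif is bound
    carrying = sorted({p for c in CONDITIONS for p, _m, _o, _w in truth.bound_motifs[c]})
    for p in carrying:
        mean_atac[ppos[p], :] *= cfg.bound_peak_boost
    for c in CONDITIONS:
        cmask = cond == c
        boosted = {p for p, _m, _o, _w in truth.bound_motifs[c]}
        for p in sorted(boosted):
            mean_atac[ppos[p], cmask] *= cfg.bound_peak_boost

    rna_counts = _draw_nb(rng, mean_rna * depth[None, :], cfg.nb_dispersion)
    atac_counts = _draw_nb(rng, mean_atac * depth[None, :], cfg.nb_dispersion)
    rna = CountMatrix(
        pd.DataFrame(rna_counts, index=gene_ids, columns=samples.index), samples.copy()
    )
    atac = CountMatrix(
        pd.DataFrame(atac_counts, index=peak_ids, columns=samples.index), samples.copy()
    )
    return rna, atac


# ---------------------------------------------------------------- fragments


def simulate_fragments(cfg: SimConfig, peaks: PeakSet, truth: TruthSet) -> pd.DataFrame:
    """ATAC fragment records (chrom, start, end, sample, condition).

    Insertion sites are sampled uniformly within accessible peaks, with the
    density over bound-motif spans multiplied by (1 - footprint_protection) in
    the condition where the motif is bound. Fragment ends are placed so the
    standard (+4, -5) shift recovers the sampled insertion sites exactly.
    """
    rng = cfg.rng(3)
    samples = _sample_sheet(cfg)
    spans_by_cond: dict[str, dict[str, list[tuple[int, int]]]] = {
        c: {} for c in CONDITIONS
    }
    for c in CONDITIONS:
        for peak, _motif, off, w in truth.bound_motifs[c]:
            spans_by_cond[c].setdefault(peak, []).append((off - w // 2, off - w // 2 + w))

    rows = []
    peak_df = peaks.df
    for sample, meta in samples.iterrows():
        c = meta["condition"]
        for rec in peak_df.itertuples():
            lo, hi = rec.start + 4, rec.end - 5
            positions = np.arange(lo, hi)
            weights = np.ones(len(positions), dtype=float)
            for s_off, e_off in spans_by_cond[c].get(rec.name, []):
                a = rec.summit + s_off
                b = rec.summit + e_off
                weights[(positions >= a) & (positions < b)] *= 1.0 - cfg.footprint_protection
            total = weights.sum()
            if total == 0:
                continue
            w = weights / total
            pts = rng.choice(positions, size=(cfg.frags_per_peak, 2), p=w)
            starts = pts.min(axis=1) - 4
            ends = pts.max(axis=1) + 5
            for s, e in zip(starts, ends):
                rows.append((rec.chrom, int(s), int(e), sample, c))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "condition"])


# ---------------------------------------------------------------- bundle


@dataclass
class SimBundle:
    """Everything one simulated study produces."""

    cfg: SimConfig
    genome: dict[str, str]
    genes: GeneModels
    peaks: PeakSet
    pwms: list[PWM]
    truth: TruthSet
    rna: CountMatrix
    atac: CountMatrix
    fragments: pd.DataFrame


def simulate_study(cfg: SimConfig, pwms: list[PWM] | None = None,
                   with_fragments: bool = True) -> SimBundle:
    """Run the full generator pipeline under one config."""
    genome, genes, peaks = make_reference(cfg)
    if pwms is None:
        n_pwm = cfg.n_tfs + cfg.n_unbound_tfs
        pwms = default_pwm_panel(n_pwm) if n_pwm else []
    genome, truth = plant_motifs_and_truth(cfg, genome, genes, peaks, pwms)
    rna, atac = simulate_counts(cfg, genes, peaks, truth)
    frags = (
        simulate_fragments(cfg, peaks, truth)
        if with_fragments
        else pd.DataFrame(columns=["chrom", "start", "end", "sample", "condition"])
    )
    return SimBundle(cfg, genome, genes, peaks, pwms, truth, rna, atac, frags)
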