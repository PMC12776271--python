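"""Position-weight-matrix construction, scanning and comparison.

A PFM (integer counts, 4 x width) is converted to a position probability
matrix with a background-weighted pseudocount and then to a log2-odds PWM.
Peak scanning resizes each peak to a fixed window around its summit, scores
both strands at every offset, and keeps matches above a *match fraction*
threshold, where the match fraction rescales the log-odds score between the
minimum and maximum attainable score of the motif (so 1.0 is the consensus and
the conventional 70% cutoff is scale-free). ``best_central`` mode keeps, per
peak x motif, the surviving hit closest to the window centre.

Motif-family clustering uses the maximum Pearson correlation between aligned
probability matrices over all ungapped offsets and the reverse complement,
with average-linkage hierarchical clustering.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy.cluster.hierarchy import average, dendrogram, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .intervals import GeneModels, PeakSet, warn  # noqa: F401  (GeneModels re-export convenience)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0])


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N) -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class PWM:
    """A position weight model.

    Attributes
    ----------
    motif_id : str
    counts : (4, w) array or None
        The source PFM, if built from counts.
    ppm : (4, w) array
        Position probability matrix; columns sum to 1.
    background : (4,) array
    logodds : (4, w) array
        log2(ppm / background).
    """

    motif_id: str
    ppm: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.ppm.shape[0] != 4 or self.ppm.shape[1] < 4:
            raise ValueError("PPM must be 4 x width with width >= 4")
        if not np.allclose(self.ppm.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PPM columns must sum to 1")
        self.background = np.asarray(self.background, dtype=float)
        self.logodds = np.log2(self.ppm / self.background[:, None])

    @property
    def width(self) -> int:
        return self.ppm.shape[1]

    @property
    def min_score(self) -> float:
        return float(self.logodds.min(axis=0).sum())

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.ppm.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        rc = PWM.__new__(PWM)
        rc.motif_id = self.motif_id
        rc.ppm = self.ppm[::-1, ::-1].copy()
        rc.background = self.background[::-1].copy()
        rc.counts = None if self.counts is None else self.counts[::-1, ::-1].copy()
        rc.logodds = self.logodds[::-1, ::-1].copy()
        return rc

    def match_fraction(self, score: float | np.ndarray) -> np.ndarray:
        return (score - self.min_score) / (self.max_score - self.min_score)


def build_pwm(
    pfm: np.ndarray,
    motif_id: str = "motif",
    pseudocount: float = 0.8,
    background: np.ndarray | None = None,
) -> PWM:
    """PFM counts -> PWM with probabilities (count + pc*bg) / (colsum + pc)."""
    pfm = np.asarray(pfm, dtype=float)
    if (pfm < 0).any():
        raise ValueError("PFM counts must be >= 0")
    colsum = pfm.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError("PFM has a zero-sum column")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    ppm = (pfm + pseudocount * bg[:, None]) / (colsum + pseudocount)
    return PWM(motif_id, ppm, background=bg, counts=pfm)


# ---------------------------------------------------------------- JASPAR I/O


def read_jaspar(path_or_text: str) -> list[PWM]:
    """Read JASPAR-format PFMs (file path or raw text) and build PWMs."""
    try:
        fh = open(path_or_text)
    except (OSError, ValueError):
        fh = _io.StringIO(path_or_text)
    with fh:
        records = bio_motifs.parse(fh, "jaspar")
        out = []
        for rec in records:
            pfm = np.array([list(rec.counts[b]) for b in BASES], dtype=float)
            out.append(build_pwm(pfm, motif_id=rec.matrix_id or rec.name))
    return out


def write_jaspar(pwms: list[PWM], path: str) -> None:
    from Bio.motifs import jaspar

    ms = []
    for p in pwms:
        counts = p.counts
        if counts is None:  # fall back to scaled probabilities
            counts = np.round(p.ppm * 100, 4)
        m = jaspar.Motif(
            matrix_id=p.motif_id,
            name=p.motif_id,
            counts={b: list(counts[i]) for i, b in enumerate(BASES)},
        )
        ms.append(m)
    with open(path, "w") as fh:
        fh.write(jaspar.write(ms, "jaspar"))


# ---------------------------------------------------------------- scanning


def scan_sequence(pwm: PWM, seq: str, threshold: float = 0.70) -> pd.DataFrame:
    """Scan one sequence on both strands.

    Returns a frame with columns pos (0-based start of the match on the
    forward strand), strand, score, match_fraction. N bases contribute 0
    log-odds (background).
    """
    idx = encode(seq)
    w = pwm.width
    if len(idx) < w:
        return pd.DataFrame(columns=["pos", "strand", "score", "match_fraction"])
    lut_fwd = np.vstack([pwm.logodds, np.zeros((1, w))])  # row 4 = N
    rc = pwm.reverse_complement()
    lut_rev = np.vstack([rc.logodds, np.zeros((1, w))])
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    cols = np.arange(w)
    rows = []
    for strand, lut in (("+", lut_fwd), ("-", lut_rev)):
        scores = lut[windows, cols].sum(axis=1)
        mf = pwm.match_fraction(scores)
        keep = mf >= threshold
        pos = np.nonzero(keep)[0]
        rows.append(
            pd.DataFrame(
                {"pos": pos, "strand": strand, "score": scores[keep], "match_fraction": mf[keep]}
            )
        )
    return pd.concat(rows, ignore_index=True)


def peak_windows(peaks: PeakSet, genome: dict[str, str], window: int) -> pd.DataFrame:
    """Per-peak scan windows centred on the summit, truncated at chromosome
    ends with a warning."""
    half = window // 2
    rows = []
    for name, chrom, summit in zip(peaks.df["name"], peaks.df["chrom"], peaks.df["summit"]):
        clen = len(genome[chrom])
        lo, hi = summit - half, summit + half
        if lo < 0 or hi > clen:
            warn(f"peak {name}: window truncated at chromosome end")
            lo, hi = max(0, lo), min(clen, hi)
        rows.append((name, chrom, lo, hi, summit))
    return pd.DataFrame(rows, columns=["peak", "chrom", "lo", "hi", "summit"])


def scan_peaks(
    pwms: PWM | list[PWM],
    genome: dict[str, str],
    peaks: PeakSet,
    window: int = 400,
    threshold: float = 0.70,
    mode: str = "best_central",
) -> pd.DataFrame:
    """Scan peak windows with one or more PWMs.

    Returns MotifHit rows: peak, motif, strand, offset (motif midpoint minus
    window centre, bp), score, match_fraction. ``mode='all'`` keeps every hit
    above threshold; ``mode='best_central'`` keeps per peak x motif the hit
    minimising \\|offset\\| (ties: higher score, then '+' strand).
    """
    if window % 2:
        raise ValueError("window must be even")
    if mode not in ("all", "best_central"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(pwms, PWM):
        pwms = [pwms]
    wins = peak_windows(peaks, genome, window)
    out = []
    for _, row in wins.iterrows():
        seq = genome[row["chrom"]][row["lo"] : row["hi"]]
        for pwm in pwms:
            hits = scan_sequence(pwm, seq, threshold=threshold)
            if not len(hits):
                continue
            # offset of the motif midpoint relative to the peak summit
            centre = row["summit"] - row["lo"]
            hits = hits.assign(
                peak=row["peak"],
                motif=pwm.motif_id,
                offset=hits["pos"] + pwm.width // 2 - centre,
            )
            out.append(hits[["peak", "motif", "strand", "offset", "score", "match_fraction"]])
    if not out:
        return pd.DataFrame(
            columns=["peak", "motif", "strand", "offset", "score", "match_fraction"]
        )
    hits = pd.concat(out, ignore_index=True)
    if mode == "best_central":
        hits = (
            hits.assign(_a=hits["offset"].abs(), _s=-hits["score"])
            .sort_values(["peak", "motif", "_a", "_s", "strand"], kind="mergesort")
            .groupby(["peak", "motif"], as_index=False, sort=False)
            .head(1)
            .drop(columns=["_a", "_s"])
            .reset_index(drop=True)
        )
    return hits


def positional_density(
    hits: pd.DataFrame, n_peaks: int, bin_size: int = 20, span: int = 200
) -> pd.Series:
    """Hit density per offset bin, normalised by the number of peaks.

    Bins tile [-span, span) half-open; the returned series is indexed by the
    left bin edge and sums to (hits in span) / n_peaks.
    """
    edges = np.arange(-span, span + bin_size, bin_size)
    inside = hits[(hits["offset"] >= -span) & (hits["offset"] < span)]
    counts, _ = np.histogram(inside["offset"], bins=edges)
    return pd.Series(counts / n_peaks, index=edges[:-1], name="density")


# ---------------------------------------------------------------- enrichment


def shuffle_sequences(seqs: list[str], seed: int) -> list[str]:
    """Mononucleotide shuffle (composition-preserving) of each sequence."""
    rng = np.random.default_rng(seed)
    return ["".join(rng.permutation(list(s))) for s in seqs]


def enrich_peakset(
    pwms: list[PWM],
    fg_peaks: PeakSet,
    genome: dict[str, str],
    bg_peaks: PeakSet | None = None,
    window: int = 500,
    threshold: float = 0.70,
    eps: float = 1e-3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-motif log2 enrichment of foreground hit fractions over background.

    Background defaults to mononucleotide-shuffled foreground sequences
    (seeded); alternatively a supplied background peak set. A two-sided Fisher
    exact test on the 2x2 peak-hit table gives p-values, BH-corrected across
    motifs.
    """
    if len(fg_peaks) < 20:
        raise ValueError("need >= 20 foreground peaks")
    window += window % 2  # keep even
    fg_wins = peak_windows(fg_peaks, genome, window)
    fg_seqs = [genome[r.chrom][r.lo : r.hi] for r in fg_wins.itertuples()]
    if bg_peaks is not None:
        if len(bg_peaks) == 0:
            raise ValueError("empty background peak set")
        bg_wins = peak_windows(bg_peaks, genome, window)
        bg_seqs = [genome[r.chrom][r.lo : r.hi] for r in bg_wins.itertuples()]
    else:
        bg_seqs = shuffle_sequences(fg_seqs, seed=seed)
    rows = []
    for pwm in pwms:
        hit_fg = sum(bool(len(scan_sequence(pwm, s, threshold))) for s in fg_seqs)
        hit_bg = sum(bool(len(scan_sequence(pwm, s, threshold))) for s in bg_seqs)
        n_fg, n_bg = len(fg_seqs), len(bg_seqs)
        f_fg, f_bg = hit_fg / n_fg, hit_bg / n_bg
        enr = np.log2((f_fg + eps) / (f_bg + eps))
        _, p = fisher_exact(
            [[hit_fg, n_fg - hit_fg], [hit_bg, n_bg - hit_bg]], alternative="two-sided"
        )
        rows.append((pwm.motif_id, hit_fg, n_fg, hit_bg, n_bg, f_fg, f_bg, enr, p))
    out = pd.DataFrame(
        rows,
        columns=[
            "motif", "hit_fg", "n_fg", "hit_bg", "n_bg",
            "frac_fg", "frac_bg", "log2_enrichment", "pvalue",
        ],
    )
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------- clustering


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def pwm_similarity(p1: PWM, p2: PWM, min_overlap: int = 4) -> float:
    """Max Pearson correlation of flattened aligned PPM columns over all
    ungapped offsets, forward and reverse-complement orientations."""
    best = -1.0
    for q in (p2, p2.reverse_complement()):
        a, b = p1.ppm, q.ppm
        wa, wb = a.shape[1], b.shape[1]
        for shift in range(-(wb - min_overlap), wa - min_overlap + 1):
            lo_a, hi_a = max(0, shift), min(wa, shift + wb)
            if hi_a - lo_a < min_overlap:
                continue
            sub_a = a[:, lo_a:hi_a]
            sub_b = b[:, lo_a - shift : hi_a - shift]
            best = max(best, _pearson(sub_a, sub_b))
    return best


def cluster_motifs(
    pwms: list[PWM], similarity_threshold: float = 0.8
) -> tuple[pd.DataFrame, list[str]]:
    """Average-linkage family clustering on 1 - max-Pearson PPM similarity.

    Returns (assignments frame with columns motif, family; dendrogram leaf
    order). The family label is the member motif with the highest mean
    within-family similarity.
    """
    if len(pwms) < 2:
        raise ValueError("need >= 2 motifs")
    for p in pwms:
        if p.width < 4:
            raise ValueError("motif width must be >= 4")
    n = len(pwms)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = pwm_similarity(pwms[i], pwms[j])
    dist = np.clip(1.0 - sim, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    labels = fcluster(link, t=1.0 - similarity_threshold, criterion="distance")
    order = dendrogram(link, no_plot=True)["leaves"]
    ids = [p.motif_id for p in pwms]
    fam_names = {}
    for fam in np.unique(labels):
        members = np.nonzero(labels == fam)[0]
        mean_sim = sim[np.ix_(members, members)].mean(axis=1)
        fam_names[fam] = ids[members[int(mean_sim.argmax())]]
    out = pd.DataFrame({"motif": ids, "family": [fam_names[l] for l in labels]})
    return out, [ids[i] for i in order]
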