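"""Tn5 insertion profiles and differential footprinting.

Each ATAC fragment contributes two insertion points (5' end + 4, 3' end - 5,
the standard Tn5 dyad correction), accumulated per motif site into an
``n_sites x window`` profile. The footprint score is the log2 ratio of mean
flank to mean centre insertions (deeper protection => higher score), averaged
over sites, then min-max normalised across the motif panel within each
condition so the conventional 0.2 delta threshold is scale-meaningful.
Condition differences are tested by permuting per-site raw scores between
condition labels (two-sided, add-one corrected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import warn


@dataclass
class InsertionProfile:
    """Per-site insertion counts around motif midpoints for one motif in one
    condition. ``matrix`` is (n_sites, window)."""

    motif_id: str
    condition: str
    matrix: np.ndarray
    window: int = 200
    motif_width: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.window:
            raise ValueError("matrix must be (n_sites, window)")
        if (self.matrix < 0).any():
            raise ValueError("insertion counts must be >= 0")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]


def motif_sites(hits: pd.DataFrame, peaks) -> pd.DataFrame:
    """Absolute motif-midpoint sites from scan hits: columns motif, chrom,
    center."""
    pk = peaks.df.set_index("name")
    out = hits[["motif", "peak", "offset"]].copy()
    out["chrom"] = out["peak"].map(pk["chrom"])
    out["center"] = out["peak"].map(pk["summit"]) + out["offset"]
    return out[["motif", "chrom", "center"]].reset_index(drop=True)


def insertion_profile(
    fragments: pd.DataFrame,
    sites: pd.DataFrame,
    motif_id: str,
    condition: str = "",
    window: int = 200,
    shift: tuple[int, int] = (4, -5),
    motif_width: int | None = None,
) -> InsertionProfile:
    """Accumulate shifted insertion points per site-relative base.

    ``fragments``: chrom, start, end (0-based half-open). ``sites``: chrom,
    center rows for this motif. Each fragment contributes start + shift[0] and
    end - 1 + shift[1] + 1 = end + shift[1], strandless.
    """
    sub = sites[sites["motif"] == motif_id] if "motif" in sites.columns else sites
    if not len(sub):
        raise ValueError(f"zero sites for motif {motif_id!r}")
    half = window // 2
    mat = np.zeros((len(sub), window), dtype=np.int64)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, fr in fragments.groupby("chrom"):
        pts = np.concatenate([fr["start"].values + shift[0], fr["end"].values + shift[1]])
        by_chrom[chrom] = np.sort(pts)
    for i, (chrom, center) in enumerate(zip(sub["chrom"], sub["center"])):
        pts = by_chrom.get(chrom)
        if pts is None:
            continue
        lo, hi = center - half, center + half
        sl = pts[np.searchsorted(pts, lo) : np.searchsorted(pts, hi)]
        if len(sl):
            mat[i] = np.bincount(sl - lo, minlength=window)
    return InsertionProfile(motif_id, condition, mat, window=window, motif_width=motif_width)


def _center_flank_slices(window: int, motif_width: int, flank: int):
    if window < motif_width + 2 * flank:
        raise ValueError("window must cover motif span plus both flanks")
    c_lo = window // 2 - motif_width // 2
    c_hi = c_lo + motif_width
    return (slice(c_lo - flank, c_lo), slice(c_lo, c_hi), slice(c_hi, c_hi + flank))


def per_site_scores(
    profile: InsertionProfile, flank: int = 30, eps: float = 0.1
) -> np.ndarray:
    """Per-site raw footprint score: log2((mean flank + eps)/(mean centre + eps))."""
    if profile.motif_width is None:
        raise ValueError("profile needs motif_width to place the centre span")
    left, center, right = _center_flank_slices(profile.window, profile.motif_width, flank)
    m = profile.matrix.astype(float)
    flank_mean = (m[:, left].sum(axis=1) + m[:, right].sum(axis=1)) / (
        (left.stop - left.start) + (right.stop - right.start)
    )
    center_mean = m[:, center].mean(axis=1)
    return np.log2((flank_mean + eps) / (center_mean + eps))


def footprint_score(profile: InsertionProfile, flank: int = 30, eps: float = 0.1) -> float:
    """Raw motif-level footprint score: mean of per-site scores."""
    return float(per_site_scores(profile, flank=flank, eps=eps).mean())


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.full_like(values, 0.5, dtype=float)
    return (values - lo) / (hi - lo)


class FootprintModel:
    """Differential footprinting across a motif panel.

    Parameters
    ----------
    profiles_con, profiles_ind : dict motif_id -> InsertionProfile
        Same motif panel in both conditions. Motifs with fewer than
        ``min_sites`` sites in either condition are skipped with a warning.
    """

    def __init__(
        self,
        profiles_con: dict[str, InsertionProfile],
        profiles_ind: dict[str, InsertionProfile],
        flank: int = 30,
        eps: float = 0.1,
        min_sites: int = 20,
    ):
        if set(profiles_con) != set(profiles_ind):
            raise ValueError("motif panels differ between conditions")
        self.profiles_con = profiles_con
        self.profiles_ind = profiles_ind
        self.flank = flank
        self.eps = eps
        self.min_sites = min_sites

    def fit(self, n_perm: int = 1000, seed: int = 0) -> "FootprintResults":
        motifs, site_scores = [], {}
        for m in sorted(self.profiles_con):
            pc, pi = self.profiles_con[m], self.profiles_ind[m]
            if pc.n_sites < self.min_sites or pi.n_sites < self.min_sites:
                warn(f"motif {m!r} has < {self.min_sites} sites; skipped")
                continue
            motifs.append(m)
            site_scores[m] = (
                per_site_scores(pc, self.flank, self.eps),
                per_site_scores(pi, self.flank, self.eps),
            )
        if not motifs:
            raise ValueError("no motif has enough sites")
        raw_con = np.array([site_scores[m][0].mean() for m in motifs])
        raw_ind = np.array([site_scores[m][1].mean() for m in motifs])
        score_con = _minmax(raw_con)
        score_ind = _minmax(raw_ind)
        delta = score_ind - score_con

        rng = np.random.default_rng(seed)
        pvals = np.empty(len(motifs))
        for k, m in enumerate(motifs):
            a, b = site_scores[m]
            obs = b.mean() - a.mean()
            pooled = np.concatenate([a, b])
            n_a = len(a)
            hits = 0
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                stat = perm[n_a:].mean() - perm[:n_a].mean()
                if abs(stat) >= abs(obs):
                    hits += 1
            pvals[k] = (1 + hits) / (n_perm + 1)

        table = pd.DataFrame(
            {
                "motif": motifs,
                "raw_con": raw_con,
                "raw_ind": raw_ind,
                "score_con": score_con,
                "score_ind": score_ind,
                "delta": delta,
                "pvalue": pvals,
            }
        )
        table["significant"] = (table["delta"].abs() >= 0.2) & (table["pvalue"] < 0.05)
        return FootprintResults(model=self, table=table, n_perm=n_perm, seed=seed)


@dataclass
class FootprintResults:
    """FootprintCall table: motif, score_con, score_ind, delta, pvalue,
    significant (|delta| >= 0.2 and p < 0.05)."""

    model: FootprintModel
    table: pd.DataFrame
    n_perm: int
    seed: int

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        t = self.table
        lines = [
            "Differential TF footprinting (permutation)",
            f"  motifs tested : {len(t)}",
            f"  permutations  : {self.n_perm}",
            f"  significant   : {int(t['significant'].sum())} (|delta| >= 0.2, p < 0.05)",
        ]
        for rec in t[t["significant"]].itertuples():
            lines.append(
                f"    {rec.motif}: delta = {rec.delta:+.3f}, p = {rec.pvalue:.4g}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def differential_binding(
    profiles_con: dict[str, InsertionProfile],
    profiles_ind: dict[str, InsertionProfile],
    n_perm: int = 1000,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Functional wrapper around :class:`FootprintModel`."""
    return FootprintModel(profiles_con, profiles_ind, **kwargs).fit(
        n_perm=n_perm, seed=seed
    ).table
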