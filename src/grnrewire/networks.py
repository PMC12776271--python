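"""Condition-specific gene-regulatory-network construction and differencing.

A TF is linked to a candidate target gene when a peak assigned to that gene
(promoter overlap, else nearest TSS within a distal limit) carries a motif hit
for the TF. Each candidate edge gets a transparent confidence score on [0, 1]:
the geometric mean of (i) the best hit's motif match fraction, (ii) the
accessibility quantile rank of the linking peak within the condition's mean
normalised ATAC signal, and (iii) the absolute Pearson correlation between TF
and target expression across the condition's samples (blocks pooled). Edges
are retained when score > 0.5 and |corr| > 0.3; networks are compared by
normalised out-degree, TF-TF target sharing, and edge-set overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .diff import CountMatrix, size_factors
from .intervals import GeneModels, PeakSet, warn

EDGE_COLUMNS = ["tf", "target", "peak", "score", "corr", "condition"]


# ---------------------------------------------------------------- peak -> gene


def assign_peaks_to_genes(
    peaks: PeakSet,
    genes: GeneModels,
    promoter: int = 3000,
    max_distal: int = 100_000,
) -> pd.DataFrame:
    """Assign each peak to a gene by summit position.

    A summit inside a promoter window [TSS - promoter, TSS + promoter)
    assigns the peak to that gene (nearest TSS when several promoters
    overlap); otherwise the nearest TSS within ``max_distal`` gives a distal
    assignment; otherwise the peak is unassigned (gene = NA).

    Returns a frame: peak, gene, distance, assignment in
    {promoter, distal, unassigned}.
    """
    rows = []
    by_chrom = {c: sub.reset_index(drop=True) for c, sub in genes.df.groupby("chrom")}
    sorted_tss = {
        c: (np.sort(sub["tss"].values), np.argsort(sub["tss"].values, kind="mergesort"))
        for c, sub in by_chrom.items()
    }
    for name, chrom, summit in zip(peaks.df["name"], peaks.df["chrom"], peaks.summits):
        sub = by_chrom.get(chrom)
        if sub is None or not len(sub):
            rows.append((name, pd.NA, np.nan, "unassigned"))
            continue
        tss_sorted, order = sorted_tss[chrom]
        j = np.searchsorted(tss_sorted, summit)
        cand = [k for k in (j - 1, j) if 0 <= k < len(tss_sorted)]
        dists = np.abs(tss_sorted[np.array(cand)] - summit)
        best = cand[int(np.argmin(dists))]
        gene_row = sub.iloc[order[best]]
        dist = int(abs(gene_row["tss"] - summit))
        # promoter rule: half-open [tss - promoter, tss + promoter)
        in_prom = gene_row["tss"] - promoter <= summit < gene_row["tss"] + promoter
        if in_prom:
            rows.append((name, gene_row["gene_id"], dist, "promoter"))
        elif dist <= max_distal:
            rows.append((name, gene_row["gene_id"], dist, "distal"))
        else:
            rows.append((name, pd.NA, np.nan, "unassigned"))
    return pd.DataFrame(rows, columns=["peak", "gene", "distance", "assignment"])


# ---------------------------------------------------------------- GRN


@dataclass
class GRN:
    """A condition-specific directed TF -> target network."""

    condition: str
    edges: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EDGE_COLUMNS))

    def __post_init__(self) -> None:
        self.edges = self.edges.reset_index(drop=True)

    @property
    def nodes(self) -> set[str]:
        return set(self.edges["tf"]) | set(self.edges["target"])

    @property
    def tfs(self) -> set[str]:
        return set(self.edges["tf"])

    def edge_keys(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["tf"], self.edges["target"]))

    def __len__(self) -> int:
        return len(self.edges)


def _log_expression(counts: pd.DataFrame, cols: pd.Index, blocks: pd.Series) -> pd.DataFrame:
    """log2 normalised expression, centred within block.

    Pooling cell-line blocks without centring lets block baseline offsets
    masquerade as TF-target correlation; per-block centring is the
    correlation analogue of the additive ~ block + condition design.
    """
    sf = size_factors(counts)
    norm = np.log2(counts[cols] / sf[cols] + 1.0)
    for b in blocks.unique():
        bcols = cols[blocks[cols] == b]
        norm[bcols] = norm[bcols].sub(norm[bcols].mean(axis=1), axis=0)
    return norm


def build_grn(
    rna: CountMatrix,
    atac: CountMatrix,
    hits: pd.DataFrame,
    peak2gene: pd.DataFrame,
    tf2motif: dict[str, list[str] | str],
    condition: str,
    score_threshold: float = 0.5,
    corr_threshold: float = 0.3,
) -> GRN:
    """Build the TF -> target network for one condition.

    ``hits`` are MotifHit rows from :func:`grnrewire.motifs.scan_peaks`;
    ``peak2gene`` from :func:`assign_peaks_to_genes`; ``tf2motif`` maps TF gene
    ids to their motif id(s). When several peaks link a pair, the max-score
    peak is kept.
    """
    cols = rna.sample_ids(condition)
    if len(cols) < 3:
        raise ValueError(f"need >= 3 samples in condition {condition!r} for correlation")

    expr = _log_expression(rna.counts, cols, rna.samples["block"])
    # accessibility quantile rank of each peak within the condition
    atac_cols = atac.sample_ids(condition)
    atac_sf = size_factors(atac.counts)
    acc_mean = (atac.counts[atac_cols] / atac_sf[atac_cols]).mean(axis=1)
    n_pk = len(acc_mean)
    acc_rank = pd.Series(
        (rankdata(acc_mean.values, method="average") - 1) / max(n_pk - 1, 1),
        index=acc_mean.index,
    )

    motif2tfs: dict[str, list[str]] = {}
    for tf, ms in tf2motif.items():
        if tf not in rna.counts.index:
            warn(f"TF {tf!r} absent from RNA features; excluded")
            continue
        for m in [ms] if isinstance(ms, str) else list(ms):
            motif2tfs.setdefault(m, []).append(tf)

    gene_of = peak2gene.set_index("peak")["gene"]
    cand = hits[hits["motif"].isin(motif2tfs)].copy()
    cand["target"] = cand["peak"].map(gene_of)
    cand = cand.dropna(subset=["target"])

    # best hit per (motif, peak)
    cand = (
        cand.sort_values("match_fraction", ascending=False, kind="mergesort")
        .groupby(["motif", "peak"], as_index=False, sort=False)
        .head(1)
    )

    expr_v = expr.values
    feat_pos = {f: i for i, f in enumerate(expr.index)}
    X = expr_v - expr_v.mean(axis=1, keepdims=True)
    norms = np.sqrt((X**2).sum(axis=1))

    def corr(a: str, b: str) -> float:
        ia, ib = feat_pos.get(a), feat_pos.get(b)
        if ia is None or ib is None or norms[ia] == 0 or norms[ib] == 0:
            return 0.0
        return float(X[ia] @ X[ib] / (norms[ia] * norms[ib]))

    rows = []
    for rec in cand.itertuples():
        for tf in motif2tfs[rec.motif]:
            target = rec.target
            if target == tf:
                # a gene's correlation with itself is degenerate (r = 1);
                # self-edges carry no co-expression evidence and are dropped
                continue
            r = corr(tf, target)
            rank = float(acc_rank.get(rec.peak, 0.0))
            score = float((rec.match_fraction * rank * abs(r)) ** (1.0 / 3.0))
            if score > score_threshold and abs(r) > corr_threshold:
                rows.append((tf, target, rec.peak, score, r, condition))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    if len(edges):
        edges = (
            edges.sort_values("score", ascending=False, kind="mergesort")
            .groupby(["tf", "target"], as_index=False, sort=False)
            .head(1)
            .sort_values(["tf", "target"], kind="mergesort")
            .reset_index(drop=True)
        )
    return GRN(condition=condition, edges=edges)


# ---------------------------------------------------------------- comparisons


def _degrees(grn: GRN) -> pd.Series:
    n_nodes = len(grn.nodes)
    if n_nodes == 0:
        warn(f"network {grn.condition!r} is empty; all degrees 0")
        return pd.Series(dtype=float)
    denom = max(n_nodes - 1, 1)
    out_deg = grn.edges.groupby("tf").size() / denom
    return out_deg


def degree_and_delta(
    grn_con: GRN | list[GRN], grn_ind: GRN | list[GRN]
) -> pd.DataFrame:
    """Normalised out-degree per TF and its condition difference.

    degree = out-degree / (N - 1) with N the node count of that network;
    replicate networks (lists) are averaged. TFs absent from a network get
    degree 0 so delta_degree is always defined.
    """
    reps_con = grn_con if isinstance(grn_con, list) else [grn_con]
    reps_ind = grn_ind if isinstance(grn_ind, list) else [grn_ind]
    deg_con = pd.concat([_degrees(g) for g in reps_con], axis=1).fillna(0.0).mean(axis=1)
    deg_ind = pd.concat([_degrees(g) for g in reps_ind], axis=1).fillna(0.0).mean(axis=1)
    tfs = sorted(set(deg_con.index) | set(deg_ind.index))
    out = pd.DataFrame(
        {
            "degree_con": deg_con.reindex(tfs).fillna(0.0),
            "degree_ind": deg_ind.reindex(tfs).fillna(0.0),
        },
        index=pd.Index(tfs, name="tf"),
    )
    out["delta_degree"] = out["degree_ind"] - out["degree_con"]
    return out


def tf_tf_projection(grn: GRN) -> nx.Graph:
    """Weighted TF-TF graph; weight(u, v) = |targets(u) & targets(v)|,
    zero-weight pairs omitted."""
    targets = {tf: set(sub["target"]) for tf, sub in grn.edges.groupby("tf")}
    g = nx.Graph()
    g.add_nodes_from(targets)
    tfs = sorted(targets)
    for i, u in enumerate(tfs):
        for v in tfs[i + 1 :]:
            w = len(targets[u] & targets[v])
            if w > 0:
                g.add_edge(u, v, weight=w)
    return g


def network_overlap(grn_a: GRN, grn_b: GRN) -> dict[str, float]:
    """Edge-set overlap by (tf, target) key.

    Returns shared_fraction = |A & B| / |A | B| plus the per-network shared
    fractions |A & B|/|A| and |A & B|/|B| (NaN with a warning when both are
    empty).
    """
    ea, eb = grn_a.edge_keys(), grn_b.edge_keys()
    union = ea | eb
    inter = ea & eb
    if not union:
        warn("both networks empty; overlap undefined")
        return {
            "shared_fraction": float("nan"),
            "fraction_of_a": float("nan"),
            "fraction_of_b": float("nan"),
            "n_shared": 0,
        }
    return {
        "shared_fraction": len(inter) / len(union),
        "fraction_of_a": len(inter) / len(ea) if ea else float("nan"),
        "fraction_of_b": len(inter) / len(eb) if eb else float("nan"),
        "n_shared": len(inter),
    }


GROUP_OF_STATUS = {"up": "Activated", "down": "Repressed", "ns": "Unchanged"}


def summarize_tfs(
    diff_table: pd.DataFrame,
    footcalls: pd.DataFrame | None,
    degrees: pd.DataFrame,
) -> pd.DataFrame:
    """Join connectivity, expression and footprint modalities per TF.

    ``diff_table`` is an NBDiffResults table (indexed by feature), ``footcalls``
    a FootprintResults table keyed by motif/TF (may be None), ``degrees`` from
    :func:`degree_and_delta`. TFs missing a modality carry missing values; the
    group follows the expression status (Activated/Repressed/Unchanged).
    """
    out = degrees.copy()
    tfs = out.index
    de = diff_table.reindex(tfs)
    out["log2fc"] = de["log2fc"]
    out["padj"] = de["padj"]
    out["de_status"] = de["status"]
    if footcalls is not None and len(footcalls):
        fc = footcalls.set_index("motif") if "motif" in footcalls.columns else footcalls
        out["footprint_delta"] = fc["delta"].reindex(tfs)
    else:
        out["footprint_delta"] = np.nan
    out["group"] = out["de_status"].map(GROUP_OF_STATUS)
    return out
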