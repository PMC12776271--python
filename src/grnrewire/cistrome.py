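"""Two-factor x two-condition cistrome stratification and annotation.

Four ChIP peak sets (factor A and factor B, each under a control and an
induced condition) are stratified into six groups: per factor, a control peak
is *shared* iff it overlaps (>= 1 bp) any induced-condition peak, otherwise
condition-specific (and symmetrically for induced peaks). Peaks are annotated
by summit position as promoter (+/- 3 kb of a TSS), intragenic (inside a gene
body outside promoters) or distal intergenic, with promoter > intragenic >
distal priority. Association tables count differential regions overlapping
each group and the unique differential genes its peaks are assigned to, and
the redistribution statistic measures how much of one factor's lost cistrome
is taken over by the other factor's gained sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GeneModels, PeakSet, merge_union, warn

GROUPS = ["A_CON_specific", "A_IND_specific", "A_shared",
          "B_CON_specific", "B_IND_specific", "B_shared"]


@dataclass
class GroupAssignment:
    group: str
    peaks: PeakSet
    # counts of the shared side(s) used to build the group
    n_con: int = 0
    n_ind: int = 0


def _stratify_factor(
    con: PeakSet, ind: PeakSet, prefix: str
) -> tuple[dict[str, GroupAssignment], dict[str, float]]:
    if len(con) == 0 or len(ind) == 0:
        warn(f"{prefix}: empty input set; groups empty")
    con_shared = con.overlaps_any(ind)
    ind_shared = ind.overlaps_any(con)
    shared_con = con.subset(con_shared, f"{prefix}_shared_CON")
    shared_ind = ind.subset(ind_shared, f"{prefix}_shared_IND")
    merged = merge_union(shared_con, shared_ind, name=f"{prefix}_shared")
    groups = {
        f"{prefix}_CON_specific": GroupAssignment(
            f"{prefix}_CON_specific", con.subset(~con_shared, f"{prefix}_CON_specific")
        ),
        f"{prefix}_IND_specific": GroupAssignment(
            f"{prefix}_IND_specific", ind.subset(~ind_shared, f"{prefix}_IND_specific")
        ),
        f"{prefix}_shared": GroupAssignment(
            f"{prefix}_shared", merged, n_con=int(con_shared.sum()), n_ind=int(ind_shared.sum())
        ),
    }
    n_con, n_ind = len(con), len(ind)
    n_sh_con = int(con_shared.sum())
    summary = {
        "n_con": n_con,
        "n_ind": n_ind,
        "n_shared_con_side": n_sh_con,
        "n_shared_ind_side": int(ind_shared.sum()),
        "n_shared_merged": len(merged),
        "pct_shared_of_con": 100.0 * n_sh_con / n_con if n_con else float("nan"),
        "pct_shared_of_ind": 100.0 * int(ind_shared.sum()) / n_ind if n_ind else float("nan"),
        "n_con_specific": n_con - n_sh_con,
        "n_ind_specific": n_ind - int(ind_shared.sum()),
    }
    return groups, summary


def stratify_peak_groups(
    a_con: PeakSet, a_ind: PeakSet, b_con: PeakSet, b_ind: PeakSet
) -> tuple[dict[str, GroupAssignment], dict[str, dict[str, float]]]:
    """Six-group stratification of two factors' cistromes across conditions.

    Returns (groups keyed by the C1..C6-style names A/B x
    {CON_specific, IND_specific, shared}, per-factor overlap summary). Shared
    counts are reported from both sides plus as merged union regions, with the
    shared percentages shared/|CON| and shared/|IND|.
    """
    groups_a, summary_a = _stratify_factor(a_con, a_ind, "A")
    groups_b, summary_b = _stratify_factor(b_con, b_ind, "B")
    return {**groups_a, **groups_b}, {"A": summary_a, "B": summary_b}


def annotate_context(
    peaks: PeakSet, genes: GeneModels, promoter: int = 3000
) -> tuple[pd.Series, pd.Series]:
    """Label each peak summit as promoter / intragenic / distal_intergenic.

    Priority promoter > intragenic > distal; promoter windows are
    [TSS - promoter, TSS + promoter) and gene bodies span TSS..TES.
    Returns (per-peak labels indexed by peak name, per-set fractions).
    """
    bodies = genes.body_bounds()
    labels = []
    for name, chrom, summit in zip(peaks.df["name"], peaks.df["chrom"], peaks.summits):
        g = genes.df[genes.df["chrom"] == chrom]
        if len(g) and (
            (g["tss"] - promoter <= summit) & (summit < g["tss"] + promoter)
        ).any():
            labels.append("promoter")
            continue
        b = bodies[bodies["chrom"] == chrom]
        if len(b) and ((b["lo"] <= summit) & (summit < b["hi"])).any():
            labels.append("intragenic")
        else:
            labels.append("distal_intergenic")
    lab = pd.Series(labels, index=peaks.df["name"], name="context")
    frac = lab.value_counts(normalize=True).reindex(
        ["promoter", "intragenic", "distal_intergenic"], fill_value=0.0
    )
    return lab, frac


def associate_dars_degs(
    groups: dict[str, GroupAssignment],
    dar_peaks: PeakSet,
    dar_table: pd.DataFrame,
    deg_table: pd.DataFrame,
    peak2gene: pd.DataFrame,
) -> pd.DataFrame:
    """Per-group counts of overlapping open/closed DARs and linked up/down DEGs.

    ``dar_peaks`` is the ATAC peak universe (names matching ``dar_table``
    index, an NBDiffResults table on peaks); ``deg_table`` an NBDiffResults
    table on genes; ``peak2gene`` assigns group peaks to genes (peaks without
    a gene are excluded from DEG counting only). DEGs are de-duplicated per
    group.
    """
    dar_status = dar_table["status"]
    open_mask = (dar_status == "up").reindex(dar_peaks.df["name"]).fillna(False).values
    closed_mask = (dar_status == "down").reindex(dar_peaks.df["name"]).fillna(False).values
    open_dars = dar_peaks.subset(open_mask, "open_DARs")
    closed_dars = dar_peaks.subset(closed_mask, "closed_DARs")
    gene_of = peak2gene.set_index("peak")["gene"]
    deg_status = deg_table["status"]
    rows = []
    for name, ga in groups.items():
        n_open = int(open_dars.overlaps_any(ga.peaks).sum()) if len(ga.peaks) else 0
        n_closed = int(closed_dars.overlaps_any(ga.peaks).sum()) if len(ga.peaks) else 0
        genes_hit = (
            gene_of.reindex(ga.peaks.df["name"]).dropna().unique()
            if len(ga.peaks)
            else np.array([], dtype=object)
        )
        st = deg_status.reindex(genes_hit)
        rows.append((name, n_open, n_closed, int((st == "up").sum()), int((st == "down").sum())))
    return pd.DataFrame(
        rows, columns=["group", "n_open_DAR", "n_closed_DAR", "n_up_DEG", "n_down_DEG"]
    ).set_index("group")


def redistribution(
    lost_b: PeakSet, gained_a: PeakSet, genes: GeneModels | None = None, promoter: int = 3000
) -> dict[str, float]:
    """Fraction of factor B's condition-lost peaks overlapping factor A's
    condition-gained peaks, and the promoter-proximal fraction of that
    redistributed subset."""
    if len(lost_b) == 0:
        warn("no lost peaks; redistribution undefined")
        return {"n_lost": 0, "n_redistributed": 0,
                "fraction": float("nan"), "promoter_fraction": float("nan")}
    mask = lost_b.overlaps_any(gained_a)
    redis = lost_b.subset(mask, "redistributed")
    out = {
        "n_lost": len(lost_b),
        "n_redistributed": len(redis),
        "fraction": len(redis) / len(lost_b),
    }
    if genes is not None and len(redis):
        _, frac = annotate_context(redis, genes, promoter=promoter)
        out["promoter_fraction"] = float(frac["promoter"])
    else:
        out["promoter_fraction"] = float("nan")
    return out
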