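"""Negative-binomial differential testing for RNA and ATAC count matrices.

The model is a deliberately transparent stand-in for a full NB GLM pipeline:
median-of-ratios size factors, a method-of-moments dispersion per feature, and
a per-block Wald statistic on the log2 ratio of normalised condition means
(delta-method standard errors under NB variance), with blocks combined by
inverse-variance weighting. This mirrors an additive ``~ block + condition``
design: the block (e.g. cell line) contributes a baseline offset that the
within-block contrast removes. Benjamini-Hochberg correction is applied
across features and features are classified up/down/ns at the conventional
|log2FC| > 1, adjusted p < 0.05 rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import warn

LN2 = np.log(2.0)


@dataclass
class CountMatrix:
    """Integer features x samples with sample metadata.

    Parameters
    ----------
    counts : DataFrame, features x samples, non-negative integers.
    samples : DataFrame indexed by sample id with columns ``condition``
        (two levels, e.g. CON/IND), ``replicate`` and ``block``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.counts.columns) == set(self.samples.index):
            raise ValueError("counts columns and sample sheet do not match")
        self.counts = self.counts[self.samples.index]
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        for col in ("condition", "block"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet missing {col!r}")
        levels = self.samples["condition"].unique()
        if len(levels) == 2:
            counts_per = self.samples["condition"].value_counts()
            if (counts_per < 2).any():
                raise ValueError("need >= 2 samples per condition")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.samples["condition"].unique())

    def sample_ids(self, condition: str | None = None) -> pd.Index:
        if condition is None:
            return self.samples.index
        return self.samples.index[self.samples["condition"] == condition]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Features with a zero geometric mean (any zero count) are excluded from the
    medians; if none remain, falls back to library-size ratios with a warning.
    """
    mat = counts.values.astype(float)
    if (mat.sum(axis=0) == 0).any():
        raise ValueError("every sample needs at least one nonzero count")
    with np.errstate(divide="ignore"):
        logmat = np.log(mat)
    geo = logmat.mean(axis=1)  # -inf where any zero
    usable = np.isfinite(geo)
    if usable.sum() == 0:
        warn("no feature expressed in all samples; falling back to library-size factors")
        sf = mat.sum(axis=0)
    else:
        ratios = logmat[usable] - geo[usable, None]
        sf = np.exp(np.median(ratios, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def nb_dispersion(counts: pd.DataFrame, sf: pd.Series, condition: pd.Series) -> pd.Series:
    """Per-feature NB dispersion alpha by method of moments.

    alpha = max(0, (s^2 - m) / m^2) on normalised counts pooled within each
    condition (unbiased sample variance), averaged across conditions;
    constant features come out exactly 0.
    """
    norm = counts.values / sf.values[None, :]
    alphas = []
    for lev in sorted(condition.unique()):
        cols = (condition == lev).values
        sub = norm[:, cols]
        n = sub.shape[1]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1) if n > 1 else np.zeros(sub.shape[0])
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / m**2
        a = np.where(m > 0, a, 0.0)
        alphas.append(np.maximum(a, 0.0))
    return pd.Series(np.mean(alphas, axis=0), index=counts.index, name="dispersion")


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    return multipletests(pvalues, method="fdr_bh")[1]


class NBDiffModel:
    """Blocked NB Wald test of condition IND vs CON.

    Parameters
    ----------
    data : CountMatrix
    baseline, treated : str
        Condition labels; log2FC is treated vs baseline.
    """

    def __init__(self, data: CountMatrix, baseline: str = "CON", treated: str = "IND"):
        levels = set(data.samples["condition"])
        if not {baseline, treated} <= levels:
            raise ValueError(f"conditions {baseline}/{treated} not both present in {levels}")
        self.data = data
        self.baseline = baseline
        self.treated = treated

    def fit(
        self,
        alpha: float = 0.05,
        lfc_threshold: float = 1.0,
        pseudocount: float = 0.5,
    ) -> "NBDiffResults":
        cm = self.data
        sf = size_factors(cm.counts)
        disp = nb_dispersion(cm.counts, sf, cm.samples["condition"])
        counts = cm.counts.values.astype(float)
        norm = counts / sf.values[None, :]
        disp_v = np.maximum(disp.values, 1e-8)  # variance floor only

        lfc_blocks, var_blocks = [], []
        used_blocks = []
        for block in sorted(cm.samples["block"].unique()):
            in_block = cm.samples["block"] == block
            cols_con = ((cm.samples["condition"] == self.baseline) & in_block).values
            cols_ind = ((cm.samples["condition"] == self.treated) & in_block).values
            if cols_con.sum() == 0 or cols_ind.sum() == 0:
                warn(f"block {block!r} missing one condition; dropped")
                continue
            used_blocks.append(block)
            lfc_b, var_b = self._block_stats(
                norm, sf.values, disp_v, cols_con, cols_ind, pseudocount
            )
            lfc_blocks.append(lfc_b)
            var_blocks.append(var_b)
        if not lfc_blocks:
            raise ValueError("all blocks dropped: no block has both conditions")

        lfc_blocks = np.array(lfc_blocks)  # (B, F)
        var_blocks = np.array(var_blocks)
        w = 1.0 / var_blocks
        lfc = (w * lfc_blocks).sum(axis=0) / w.sum(axis=0)
        se = 1.0 / np.sqrt(w.sum(axis=0))
        z = lfc / se
        pvalue = 2.0 * stats.norm.sf(np.abs(z))

        # zero-mean features: defined as lfc 0, p 1 (keeps the table rectangular)
        dead = norm.mean(axis=1) == 0
        lfc[dead], se[dead], pvalue[dead] = 0.0, np.inf, 1.0

        padj = benjamini_hochberg(pvalue)
        status = np.where(
            (padj < alpha) & (lfc > lfc_threshold),
            "up",
            np.where((padj < alpha) & (lfc < -lfc_threshold), "down", "ns"),
        )
        table = pd.DataFrame(
            {
                "feature": cm.counts.index,
                "log2fc": lfc,
                "se": se,
                "pvalue": pvalue,
                "padj": padj,
                "status": status,
            }
        ).set_index("feature")
        return NBDiffResults(
            model=self,
            table=table,
            size_factors=sf,
            dispersions=disp,
            blocks=used_blocks,
            alpha=alpha,
            lfc_threshold=lfc_threshold,
        )

    @staticmethod
    def _block_stats(norm, sf, disp, cols_con, cols_ind, pseudocount):
        out = []
        for cols in (cols_con, cols_ind):
            sub = norm[:, cols]
            m = sub.mean(axis=1)
            n = cols.sum()
            # Var(K_j / s_j) = m / s_j + alpha m^2 under NB(m s_j, alpha)
            var_mean = (m[:, None] / sf[None, cols] + disp[:, None] * m[:, None] ** 2).sum(
                axis=1
            ) / n**2
            mshift = m + pseudocount
            var_log2 = var_mean / (mshift**2 * LN2**2)
            out.append((np.log2(mshift), var_log2))
        (l_con, v_con), (l_ind, v_ind) = out
        var = v_con + v_ind
        return l_ind - l_con, np.maximum(var, 1e-12)


@dataclass
class NBDiffResults:
    """Differential-test results; ``table`` holds one row per feature with
    log2fc, se, pvalue, padj and status in {up, down, ns}."""

    model: NBDiffModel
    table: pd.DataFrame
    size_factors: pd.Series
    dispersions: pd.Series
    blocks: list
    alpha: float
    lfc_threshold: float

    @property
    def n_up(self) -> int:
        return int((self.table["status"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["status"] == "down").sum())

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["status"] != "ns"]

    def summary(self) -> str:
        t = self.table
        lines = [
            "NB blocked Wald differential test",
            f"  contrast        : {self.model.treated} vs {self.model.baseline}",
            f"  blocks combined : {len(self.blocks)} ({', '.join(map(str, self.blocks))})",
            f"  features        : {len(t)}",
            f"  thresholds      : padj < {self.alpha}, |log2FC| > {self.lfc_threshold}",
            f"  up / down / ns  : {self.n_up} / {self.n_down} / {int((t['status'] == 'ns').sum())}",
            f"  median dispersion: {float(np.median(self.dispersions)):.4g}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def diff_test(
    data: CountMatrix,
    baseline: str = "CON",
    treated: str = "IND",
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Functional wrapper: fit the blocked NB Wald model and return the table."""
    return NBDiffModel(data, baseline=baseline, treated=treated).fit(
        alpha=alpha, lfc_threshold=lfc_threshold
    ).table
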