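"""Genomic interval containers and overlap algebra.

All coordinates are 0-based half-open (BED convention). The :class:`PeakSet`
is the unit of cistrome algebra: a named, sorted, duplicate-free collection of
intervals with an optional summit per interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

PEAK_COLUMNS = ["chrom", "start", "end", "name", "summit"]


@dataclass
class PeakSet:
    """A named set of genomic intervals (0-based half-open).

    Parameters
    ----------
    name : str
        Label for the set (e.g. ``"IKAROS_CON"``).
    df : pandas.DataFrame
        Columns ``chrom, start, end, name`` and optionally ``summit``
        (absolute coordinate). Rows are sorted per chromosome and
        de-duplicated on (chrom, start, end).
    factor, condition : str, optional
        The ChIP factor and condition this cistrome belongs to.
    """

    name: str
    df: pd.DataFrame
    factor: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "name" not in df.columns:
            df["name"] = [f"{self.name}_{i}" for i in range(len(df))]
        if "summit" not in df.columns:
            df["summit"] = ((df["start"] + df["end"]) // 2).astype(int)
        df = df[PEAK_COLUMNS]
        if len(df):
            if (df["start"] >= df["end"]).any():
                raise ValueError("intervals must satisfy start < end")
            df = df.drop_duplicates(subset=["chrom", "start", "end"])
            df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def summits(self) -> pd.Series:
        """Summit coordinate per peak (midpoint when no summit was recorded)."""
        return self.df["summit"]

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees for overlap queries."""
        out: dict[str, IntervalTree] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            out[chrom] = IntervalTree.from_tuples(
                (s, e, i) for i, (s, e) in zip(sub.index, zip(sub["start"], sub["end"]))
            )
        return out

    def overlaps_any(self, other: "PeakSet") -> np.ndarray:
        """Boolean mask: does each interval overlap (>= 1 bp) any in *other*?"""
        trees = other.trees()
        mask = np.zeros(len(self.df), dtype=bool)
        for i, (chrom, s, e) in enumerate(
            zip(self.df["chrom"], self.df["start"], self.df["end"])
        ):
            tree = trees.get(chrom)
            if tree is not None and tree.overlaps(s, e):
                mask[i] = True
        return mask

    def subset(self, mask: Iterable[bool], name: str | None = None) -> "PeakSet":
        return PeakSet(
            name or self.name,
            self.df.loc[np.asarray(list(mask), dtype=bool)].reset_index(drop=True),
            factor=self.factor,
            condition=self.condition,
        )


def merge_union(a: PeakSet, b: PeakSet, name: str = "merged") -> PeakSet:
    """Union-merge the intervals of two peak sets (overlap- or book-ended
    intervals are collapsed into one)."""
    df = pd.concat([a.df, b.df], ignore_index=True)
    rows = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out["name"] = [f"{name}_{i}" for i in range(len(out))]
    return PeakSet(name, out)


@dataclass
class GeneModels:
    """Gene models with TSS/TES; internal coordinates are 0-based.

    ``df`` columns: gene_id, chrom, strand ('+'/'-'), tss, tes. TSS and TES
    are inclusive base positions; the gene body spans
    [min(tss, tes), max(tss, tes) + 1) half-open.
    """

    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "strand", "tss", "tes"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        if self.df["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def body_bounds(self) -> pd.DataFrame:
        lo = np.minimum(self.df["tss"], self.df["tes"])
        hi = np.maximum(self.df["tss"], self.df["tes"]) + 1
        return pd.DataFrame(
            {"gene_id": self.df["gene_id"], "chrom": self.df["chrom"], "lo": lo, "hi": hi}
        )


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
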