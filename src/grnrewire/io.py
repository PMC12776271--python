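"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA via Bio.SeqIO, BED6 for peaks and fragments, a GTF-lite TSV for gene
models (1-based inclusive on disk, converted to 0-based internally), TSV count
matrices with a sample sheet, JASPAR-format PFMs via Bio.motifs, and a JSON
truth file for simulations.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GeneModels, PeakSet

# ---------------------------------------------------------------- FASTA


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- BED


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    df = peaks.df.copy()
    df["score"] = 0
    df["strand"] = "."
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: str | Path, name: str | None = None) -> PeakSet:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"],
        dtype={0: str},
    )
    return PeakSet(name or Path(path).stem, df)


def write_fragments(fragments: pd.DataFrame, path: str | Path) -> None:
    """Fragment records: chrom, start, end (0-based half-open; both ends are
    Tn5 insertion-derived), plus sample and condition columns."""
    fragments[["chrom", "start", "end", "sample", "condition"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_fragments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "sample", "condition"],
        dtype={0: str},
    )


# ---------------------------------------------------------------- gene models


def write_genes(genes: GeneModels, path: str | Path) -> None:
    # GTF-lite on disk: 1-based inclusive start/end of the gene body plus
    # strand; TSS/TES (inclusive base positions) are recovered from strand.
    df = genes.df.copy()
    lo = df[["tss", "tes"]].min(axis=1)
    hi = df[["tss", "tes"]].max(axis=1)
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "chrom": df["chrom"],
            "strand": df["strand"],
            "start": lo + 1,  # 1-based inclusive
            "end": hi + 1,
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path) -> GeneModels:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    lo = df["start"] - 1  # back to 0-based inclusive positions
    hi = df["end"] - 1
    plus = df["strand"] == "+"
    tss = lo.where(plus, hi)
    tes = hi.where(plus, lo)
    return GeneModels(
        pd.DataFrame(
            {
                "gene_id": df["gene_id"],
                "chrom": df["chrom"],
                "strand": df["strand"],
                "tss": tss.astype(int),
                "tes": tes.astype(int),
            }
        )
    )


# ---------------------------------------------------------------- counts


def write_counts(counts: pd.DataFrame, samples: pd.DataFrame, prefix: str | Path) -> None:
    prefix = Path(prefix)
    counts.to_csv(prefix.with_suffix(".counts.tsv"), sep="\t")
    samples.to_csv(prefix.with_suffix(".samples.tsv"), sep="\t")


def read_counts(prefix: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    prefix = Path(prefix)
    counts = pd.read_csv(prefix.with_suffix(".counts.tsv"), sep="\t", index_col=0)
    samples = pd.read_csv(prefix.with_suffix(".samples.tsv"), sep="\t", index_col=0)
    return counts, samples


# ---------------------------------------------------------------- truth JSON


def write_truth(truth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def read_truth(path: str | Path):
    from .simulate import TruthSet

    with open(path) as fh:
        return TruthSet.from_dict(json.load(fh))
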