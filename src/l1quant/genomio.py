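"""Reading and writing the interval formats the genomics arm exchanges.

Internally every interval is 0-based half-open (BED convention) in a pandas
frame with at least ``chrom``, ``start``, ``end``.  GTF files are written
1-based closed per the format's standard and converted back on ingest.
"""

from __future__ import annotations

import re

import pandas as pd

__all__ = ["read_bed", "write_bed", "read_gtf_genes", "write_gtf_genes"]

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _BED_COLS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in _BED_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gtf_genes(path) -> pd.DataFrame:
    """Read gene features from a GTF into 0-based half-open intervals."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=[
            "chrom", "source", "feature", "start", "end",
            "score", "strand", "frame", "attributes",
        ],
    )
    df = df[df["feature"] == "gene"].copy()
    df["gene_id"] = df["attributes"].map(
        lambda s: (re.search(r'gene_id "([^"]+)"', s) or [None, None])[1]
    )
    df["start"] = df["start"].astype(int) - 1  # 1-based closed -> 0-based half-open
    df["end"] = df["end"].astype(int)
    return df[["chrom", "start", "end", "strand", "gene_id"]].reset_index(drop=True)


def write_gtf_genes(genes: pd.DataFrame, path) -> None:
    """Write gene intervals (0-based half-open in memory) as GTF gene lines."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        str(row.chrom),
                        "l1quant",
                        "gene",
                        str(int(row.start) + 1),
                        str(int(row.end)),
                        ".",
                        getattr(row, "strand", "+"),
                        ".",
                        f'gene_id "{row.gene_id}";',
                    ]
                )
                + "\n"
            )
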