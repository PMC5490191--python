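"""Readers and writers for the package's plain-text formats.

Everything is TSV-based: gene tables, chromosome sizes, restriction-site
maps, long-format count tables, BED peaks/regions and bedGraph-style
coverage. Coordinates are 0-based half-open throughout. Floats are
written with a fixed format so identical runs produce identical bytes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.6g"


def write_tsv(df: pd.DataFrame, path, header: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, header=header, float_format=FLOAT_FORMAT)


def read_gene_table(path) -> pd.DataFrame:
    """Gene table: gene_id, chrom, strand, tss, tts (TSV with header)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    return df[["gene_id", "chrom", "strand", "tss", "tts"]]


def write_gene_table(genes: pd.DataFrame, path) -> None:
    write_tsv(genes[["gene_id", "chrom", "strand", "tss", "tts"]], path)


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={"chrom": str})
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    write_tsv(
        pd.DataFrame({"chrom": list(sizes), "size": list(sizes.values())}), path, header=False
    )


def read_sites(path) -> dict[str, np.ndarray]:
    """Restriction-site map: chrom <tab> position, sorted per chromosome."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos"], dtype={"chrom": str})
    return {
        str(chrom): np.sort(sub["pos"].to_numpy(dtype=np.int64))
        for chrom, sub in df.groupby("chrom", sort=True)
    }


def write_sites(sites: Mapping[str, np.ndarray], path) -> None:
    frames = [
        pd.DataFrame({"chrom": chrom, "pos": np.sort(np.asarray(pos, dtype=np.int64))})
        for chrom, pos in sites.items()
    ]
    write_tsv(pd.concat(frames, ignore_index=True), path, header=False)


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "group": str, "cell_type": str, "region_id": str, "region_class": str},
    )


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader: chrom, start, end (+ name if present)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    write_tsv(df[cols], path, header=False)


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"], dtype={"chrom": str}
    )


def write_bedgraph(df: pd.DataFrame, path) -> None:
    write_tsv(df[["chrom", "start", "end", "value"]], path, header=False)
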