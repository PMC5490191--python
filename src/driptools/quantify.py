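"""Read counting in regions and library-size / length normalization.

A read is counted in a region iff the two half-open intervals overlap by at
least one base; a read overlapping the regions of two genes is counted in
both (each gene is quantified independently). Normalization follows the
reads-per-million-mapped, per-100-kb convention::

    normalized = raw_count * (1e6 / total_mapped) * (1e5 / region_length)

so a region with exactly one read per 100 kb per million mapped reads
scores 1.0, and values are comparable across samples with different
sequencing depth and across region classes of different length.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

COUNT_COLUMNS = [
    "sample_id",
    "group",
    "cell_type",
    "region_id",
    "region_class",
    "region_length",
    "raw_count",
    "total_mapped",
    "normalized",
]


def count_reads(reads: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Count reads overlapping each region (any-overlap, half-open).

    ``reads``: columns chrom, start, end. ``regions``: columns chrom, start,
    end (other columns preserved). Returns a copy of ``regions`` with a
    ``raw_count`` column. Regions on chromosomes absent from the reads get
    count 0 with a warning.

    For a sorted read set, the number of reads overlapping [s, e) equals
    ``#{read.start < e} − #{read.end <= s}`` (the two excluded sets are
    disjoint because every read has start < end).
    """
    out = regions.copy()
    counts = np.zeros(len(out), dtype=np.int64)
    read_chroms = set(reads["chrom"].unique()) if len(reads) else set()
    for chrom, idx in out.groupby("chrom", sort=False).groups.items():
        sub = reads[reads["chrom"] == chrom] if len(reads) else reads
        if len(sub) == 0:
            if chrom not in read_chroms:
                log.warning("no reads on chromosome %s; regions counted as 0", chrom)
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        r_start = out.loc[idx, "start"].to_numpy()
        r_end = out.loc[idx, "end"].to_numpy()
        n_start_before_end = np.searchsorted(starts, r_end, side="left")
        n_end_before_start = np.searchsorted(ends, r_start, side="right")
        counts[out.index.get_indexer(idx)] = n_start_before_end - n_end_before_start
    out["raw_count"] = counts
    return out


def normalize(
    raw_count: np.ndarray | float,
    total_mapped: np.ndarray | float,
    region_length: np.ndarray | float,
) -> np.ndarray | float:
    """Reads per million mapped reads per 100 kb of region."""
    total = np.asarray(total_mapped, dtype=float)
    length = np.asarray(region_length, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total_mapped must be positive")
    if np.any(length <= 0):
        raise ValueError("region_length must be positive")
    return np.asarray(raw_count, dtype=float) * (1e6 / total) * (1e5 / length)


def make_count_table(
    counted: pd.DataFrame,
    sample_id: str,
    group: str,
    cell_type: str,
    total_mapped: int,
) -> pd.DataFrame:
    """Assemble a long-format count table for one sample.

    ``counted`` is the output of :func:`count_reads` on a RegionSet frame
    (needs region_id, region_class, raw_count and start/end or
    region_length). Zero-length regions are excluded with a log record.
    """
    df = counted.copy()
    if "region_length" not in df.columns:
        df["region_length"] = df["end"] - df["start"]
    bad = df["region_length"] <= 0
    if bad.any():
        log.warning("excluding %d zero-length regions from normalization", int(bad.sum()))
        df = df[~bad]
    df = df[["region_id", "region_class", "region_length", "raw_count"]].copy()
    df.insert(0, "sample_id", sample_id)
    df.insert(1, "group", group)
    df.insert(2, "cell_type", cell_type)
    df["total_mapped"] = total_mapped
    df["normalized"] = normalize(
        df["raw_count"].to_numpy(), total_mapped, df["region_length"].to_numpy()
    )
    return df[COUNT_COLUMNS]
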