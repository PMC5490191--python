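"""Peak post-processing: restriction-fragment extension, TSS assignment,
group consensus, the two-group BRCA1-associated classification, and
set-overlap statistics.

DRIP is performed on restriction-digested genomic DNA, so the natural
resolution of an R-loop signal is the restriction fragment: every called
peak is first extended outward to the nearest enzyme cut sites (or the
chromosome ends). A gene is TSS-bound in a sample when a peak overlaps its
TSS coordinate, and a group's consensus set is the intersection over all
of its samples — a gene must be TSS-peaked in every donor of the group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

PEAK_COLUMNS = ["chrom", "start", "end", "orig_start", "orig_end"]


@dataclass
class PeakSet:
    """Per-sample peak intervals, optionally restriction-fragment extended.

    ``peaks`` columns: chrom, start, end and (after extension) orig_start,
    orig_end recording the pre-extension span for provenance.
    """

    sample_id: str
    peaks: pd.DataFrame
    extended: bool = False

    def __post_init__(self) -> None:
        if len(self.peaks) and not (self.peaks["start"] < self.peaks["end"]).all():
            raise ValueError("peak intervals must satisfy start < end")

    @classmethod
    def from_intervals(cls, sample_id: str, intervals: Iterable[tuple[str, int, int]]) -> "PeakSet":
        df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
        return cls(sample_id, df)


def _merge_overlapping(df: pd.DataFrame) -> pd.DataFrame:
    """Merge strictly overlapping intervals per chromosome, pooling provenance."""
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"]).to_dict("records")
        cur = dict(sub[0])
        for nxt in sub[1:]:
            if nxt["start"] < cur["end"]:  # strict overlap; touching peaks stay separate
                cur["end"] = max(cur["end"], nxt["end"])
                cur["orig_start"] = min(cur["orig_start"], nxt["orig_start"])
                cur["orig_end"] = max(cur["orig_end"], nxt["orig_end"])
            else:
                rows.append(cur)
                cur = dict(nxt)
        rows.append(cur)
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def extend_peaks(
    peakset: PeakSet,
    sites: Mapping[str, np.ndarray],
    chrom_sizes: Mapping[str, int],
) -> PeakSet:
    """Extend every peak outward to the nearest restriction cut sites.

    New start = greatest cut site ≤ original start (else chromosome start);
    new end = least cut site ≥ original end (else chromosome end).
    Overlapping extended peaks are merged. Peaks on a chromosome missing
    from the site map extend to the chromosome bounds with a warning.
    """
    if len(peakset.peaks) == 0:
        return PeakSet(peakset.sample_id, peakset.peaks.assign(orig_start=[], orig_end=[]), True)
    parts = []
    for chrom, sub in peakset.peaks.groupby("chrom", sort=True):
        size = chrom_sizes[chrom]
        cut = np.sort(np.asarray(sites.get(chrom, []), dtype=np.int64))
        if cut.size == 0:
            log.warning(
                "sample %s: chromosome %s absent from site map; peaks extended to bounds",
                peakset.sample_id, chrom,
            )
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        if cut.size == 0:
            new_start = np.zeros_like(starts)
            new_end = np.full_like(ends, size)
        else:
            i = np.searchsorted(cut, starts, side="right") - 1
            new_start = np.where(i >= 0, cut[np.maximum(i, 0)], 0)
            j = np.searchsorted(cut, ends, side="left")
            new_end = np.where(j < cut.size, cut[np.minimum(j, cut.size - 1)], size)
        parts.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": new_start,
                    "end": new_end,
                    "orig_start": starts,
                    "orig_end": ends,
                }
            )
        )
    ext = _merge_overlapping(pd.concat(parts, ignore_index=True))
    return PeakSet(peakset.sample_id, ext, extended=True)


def assign_tss_peaks(
    peakset: PeakSet,
    genes: pd.DataFrame,
    tss_window: int = 1,
) -> set[str]:
    """Gene ids whose TSS locus is overlapped by a peak in this sample.

    The TSS locus is the ``tss_window``-bp half-open window
    [tss − tss_window//2, tss + (tss_window+1)//2); the default 1 bp is the
    strict reading of "1 bp overlap to the 5' TSS".
    """
    if tss_window < 1:
        raise ValueError("tss_window must be >= 1")
    bound: set[str] = set()
    for chrom, sub in genes.groupby("chrom", sort=False):
        pk = peakset.peaks[peakset.peaks["chrom"] == chrom]
        if len(pk) == 0:
            continue
        starts = np.sort(pk["start"].to_numpy())
        ends = np.sort(pk["end"].to_numpy())
        lo = sub["tss"].to_numpy(dtype=np.int64) - tss_window // 2
        hi = sub["tss"].to_numpy(dtype=np.int64) + (tss_window + 1) // 2
        n_overlap = np.searchsorted(starts, hi, side="left") - np.searchsorted(
            ends, lo, side="right"
        )
        bound |= set(sub.loc[n_overlap > 0, "gene_id"])
    return bound


def consensus_genes(bound_sets: Mapping[str, set[str]]) -> set[str]:
    """Genes TSS-bound in *every* sample of a group (intersection)."""
    if not bound_sets:
        raise ValueError("consensus requires at least one sample")
    sets = list(bound_sets.values())
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


GROUP1 = "group1_quantitative"
GROUP2 = "group2_B1_only"
NONE = "none"


def classify_brca1_associated(
    consensus_nc: set[str],
    consensus_b1: set[str],
    differential: pd.DataFrame,
    fc_cutoff: float = 0.8,
    padj_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Two-group definition of genes with BRCA1-mutation-associated TSS R-loops.

    group1: TSS-consensus-peaked in both NC and B1 with quantitatively
    higher B1 signal (TSS log2FC ≥ fc_cutoff and adjusted P ≤ padj_cutoff).
    group2: TSS-consensus-peaked only in B1. Everything else: none.
    ``differential`` is a differential_rloop table; only its TSS rows are
    used. Genes peaked in both consensuses but missing from the
    differential table are flagged and ineligible for group1.
    """
    tss = differential[differential["region_class"] == "tss"].set_index("gene_id")
    universe = set(tss.index) | consensus_nc | consensus_b1
    rows = []
    for gene in sorted(universe):
        label = NONE
        flagged = False
        if gene in consensus_b1 and gene not in consensus_nc:
            label = GROUP2
        elif gene in consensus_b1 and gene in consensus_nc:
            if gene not in tss.index:
                flagged = True
                log.warning("gene %s in both consensuses but absent from differential table", gene)
            else:
                rec = tss.loc[gene]
                if rec["log2FC"] >= fc_cutoff and rec["p_adj"] <= padj_cutoff:
                    label = GROUP1
        rows.append(dict(gene_id=gene, classification=label, flagged=flagged))
    return pd.DataFrame(rows, columns=["gene_id", "classification", "flagged"])


@dataclass
class OverlapResult:
    """2×2 overlap contingency of two gene sets over a universe."""

    table: np.ndarray  # [[both, a_only], [b_only, neither]]
    odds_ratio: float
    p_value: float
    haldane: bool = field(default=False)


def overlap_fisher(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> OverlapResult:
    """Fisher's exact test (two-sided) for the overlap of two gene sets.

    Odds ratio uses the Haldane–Anscombe +0.5 correction when any cell is
    zero. A and B are intersected with the universe.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    a = set_a & universe
    b = set_b & universe
    both = len(a & b)
    a_only = len(a) - both
    b_only = len(b) - both
    neither = len(universe) - both - a_only - b_only
    table = np.array([[both, a_only], [b_only, neither]], dtype=np.int64)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    haldane = bool((table == 0).any())
    t = table + 0.5 if haldane else table
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return OverlapResult(table=table, odds_ratio=float(odds), p_value=float(p), haldane=haldane)


def toy_peak_caller(
    coverage: pd.DataFrame,
    background: float,
    fold_threshold: float = 5.0,
    min_width: int = 50,
) -> pd.DataFrame:
    """Threshold-and-run peak caller over a bedGraph-style coverage track.

    Maximal runs of bases with coverage ≥ fold_threshold × background
    become peaks; runs narrower than ``min_width`` are dropped. This is
    deliberately simple plumbing so the downstream peak stages can be
    exercised end to end; it is not a model-based caller.
    """
    if background <= 0:
        raise ValueError("background rate must be positive")
    thresh = fold_threshold * background
    rows = []
    for chrom, sub in coverage.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_start = cur_end = None
        for r in sub.itertuples(index=False):
            if r.value >= thresh:
                if cur_end is not None and r.start <= cur_end:
                    cur_end = max(cur_end, r.end)
                else:
                    if cur_start is not None and cur_end - cur_start >= min_width:
                        rows.append((chrom, cur_start, cur_end))
                    cur_start, cur_end = r.start, r.end
        if cur_start is not None and cur_end - cur_start >= min_width:
            rows.append((chrom, cur_start, cur_end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
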