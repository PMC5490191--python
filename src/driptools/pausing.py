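"""Pol II pausing index (travelling ratio) from coverage tracks.

The pausing index of a gene is the ratio of mean Pol II density in the
promoter-proximal window (TSS −30 bp to +300 bp, in the direction of
transcription) to the mean density over the remaining transcribed region
(TSS +300 bp to the TTS). Values well above 1 indicate promoter-proximal
pausing. Coverage is supplied as a bedGraph-style table (chrom, start,
end, value) with non-overlapping intervals; a gene whose body density is
zero has an undefined index and is excluded from cumulative curves rather
than assigned an infinite value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffstats import ranksum_greater
from .regions import GeneModel, tx_window

#: promoter-proximal window in transcription coordinates: [-30, +300) bp
PROMOTER_UPSTREAM = 30
PROMOTER_DOWNSTREAM = 300
#: minimum summed promoter coverage for a gene to count as Pol II-bound
MIN_PROMOTER_SIGNAL = 10.0


@dataclass
class PausingRecord:
    gene_id: str
    promoter_density: float
    body_density: float
    pausing_index: float  # NaN when undefined (zero/empty body)
    polII_bound: bool
    defined: bool


class CoverageTrack:
    """Queryable per-chromosome bedGraph coverage (non-overlapping intervals)."""

    def __init__(self, frame: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in frame.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            self._by_chrom[str(chrom)] = (
                sub["start"].to_numpy(dtype=np.int64),
                sub["end"].to_numpy(dtype=np.int64),
                sub["value"].to_numpy(dtype=float),
            )

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Total coverage (value × overlapped bases) over [start, end)."""
        if end <= start or chrom not in self._by_chrom:
            return 0.0
        starts, ends, values = self._by_chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(values[lo:hi] * np.maximum(ov, 0)))


def pausing_index(
    coverage: CoverageTrack | pd.DataFrame,
    gene: GeneModel,
    promoter_upstream: int = PROMOTER_UPSTREAM,
    promoter_downstream: int = PROMOTER_DOWNSTREAM,
    min_promoter_signal: float = MIN_PROMOTER_SIGNAL,
) -> PausingRecord:
    """Travelling ratio of one gene from a Pol II coverage track.

    Windows are strand-aware (minus-strand genes mirrored). The record is
    flagged undefined when the transcribed window beyond +300 bp is empty
    (gene too short) or carries zero coverage.
    """
    cov = coverage if isinstance(coverage, CoverageTrack) else CoverageTrack(coverage)
    ps, pe = tx_window(gene.strand, gene.tss, -promoter_upstream, promoter_downstream)
    bs, be = tx_window(gene.strand, gene.tss, promoter_downstream, gene.length)
    prom_len = max(pe - ps, 0)
    body_len = max(be - bs, 0)
    prom_sum = cov.window_sum(gene.chrom, ps, pe)
    body_sum = cov.window_sum(gene.chrom, bs, be)
    prom_density = prom_sum / prom_len if prom_len else 0.0
    body_density = body_sum / body_len if body_len else 0.0
    defined = body_len > 0 and body_density > 0
    idx = prom_density / body_density if defined else float("nan")
    return PausingRecord(
        gene_id=gene.gene_id,
        promoter_density=prom_density,
        body_density=body_density,
        pausing_index=idx,
        polII_bound=prom_sum >= min_promoter_signal,
        defined=defined,
    )


def records_frame(records: list[PausingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                gene_id=r.gene_id,
                promoter_density=r.promoter_density,
                body_density=r.body_density,
                pausing_index=r.pausing_index,
                polII_bound=r.polII_bound,
                defined=r.defined,
            )
            for r in records
        ],
        columns=[
            "gene_id", "promoter_density", "body_density",
            "pausing_index", "polII_bound", "defined",
        ],
    )


def pausing_curve(
    records: pd.DataFrame, gene_subset: set[str] | None = None
) -> pd.DataFrame:
    """Cumulative percentage of Pol II-bound genes at or below each index.

    The empirical distribution is restricted to Pol II-bound genes with a
    defined (finite) pausing index; the final value is 100%.
    """
    df = records[records["polII_bound"] & records["defined"]]
    if gene_subset is not None:
        df = df[df["gene_id"].isin(gene_subset)]
    vals = np.sort(df["pausing_index"].to_numpy(dtype=float))
    if vals.size == 0:
        raise ValueError("no Pol II-bound genes with a defined pausing index in subset")
    cum_pct = 100.0 * np.arange(1, vals.size + 1) / vals.size
    return pd.DataFrame({"pausing_index": vals, "cum_pct": cum_pct})


def compare_pausing(indices_a: np.ndarray, indices_b: np.ndarray) -> float:
    """One-sided rank-sum P that set A has larger pausing indices than B.

    Convention: A is the gene set expected to pause more (e.g. genes with
    TSS R-loop peaks), B the comparison set. NaN (undefined) indices are
    dropped; an entirely undefined set is an error.
    """
    a = np.asarray(indices_a, dtype=float)
    b = np.asarray(indices_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both sets need at least one defined pausing index")
    return ranksum_greater(a, b)


def locus_pausing_index(chip_signal_tss: float, chip_signal_body: float) -> float:
    """Amplicon-level pausing index: total Pol II ChIP signal TSS / gene body.

    Used for locus-specific (qPCR-style) measurements where the inputs are
    background-subtracted signals, not coverage windows. Nonpositive body
    signal → NaN (undefined).
    """
    if chip_signal_body <= 0:
        return float("nan")
    return chip_signal_tss / chip_signal_body
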