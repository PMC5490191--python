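"""Strand-aware region construction around annotated genes.

Five region classes are built per the standard DRIP-seq partition of the
genome: the TSS region (±2 kb of the transcription start site), the TTS
region (±2 kb of the termination site), the gene body (between the two
flanks), a promoter-distal control window (100 bp to 2 kb upstream of the
TSS), and gene deserts (fixed 20 kb windows whose every base lies at least
1 Mb from any TSS, used as genome-wide background).

All coordinates are 0-based half-open (BED convention). A gene is anchored
by its annotated 5' end (``tss``) and 3' end (``tts``): on the + strand
``tss < tts`` and the transcribed span is ``[tss, tts)``; on the − strand
``tss > tts`` and the span is ``[tts, tss)``. Strand-aware windows are
expressed in transcription coordinates: offset ``o`` maps to base
``tss + o`` on the + strand and ``tss − o`` on the − strand, so − strand
regions are exact mirrors of their + strand counterparts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REGION_CLASSES = ("tss", "body", "tts", "distal", "desert")

#: half-width of the TSS and TTS flanking windows (bp)
TSS_FLANK = 2000
#: distal control window spans [DISTAL_FAR, DISTAL_NEAR) bp upstream of the TSS
DISTAL_NEAR = 100
DISTAL_FAR = 2000
#: gene-desert tiling window (bp) and minimum base-to-TSS distance (bp)
DESERT_WINDOW = 20_000
DESERT_MIN_TSS_DIST = 1_000_000

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tts"]


@dataclass(frozen=True)
class GeneModel:
    """A single-isoform gene with unique annotated TSS and TTS."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss == self.tts:
            raise ValueError(f"gene {self.gene_id}: tss == tts")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tts")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss > tts")

    @property
    def length(self) -> int:
        return abs(self.tts - self.tss)

    @property
    def span(self) -> tuple[int, int]:
        """Transcribed interval as (start, end), half-open."""
        return (self.tss, self.tts) if self.strand == "+" else (self.tts, self.tss)


def tx_window(strand: str, anchor: int, lo: int, hi: int) -> tuple[int, int]:
    """Half-open genomic interval covering transcription offsets [lo, hi).

    Offset ``o`` is the base ``anchor + o`` on the + strand and
    ``anchor − o`` on the − strand.
    """
    if hi <= lo:
        return (anchor, anchor)  # empty
    if strand == "+":
        return (anchor + lo, anchor + hi)
    return (anchor - hi + 1, anchor - lo + 1)


@dataclass
class RegionSet:
    """Per-gene region intervals plus the genome-wide desert tiling.

    ``genic``: columns chrom, start, end, gene_id, region_class, strand.
    ``deserts``: columns chrom, start, end, desert_id.
    """

    genic: pd.DataFrame
    deserts: pd.DataFrame

    @property
    def frame(self) -> pd.DataFrame:
        """Unified table keyed by region_id (gene_id or desert_id)."""
        g = self.genic.rename(columns={"gene_id": "region_id"}).copy()
        d = self.deserts.rename(columns={"desert_id": "region_id"}).copy()
        d["region_class"] = "desert"
        d["strand"] = "."
        cols = ["chrom", "start", "end", "region_id", "region_class", "strand"]
        out = pd.concat([g[cols], d[cols]], ignore_index=True)
        out["region_length"] = out["end"] - out["start"]
        return out

    def to_bed(self, path) -> None:
        df = self.frame
        bed = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "name": df["region_id"] + "|" + df["region_class"],
                "score": 0,
                "strand": df["strand"],
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str},
        )
        ids = bed["name"].str.rsplit("|", n=1)
        bed["region_id"] = ids.str[0]
        bed["region_class"] = ids.str[1]
        genic = bed[bed["region_class"] != "desert"].rename(
            columns={"region_id": "gene_id"}
        )[["chrom", "start", "end", "gene_id", "region_class", "strand"]]
        deserts = bed[bed["region_class"] == "desert"].rename(
            columns={"region_id": "desert_id"}
        )[["chrom", "start", "end", "desert_id"]]
        return cls(genic.reset_index(drop=True), deserts.reset_index(drop=True))


def _clip(start: int, end: int, size: int) -> tuple[int, int]:
    return max(0, min(start, size)), max(0, min(end, size))


def gene_regions(gene: GeneModel, chrom_size: int) -> list[dict]:
    """The four genic region intervals for one gene, clipped to the chromosome.

    The body is empty (omitted) when the gene span is ≤ 4 kb.
    """
    s = gene.strand
    out = []

    def add(region_class: str, iv: tuple[int, int]) -> None:
        start, end = _clip(*iv, chrom_size)
        if end > start:
            out.append(
                dict(
                    chrom=gene.chrom,
                    start=start,
                    end=end,
                    gene_id=gene.gene_id,
                    region_class=region_class,
                    strand=s,
                )
            )

    add("tss", tx_window(s, gene.tss, -TSS_FLANK, TSS_FLANK))
    add("tts", tx_window(s, gene.tts, -TSS_FLANK, TSS_FLANK))
    add("body", tx_window(s, gene.tss, TSS_FLANK, gene.length - TSS_FLANK))
    add("distal", tx_window(s, gene.tss, -DISTAL_FAR, -DISTAL_NEAR))
    return out


def desert_windows(
    tss_positions: np.ndarray,
    chrom_size: int,
    window: int = DESERT_WINDOW,
    min_dist: int = DESERT_MIN_TSS_DIST,
) -> np.ndarray:
    """Start coordinates of desert windows on one chromosome.

    A window [s, s+window) qualifies iff every base is at distance ≥ min_dist
    from every TSS, i.e. no TSS falls strictly inside (s − min_dist,
    s + window − 1 + min_dist). Tiling is fixed-phase from coordinate 0.
    """
    tss = np.sort(np.asarray(tss_positions, dtype=np.int64))
    starts = np.arange(0, chrom_size - window + 1, window, dtype=np.int64)
    if starts.size == 0:
        return starts
    lo = np.searchsorted(tss, starts - min_dist, side="right")
    hi = np.searchsorted(tss, starts + window - 1 + min_dist, side="left")
    return starts[lo == hi]


def genes_from_frame(genes: pd.DataFrame) -> list[GeneModel]:
    return [
        GeneModel(str(r.gene_id), str(r.chrom), str(r.strand), int(r.tss), int(r.tts))
        for r in genes.itertuples(index=False)
    ]


def build_regions(
    genes: pd.DataFrame | Iterable[GeneModel],
    chrom_sizes: Mapping[str, int],
) -> RegionSet:
    """Construct the five region classes for a gene table.

    Genes lying off their chromosome are rejected individually (logged),
    not fatal. Desert windows are computed per chromosome against all TSS
    on that chromosome.
    """
    if isinstance(genes, pd.DataFrame):
        genes = genes_from_frame(genes)
    genic_rows: list[dict] = []
    tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        size = chrom_sizes.get(g.chrom)
        if size is None:
            log.warning("gene %s: chromosome %s not in chrom_sizes; skipped", g.gene_id, g.chrom)
            continue
        lo, hi = g.span
        if lo < 0 or hi > size:
            log.warning("gene %s: span [%d,%d) off chromosome (size %d); skipped", g.gene_id, lo, hi, size)
            continue
        genic_rows.extend(gene_regions(g, size))
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)

    genic = pd.DataFrame(
        genic_rows, columns=["chrom", "start", "end", "gene_id", "region_class", "strand"]
    )
    desert_rows = []
    for chrom, size in chrom_sizes.items():
        starts = desert_windows(np.array(tss_by_chrom.get(chrom, []), dtype=np.int64), size)
        for s in starts:
            desert_rows.append(dict(chrom=chrom, start=int(s), end=int(s) + DESERT_WINDOW))
    deserts = pd.DataFrame(desert_rows, columns=["chrom", "start", "end"])
    deserts["desert_id"] = [f"desert_{i:06d}" for i in range(len(deserts))]
    return RegionSet(genic=genic, deserts=deserts)


def gc_skew_profile(sequence: str, window: int, step: int | None = None) -> pd.DataFrame:
    """Windowed GC skew (G−C)/(G+C) along a sequence.

    High positive skew on the non-template strand is a classical predictor
    of promoter-proximal R-loop formation. Windows with no G or C score 0
    by convention; only full windows are emitted. Case-insensitive; N and
    other letters are ignored in the counts.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if step is None:
        step = window
    if step < 1:
        raise ValueError("step must be >= 1")
    seq = sequence.upper()
    n = len(seq)
    rows = []
    if n >= window:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_g = (arr == ord("G")).astype(np.int64)
        is_c = (arr == ord("C")).astype(np.int64)
        cg = np.concatenate([[0], np.cumsum(is_g)])
        cc = np.concatenate([[0], np.cumsum(is_c)])
        for start in range(0, n - window + 1, step):
            end = start + window
            g = int(cg[end] - cg[start])
            c = int(cc[end] - cc[start])
            skew = 0.0 if g + c == 0 else (g - c) / (g + c)
            rows.append(dict(start=start, end=end, skew=skew))
    return pd.DataFrame(rows, columns=["start", "end", "skew"])
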