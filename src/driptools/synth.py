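"""Synthetic genomes, DRIP count tables, Pol II coverage and truth peaks.

The generator emulates the study design the analysis assumes: two donor
groups (NC = non-carriers, B1 = BRCA1 mutation carriers, four donors
each), four flow-sorted breast cell populations (stromal, basal, luminal
progenitor LP, mature luminal ML), DRIP read counts per genic region with
a luminal-lineage baseline boost and a genotype-specific enrichment at the
TSS of a subset of "R-loop positive" genes, restriction-fragment peak
structure from a multi-enzyme digest, and Pol II coverage with
promoter-proximal pausing at a subset of genes that is correlated with
R-loop status. Ground-truth labels are returned for every gene so
downstream parameter-recovery tests can score sensitivity and precision.

Counts follow a negative-binomial model (mean ``mu``, variance
``mu + dispersion·mu²``), the standard overdispersed choice for sequencing
counts; ``dispersion → 0`` recovers the Poisson limit. Identical
configurations and seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import quantify
from .regions import RegionSet, build_regions, tx_window

GROUPS = ("NC", "B1")
CELL_TYPES = ("stromal", "basal", "LP", "ML")
LUMINAL = ("LP", "ML")

#: relative per-bp read density of each region class (TSS and TTS genic
#: hotspots dominate; deserts are near-background)
CLASS_DENSITY = {"tss": 20.0, "tts": 10.0, "body": 1.0, "distal": 1.0, "desert": 0.2}


class SizingError(ValueError):
    """Chromosome too small for the requested gene count."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Effect-size fields express the simulated analogue of the differential
    enrichment the analysis is meant to detect; ``true_log2fc`` applies at
    the TSS of R-loop-positive genes in B1 luminal (LP/ML) samples only.
    """

    n_genes: int = 2000
    chrom: str = "chrS"
    chrom_length: int = 90_000_000
    n_donors_per_group: int = 4
    cell_types: tuple[str, ...] = CELL_TYPES
    frac_rloop_positive: float = 0.1
    true_log2fc: float = 1.5
    luminal_boost: float = 2.0
    frac_paused: float = 0.3
    pausing_rloop_coupling: float = 0.9  # P(paused | rloop_positive)
    pausing_strength: float = 5.0
    dispersion: float = 0.02
    total_reads_per_sample: int = 1_000_000
    seed: int = 0
    # genome geometry
    gene_length_min: int = 4000
    gene_length_mean: int = 8000
    # human-like spacing: tens of kb between genes, so neighbouring TSSs
    # rarely share a restriction fragment (median fragment 3 kb)
    intergenic_gap_mean: int = 30_000
    median_fragment: int = 3000
    # noise structure
    gene_baseline_sd: float = 0.25  # sd of per-gene log-normal baseline
    coverage_noise_sd: float = 0.3  # per-bin log-normal sd of Pol II coverage
    coverage_bin: int = 50
    polII_body_density: float = 0.5  # reads per bp over gene bodies
    # truth-peak emission
    peak_quantile: float = 0.8

    def __post_init__(self) -> None:
        for name in ("frac_rloop_positive", "frac_paused", "pausing_rloop_coupling", "peak_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("true_log2fc", "luminal_boost", "pausing_strength"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name in (
            "n_donors_per_group", "chrom_length", "total_reads_per_sample",
            "gene_length_min", "gene_length_mean", "intergenic_gap_mean",
            "median_fragment", "coverage_bin",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.luminal_boost <= 0 or self.pausing_strength <= 0:
            raise ValueError("luminal_boost and pausing_strength must be positive")
        self.cell_types = tuple(self.cell_types)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_types"] = list(self.cell_types)
        return d

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        return np.random.default_rng([self.seed, stream])


#: margin past the last TSS reserved so gene deserts are definable
_DESERT_RESERVE = 1_200_000


def make_genome(
    config: SynthConfig, with_sequence: bool = False
) -> tuple[pd.DataFrame, dict[str, np.ndarray], dict[str, int], str | None]:
    """Generate a gene table and restriction-site map on one chromosome.

    Genes are non-overlapping, single-isoform, length ≥ ``gene_length_min``
    (4 kb default) with exponential length/gap tails; a TSS-free tail block
    of > 1 Mb is reserved so desert windows exist. Cut sites mimic a
    multi-enzyme digest as a Poisson process with configurable median
    fragment length (3 kb default). Returns (genes, sites, chrom_sizes,
    sequence); sequence is None unless requested.
    """
    rng = config.rng(1)
    rows = []
    cursor = 10_000
    limit = config.chrom_length - _DESERT_RESERVE
    for i in range(config.n_genes):
        length = config.gene_length_min + int(
            rng.exponential(max(config.gene_length_mean - config.gene_length_min, 1))
        )
        gap = 200 + int(rng.exponential(config.intergenic_gap_mean))
        start = cursor
        end = start + length
        if end > limit:
            raise SizingError(
                f"chrom_length={config.chrom_length} too small for {config.n_genes} genes: "
                f"gene {i} would end at {end} but only {limit} bp are available "
                f"({_DESERT_RESERVE} bp reserved for gene deserts)"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tts = (start, end) if strand == "+" else (end, start)
        rows.append(
            dict(gene_id=f"g{i:05d}", chrom=config.chrom, strand=strand, tss=tss, tts=tts)
        )
        cursor = end + gap
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tts"])

    # multi-enzyme digest ~ Poisson cut process; exponential spacing with
    # the requested median (median = scale * ln 2)
    scale = config.median_fragment / np.log(2.0)
    n_est = int(config.chrom_length / scale * 1.3) + 100
    gaps = rng.exponential(scale, size=n_est)
    pos = np.cumsum(gaps)
    while pos[-1] < config.chrom_length:
        extra = np.cumsum(rng.exponential(scale, size=n_est)) + pos[-1]
        pos = np.concatenate([pos, extra])
    sites = np.unique(pos[pos < config.chrom_length].astype(np.int64))
    sites = sites[sites > 0]

    chrom_sizes = {config.chrom: config.chrom_length}
    sequence = None
    if with_sequence:
        if config.chrom_length > 20_000_000:
            raise ValueError("sequence generation supported only for chromosomes <= 20 Mb")
        sequence = "".join(rng.choice(list("ACGT"), size=config.chrom_length))
    return genes, {config.chrom: sites}, chrom_sizes, sequence


def _ground_truth(genes: pd.DataFrame, config: SynthConfig) -> pd.DataFrame:
    """Per-gene truth flags and cell-type baseline profiles."""
    rng = config.rng(2)
    n = len(genes)
    rloop = rng.random(n) < config.frac_rloop_positive
    # couple pausing to R-loop status: P(paused | rloop+) is high, and the
    # rate among the rest is set so the overall fraction matches frac_paused
    p_pos = config.pausing_rloop_coupling
    frac_pos = config.frac_rloop_positive
    if frac_pos < 1.0:
        p_rest = (config.frac_paused - p_pos * frac_pos) / (1.0 - frac_pos)
    else:
        p_rest = 0.0
    p_rest = min(max(p_rest, 0.0), 1.0)
    u = rng.random(n)
    paused = np.where(rloop, u < p_pos, u < p_rest)
    baseline = np.exp(rng.normal(0.0, config.gene_baseline_sd, size=n))
    truth = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "rloop_positive": rloop,
            "paused": paused,
            "baseline": baseline,
        }
    )
    for ct in config.cell_types:
        boost = config.luminal_boost if ct in LUMINAL else 1.0
        truth[f"profile_{ct}"] = baseline * boost
    return truth


def sample_table(config: SynthConfig) -> pd.DataFrame:
    """Sample metadata: one row per donor × cell type, both groups."""
    rows = [
        dict(sample_id=f"{grp}{d + 1}_{ct}", group=grp, donor=f"{grp}{d + 1}", cell_type=ct)
        for grp in GROUPS
        for d in range(config.n_donors_per_group)
        for ct in config.cell_types
    ]
    return pd.DataFrame(rows)


def simulate_drip_counts(
    genes: pd.DataFrame,
    config: SynthConfig,
    regions: RegionSet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial DRIP counts per sample × region, plus ground truth.

    The expected count of a region is proportional to its class density ×
    length × the gene's cell-type baseline profile, multiplied by
    ``2**true_log2fc`` when the sample is a B1 luminal (LP/ML) sample, the
    gene is R-loop positive and the region is the TSS window. Counts are
    scaled so the expected per-sample total (without the enrichment term)
    equals ``total_reads_per_sample``; ``total_mapped`` records the
    realized total.
    """
    if regions is None:
        regions = build_regions(genes, {config.chrom: config.chrom_length})
    truth = _ground_truth(genes, config)
    rng = config.rng(3)

    rf = regions.frame.copy()
    gene_idx = truth.set_index("gene_id")
    is_desert = (rf["region_class"] == "desert").to_numpy()
    baseline = np.ones(len(rf))
    rloop_pos = np.zeros(len(rf), dtype=bool)
    genic_ids = rf.loc[~is_desert, "region_id"]
    baseline[~is_desert] = gene_idx.loc[genic_ids, "baseline"].to_numpy()
    rloop_pos[~is_desert] = gene_idx.loc[genic_ids, "rloop_positive"].to_numpy()
    density = rf["region_class"].map(CLASS_DENSITY).to_numpy()
    length = rf["region_length"].to_numpy(dtype=float)
    is_tss = (rf["region_class"] == "tss").to_numpy()

    tables = []
    for s in sample_table(config).itertuples(index=False):
        luminal = s.cell_type in LUMINAL
        ct_boost = config.luminal_boost if luminal else 1.0
        w = density * length * baseline
        w[~is_desert] *= ct_boost
        scale = config.total_reads_per_sample / w.sum()
        mu = scale * w
        if s.group == "B1" and luminal:
            mu = mu * np.where(rloop_pos & is_tss, 2.0 ** config.true_log2fc, 1.0)
        if config.dispersion <= 1e-9:
            raw = rng.poisson(mu)
        else:
            r = 1.0 / config.dispersion
            p = r / (r + mu)
            raw = rng.negative_binomial(r, p)
        total = int(max(raw.sum(), 1))
        tab = pd.DataFrame(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "cell_type": s.cell_type,
                "region_id": rf["region_id"],
                "region_class": rf["region_class"],
                "region_length": rf["region_length"],
                "raw_count": raw,
                "total_mapped": total,
            }
        )
        tab["normalized"] = quantify.normalize(raw, total, length)
        tables.append(tab)
    counts = pd.concat(tables, ignore_index=True)[quantify.COUNT_COLUMNS]
    return counts, truth


def simulate_polII_coverage(
    genes: pd.DataFrame,
    truth: pd.DataFrame,
    config: SynthConfig,
) -> pd.DataFrame:
    """Piecewise-constant Pol II coverage with promoter-proximal pausing.

    Paused genes get promoter density ``pausing_strength ×`` their body
    density over the promoter-proximal window (TSS −30 to +300 bp,
    strand-aware); non-paused genes are flat. With
    ``coverage_noise_sd = 0`` the construction is exact (pausing index
    equals pausing_strength for paused genes, 1 otherwise); otherwise each
    ``coverage_bin``-bp bin carries an independent mean-one log-normal
    factor. Returns a bedGraph-style frame (chrom, start, end, value).
    """
    rng = config.rng(4)
    paused = truth.set_index("gene_id")["paused"]
    sd = config.coverage_noise_sd
    out_chrom, out_start, out_end, out_val = [], [], [], []

    def emit(start: int, end: int, dens: float) -> None:
        if end <= start or dens <= 0:
            return
        if sd <= 0:
            edges = np.array([start, end], dtype=np.int64)
        else:
            edges = np.arange(start, end, config.coverage_bin, dtype=np.int64)
            edges = np.append(edges, end)
        vals = np.full(edges.size - 1, dens)
        if sd > 0:
            vals = vals * np.exp(rng.normal(-0.5 * sd * sd, sd, size=vals.size))
        out_chrom.extend([chrom] * (edges.size - 1))
        out_start.extend(edges[:-1].tolist())
        out_end.extend(edges[1:].tolist())
        out_val.extend(vals.tolist())

    for g in genes.itertuples(index=False):
        chrom = g.chrom
        length = abs(g.tts - g.tss)
        body_density = config.polII_body_density
        prom_density = body_density * (config.pausing_strength if paused[g.gene_id] else 1.0)
        ps, pe = tx_window(g.strand, g.tss, -30, 300)
        bs, be = tx_window(g.strand, g.tss, 300, length)
        emit(ps, pe, prom_density)
        emit(bs, be, body_density)
    return pd.DataFrame(
        {"chrom": out_chrom, "start": out_start, "end": out_end, "value": out_val}
    )


def emit_truth_peaks(
    counts: pd.DataFrame,
    genes: pd.DataFrame,
    sites: dict[str, np.ndarray],
    config: SynthConfig,
) -> dict[str, "object"]:
    """Per-sample peak sets standing in for a peak caller's output.

    A sample emits a TSS-overlapping peak for a gene iff the gene's
    normalized TSS signal in that sample exceeds a detection threshold
    shared by all samples: the ``peak_quantile`` quantile of the pooled
    normalized TSS signal distribution across every sample (quantile 0 →
    every gene peaked in every sample, quantile 1 → none). A pooled rather
    than per-sample quantile mimics a caller's absolute detection limit
    and keeps presence calls comparable between groups. Peak boundaries
    are drawn uniformly within the restriction fragment enclosing the
    TSS, so fragment extension is exercised downstream.
    """
    from .peaks import PeakSet  # deferred to avoid a cycle at import time

    rng = config.rng(5)
    gene_pos = genes.set_index("gene_id")[["chrom", "tss"]]
    tss_counts = counts[counts["region_class"] == "tss"]
    threshold = (
        float(np.quantile(tss_counts["normalized"].to_numpy(), config.peak_quantile))
        if 0 < config.peak_quantile < 1
        else None
    )
    out: dict[str, PeakSet] = {}
    for sample_id, sub in tss_counts.groupby("sample_id", sort=True):
        vals = sub["normalized"].to_numpy()
        if config.peak_quantile <= 0:
            keep = np.ones(len(sub), dtype=bool)
        elif config.peak_quantile >= 1:
            keep = np.zeros(len(sub), dtype=bool)
        else:
            keep = vals > threshold
        rows = []
        for gid in sub.loc[keep, "region_id"]:
            chrom = gene_pos.loc[gid, "chrom"]
            tss = int(gene_pos.loc[gid, "tss"])
            cut = sites[chrom]
            i = int(np.searchsorted(cut, tss, side="right"))
            frag_start = int(cut[i - 1]) if i > 0 else 0
            frag_end = int(cut[i]) if i < cut.size else config.chrom_length
            start = int(rng.integers(frag_start, tss + 1))
            end = int(rng.integers(tss + 1, frag_end + 1))
            rows.append((chrom, start, end))
        out[sample_id] = PeakSet.from_intervals(
            sample_id, rows if rows else []
        )
    return out
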