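# Methods

This note documents the statistical model behind `driptools`, the
conventions and defaults it commits to, what the synthetic-data generator
does and does not emulate, and the design choices made where more than one
reading was defensible.

## Coordinates and regions

All intervals are 0-based half-open (BED convention); 1-based coordinates
appear only at I/O boundaries when a format demands them. A gene is
anchored by its annotated 5′ end (`tss`) and 3′ end (`tts`); on the −
strand `tss > tts`. Strand-aware windows are defined in transcription
coordinates: offset *o* maps to base `tss + o` on the + strand and
`tss − o` on the − strand, with half-open offset ranges. Consequently a −
strand window is the exact point reflection of its + strand counterpart;
because reflection of a half-open interval shifts its endpoints by one
base, a − strand TSS region is `[tss−1999, tss+2001)` rather than
`[tss−2000, tss+2000)`. All windows have identical lengths on both
strands, and every density is a mean over the window, so this one-base
bookkeeping has no numerical effect.

Region classes per gene: TSS flank ±2 kb (4 kb), TTS flank ±2 kb, gene
body between the flanks (empty when the gene spans ≤ 4 kb), and a distal
control covering 100 bp–2 kb upstream of the TSS (1.9 kb). "Upstream" is
taken strand-aware for the distal window; the mirrored interpretation is
the only one consistent with the transcription-coordinate convention
used everywhere else. Regions of neighbouring genes are deliberately
**not** deduplicated: each gene is quantified independently, matching the
per-gene hypothesis tests downstream.

Gene deserts are fixed-phase 20 kb tilings from the chromosome start;
a window qualifies only if every base lies ≥ 1 Mb from every TSS. The
tiling is verified in tests against an exhaustive per-base distance scan.

## Quantification and normalization

A read counts toward a region if the two half-open intervals share at
least one base (any-overlap; a read spanning two regions counts in both).
Counting uses the sorted-endpoints identity
`#overlapping = #{start < region.end} − #{end ≤ region.start}`, checked
against per-read enumeration in tests. Normalized signal is
`raw · (10^6/total_mapped) · (10^5/length)` — reads per million mapped
per 100 kb — which makes values comparable across samples of different
depth and across region classes of different length, including deserts
(the same formula is applied uniformly). Zero-length regions are excluded
with a log record.

## Differential calls

Per gene and region class, the per-sample normalized values of the two
donor groups are compared one-sided (alternative: carriers higher). The
default test is a Welch two-sample t-test; for gene-body regions shorter
than 2 kb a Wilcoxon rank-sum test is used instead — short bodies are where
counts are sparsest and a normal-theory test is least trustworthy, so
the fallback keys on length rather than on observed counts. "Signed" tests
are read as one-sided directionality; a t-test requires per-sample values,
so the group averages enter only the fold-change, not the test itself.
log2FC uses a pseudocount of 0.5 normalized units on both group means
(configurable) to avoid infinities at zero signal. P values are
BH-adjusted within each region class, so the TSS family is corrected
independently of, e.g., the TTS family, mirroring per-region reporting.
A gene is called differential when log2FC ≥ 0.8 **and** adjusted
p ≤ 0.05, both inclusive. Groups with fewer than two samples yield
undefined p values and no calls.

The rank-sum p is computed by exact enumeration of group assignments over
pooled midranks whenever C(n1+n2, n1) ≤ 20,000 (covering all designs up
to 8 vs 8, ties handled exactly); otherwise the tie-corrected normal
approximation is used. The group-level permutation test (statistic:
difference of group means) enumerates all regroupings when
C(n1+n2, n1) ≤ 10,000 — exactly 70 at 4 vs 4 — and falls back to Monte
Carlo with the (1 + hits)/(1 + draws) estimator so p is never 0.

## Peaks, consensus and classification

Peak boundaries are snapped outward to the nearest restriction cut sites
(or chromosome ends), reflecting that DRIP fragments — not base-pair peak
calls — are the physical unit of the assay. Overlapping extended peaks
within a sample are merged (preventing double-counting of a fragment);
the pre-extension span is retained as provenance. Extension is idempotent
and monotone; both properties are tested.

TSS binding uses the strict 1 bp reading: a peak must overlap the single
TSS coordinate (window configurable via `tss_window`). Group consensus is
the intersection over all samples of the group. The carrier-associated
set is group 1 (both consensuses, log2FC ≥ 0.8 and adjusted p ≤ 0.05 at
the TSS) plus group 2 (carrier consensus only, defined as
`consensus_B1 \ consensus_NC` regardless of fold change); genes in both
consensuses but missing from the differential table are flagged and
ineligible for group 1. Set overlaps are scored with a two-sided Fisher
exact test over a configurable universe (default: all annotated genes),
with Haldane-corrected odds ratios when a cell is zero.

A deliberately simple threshold-and-run peak caller
(`toy_peak_caller`) is included as plumbing so the peak stages can be
exercised from coverage tracks; it is not a model-based caller and makes
no claim beyond that.

## Pausing index

The travelling ratio is mean coverage over the promoter-proximal window
`[TSS−30, TSS+300)` (330 bp; the inclusive 331 bp reading differs by
<0.5% and is selectable via the window arguments) divided by mean
coverage over `[TSS+300, TTS)`, strand-aware. Genes whose body window is
empty or has zero coverage are flagged undefined and excluded from
cumulative curves rather than assigned an infinite index. "Pol II-bound"
is operationalized as summed promoter coverage ≥ 10 (configurable
absolute threshold); cumulative curves are ECDFs over bound genes with
defined indices, ending at 100%. Gene-set comparisons use the one-sided
rank-sum above. For amplicon-level (qPCR-style) data,
`locus_pausing_index` is the plain TSS/body signal ratio with no window
arithmetic.

## The synthetic study

The generator emulates the design the analysis assumes: two donor groups
(4 NC vs 4 B1) × four sorted populations (stromal, basal, LP, ML), one
chromosome, single-isoform non-overlapping genes with unique TSS/TTS.
What it reproduces: region-class signal hierarchy (TSS > TTS ≫
body/distal > desert), a luminal-lineage baseline boost, a
carrier-specific multiplicative TSS enrichment at a labelled gene subset,
restriction-fragment peak geometry from a Poisson cut-site process, and
Pol II coverage with promoter pausing correlated with R-loop status.
What it does not: sequence composition or mappability, read-level
(FASTQ) structure, isoforms or alternative TSSs, donor-specific global
effects, and inter-gene correlation. Passing recovery tests therefore
demonstrates correctness of the inference chain under the stated
stochastic model, not performance on real tissue data.

Counts are negative binomial with mean
`scale · density(class) · length · baseline_g · luminal_boost^{[LP/ML]} ·
2^{true_log2fc·[B1 ∧ luminal ∧ rloop⁺ ∧ TSS]}` and variance
`μ + dispersion·μ²`; `scale` sets the expected library size, and
`total_mapped` records the realized total. Defaults, chosen once and
fixed (units in brackets):

| parameter | default | rationale |
|---|---|---|
| n_genes / chrom_length | 2000 / 90 Mb [bp] | desk-scale cohort; ~1 gene / 45 kb approximates human gene spacing so neighbouring TSSs rarely share a 3 kb restriction fragment |
| gene length | ≥ 4 kb, mean 8 kb | compact genes keep runtimes small while leaving nonempty bodies for most genes |
| intergenic gap mean | 30 kb [bp] | see spacing rationale above; with dense packing, fragment-extended peaks of one gene systematically capture neighbour TSSs, which is an artifact of over-dense toy genomes rather than of the method |
| median_fragment | 3 kb [bp] | multi-enzyme digest scale |
| class densities | TSS 20, TTS 10, body 1, distal 1, desert 0.2 | reproduces the observed 5′ > 3′ ≫ background hierarchy; TSS/desert ≈ 100× |
| frac_rloop_positive / true_log2fc | 0.1 / 1.5 [log2] | a tenth of genes carry the carrier effect, comfortably above the 0.8 call threshold |
| luminal_boost | 2.0 [×] | luminal populations carry roughly twice the baseline R-loop signal of stromal/basal |
| gene_baseline_sd | 0.25 [ln units] | modest between-gene spread; larger spreads defeat quantile-threshold peak emission for weakly expressed genes |
| dispersion | 0.02 | between-donor CV ≈ 14%, a moderate-noise setting at which a 4+4 design has adequate power for a 2.8-fold effect under BH correction; at 0.05–0.1 (noisier donors) sensitivity of the t-test stage degrades substantially, which is a property of the 4+4 design, not of the implementation |
| total_reads_per_sample | 10⁶ | hundreds of reads per TSS window — deep enough that sampling noise is dominated by donor dispersion |
| frac_paused / coupling | 0.3 / P(paused∣rloop⁺)=0.9 | pausing is common and strongly, not perfectly, associated with R-loop status |
| pausing_strength | 5 [×] | promoter/body density ratio of paused genes |
| coverage_noise_sd / bin | 0.3 [ln] / 50 bp | mean-one log-normal bin noise; 0 gives the exact constructions used by tests |
| peak_quantile | 0.8 | peaks are emitted where a sample's normalized TSS signal exceeds the pooled 80th percentile — an absolute detection limit shared by all samples, emulating a caller's q-value cutoff; per-sample adaptive thresholds would make presence calls incomparable between groups |

Every stage draws from its own deterministic stream spawned from the
single configuration seed, so identical configurations are bit-identical
and stages can be re-run independently.

## Numerical conventions

Zero-variance identical groups give p = 1 (no evidence) rather than NaN;
p values are clipped into (0, 1]. Exhaustive permutation comparisons use
an absolute-plus-relative tolerance of ~1e−9 when comparing permuted
statistics to the observed one, guarding against summation-order jitter.
Peak-emission quantiles 0 and 1 are handled as explicit boundary
conventions (all genes / no genes). Desert construction, counting and
extension all operate per chromosome; a chromosome missing from an input
map degrades gracefully (zero counts or bounds-extension, with a
warning).

## Known limitations

Real-data ingestion covers interval files and pre-binned coverage, not
BAM alignment or MACS peak calling (upstream tools produce those). The
two-group classification inherits the instability of presence/absence
consensus calls for genes near the peak-detection limit; with only four
donors per group this is intrinsic to the design. The pipeline's
end-to-end runner is wired for simulated data; real cohorts are analysed
by composing the module functions directly.
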