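# driptools

Differential R-loop analysis for DRIP-seq cohorts, with promoter-proximal
RNA polymerase II pausing metrics and a fully specified synthetic-data
generator for validation at desk scale.

## The problem

R-loops are three-stranded structures (an RNA:DNA hybrid plus displaced
single-stranded DNA) that form co-transcriptionally, preferentially at the
5′ end of genes. In breast tissue of *BRCA1* mutation carriers, R-loops
accumulate specifically in luminal epithelial cells — the lineage of origin
of *BRCA1*-associated tumours — and preferentially at promoters with
paused Pol II. Detecting this signal from DRIP-seq (DNA-RNA
immunoprecipitation sequencing of restriction-digested genomic DNA)
requires a chain of inference steps: region-based quantification,
library-size normalization, directional group tests with multiple-testing
control, restriction-fragment-aware peak processing with per-group
consensus, a two-group classification of carrier-associated genes, and the
Pol II pausing index. `driptools` implements that chain as a tested,
reusable library for people analysing grouped DRIP-seq / ChIP-seq designs
(cases vs controls × sorted cell populations).

## The model and statistics

For each annotated gene (unique TSS and TTS) five region classes are
built, 0-based half-open and strand-aware: **TSS** `[TSS−2kb, TSS+2kb)`,
**TTS** `[TTS−2kb, TTS+2kb)`, **gene body** (between the flanks),
**distal** `[TSS−2kb, TSS−100)` upstream, and **gene deserts** — 20 kb
windows every base of which is ≥ 1 Mb from any TSS. Raw region counts are
normalized to

```
normalized = raw · (10^6 / total_mapped) · (10^5 / region_length)
```

(reads per million mapped per 100 kb). Differential R-loops between
carrier (B1) and non-carrier (NC) donors are tested one-sided
(alternative: B1 > NC) with a Welch t-test on per-sample normalized
values — a Wilcoxon rank-sum test for gene bodies shorter than 2 kb —
BH-adjusted per region class; a gene is *differential* when
log2FC ≥ 0.8 and adjusted p ≤ 0.05. Group-level comparisons use an
exhaustive label-regrouping permutation test (all C(n1+n2, n1)
regroupings when feasible, e.g. exactly 70 at 4 vs 4 donors).

Peaks are extended outward to the nearest restriction cut sites
(HindIII/EcoRI/BsrGI/XbaI/SspI-style multi-enzyme digest), a gene is
TSS-bound when a peak overlaps its TSS coordinate, and a group's
consensus requires TSS binding in **all** of its samples.
Carrier-associated genes are then **group 1** (consensus peaks in both
groups, quantitatively higher in B1 per the differential rule) or
**group 2** (consensus peaks only in B1). The Pol II pausing index
(travelling ratio) of a gene is the mean coverage over
`[TSS−30, TSS+300)` divided by the mean over `[TSS+300, TTS)`; gene sets
are compared by one-sided rank-sum on their index distributions.

The `synth` module generates the whole study design — 4+4 donors × four
sorted populations (stromal, basal, LP, ML), negative-binomial counts with
a luminal baseline boost and a TSS-specific carrier effect
(`2^true_log2fc`) at a labelled subset of genes, restriction maps, peak
sets and Pol II coverage with R-loop-coupled pausing — with ground truth
for recovery testing. See `docs/methods.md` for parameters and rationale.

## Worked example

```
$ python examples/01_differential_rloops.py
genes simulated:            500
truly enriched (ground truth): 43
TSS regions called differential: 35
  of which truly enriched:       35

gene_id   log2FC    p_adj
 g00351 1.606973 0.024908
 g00069 1.547623 0.004942
 g00047 1.547376 0.001767
 g00098 1.547250 0.004942
 g00295 1.545860 0.009451
```

Of 43 genes simulated with a true carrier-specific TSS enrichment
(log2FC 1.5 in luminal cells), 35 are called at the default cutoffs with
no false calls; the top genes show estimated log2FC near the simulated
1.5. The other examples cover peak consensus and classification
(`02`), pausing curves (`03`), the one-call pipeline with its
reproducibility manifest (`04`), and GC-skew profiling (`05`). The same
flow is available from the shell:

```
driptools run-all --simulate --seed 7 --outdir out/
driptools diff --counts out/counts.tsv --cell-type LP --out diff.tsv
```

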