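"""Differential R-loop calls on a simulated donor cohort.

Simulates DRIP-seq counts for 4 BRCA1-mutation carriers (B1) and 4
non-carriers (NC) across four sorted breast cell populations, then runs
the one-sided B1-vs-NC test per gene and region class in the luminal
progenitor (LP) population.
"""

import driptools as dt

cfg = dt.SynthConfig(n_genes=500, chrom_length=25_000_000, seed=1)
genes, sites, chrom_sizes, _ = dt.make_genome(cfg)
counts, truth = dt.simulate_drip_counts(genes, cfg)

diff = dt.differential_rloop(counts, cell_type="LP")
tss = diff[diff["region_class"] == "tss"].merge(
    truth[["gene_id", "rloop_positive"]], on="gene_id"
)

called = tss[tss["call"]]
print(f"genes simulated:            {len(genes)}")
print(f"truly enriched (ground truth): {int(truth['rloop_positive'].sum())}")
print(f"TSS regions called differential: {len(called)}")
print(f"  of which truly enriched:       {int(called['rloop_positive'].sum())}")
print()
print(called.nlargest(5, "log2FC")[["gene_id", "log2FC", "p_adj"]].to_string(index=False))
print()
print("A call requires log2FC >= 0.8 and BH-adjusted p <= 0.05 (one-sided,")
print("alternative: carriers > non-carriers). With the default donor")
print("variability most truly enriched genes are recovered with few false calls.")
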