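"""Synthetic-data generator: determinism, genome geometry, the count
model's moments and effect sizes, coverage construction, peak emission."""

import numpy as np
import pandas as pd
import pytest

import driptools as dt
from driptools.synth import SizingError, _ground_truth, sample_table


class TestMakeGenome:
    def test_zero_genes_degenerate(self):
        cfg = dt.SynthConfig(n_genes=0, chrom_length=3_000_000, seed=0)
        genes, sites, sizes, _ = dt.make_genome(cfg)
        assert len(genes) == 0
        assert len(sites[cfg.chrom]) > 0

    def test_determinism_bit_identical(self):
        cfg = dt.SynthConfig(n_genes=100, chrom_length=8_000_000, seed=1)
        g1, s1, _, _ = dt.make_genome(cfg)
        g2, s2, _, _ = dt.make_genome(cfg)
        pd.testing.assert_frame_equal(g1, g2)
        np.testing.assert_array_equal(s1[cfg.chrom], s2[cfg.chrom])

    def test_median_fragment_length(self):
        """Empirical median spacing within 20% of the requested 3 kb over
        ≥1,000 fragments."""
        cfg = dt.SynthConfig(n_genes=0, chrom_length=10_000_000, seed=2, median_fragment=3000)
        _, sites, _, _ = dt.make_genome(cfg)
        frags = np.diff(sites[cfg.chrom])
        assert len(frags) >= 1000
        assert abs(np.median(frags) - 3000) / 3000 < 0.2

    def test_genes_nonoverlapping_and_min_length(self, genome):
        genes, _, _ = genome
        assert (genes.apply(lambda r: abs(r.tts - r.tss), axis=1) >= 4000).all()
        spans = sorted(
            (min(r.tss, r.tts), max(r.tss, r.tts)) for r in genes.itertuples(index=False)
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_sizing_error(self):
        with pytest.raises(SizingError):
            dt.make_genome(dt.SynthConfig(n_genes=500, chrom_length=2_000_000, seed=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            dt.SynthConfig(frac_rloop_positive=1.5)
        with pytest.raises(ValueError):
            dt.SynthConfig(dispersion=-0.1)
        with pytest.raises(ValueError):
            dt.SynthConfig(true_log2fc=float("inf"))


class TestGroundTruth:
    def test_each_gene_once_and_fractions(self, genome, small_cfg):
        genes, _, _ = genome
        truth = _ground_truth(genes, small_cfg)
        assert truth["gene_id"].tolist() == genes["gene_id"].tolist()
        n = len(truth)
        frac = truth["rloop_positive"].mean()
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(frac - small_cfg.frac_rloop_positive) < 4 * se
        frac_paused = truth["paused"].mean()
        se_p = np.sqrt(0.3 * 0.7 / n)
        assert abs(frac_paused - small_cfg.frac_paused) < 4 * se_p

    def test_pausing_coupled_to_rloop(self, genome, small_cfg):
        genes, _, _ = genome
        truth = _ground_truth(genes, small_cfg)
        p_pos = truth.loc[truth["rloop_positive"], "paused"].mean()
        p_rest = truth.loc[~truth["rloop_positive"], "paused"].mean()
        assert p_pos > p_rest


class TestSimulateCounts:
    def test_determinism(self, genome, regions, small_cfg):
        genes, _, _ = genome
        c1, t1 = dt.simulate_drip_counts(genes, small_cfg, regions)
        c2, t2 = dt.simulate_drip_counts(genes, small_cfg, regions)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_sample_layout(self, small_cfg):
        st = sample_table(small_cfg)
        assert len(st) == 2 * 4 * 4  # groups × donors × cell types
        assert set(st["group"]) == {"NC", "B1"}

    def test_totals_near_library_size(self, study, small_cfg):
        counts, _ = study
        totals = counts.groupby("sample_id")["raw_count"].sum()
        assert (abs(totals - small_cfg.total_reads_per_sample)
                / small_cfg.total_reads_per_sample < 0.25).all()

    def test_genic_hotspots_exceed_background(self, study):
        """TSS and TTS normalized density above body/distal, deserts lowest."""
        counts, _ = study
        m = counts.groupby("region_class")["normalized"].mean()
        assert m["tss"] > m["tts"] > m["body"]
        assert m["tts"] > m["distal"]
        assert m["desert"] < m["body"]

    def test_luminal_boost_visible(self, study):
        counts, _ = study
        tss = counts[counts["region_class"] == "tss"]
        m = tss.groupby("cell_type")["normalized"].mean()
        assert m["LP"] > m["stromal"] and m["ML"] > m["basal"]

    def test_null_model_centred_log2fc(self):
        """All effects off: group-mean log2FC at TSS centred on 0 within
        3 Monte-Carlo standard errors."""
        cfg = dt.SynthConfig(n_genes=200, chrom_length=12_000_000, seed=7,
                             true_log2fc=0.0, luminal_boost=1.0,
                             cell_types=("LP",))
        genes, _, sizes, _ = dt.make_genome(cfg)
        counts, _ = dt.simulate_drip_counts(genes, cfg)
        tss = counts[counts["region_class"] == "tss"]
        piv = tss.pivot_table(index="region_id", columns="group", values="normalized")
        lfc = np.log2((piv["B1"] + 0.5) / (piv["NC"] + 0.5))
        assert abs(lfc.mean()) < 3 * lfc.std() / np.sqrt(len(lfc))

    def test_poisson_limit_variance_equals_mean(self):
        """dispersion → 0: var/mean ≈ 1 across >10,000 replicate draws."""
        cfg = dt.SynthConfig(n_genes=25, chrom_length=3_500_000, seed=8,
                             dispersion=0.0, n_donors_per_group=60,
                             cell_types=("stromal",), true_log2fc=0.0)
        genes, _, _, _ = dt.make_genome(cfg)
        counts, _ = dt.simulate_drip_counts(genes, cfg)
        nc = counts[(counts["group"] == "NC") & (counts["region_class"] == "tss")]
        ratios = nc.groupby("region_id")["raw_count"].agg(["mean", "var"])
        assert len(nc) >= 10_000 / 8  # 60 draws × 25 genes
        ratio = (ratios["var"] / ratios["mean"]).mean()
        assert 0.8 < ratio < 1.2

    def test_overdispersion_inflates_variance(self):
        cfg = dt.SynthConfig(n_genes=25, chrom_length=3_500_000, seed=8,
                             dispersion=0.5, n_donors_per_group=60,
                             cell_types=("stromal",), true_log2fc=0.0)
        genes, _, _, _ = dt.make_genome(cfg)
        counts, _ = dt.simulate_drip_counts(genes, cfg)
        nc = counts[(counts["group"] == "NC") & (counts["region_class"] == "tss")]
        ratios = nc.groupby("region_id")["raw_count"].agg(["mean", "var"])
        assert (ratios["var"] / ratios["mean"]).mean() > 10

    def test_effect_size_recovered_in_raw_means(self):
        """R-loop-positive genes: B1-LP vs NC-LP mean raw TSS counts in
        ratio ≈ 2^1.5 (averaged over 50 donors per group)."""
        cfg = dt.SynthConfig(n_genes=100, chrom_length=8_000_000, seed=9,
                             n_donors_per_group=50, cell_types=("LP",),
                             true_log2fc=1.5)
        genes, _, _, _ = dt.make_genome(cfg)
        counts, truth = dt.simulate_drip_counts(genes, cfg)
        pos = set(truth.loc[truth["rloop_positive"], "gene_id"])
        tss = counts[(counts["region_class"] == "tss") & counts["region_id"].isin(pos)]
        m = tss.groupby("group")["raw_count"].mean()
        assert m["B1"] / m["NC"] == pytest.approx(2 ** 1.5, rel=0.05)


class TestEmitPeaks:
    def test_quantile_zero_every_gene_peaked(self, genome, study, small_cfg):
        genes, sites, _ = genome
        counts, _ = study
        cfg = dt.SynthConfig(**{**small_cfg.to_dict(), "peak_quantile": 0.0})
        pks = dt.emit_truth_peaks(counts, genes, sites, cfg)
        for ps in pks.values():
            assert len(ps.peaks) == len(genes)

    def test_quantile_one_no_peaks(self, genome, study, small_cfg):
        genes, sites, _ = genome
        counts, _ = study
        cfg = dt.SynthConfig(**{**small_cfg.to_dict(), "peak_quantile": 1.0})
        pks = dt.emit_truth_peaks(counts, genes, sites, cfg)
        assert all(len(ps.peaks) == 0 for ps in pks.values())

    def test_peaks_overlap_tss_within_enclosing_fragment(self, genome, study, small_cfg):
        genes, sites, _ = genome
        counts, _ = study
        pks = dt.emit_truth_peaks(counts, genes, sites, small_cfg)
        cut = sites[small_cfg.chrom]
        tss_by_chrom = genes.set_index("gene_id")["tss"]
        some = next(iter(pks.values()))
        assert len(some.peaks) > 0
        for ps in list(pks.values())[:4]:
            for r in ps.peaks.itertuples(index=False):
                # peak must contain at least one TSS
                hit = tss_by_chrom[(tss_by_chrom >= r.start) & (tss_by_chrom < r.end)]
                assert len(hit) >= 1
                t = int(hit.iloc[0])
                i = np.searchsorted(cut, t, side="right")
                frag_lo = cut[i - 1] if i > 0 else 0
                frag_hi = cut[i] if i < len(cut) else small_cfg.chrom_length
                assert frag_lo <= r.start and r.end <= frag_hi


class TestCoverage:
    def test_determinism(self, genome, study, small_cfg):
        genes, _, _ = genome
        _, truth = study
        c1 = dt.simulate_polII_coverage(genes, truth, small_cfg)
        c2 = dt.simulate_polII_coverage(genes, truth, small_cfg)
        pd.testing.assert_frame_equal(c1, c2)

    def test_nonnegative_and_within_bounds(self, genome, study, small_cfg):
        genes, _, _ = genome
        _, truth = study
        covr = dt.simulate_polII_coverage(genes, truth, small_cfg)
        assert (covr["value"] >= 0).all()
        assert covr["start"].min() >= 0
        assert covr["end"].max() <= small_cfg.chrom_length

    def test_paused_genes_detectable_by_ranksum(self, genome, study, small_cfg):
        """With noise on, paused vs non-paused indices separate at p < 0.01."""
        genes, _, _ = genome
        _, truth = study
        covr = dt.CoverageTrack(dt.simulate_polII_coverage(genes, truth, small_cfg))
        from driptools.regions import genes_from_frame
        from driptools.pausing import records_frame
        frame = records_frame([dt.pausing_index(covr, g) for g in genes_from_frame(genes)])
        merged = frame.merge(truth[["gene_id", "paused"]], on="gene_id")
        ok = merged[merged["defined"]]
        p = dt.compare_pausing(
            ok.loc[ok["paused"], "pausing_index"].to_numpy(),
            ok.loc[~ok["paused"], "pausing_index"].to_numpy(),
        )
        assert p < 0.01
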