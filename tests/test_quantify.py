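"""Spike-in normalization, gene quantification, metaprofiles, FC scatter."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from ubiquifold import (
    ChromatinDomain,
    CoverageTrack,
    InputError,
    SpikeInStats,
    accessibility_fc_scatter,
    class_median_fc,
    domain_metaprofile,
    fold_changes,
    gene_body_coverage,
    implied_spikein_fraction,
    normalize_track,
    simulate_coverage,
    spikein_scale_factors,
)


def make_track(values, bin_size=200, mark="H2Aub1", sample=""):
    values = np.asarray(values, dtype=float)
    return CoverageTrack(
        genome={"chr2L": values.size * bin_size},
        bin_size=bin_size,
        values={"chr2L": values},
        mark=mark,
        sample=sample,
    )


def gene_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


class TestSpikeInScaleFactors:
    def test_equal_spikein_gives_unit_factors(self):
        stats = spikein_scale_factors(
            [SpikeInStats("wt", 1000, 200), SpikeInStats("mut", 1500, 200)], "wt"
        )
        assert [s.scale_factor for s in stats] == [1.0, 1.0]

    def test_double_spikein_halves_factor(self):
        stats = spikein_scale_factors(
            [SpikeInStats("wt", 1000, 200), SpikeInStats("mut", 1000, 400)], "wt"
        )
        factors = {s.sample: s.scale_factor for s in stats}
        assert factors == {"wt": 1.0, "mut": 0.5}

    def test_zero_spikein_rejected(self):
        with pytest.raises(InputError):
            spikein_scale_factors(
                [SpikeInStats("wt", 1000, 0), SpikeInStats("mut", 1000, 10)], "wt"
            )

    def test_depth_difference_cancelled(self, planted_genome):
        """A mutant sequenced at twice the depth but with no biological
        change normalizes back to a background ratio of ~1."""
        params, annotation, _, _ = planted_genome
        wt, s_wt = simulate_coverage(annotation, params, "H2Aub1", "wt")
        mut_deep = wt.scaled(2.0)
        s_mut = 2 * s_wt
        stats = spikein_scale_factors(
            [
                SpikeInStats("wt", int(wt.total()), s_wt),
                SpikeInStats("mut", int(mut_deep.total()), s_mut),
            ],
            "wt",
        )
        factors = {s.sample: s.scale_factor for s in stats}
        wt_n = normalize_track(wt, factors["wt"])
        mut_n = normalize_track(mut_deep, factors["mut"])
        ratio = mut_n.values["chr2L"].sum() / wt_n.values["chr2L"].sum()
        assert ratio == pytest.approx(1.0, abs=0.01)


class TestNormalizeTrack:
    def test_identity_and_halving(self):
        track = make_track(np.arange(1, 11, dtype=float))
        same = normalize_track(track, 1.0)
        assert np.array_equal(same.values["chr2L"], track.values["chr2L"])
        half = normalize_track(track, 0.5)
        assert np.allclose(half.values["chr2L"], track.values["chr2L"] * 0.5)
        assert half.scale_factor == 0.5


class TestGeneBodyCoverage:
    def test_constant_track(self):
        track = make_track(np.full(50, 7.0))
        genes = gene_table([("g1", "chr2L", 1000, 3000), ("g2", "chr2L", 4100, 9900)])
        out = gene_body_coverage(track, genes)
        assert np.allclose(out["mean_coverage"], 7.0)

    def test_partial_bin_weighting(self):
        # gene covers the second half of bin0 (value 2) and first half of
        # bin1 (value 4) -> mean 3
        track = make_track(np.array([2.0, 4.0]))
        out = gene_body_coverage(track, gene_table([("g1", "chr2L", 100, 300)]))
        assert out["mean_coverage"].iloc[0] == pytest.approx(3.0)

    def test_out_of_genome_gene_skipped(self):
        track = make_track(np.full(10, 1.0))
        genes = gene_table([("g1", "chr2L", 0, 500), ("g2", "chr2L", 1900, 99_999)])
        out = gene_body_coverage(track, genes)
        assert len(out) == 1
        assert out.attrs["n_skipped"] == 1

    def test_planted_enrichment_ratio(self, planted_genome):
        params, annotation, genes, _ = planted_genome
        mut, _ = simulate_coverage(annotation, params, "H2Aub1", "mut")
        q = gene_body_coverage(mut, genes, annotation)
        means = q.groupby("class")["mean_coverage"].mean()
        assert means["canonical"] / means["neutral"] == pytest.approx(5.0, rel=0.1)


class TestFoldChanges:
    def test_identity(self, planted_genome):
        params, annotation, genes, _ = planted_genome
        wt, _ = simulate_coverage(annotation, params, "H2Aub1", "wt")
        q = gene_body_coverage(wt, genes, annotation)
        fc = fold_changes(q, q, pseudocount=0.7)
        assert np.allclose(fc["fold_change"], 1.0)
        assert np.allclose(fc["log2_fc"], 0.0)

    def test_fourfold_definition(self):
        track = make_track(np.full(50, 10.0))
        genes = gene_table([("g1", "chr2L", 0, 10_000)])
        q_wt = gene_body_coverage(track, genes)
        q_mut = gene_body_coverage(normalize_track(track, 4.0), genes)
        fc = fold_changes(q_mut, q_wt, pseudocount=1e-9)
        assert fc["fold_change"].iloc[0] == pytest.approx(4.0)
        assert fc["log2_fc"].iloc[0] == pytest.approx(2.0)

    def test_gene_set_mismatch_rejected(self):
        track = make_track(np.full(10, 1.0))
        qa = gene_body_coverage(track, gene_table([("g1", "chr2L", 0, 500)]))
        qb = gene_body_coverage(track, gene_table([("g2", "chr2L", 0, 500)]))
        with pytest.raises(InputError):
            fold_changes(qa, qb)

    def test_class_median_recovery_caly_design(self, planted_genome):
        """Global 4x plus canonical-restricted 20x H2Aub1 gain is read back
        from the spike-in-normalized class medians."""
        params, annotation, genes, _ = planted_genome
        wt, s_wt = simulate_coverage(annotation, params, "H2Aub1", "wt")
        f_mut = implied_spikein_fraction(annotation, params, "H2Aub1", "mut", "wt")
        mut, s_mut = simulate_coverage(
            annotation, params, "H2Aub1", "mut", spikein_fraction=f_mut
        )
        stats = spikein_scale_factors(
            [
                SpikeInStats("wt", int(wt.total()), s_wt),
                SpikeInStats("mut", int(mut.total()), s_mut),
            ],
            "wt",
        )
        factors = {s.sample: s.scale_factor for s in stats}
        q_wt = gene_body_coverage(normalize_track(wt, factors["wt"]), genes, annotation)
        q_mut = gene_body_coverage(normalize_track(mut, factors["mut"]), genes, annotation)
        med = class_median_fc(fold_changes(q_mut, q_wt))
        assert med["neutral"] == pytest.approx(4.0, rel=0.15)
        assert med["canonical"] == pytest.approx(20.0, rel=0.15)

    def test_scaling_invariance(self, planted_genome):
        """Scaling a library (track and spike-in together) leaves every
        fold change unchanged."""
        params, annotation, genes, _ = planted_genome
        wt, s_wt = simulate_coverage(annotation, params, "H2Aub1", "wt")
        mut, s_mut = simulate_coverage(annotation, params, "H2Aub1", "mut")

        def run(wt_track, s_w, mut_track, s_m):
            stats = spikein_scale_factors(
                [
                    SpikeInStats("wt", int(wt_track.total()), s_w),
                    SpikeInStats("mut", int(mut_track.total()), s_m),
                ],
                "wt",
            )
            f = {s.sample: s.scale_factor for s in stats}
            q_wt = gene_body_coverage(normalize_track(wt_track, f["wt"]), genes)
            q_mut = gene_body_coverage(normalize_track(mut_track, f["mut"]), genes)
            return fold_changes(q_mut, q_wt)["fold_change"].to_numpy()

        base = run(wt, s_wt, mut, s_mut)
        rescaled = run(wt, s_wt, mut.scaled(3.0), 3 * s_mut)
        assert np.allclose(base, rescaled, rtol=1e-12)


class TestDomainMetaprofile:
    def test_constant_track_flat_profile(self):
        track = make_track(np.full(500, 4.0))
        domains = [ChromatinDomain("chr2L", 20_000, 40_000, "canonical")]
        mp = domain_metaprofile(track, domains)
        assert np.allclose(mp.profile, 4.0)
        assert mp.profile.size == 100

    def test_step_function_recovered(self):
        vals = np.ones(500)
        vals[100:200] = 5.0  # domain body 20-40 kb
        track = make_track(vals)
        domains = [ChromatinDomain("chr2L", 20_000, 40_000, "canonical")]
        mp = domain_metaprofile(track, domains, flank_bp=5000)
        body = mp.profile[mp.body_slice]
        assert np.allclose(body[2:-2], 5.0)
        assert np.allclose(mp.profile[:20], 1.0)  # outer upstream flank
        assert np.allclose(mp.profile[-20:], 1.0)

    def test_single_domain_equals_its_profile(self):
        rng = np.random.default_rng(55)
        track = make_track(rng.uniform(1, 9, 400))
        dom = [ChromatinDomain("chr2L", 30_000, 50_000, "x")]
        mp1 = domain_metaprofile(track, dom)
        mp2 = domain_metaprofile(track, dom * 1)
        assert np.allclose(mp1.profile, mp2.profile)

    def test_empty_domain_list_rejected(self):
        with pytest.raises(InputError):
            domain_metaprofile(make_track(np.ones(10)), [])

    def test_step_converges_with_finer_bins(self):
        """Meta-profile of a step track approaches the step as bins shrink."""
        errs = []
        start, end = 20_150, 40_150  # deliberately not bin-aligned
        for bs in (400, 100):
            nb = 100_000 // bs
            vals = np.ones(nb)
            edges = np.arange(nb) * bs
            frac = np.clip((np.minimum(edges + bs, end) - np.maximum(edges, start)) / bs, 0, 1)
            vals = vals + 4.0 * frac
            track = make_track(vals, bin_size=bs)
            dom = [ChromatinDomain("chr2L", start, end, "x")]
            mp = domain_metaprofile(track, dom, flank_bp=5000)
            ideal = np.concatenate([np.ones(25), np.full(50, 5.0), np.ones(25)])
            errs.append(np.abs(mp.profile - ideal).mean())
        assert errs[1] < errs[0]


class TestAccessibilityFcScatter:
    def regions(self):
        return [
            ChromatinDomain("chr2L", 10_000, 20_000, "low"),
            ChromatinDomain("chr2L", 50_000, 60_000, "high"),
        ]

    def test_identical_tracks_zero_fc(self):
        track = make_track(np.full(500, 6.0))
        table = accessibility_fc_scatter(track, track, track, track, self.regions())
        assert np.allclose(table["atac_log2_fc"], 0.0)
        assert np.allclose(table["h2aub_log2_fc"], 0.0)
        assert list(table["accessibility"]) == ["low", "high"]

    def test_planted_co_gain(self, planted_genome):
        """Canonical regions with ATAC x2 and H2Aub1 x20 co-gain land near
        (1, log2(20)) in the fold-change plane and correlate positively."""
        params, annotation, _, _ = planted_genome
        atac_wt, _ = simulate_coverage(annotation, params, "ATAC", "wt")
        atac_mut, _ = simulate_coverage(annotation, params, "ATAC", "mut")
        h_wt, _ = simulate_coverage(annotation, params, "H2Aub1", "wt")
        h_mut, _ = simulate_coverage(annotation, params, "H2Aub1", "mut")
        # fixed 2-kb tiling regions stand in for accessibility segments
        regions = [
            ChromatinDomain("chr2L", s, s + 2000, "low")
            for s in range(0, 600_000, 2000)
        ]
        table = accessibility_fc_scatter(
            atac_mut, atac_wt, h_mut, h_wt, regions, annotation=annotation
        )
        canonical = table[table["class"] == "canonical"]
        assert canonical["atac_log2_fc"].median() == pytest.approx(1.0, abs=0.15)
        assert canonical["h2aub_log2_fc"].median() == pytest.approx(
            np.log2(20), abs=0.2
        )
        rho, p = spearmanr(table["atac_log2_fc"], table["h2aub_log2_fc"])
        assert rho > 0 and p < 0.01

    def test_out_of_genome_region_skipped(self):
        track = make_track(np.full(500, 2.0))
        regions = self.regions() + [ChromatinDomain("chrX", 0, 1000, "low")]
        table = accessibility_fc_scatter(track, track, track, track, regions)
        assert len(table) == 2
        assert table.attrs["n_skipped"] == 1
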