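"""Synthetic-data generators: determinism, planted structure, noise model."""

import numpy as np
import pandas as pd
import pytest

from athcnv.locus import LcrPair, GenomicInterval, default_locus_map, nahr_deletion_size
from athcnv.simulate import (
    AccessionProfile,
    PanelConfig,
    mlpa_expected_signal,
    panel_to_frame,
    simulate_accession_sequence,
    simulate_ddpcr_wells,
    simulate_junction_amplicon,
    simulate_mlpa_peaks,
    simulate_panel,
    simulate_pseudogenome,
    simulate_reference,
    simulate_snp_matrix,
)
from athcnv import popstats


class TestProfiles:
    def test_pattern_copy_number_consistency_enforced(self):
        with pytest.raises(ValueError):
            AccessionProfile("a", "del-2", msh2_cn=2, block_cn=2,
                             breakpoint_interval=1)
        with pytest.raises(ValueError):
            AccessionProfile("a", "basic", msh2_cn=4, block_cn=2)
        with pytest.raises(ValueError):  # MSH2 never deleted
            AccessionProfile("a", "basic", msh2_cn=0, block_cn=2)
        with pytest.raises(ValueError):  # odd copy number (heterozygote)
            AccessionProfile("a", "dupl-2", msh2_cn=2, block_cn=5,
                             breakpoint_interval=2)

    def test_del2_requires_breakpoint_interval(self):
        with pytest.raises(ValueError):
            AccessionProfile("a", "del-2", msh2_cn=2, block_cn=0)

    def test_default_panel_reproduces_study_mix(self, default_panel):
        counts = pd.Series(
            [p.genotype_pattern for p in default_panel]
        ).value_counts()
        assert counts["basic"] == 67
        assert counts["del-2"] == 101
        assert counts["dupl-1"] == 1
        assert counts["dupl-2"] == 9
        assert counts["dupl-3-a"] == 6
        assert counts["dupl-3-b"] == 5
        assert default_panel[0].accession_id == "Col-0"

    def test_default_panel_reproduces_cluster_structure(self, default_panel):
        msh2 = pd.Series([min(p.msh2_cn, 8) for p in default_panel])
        block = pd.Series([min(p.block_cn, 8) for p in default_panel])
        assert msh2.value_counts().to_dict() == {2: 177, 4: 5, 6: 2, 8: 5}
        assert block.value_counts().to_dict() == {
            0: 101, 2: 68, 4: 10, 6: 3, 8: 7
        }

    def test_panel_determinism(self):
        assert simulate_panel(seed=5) == simulate_panel(seed=5)


class TestReference:
    def test_lcr_pairwise_identity(self, reference_and_locus):
        _, locus = reference_and_locus
        left, right = locus.lcr.left_seq(), locus.lcr.right_seq()
        ident = sum(a == b for a, b in zip(left, right)) / 1238
        assert ident == pytest.approx((1238 - 11) / 1238)

    def test_zero_psvs_identical_repeats(self):
        base = default_locus_map()
        lcr = LcrPair(
            left=base.lcr.left, right=base.lcr.right,
            psv_positions=(), left_alleles="", right_alleles="",
        )
        from athcnv.locus import LocusMap
        locus = LocusMap(
            region=base.region, genes=base.genes, lcr=lcr,
            probe_targets=base.probe_targets,
            primer_anchors=base.primer_anchors,
        )
        _, out = simulate_reference(locus, seed=0)
        assert out.lcr.left_seq() == out.lcr.right_seq()

    def test_determinism(self):
        s1, _ = simulate_reference(seed=42)
        s2, _ = simulate_reference(seed=42)
        assert s1 == s2

    def test_repeats_planted_at_declared_coordinates(
        self, reference_and_locus
    ):
        ref, locus = reference_and_locus
        lcr, region = locus.lcr, locus.region
        i = lcr.left.start - region.start
        j = lcr.right.start - region.start
        assert ref[i: i + 1238] == lcr.left_seq()
        assert ref[j: j + 1238] == lcr.right_seq()


class TestAccessionSequences:
    def test_basic_is_reference(self, reference_and_locus):
        ref, locus = reference_and_locus
        prof = AccessionProfile("b", "basic", 2, 2)
        assert simulate_accession_sequence(prof, ref, locus) == ref

    def test_del2_loses_exactly_the_nahr_segment(self, reference_and_locus):
        ref, locus = reference_and_locus
        prof = AccessionProfile("d", "del-2", 2, 0, breakpoint_interval=1)
        seq = simulate_accession_sequence(prof, ref, locus)
        assert len(ref) - len(seq) == nahr_deletion_size(locus.lcr)

    @pytest.mark.parametrize("block_cn,extra", [(4, 1), (6, 2), (8, 3)])
    def test_dupl2_gains_one_unit_per_two_copies(
        self, reference_and_locus, block_cn, extra
    ):
        ref, locus = reference_and_locus
        prof = AccessionProfile(
            "u", "dupl-2", 2, block_cn, breakpoint_interval=2
        )
        seq = simulate_accession_sequence(prof, ref, locus)
        assert len(seq) - len(ref) == extra * nahr_deletion_size(locus.lcr)

    def test_del2_and_dupl2_are_reciprocal(self, reference_and_locus):
        # same breakpoint interval: deletion's chimeric repeat reads L->R,
        # the duplication junction repeat reads R->L with identical
        # switch geometry
        ref, locus = reference_and_locus
        lcr = locus.lcr
        for interval in (1, 2, 5):
            d = AccessionProfile("d", "del-2", 2, 0,
                                 breakpoint_interval=interval)
            u = AccessionProfile("u", "dupl-2", 2, 4,
                                 breakpoint_interval=interval)
            jd = simulate_junction_amplicon(d, ref, locus, flank=0)
            ju = simulate_junction_amplicon(u, ref, locus, flank=0)
            for p, la, ra in zip(
                lcr.psv_positions, lcr.left_alleles, lcr.right_alleles
            ):
                assert {jd[p - 1], ju[p - 1]} == {la, ra}

    def test_junction_amplicon_only_for_rearranged(self, reference_and_locus):
        ref, locus = reference_and_locus
        with pytest.raises(ValueError):
            simulate_junction_amplicon(
                AccessionProfile("b", "basic", 2, 2), ref, locus
            )


class TestMlpaPeaks:
    def test_noiseless_linear_ratios_exact(
        self, reference_and_locus, noiseless_config
    ):
        _, locus = reference_and_locus
        cfg = PanelConfig(
            mlpa_noise_cv=0.0, sample_scale_cv=0.0, mlpa_saturation=0.0
        )
        panel = [
            AccessionProfile("Col-0", "basic", 2, 2),
            AccessionProfile("dup", "dupl-2", 2, 4, breakpoint_interval=2),
            AccessionProfile("del", "del-2", 2, 0, breakpoint_interval=1),
        ]
        peaks = simulate_mlpa_peaks(panel, cfg, locus, seed=0)
        ratios = peaks / peaks.loc["Col-0"]
        assert ratios.loc["dup", "mlpaE"] == pytest.approx(2.0)
        # deleted block probes sit at background, far below 0.5
        for probe in ("mlpaD", "mlpaE", "mlpaF", "mlpaG"):
            assert ratios.loc["del", probe] == pytest.approx(0.01)

    def test_saturation_compresses_high_copy_numbers(self):
        r12 = mlpa_expected_signal(12, saturation=0.108)
        r2 = mlpa_expected_signal(2, saturation=0.108)
        assert r12 / r2 == pytest.approx(3.9, abs=0.05)
        assert mlpa_expected_signal(12, saturation=0.0) == 6.0

    def test_requires_calibrator(self, noiseless_config):
        panel = [AccessionProfile("x", "basic", 2, 2)]
        with pytest.raises(ValueError):
            simulate_mlpa_peaks(panel, noiseless_config, seed=0)

    def test_determinism(self, default_panel):
        cfg = PanelConfig()
        p1 = simulate_mlpa_peaks(default_panel, cfg, seed=7)
        p2 = simulate_mlpa_peaks(default_panel, cfg, seed=7)
        pd.testing.assert_frame_equal(p1, p2)

    def test_negative_cv_rejected(self, default_panel):
        with pytest.raises(ValueError):
            PanelConfig(mlpa_noise_cv=-0.1)


class TestDdpcrWells:
    def test_zero_lambda_gives_zero_positives(self):
        panel = [AccessionProfile("Col-0", "basic", 2, 2)]
        cfg = PanelConfig(lambda_ref=0.0, lambda_ntc=0.0)
        wells = simulate_ddpcr_wells(panel, cfg, seed=0)
        assert (wells["positive_droplets"] == 0).all()

    def test_dose_doubling_doubles_occupancy(self):
        # CN 4 vs CN 2: positive fractions near 1-e^(-2λ) vs 1-e^(-λ)
        cfg = PanelConfig(n_wells=20, lambda_ntc=0.0)
        panel = [
            AccessionProfile("Col-0", "basic", 2, 2),
            AccessionProfile("dup", "dupl-2", 2, 4, breakpoint_interval=2),
        ]
        wells = simulate_ddpcr_wells(panel, cfg, seed=3)
        frac = (
            wells[~wells["is_ntc"]]
            .groupby(["sample", "assay"])
            .apply(
                lambda g: g["positive_droplets"].sum()
                / g["total_droplets"].sum(),
                include_groups=False,
            )
        )
        lam = cfg.lambda_ref
        assert frac.loc[("Col-0", "AT3G18530")] == pytest.approx(
            1 - np.exp(-lam), abs=0.01
        )
        assert frac.loc[("dup", "AT3G18530")] == pytest.approx(
            1 - np.exp(-2 * lam), abs=0.01
        )

    def test_determinism(self, default_panel):
        w1 = simulate_ddpcr_wells(default_panel, seed=11)
        w2 = simulate_ddpcr_wells(default_panel, seed=11)
        pd.testing.assert_frame_equal(w1, w2)


class TestPseudogenomes:
    def test_del2_block_fully_masked_without_noise(self, reference_and_locus):
        ref, locus = reference_and_locus
        prof = AccessionProfile("d", "del-2", 2, 0, breakpoint_interval=1)
        pg = simulate_pseudogenome(prof, ref, locus, n_noise_rate=0.0, seed=0)
        frac = popstats.missingness_fraction(
            pg, locus.block_region, locus.region
        )
        assert frac == 1.0

    def test_basic_missingness_stays_near_noise_rate(
        self, reference_and_locus
    ):
        ref, locus = reference_and_locus
        prof = AccessionProfile("b", "basic", 2, 2)
        pg = simulate_pseudogenome(prof, ref, locus, n_noise_rate=0.05, seed=1)
        frac = popstats.missingness_fraction(
            pg, locus.block_region, locus.region
        )
        assert frac == pytest.approx(0.05, abs=0.02)
        assert not popstats.predict_del2(frac)

    def test_duplications_never_classified_as_deleted(
        self, reference_and_locus
    ):
        ref, locus = reference_and_locus
        for pattern, cn in (("dupl-2", 4), ("dupl-3-a", 4)):
            prof = AccessionProfile(
                "u", pattern, 2 if pattern == "dupl-2" else 4, cn,
                breakpoint_interval=2,
            )
            pg = simulate_pseudogenome(prof, ref, locus, seed=2)
            frac = popstats.missingness_fraction(
                pg, locus.block_region, locus.region
            )
            assert not popstats.predict_del2(frac)

    def test_noise_rate_bounds(self, reference_and_locus):
        ref, locus = reference_and_locus
        prof = AccessionProfile("b", "basic", 2, 2)
        with pytest.raises(ValueError):
            simulate_pseudogenome(prof, ref, locus, n_noise_rate=0.3)


class TestSnpMatrix:
    def test_shape_and_determinism(self, default_panel):
        cfg = PanelConfig()
        m1, t1 = simulate_snp_matrix(default_panel, cfg, seed=4)
        m2, _ = simulate_snp_matrix(default_panel, cfg, seed=4)
        pd.testing.assert_frame_equal(m1, m2)
        assert m1.shape == (cfg.n_snps, len(default_panel))
        assert set(np.unique(m1.to_numpy())) <= set("ACGTN")

    def test_high_maf_sites_pass_frequency_filter(self, default_panel):
        cfg = PanelConfig(maf_min=0.5, maf_max=0.5, snp_missing_rate=0.0,
                          n_snps=50)
        m, _ = simulate_snp_matrix(default_panel, cfg, seed=6)
        kept = popstats.filter_snps(m)
        assert len(kept) == len(m)

    def test_cnv_independent_simulation_keeps_ld_low(self, default_panel):
        cfg = PanelConfig(n_snps=300)
        m, _ = simulate_snp_matrix(default_panel, cfg, seed=8)
        truth = panel_to_frame(default_panel)
        ld = popstats.cnv_ld_scan(popstats.filter_snps(m), truth)
        assert np.nanmax(ld["max_r2"].to_numpy()) < 0.3
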