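import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svpanel.imputation import (
    DEFAULT_GL_CUTOFFS,
    expected_discordance,
    extract_gold_standard,
    haplotype_copy_imputer,
    regularize_gl,
    relative_reduction,
    stratify_by_maf,
    threshold_sweep,
)
from svpanel.records import VariantRecord


def _svs(n, vtype="DEL", length=100):
    if vtype in ("INS", "MEI"):
        return [VariantRecord("1", 1000 * i, 1000 * i, vtype, length, f"v{i}")
                for i in range(n)]
    return [VariantRecord("1", 1000 * i, 1000 * i + length, vtype, length,
                          f"v{i}") for i in range(n)]


class TestRegularizeGl:
    def test_point_mass_is_floored_and_renormalized(self):
        out = regularize_gl(np.array([1.0, 0.0, 0.0]), epsilon=1e-4)
        assert (out >= 1e-4 - 1e-15).all()
        assert out.sum() == pytest.approx(1.0)
        assert out[0] > 0.99

    def test_uniform_distribution_unchanged(self):
        u = np.full(3, 1 / 3)
        np.testing.assert_allclose(regularize_gl(u), u)

    def test_idempotent_when_already_floored(self):
        p = np.array([0.5, 0.3, 0.2])
        np.testing.assert_allclose(regularize_gl(regularize_gl(p)),
                                   regularize_gl(p))

    def test_epsilon_bounds_enforced(self):
        with pytest.raises(ValueError):
            regularize_gl(np.full(3, 1 / 3), epsilon=1 / 3)
        with pytest.raises(ValueError):
            regularize_gl(np.full(3, 1 / 3), epsilon=0.0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=3, max_size=3))
    def test_output_is_a_distribution(self, raw):
        p = np.array(raw) / np.sum(raw)
        out = regularize_gl(p)
        assert out.sum() == pytest.approx(1.0)
        assert (out >= 0).all()


class TestGoldStandard:
    def test_confident_het_retained_at_strict_threshold(self):
        probs = np.array([[[0.0003, 0.9996, 0.0001]]])
        gold = extract_gold_standard(probs, _svs(1))
        assert gold.retained[0, 0]
        assert gold.genotypes[0, 0] == 1

    def test_marginal_call_dropped_at_strict_threshold(self):
        probs = np.array([[[0.99, 0.005, 0.005]]])
        gold = extract_gold_standard(probs, _svs(1))
        assert not gold.retained[0, 0]
        assert gold.genotypes[0, 0] == -1

    def test_mei_class_uses_laxer_threshold(self):
        probs = np.array([[[0.9, 0.07, 0.03]]])
        assert extract_gold_standard(probs, _svs(1, "MEI", 300)).retained.all()
        assert not extract_gold_standard(probs, _svs(1)).retained.any()

    def test_unknown_class_without_default_rejected(self):
        probs = np.array([[[1.0, 0.0, 0.0]]])
        with pytest.raises(ValueError, match="threshold"):
            extract_gold_standard(probs, _svs(1), {"MEI": 0.85})

    def test_extraction_is_a_pure_filter(self, rng):
        probs = rng.dirichlet([0.3, 0.3, 0.3], size=(20, 5))
        gold = extract_gold_standard(probs, _svs(20))
        argmax = probs.argmax(axis=2)
        assert (gold.genotypes[gold.retained]
                == argmax[gold.retained]).all()
        assert (gold.genotypes[~gold.retained] == -1).all()

    def test_counts_per_class_reported(self):
        probs = np.ones((2, 3, 3)) / 3
        probs[0, :, 0] = 1.0
        probs[0, :, 1:] = 0.0
        variants = [_svs(1)[0], _svs(1, "MEI", 300)[0]]
        gold = extract_gold_standard(probs, variants)
        assert gold.counts_per_class == {"DEL": 3, "MEI": 0}


class TestExpectedDiscordance:
    def test_identical_point_masses_agree_exactly(self):
        p = np.array([0.0, 1.0, 0.0])
        assert expected_discordance(p, p) == 0.0

    def test_uniform_against_point_mass(self):
        u = np.full(3, 1 / 3)
        g = np.array([1.0, 0.0, 0.0])
        assert expected_discordance(u, g) == pytest.approx(2 / 3)

    def test_closed_form_against_het_gold(self):
        imputed = np.array([0.9, 0.1, 0.0])
        gold = np.array([0.0, 1.0, 0.0])
        assert expected_discordance(imputed, gold) == pytest.approx(0.9)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.001, 1), min_size=6, max_size=6))
    def test_symmetric_and_bounded(self, raw):
        p = np.array(raw[:3]) / np.sum(raw[:3])
        q = np.array(raw[3:]) / np.sum(raw[3:])
        d = expected_discordance(p, q)
        assert d == pytest.approx(expected_discordance(q, p))
        assert 0 <= d <= 1


class TestHaplotypeCopyImputer:
    def _panel(self, rng, n_hap=8, n_snp=40, n_sv=5):
        snp_hap = rng.integers(0, 2, (n_snp, n_hap)).astype(np.int8)
        sv_hap = rng.integers(0, 2, (n_sv, n_hap)).astype(np.int8)
        snps = [VariantRecord("1", 100 * (i + 1), 100 * (i + 1) + 1, "SNP",
                              1, f"s{i}") for i in range(n_snp)]
        svs = [VariantRecord("1", 90 * (i + 1), 90 * (i + 1) + 50, "DEL", 50,
                             f"d{i}") for i in range(n_sv)]
        return snps, snp_hap, svs, sv_hap

    def test_target_present_in_panel_recovers_truth_exactly(self, rng):
        snps, snp_hap, svs, sv_hap = self._panel(rng)
        # panel haplotypes must be distinct for the match to be unique
        assert len({tuple(snp_hap[:, h]) for h in range(8)}) == 8
        tgt = snp_hap[:, 2] + snp_hap[:, 5]
        truth = sv_hap[:, 2] + sv_hap[:, 5]
        probs, no_flank = haplotype_copy_imputer(
            tgt[:, None], snps, snp_hap, svs, sv_hap,
            window_snps=40, mismatch_rate=0.0)
        assert not no_flank.any()
        gold = np.zeros((len(svs), 1, 3))
        gold[np.arange(len(svs)), 0, truth] = 1.0
        d = expected_discordance(probs, gold)
        assert (d == 0.0).all()

    def test_monomorphic_sv_imputes_hom_ref_point_mass(self, rng):
        snps, snp_hap, svs, sv_hap = self._panel(rng)
        sv_hap[:] = 0
        tgt = snp_hap[:, 0] + snp_hap[:, 3]
        probs, _ = haplotype_copy_imputer(tgt[:, None], snps, snp_hap,
                                          svs, sv_hap)
        np.testing.assert_allclose(probs[:, 0, 0], 1.0)

    def test_no_flanking_snps_returns_uniform_flagged(self, rng):
        snps, snp_hap, svs, sv_hap = self._panel(rng)
        lonely = [VariantRecord("9", 100, 150, "DEL", 50, "far")]
        probs, no_flank = haplotype_copy_imputer(
            (snp_hap[:, 0] + snp_hap[:, 1])[:, None], snps, snp_hap,
            lonely, sv_hap[:1])
        assert no_flank[0]
        np.testing.assert_allclose(probs[0, 0], 1 / 3)

    def test_output_rows_are_distributions(self, rng):
        snps, snp_hap, svs, sv_hap = self._panel(rng)
        tgt = rng.integers(0, 3, (len(snps), 3))
        probs, _ = haplotype_copy_imputer(tgt, snps, snp_hap, svs, sv_hap)
        np.testing.assert_allclose(probs.sum(axis=2), 1.0, rtol=1e-9)

    def test_denser_snp_windows_do_not_hurt_recovery(self, rng):
        # panel-density parameter recovery: imputing the same cohort with
        # more informative SNPs must not increase discordance
        from svpanel.studies import imputation_study

        results = [imputation_study(seed=31, snp_density=d, scale=0.08)
                   for d in (25.0, 300.0)]
        sparse, dense = [r["overall_discordance_095"] for r in results]
        assert dense <= sparse


class TestThresholdSweep:
    def _inputs(self, rng, n=60):
        svs = _svs(n)
        gold_probs = np.zeros((n, 2, 3))
        truth = rng.integers(0, 3, (n, 2))
        for i in range(n):
            for j in range(2):
                gold_probs[i, j, truth[i, j]] = 1.0
        imputed = 0.85 * gold_probs + 0.15 * rng.dirichlet([1, 1, 1],
                                                           size=(n, 2))
        gold = extract_gold_standard(gold_probs, svs)
        return imputed, gold, svs

    def test_lowest_cutoff_misses_nothing(self, rng):
        imputed, gold, svs = self._inputs(rng)
        curve = threshold_sweep(imputed, gold, svs)
        at_033 = curve.table.loc[curve.table["cutoff"] == 0.33]
        assert (at_033["missing_fraction"] == 0.0).all()

    def test_missing_fraction_non_decreasing(self, rng):
        imputed, gold, svs = self._inputs(rng)
        curve = threshold_sweep(imputed, gold, svs)
        for _, grp in curve.table.groupby("vclass"):
            missing = grp.sort_values("cutoff")["missing_fraction"]
            assert (missing.diff().dropna() >= 0).all()

    def test_concordance_complements_discordance(self, rng):
        imputed, gold, svs = self._inputs(rng)
        curve = threshold_sweep(imputed, gold, svs)
        ok = curve.table["discordance"].notna()
        np.testing.assert_allclose(
            curve.table.loc[ok, "concordance"]
            + curve.table.loc[ok, "discordance"], 1.0)

    def test_unsorted_cutoffs_rejected(self, rng):
        imputed, gold, svs = self._inputs(rng)
        with pytest.raises(ValueError, match="sorted"):
            threshold_sweep(imputed, gold, svs, cutoffs=(0.9, 0.5))

    def test_class_without_gold_calls_is_skipped_and_logged(self, rng):
        imputed, gold, svs = self._inputs(rng)
        svs = list(svs)
        svs[0] = VariantRecord("1", 0, 0, "MEI", 300, "v0")
        gold.retained[0] = False
        curve = threshold_sweep(imputed, gold, svs)
        assert "MEI" not in set(curve.table["vclass"])
        assert any("MEI" in f for f in curve.flags)


class TestMafStratification:
    def test_bin_assignment_follows_floor_rule(self, rng):
        svs = _svs(1)
        gold_probs = np.zeros((1, 1, 3))
        gold_probs[0, 0, 1] = 1.0
        gold = extract_gold_standard(gold_probs, svs)
        imputed = gold_probs.copy()
        out = stratify_by_maf(imputed, gold, svs, panel_af=np.array([0.26]))
        assert out.loc[out["n_calls"] > 0, "bin"].iloc[0] == 11

    def test_bins_tile_half_open_unit_interval(self, rng):
        svs = _svs(4)
        gold_probs = np.zeros((4, 1, 3))
        gold_probs[:, 0, 0] = 1.0
        gold = extract_gold_standard(gold_probs, svs)
        out = stratify_by_maf(gold_probs, gold, svs,
                              panel_af=np.array([0.01, 0.025, 0.26, 0.5]))
        assert len(out) == 20
        assert out["maf_low"].iloc[0] == 0.0
        assert out["maf_high"].iloc[-1] == 0.5
        np.testing.assert_allclose(out["maf_low"].iloc[1:],
                                   out["maf_high"].iloc[:-1])

    def test_rare_allele_restriction_discards_hom_major(self):
        svs = _svs(1)
        gold_probs = np.zeros((1, 2, 3))
        gold_probs[0, 0, 0] = 1.0   # hom-major (af < 0.5)
        gold_probs[0, 1, 1] = 1.0   # carries the rare allele
        gold = extract_gold_standard(gold_probs, svs)
        full = stratify_by_maf(gold_probs, gold, svs,
                               panel_af=np.array([0.1]))
        rare = stratify_by_maf(gold_probs, gold, svs,
                               panel_af=np.array([0.1]),
                               rare_allele_only=True)
        assert full["n_calls"].sum() == 2
        assert rare["n_calls"].sum() == 1


class TestRelativeReduction:
    def test_no_change_gives_zero(self):
        assert relative_reduction(3.0, 3.0) == 0

    def test_rounds_half_away_from_zero(self):
        assert relative_reduction(4.0, 3.9) == 3  # 2.5% -> 3
        assert relative_reduction(100.0, 0.0) == 100

    def test_increase_reports_negative_reduction(self):
        assert relative_reduction(2.0, 3.0) == -50

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            relative_reduction(0.0, 1.0)
        with pytest.raises(ValueError):
            relative_reduction(1.0, -0.5)

    def test_default_cutoffs_are_the_documented_six(self):
        assert DEFAULT_GL_CUTOFFS == (0.33, 0.75, 0.9, 0.95, 0.99, 0.999)
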