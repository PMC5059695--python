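import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svpanel.records import Pedigree, PedigreeSample, VariantRecord
from svpanel.spectrum import (
    annotate_novelty,
    annotation_enrichment_test,
    assign_quartiles,
    compute_allele_frequencies,
    haplotype_load,
    stratify_quartiles,
    tdt,
)


def _dels(n, length=100, gap=1000):
    return [VariantRecord("1", i * gap, i * gap + length, "DEL", length,
                          f"d{i}") for i in range(n)]


def _founder_ped(n):
    return Pedigree(samples=[PedigreeSample(f"s{i}", None, None, f"f{i}")
                             for i in range(n)])


class TestAlleleFrequencies:
    def test_counts_alt_alleles_over_founder_chromosomes(self):
        # 10 founders, 3 het + 1 hom-alt: AF = 5 / 20
        gt = np.zeros((1, 10), dtype=int)
        gt[0, :3] = 1
        gt[0, 3] = 2
        table = compute_allele_frequencies(
            gt, [f"s{i}" for i in range(10)], _dels(1),
            pedigree=_founder_ped(10))
        assert table["af"].iloc[0] == 0.25
        assert table["maf"].iloc[0] == 0.25

    def test_all_hom_ref_gives_zero(self):
        gt = np.zeros((1, 6), dtype=int)
        table = compute_allele_frequencies(
            gt, [f"s{i}" for i in range(6)], _dels(1),
            pedigree=_founder_ped(6))
        assert table["af"].iloc[0] == 0.0

    def test_offspring_genotypes_do_not_change_founder_af(self):
        ped = Pedigree(samples=[
            PedigreeSample("dad", None, None, "f"),
            PedigreeSample("mum", None, None, "f"),
            PedigreeSample("kid", "dad", "mum", "f")])
        gt = np.array([[1, 1, 2]])
        with_kid = compute_allele_frequencies(
            gt, ["dad", "mum", "kid"], _dels(1), pedigree=ped)
        without = compute_allele_frequencies(
            gt[:, :2], ["dad", "mum"],
            _dels(1), pedigree=Pedigree(samples=ped.samples[:2]))
        assert with_kid["af"].iloc[0] == without["af"].iloc[0] == 0.5

    def test_missing_genotypes_leave_denominator(self):
        gt = np.array([[1, -1, -1, 0]])
        table = compute_allele_frequencies(
            gt, [f"s{i}" for i in range(4)], _dels(1),
            pedigree=_founder_ped(4))
        assert table["af"].iloc[0] == 0.25  # 1 alt over 2x2 called founders

    def test_fully_missing_variant_flagged_undefined(self):
        gt = np.full((1, 4), -1)
        table = compute_allele_frequencies(
            gt, [f"s{i}" for i in range(4)], _dels(1),
            pedigree=_founder_ped(4))
        assert not table["af_defined"].iloc[0]
        assert np.isnan(table["af"].iloc[0])

    def test_maf_folds_high_frequencies(self):
        gt = np.full((1, 5), 2)
        gt[0, 0] = 1
        table = compute_allele_frequencies(
            gt, [f"s{i}" for i in range(5)], _dels(1),
            pedigree=_founder_ped(5))
        assert table["af"].iloc[0] == 0.9
        assert table["maf"].iloc[0] == pytest.approx(0.1)


class TestQuartiles:
    def test_eight_distinct_mafs_split_two_per_quartile(self):
        mafs = [0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08]
        (q25, q50, q75), quart = stratify_quartiles(mafs)
        assert q25 <= q50 <= q75
        assert list(quart) == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_ties_fall_into_lower_quartile(self):
        _, quart = stratify_quartiles([0.2] * 8)
        assert set(quart) == {1}

    def test_fewer_than_four_variants_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            stratify_quartiles([0.1, 0.2, 0.3])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.001, 0.5), min_size=8, max_size=60,
                    unique=True))
    def test_distinct_mafs_give_balanced_quartiles(self, mafs):
        _, quart = stratify_quartiles(mafs)
        sizes = np.bincount(quart, minlength=5)[1:]
        assert sizes.max() - sizes.min() <= 1

    def test_assign_quartiles_is_per_class(self):
        gt = np.zeros((8, 4), dtype=int)
        variants = _dels(4) + [
            VariantRecord("1", 10_000 + i, 10_000 + i, "INS", 10, f"i{i}")
            for i in range(4)]
        table = compute_allele_frequencies(
            gt, [f"s{i}" for i in range(4)], variants,
            pedigree=_founder_ped(4))
        table["maf"] = [.1, .2, .3, .4, .01, .02, .03, .04]
        table["af_defined"] = True
        out, bounds = assign_quartiles(table)
        assert set(bounds) == {"DEL", "INS"}
        assert bounds["DEL"][0] > bounds["INS"][2]


class TestNovelty:
    def test_exact_match_marks_known(self):
        v = VariantRecord("1", 100, 110, "DEL", 10, "v")
        known = {"DEL": [VariantRecord("1", 100, 110, "DEL", 10, "k")]}
        assert not annotate_novelty([v], known)[0]

    def test_empty_known_sets_leave_all_novel(self):
        assert annotate_novelty(_dels(5), {}).all()

    def test_reciprocal_overlap_match_for_large_variants(self):
        v = VariantRecord("1", 1000, 1100, "DEL", 100, "v")
        known = {"DEL": [VariantRecord("1", 1040, 1140, "DEL", 100, "k")]}
        assert not annotate_novelty([v], known)[0]  # 60% reciprocal overlap

    def test_type_mismatch_stays_novel(self):
        v = VariantRecord("1", 1000, 1100, "DEL", 100, "v")
        known = {"DUP": [VariantRecord("1", 1000, 1100, "DUP", 100, "k")]}
        assert annotate_novelty([v], known)[0]

    def test_small_variant_near_miss_stays_novel(self):
        v = VariantRecord("1", 100, 110, "DEL", 10, "v")
        known = {"DEL": [VariantRecord("1", 101, 111, "DEL", 10, "k")]}
        assert annotate_novelty([v], known)[0]


class TestEnrichment:
    def test_add_one_pvalue_when_null_equals_observed(self):
        variants = _dels(5)
        res = annotation_enrichment_test(
            variants, annotation={}, mask={"1": [(0, 100_000)]},
            n_perm=10, side="depletion", seed=0)
        assert res.observed == 0
        assert res.p == pytest.approx(1.0)  # (1 + 10) / (10 + 1)

    def test_annotation_covering_mask_gives_depletion_p_one(self):
        variants = _dels(5)
        res = annotation_enrichment_test(
            variants, annotation={"1": [(0, 100_000)]},
            mask={"1": [(0, 100_000)]}, n_perm=50, side="depletion", seed=0)
        assert res.observed == 5
        assert res.p == pytest.approx(1.0)

    def test_p_bounds_and_direction_consistency(self):
        variants = _dels(10)
        res = annotation_enrichment_test(
            variants, annotation={"1": [(0, 5_000)]},
            mask={"1": [(0, 100_000)]}, n_perm=200, side="depletion", seed=1)
        assert 1 / 201 <= res.p_depletion <= 1
        assert res.p_depletion + res.p_enrichment >= 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            annotation_enrichment_test(_dels(2), {}, {}, n_perm=10)

    def test_resample_mode_uses_size_matched_universe(self):
        variants = _dels(5)
        universe = _dels(50)
        res = annotation_enrichment_test(
            variants, annotation={"1": [(0, 2_000)]},
            mask={"1": [(0, 100_000)]}, n_perm=100, side="depletion",
            seed=2, mode="resample", universe=universe)
        assert 0 < res.p <= 1

    def test_seed_determinism(self):
        kw = dict(annotation={"1": [(0, 5_000)]},
                  mask={"1": [(0, 100_000)]}, n_perm=100, seed=3)
        a = annotation_enrichment_test(_dels(8), **kw)
        b = annotation_enrichment_test(_dels(8), **kw)
        assert a.p == b.p and a.null_mean == b.null_mean


class TestHaplotypeLoad:
    def _variants(self):
        return [VariantRecord("1", 1000, 1100, "DEL", 100, "del100"),
                VariantRecord("1", 5000, 5000, "INS", 50, "ins50"),
                VariantRecord("1", 9000, 9200, "DEL", 200, "del200")]

    def test_haplotype_load_sums_affected_bp(self):
        # hap0 carries DEL100 + INS50, hap1 nothing
        haps = np.zeros((3, 1, 2), dtype=np.int8)
        haps[0, 0, 0] = 1
        haps[1, 0, 0] = 1
        load = haplotype_load(self._variants(), haps, ["s"])
        row = load.per_sample.iloc[0]
        assert row["hap0_indel_bp"] + row["hap0_sv_bp"] == 150
        assert row["hap1_indel_bp"] + row["hap1_sv_bp"] == 0

    def test_homozygous_load_counts_shared_variants_only(self):
        # hom for the 200 bp deletion, het for the 100 bp one
        haps = np.zeros((3, 1, 2), dtype=np.int8)
        haps[2, 0, :] = 1
        haps[0, 0, 0] = 1
        load = haplotype_load(self._variants(), haps, ["s"])
        row = load.per_sample.iloc[0]
        assert row["hom_sv_bp"] == 200
        assert row["hap0_sv_bp"] == 300 and row["hap1_sv_bp"] == 200

    def test_homozygous_load_never_exceeds_haplotype_loads(self, small_panel):
        load = haplotype_load(small_panel.variants, small_panel.haplotypes,
                              small_panel.samples)
        ps = load.per_sample
        hap_min_sv = np.minimum(ps["hap0_sv_bp"], ps["hap1_sv_bp"])
        assert (ps["hom_sv_bp"] <= hap_min_sv).all()

    def test_empty_panel_gives_zeros(self):
        load = haplotype_load([], np.zeros((0, 2, 2)), ["a", "b"])
        assert load.mean_haplotype_sv_bp == 0.0

    def test_load_is_additive_over_variant_sets(self):
        variants = self._variants()
        haps = np.ones((3, 2, 2), dtype=np.int8)
        full = haplotype_load(variants, haps, ["a", "b"])
        part1 = haplotype_load(variants[:1], haps[:1], ["a", "b"])
        part2 = haplotype_load(variants[1:], haps[1:], ["a", "b"])
        assert full.mean_haplotype_indel_bp == pytest.approx(
            part1.mean_haplotype_indel_bp + part2.mean_haplotype_indel_bp)
        assert full.mean_haplotype_sv_bp == pytest.approx(
            part1.mean_haplotype_sv_bp + part2.mean_haplotype_sv_bp)

    def test_unphased_input_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="phased"):
            haplotype_load(self._variants(), None, ["s"])


def _trio_genotypes(fa, mo, ch):
    """Genotype matrix for n variants over one trio."""
    gt = np.array([fa, mo, ch]).T
    ped = Pedigree(samples=[PedigreeSample("f", None, None, "x"),
                            PedigreeSample("m", None, None, "x"),
                            PedigreeSample("c", "f", "m", "x")])
    variants = [VariantRecord("1", 10 * i, 10 * i + 5, "DEL", 5, f"v{i}")
                for i in range(gt.shape[0])]
    return gt, ["f", "m", "c"], variants, ped


class TestTdt:
    def test_pure_transmission_gives_closed_form_chi2(self):
        # 10 trios, father het, mother hom-ref, child het: b=10, c=0
        gt = np.tile(np.array([[1, 0, 1]]), (10, 1)).T.reshape(3, 10).T
        gt = np.array([[1] * 10, [0] * 10, [1] * 10]).T  # (10 trios x 3)
        samples, peds = [], []
        for t in range(10):
            samples += [f"f{t}", f"m{t}", f"c{t}"]
            peds += [PedigreeSample(f"f{t}", None, None, f"x{t}"),
                     PedigreeSample(f"m{t}", None, None, f"x{t}"),
                     PedigreeSample(f"c{t}", f"f{t}", f"m{t}", f"x{t}")]
        genotypes = gt.reshape(1, 30)
        variants = [VariantRecord("1", 0, 5, "DEL", 5, "v")]
        res = tdt(genotypes, samples, variants, Pedigree(samples=peds))
        assert res["b"].iloc[0] == 10 and res["c"].iloc[0] == 0
        assert res["chi2"].iloc[0] == pytest.approx(10.0)

    def test_balanced_transmission_gives_p_one(self):
        gt, samples, variants, ped = _trio_genotypes(
            fa=[1, 1], mo=[0, 0], ch=[1, 0])
        res = tdt(gt, samples, variants, ped)
        # two variants, one transmission and one non-transmission overall
        assert res["b"].sum() == 1 and res["c"].sum() == 1

    def test_both_parents_het_resolved_by_child(self):
        gt, samples, variants, ped = _trio_genotypes(
            fa=[1, 1, 1], mo=[1, 1, 1], ch=[2, 0, 1])
        res = tdt(gt, samples, variants, ped)
        assert list(res["b"]) == [2, 0, 1]
        assert list(res["c"]) == [0, 2, 1]

    def test_mendelian_inconsistency_excluded_and_counted(self):
        gt, samples, variants, ped = _trio_genotypes(
            fa=[0], mo=[0], ch=[2])
        res = tdt(gt, samples, variants, ped)
        assert res["n_excluded"].iloc[0] == 1
        assert np.isnan(res["chi2"].iloc[0])

    def test_minor_allele_flip_when_af_above_half(self):
        gt, samples, variants, ped = _trio_genotypes(
            fa=[1], mo=[0], ch=[1])
        direct = tdt(gt, samples, variants, ped, af=np.array([0.2]))
        flipped = tdt(gt, samples, variants, ped, af=np.array([0.8]))
        assert direct["b"].iloc[0] == 1 and direct["c"].iloc[0] == 0
        assert flipped["b"].iloc[0] == 0 and flipped["c"].iloc[0] == 1

    def test_no_informative_parents_gives_nan(self):
        gt, samples, variants, ped = _trio_genotypes(
            fa=[0], mo=[0], ch=[0])
        res = tdt(gt, samples, variants, ped)
        assert np.isnan(res["p"].iloc[0])
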