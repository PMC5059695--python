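"""Self-contained verification studies run on synthetic cohorts.

Each function defines one study — its cohort, its conditions and the
quantity it measures — and returns plain numbers.  The studies double as
the package's reproducible benchmarks: the test suite asserts their
statistical properties and the acceptance script reports their outputs.

Problem sizes are chosen to make each study conclusive at desk scale: the
merge studies use thousands of variants and a thousand random instances,
the calibration studies a few hundred replicate simulations, the imputation
study two held-out samples against ~2,000 SVs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .imputation import (
    extract_gold_standard,
    haplotype_copy_imputer,
    regularize_gl,
    threshold_sweep,
)
from .ld import enumerate_pairs, gwas_matched_sampling, pair_ld_table
from .merge import (
    CallerCall,
    brute_force_merge_oracle,
    merge_callsets,
)
from .records import Pedigree, PedigreeSample, VariantRecord
from .spectrum import annotation_enrichment_test, tdt
from .synthetic import (
    CallerProfile,
    SimulationConfig,
    TruthPanel,
    simulate_caller_callsets,
    simulate_genotype_likelihoods,
    simulate_gwas_labels,
    simulate_truth_panel,
    snps_in_high_ld_with_sv,
)

__all__ = [
    "perfect_caller_recovery",
    "random_merge_instance",
    "merge_oracle_agreement",
    "ld_calibration_study",
    "imputation_study",
    "tdt_null_study",
    "enrichment_sharp_null_study",
]


# ---------------------------------------------------------------------------
# consensus merging

_PERFECT_PROFILES = (
    CallerProfile("alpha", "split-read", breakpoint_sd=0.0, fdr=0.0,
                  sensitivity={"short": 1.0, "mid": 1.0, "large": 1.0}),
    CallerProfile("beta", "read-pair", breakpoint_sd=0.0, fdr=0.0,
                  sensitivity={"short": 1.0, "mid": 1.0, "large": 1.0}),
)


def perfect_caller_recovery(seed: int, scale: float = 1.0) -> dict:
    """Recovery of a synthetic truth set by two error-free callers.

    Two callers of different strategies with perfect sensitivity, no
    breakpoint jitter and no false calls each emit every carried truth
    variant; the consensus should recover every carried truth variant at
    its exact coordinates and emit nothing else.  The truth set holds
    ~5,200 variants across six classes at ``scale=1``.
    """
    counts = {
        "DEL": {"short": 1500, "mid": 800, "large": 700},
        "INS": {"short": 1200},
        "MEI": {"large": 300},
        "COMPLEX_INDEL": {"short": 500},
        "DUP": {"large": 150},
        "INV": {"large": 50},
    }
    counts = {t: {c: max(1, int(n * scale)) for c, n in cc.items()}
              for t, cc in counts.items()}
    cfg = SimulationConfig(
        n_families=8, genome=(("1", 20_000_000),), snp_density=0.0,
        sv_counts=counts, seed=seed)
    panel = simulate_truth_panel(cfg)
    callsets = simulate_caller_callsets(panel, _PERFECT_PROFILES,
                                        seed=seed + 1)
    calls = [c for cs in callsets.values() for c in cs]
    consensus = merge_callsets(calls)

    carried = panel.genotypes.sum(axis=1) > 0
    truth_keys = {(v.chrom, v.start, v.end, v.vtype, v.length)
                  for v, keep in zip(panel.variants, carried) if keep}
    cons_keys = {(c.chrom, c.start, c.end, c.vtype, c.length)
                 for c in consensus}
    recovered = len(truth_keys & cons_keys)
    return {
        "n_truth_total": sum(n for cc in counts.values() for n in cc.values()),
        "n_truth_carried": len(truth_keys),
        "n_consensus": len(consensus),
        "recall_pct": 100.0 * recovered / len(truth_keys),
        "false_consensus": len(cons_keys - truth_keys),
    }


_INSTANCE_VTYPES = ("DEL", "INS", "DUP", "INV", "MEI", "COMPLEX_INDEL")
_INSTANCE_CALLERS = (
    ("alpha", "split-read"), ("beta", "read-pair"), ("gamma", "read-depth"),
    ("delta", "assembly"), ("epsilon", "split-read"),
)


def random_merge_instance(rng: np.random.Generator,
                          max_calls: int = 200) -> list[CallerCall]:
    """A dense random call set exercising overlaps, chains and duplicates."""
    n = int(rng.integers(2, max_calls + 1))
    calls = []
    for i in range(n):
        vtype = _INSTANCE_VTYPES[rng.integers(0, len(_INSTANCE_VTYPES))]
        caller, strategy = _INSTANCE_CALLERS[
            rng.integers(0, len(_INSTANCE_CALLERS))]
        small = rng.random() < 0.4
        if small:
            length = int(rng.integers(1, 21))
            # coarse position grid so exact duplicates happen often
            start = int(rng.integers(0, 40)) * 25
        else:
            length = int(rng.integers(21, 400))
            start = int(rng.integers(0, 2000))
        if vtype in ("INS", "MEI"):
            end = start
        elif vtype == "DEL":
            end = start + length
        elif vtype == "COMPLEX_INDEL":
            end = start + int(rng.integers(1, 12))
        else:
            end = start + length
        calls.append(CallerCall(
            chrom="1" if rng.random() < 0.8 else "2",
            start=start, end=end, vtype=vtype, length=length,
            id=f"call_{i:04d}", caller=caller, strategy=strategy,
            accuracy_rank=int(rng.integers(1, 5))))
    return calls


def merge_oracle_agreement(seed: int, n_instances: int = 1000,
                           max_calls: int = 200) -> dict:
    """Fraction of random instances where the production merge and the
    naive all-pairs oracle return identical consensus sets."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        calls = random_merge_instance(rng, max_calls)
        if merge_callsets(calls) == brute_force_merge_oracle(calls):
            agree += 1
    return {"n_instances": n_instances,
            "agreement_pct": 100.0 * agree / n_instances}


# ---------------------------------------------------------------------------
# matched-sampling calibration

def _ld_study_panel(seed: int) -> TruthPanel:
    cfg = SimulationConfig(
        n_families=25, genome=(("1", 40_000_000),), snp_density=150.0,
        sv_counts={"DEL": {"mid": 1000, "large": 1000}},
        ld_block_bp=50_000, ld_pool_haplotypes=12, sv_tag_fraction=0.35,
        seed=seed)
    return simulate_truth_panel(cfg)


def ld_calibration_study(
    seed: int,
    replicates: int = 200,
    repetitions: int = 150,
    ld_enrichment: float = 1.0,
    fraction: float = 0.04,
    max_distance: int = 25_000,
) -> np.ndarray:
    """z-scores of the matched-sampling test over replicate label draws.

    One phased cohort is simulated; each replicate redraws the GWAS labels
    (with the stated LD enrichment; 1 = null) and reruns the full matched
    resampling.  The study is designed in the regime where the per-pair
    matched null is exchangeable with the observed set: every deletion is
    paired with its nearest SNP and each SNP is used at most once (pairs
    share no loci), and GWAS pairs are a small fraction of a large pool
    (~100 of ~2,000).  Outside this regime the z-score is intrinsically
    anti-conservative: with many pairs per SNP or per SV the observed
    fraction has clustered variance the per-pair null does not model, and
    when the GWAS set is a sizeable share of the pool the matched draws
    come from its complement and are anti-correlated with it.
    """
    panel = _ld_study_panel(seed)
    snps = [v for v in panel.variants if v.vtype == "SNP"]
    dels = [v for v in panel.variants if v.vtype == "DEL"]
    snp_df = pd.DataFrame({"snp": [s.id for s in snps],
                           "chrom": [s.chrom for s in snps],
                           "pos": [s.start for s in snps]})
    fhap = panel.founder_haplotype_matrix()
    hap_by_id = {v.id: fhap[i] for i, v in enumerate(panel.variants)}
    pairs = enumerate_pairs(snp_df, dels, max_distance=max_distance)
    # disjoint pairs: nearest SNP per deletion, every SNP at most once
    pairs = (pairs.sort_values(["sv", "distance"], kind="mergesort")
             .drop_duplicates(subset=["sv"], keep="first")
             .drop_duplicates(subset=["snp"], keep="first")
             .reset_index(drop=True))
    table = pair_ld_table(pairs, hap_by_id)
    maf = {s.id: min(hap_by_id[s.id].mean(), 1 - hap_by_id[s.id].mean())
           for s in snps}
    table["snp_maf"] = table["snp"].map(maf)

    in_high_ld = snps_in_high_ld_with_sv(panel, max_distance=max_distance)
    zs = np.full(replicates, np.nan)
    for r in range(replicates):
        flags = simulate_gwas_labels(
            panel, fraction=fraction, ld_enrichment=ld_enrichment,
            seed=seed + 100_000 + r, in_high_ld=in_high_ld)
        gwas_ids = {s.id for s, f in zip(snps, flags) if f}
        table["gwas"] = table["snp"].isin(gwas_ids)
        usable = table.loc[table["fisher_p"].notna()]
        if not usable["gwas"].any() or usable["gwas"].all():
            continue
        res = gwas_matched_sampling(table, repetitions=repetitions,
                                    seed=seed + 200_000 + r)
        zs[r] = res.z
    return zs


# ---------------------------------------------------------------------------
# imputation evaluation

def imputation_study(seed: int, snp_density: float = 150.0,
                     scale: float = 1.0) -> dict:
    """End-to-end imputation evaluation on a seeded synthetic cohort.

    Two held-out samples are genotyped from simulated reads (depth 30),
    filtered to a gold standard, reduced to array-like SNP genotypes, and
    imputed from the family founders with the haplotype-copying imputer.
    Returns the cutoff-sweep table plus headline numbers.  ~2,050 SVs at
    ``scale=1``.
    """
    counts = {
        "DEL": {"short": 700, "mid": 500, "large": 400},
        "INS": {"short": 200},
        "MEI": {"large": 150},
        "COMPLEX_INDEL": {"short": 100},
    }
    counts = {t: {c: max(1, int(n * scale)) for c, n in cc.items()}
              for t, cc in counts.items()}
    cfg = SimulationConfig(
        n_families=15, n_unrelated=2, genome=(("1", 10_000_000),),
        snp_density=snp_density, sv_counts=counts, seed=seed)
    panel = simulate_truth_panel(cfg)
    targets = [s for s in panel.samples if s.startswith("ind")]
    target_idx = np.array([panel.sample_index(s) for s in targets])
    sv_idx = np.flatnonzero(~panel.is_snp)
    snp_idx = np.flatnonzero(panel.is_snp)
    svs = [panel.variants[i] for i in sv_idx]
    snps = [panel.variants[i] for i in snp_idx]

    gl = simulate_genotype_likelihoods(
        panel, depth=30.0, error_rate=0.02, seed=seed + 7,
        variant_indices=sv_idx, sample_indices=target_idx)
    gold = extract_gold_standard(regularize_gl(gl), svs)

    array_rows = np.arange(0, len(snps), 2)
    array_snps = [snps[i] for i in array_rows]
    target_snp_gt = panel.genotypes[snp_idx][array_rows][:, target_idx]
    founder_idx = [panel.sample_index(s) for s in panel.pedigree.founders
                   if not s.startswith("ind")]
    ref_snp = panel.haplotypes[snp_idx][array_rows][:, founder_idx, :]
    ref_snp = ref_snp.reshape(len(array_rows), -1)
    ref_sv = panel.haplotypes[sv_idx][:, founder_idx, :].reshape(
        len(sv_idx), -1)
    imputed, _ = haplotype_copy_imputer(
        target_snp_gt, array_snps, ref_snp, svs, ref_sv)
    curve = threshold_sweep(imputed, gold, svs)

    t = curve.table
    overall = {}
    for cut in (t["cutoff"].min(), 0.95, t["cutoff"].max()):
        sel = t.loc[t["cutoff"] == cut]
        n = sel["n_retained"].sum()
        overall[cut] = float((sel["discordance"] * sel["n_retained"]).sum()
                             / n) if n else float("nan")
    return {
        "panel": panel,
        "gold": gold,
        "imputed": imputed,
        "curve": curve,
        "n_svs": len(svs),
        "n_gold_calls": gold.n_retained,
        "overall_discordance_low_cutoff": overall[t["cutoff"].min()],
        "overall_discordance_095": overall[0.95],
        "overall_discordance_high_cutoff": overall[t["cutoff"].max()],
        "reductions": curve.reductions,
    }


# ---------------------------------------------------------------------------
# TDT and enrichment calibration

def tdt_null_study(seed: int, n_variants: int = 10_000,
                   n_trios: int = 300, alpha: float = 0.05) -> dict:
    """Type-I error of the TDT under fair per-parent transmission.

    Parents are Hardy-Weinberg draws at moderate allele frequencies; each
    child allele is a fair coin over the parent's two alleles, so no
    variant is in transmission disequilibrium.
    """
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.2, 0.5, size=n_variants)
    f_alleles = (rng.random((n_variants, n_trios, 2))
                 < maf[:, None, None]).astype(np.int8)
    m_alleles = (rng.random((n_variants, n_trios, 2))
                 < maf[:, None, None]).astype(np.int8)
    pick_f = rng.integers(0, 2, size=(n_variants, n_trios))
    pick_m = rng.integers(0, 2, size=(n_variants, n_trios))
    fa = f_alleles.sum(axis=2)
    mo = m_alleles.sum(axis=2)
    ch = (np.take_along_axis(f_alleles, pick_f[..., None], axis=2)[..., 0]
          + np.take_along_axis(m_alleles, pick_m[..., None], axis=2)[..., 0])

    samples = []
    peds = []
    for t in range(n_trios):
        fam = f"fam{t:04d}"
        samples += [f"{fam}_f", f"{fam}_m", f"{fam}_c"]
        peds += [PedigreeSample(f"{fam}_f", None, None, fam),
                 PedigreeSample(f"{fam}_m", None, None, fam),
                 PedigreeSample(f"{fam}_c", f"{fam}_f", f"{fam}_m", fam)]
    gt = np.empty((n_variants, 3 * n_trios), dtype=np.int8)
    gt[:, 0::3] = fa
    gt[:, 1::3] = mo
    gt[:, 2::3] = ch
    variants = [VariantRecord(chrom="1", start=1000 + 10 * i,
                              end=1000 + 10 * i + 5, vtype="DEL", length=5,
                              id=f"v{i:05d}") for i in range(n_variants)]
    result = tdt(gt, samples, variants, Pedigree(samples=peds), af=maf)
    ok = result["p"].notna()
    rate = float((result.loc[ok, "p"] < alpha).mean())
    return {"n_tested": int(ok.sum()), "alpha": alpha,
            "type1_rate": rate,
            "se": float(np.sqrt(alpha * (1 - alpha) / max(ok.sum(), 1)))}


def enrichment_sharp_null_study(seed: int, n_perm: int = 10_000) -> dict:
    """Permutation p-value at its sharp lower bound.

    The variants sit on a chromosome the annotation never touches while
    every random placement must land inside the annotated chromosome, so
    every null count exceeds the observed zero and the depletion p-value
    equals exactly 1/(n_perm + 1).
    """
    variants = [VariantRecord(chrom="2", start=100 * i, end=100 * i + 50,
                              vtype="DEL", length=50, id=f"d{i}")
                for i in range(1, 30)]
    annotation = {"1": [(0, 100_000)]}
    mask = {"1": [(0, 100_000)]}
    res = annotation_enrichment_test(variants, annotation, mask,
                                     n_perm=n_perm, side="depletion",
                                     seed=seed)
    return {"observed": res.observed, "p": res.p, "printed": res.printed,
            "expected_p": 1.0 / (n_perm + 1)}
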