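"""End-to-end orchestration: simulate -> merge -> spectrum -> ld -> imputation.

Every stage reads and writes files in standard formats (VCF/PED/TSV/BED/
JSON) under the run's output directory, so any stage can be replaced by
user-supplied data.  A manifest records every seed, parameter and per-stage
counter; re-running the same configuration reproduces every output byte for
byte (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import imputation as imp
from . import io_formats as io
from . import ld as ldmod
from . import merge as mergemod
from . import spectrum as spec
from .synthetic import (
    DEFAULT_CALLER_PROFILES,
    CallerProfile,
    SimulationConfig,
    TruthPanel,
    simulate_caller_callsets,
    simulate_genotype_likelihoods,
    simulate_gwas_labels,
    simulate_truth_panel,
)

logger = logging.getLogger("svpanel")

__all__ = ["RunConfig", "run_end_to_end"]


@dataclass
class RunConfig:
    """All tunables of an end-to-end run, at their standard defaults:
    50% reciprocal overlap with a 20 bp exact-match boundary for merging,
    1 Mb pairing distance and FDR q=0.05 with 1,000 matched repetitions for
    the LD stage, 10,000 permutations for annotation enrichment, the six GL
    cutoffs 0.33..0.999 with gold thresholds 0.999 (0.85 for MEIs), and 20
    MAF bins of width 0.025."""

    seed: int = 0
    output_dir: str = "svpanel_run"
    synthetic: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(n_unrelated=2))
    profiles: tuple[CallerProfile, ...] = DEFAULT_CALLER_PROFILES
    merge_min_ro: float = 0.5
    fdr_q: float = 0.05
    enrichment_permutations: int = 10_000
    ld_max_distance: int = 1_000_000
    ld_repetitions: int = 1000
    tag_r2_min: float = 0.8
    tag_maf_min: float = 0.04
    gwas_fraction: float = 0.05
    gwas_ld_enrichment: float = 1.0
    gl_cutoffs: tuple[float, ...] = imp.DEFAULT_GL_CUTOFFS
    gold_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(imp.DEFAULT_GOLD_THRESHOLDS))
    gold_depth: float = 30.0
    gl_error_rate: float = 0.02
    window_snps: int = 12
    imputer_mismatch_rate: float = 0.05
    maf_bin_width: float = 0.025
    array_snp_stride: int = 2
    report_cutoff: float = 0.95

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d:
            d["synthetic"] = SimulationConfig(**d["synthetic"])
        if "profiles" in d:
            d["profiles"] = tuple(CallerProfile(**p) for p in d["profiles"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**d)


def _family_and_target_samples(panel: TruthPanel):
    in_family = {s.sample for s in panel.pedigree.samples
                 if s.family.startswith("fam")}
    fam = [s for s in panel.samples if s in in_family]
    targets = [s for s in panel.samples if s not in in_family]
    return fam, targets


def _synthetic_annotation(panel: TruthPanel, rng: np.random.Generator,
                          coverage: float = 0.03, exon_bp: int = 150):
    """Exon-like annotation intervals covering ~``coverage`` of each
    chromosome, plus a whole-genome mappability mask."""
    annotation: dict[str, list[tuple[int, int]]] = {}
    mask: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in panel.config.genome:
        n = max(1, int(coverage * length / exon_bp))
        starts = np.sort(rng.choice(length - exon_bp, size=n, replace=False))
        annotation[chrom] = [(int(s), int(s) + exon_bp) for s in starts]
        mask[chrom] = [(0, int(length))]
    return annotation, mask


def _stage_simulate(config: RunConfig, outdir: Path) -> dict:
    panel = simulate_truth_panel(replace(config.synthetic, seed=config.seed))
    fam, targets = _family_and_target_samples(panel)
    fam_idx = [panel.sample_index(s) for s in fam]
    contigs = dict(panel.config.genome)

    d = outdir / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    io.write_sv_vcf(
        panel.variants, d / "panel.vcf", samples=fam,
        haplotypes=panel.haplotypes[:, fam_idx, :],
        extra_info=[{"AF": round(float(a), 6)} for a in panel.af],
        contigs=contigs)
    io.write_pedigree(panel.pedigree, d / "cohort.ped")

    callsets = simulate_caller_callsets(panel, config.profiles,
                                        seed=config.seed + 1)
    (d / "callers").mkdir(exist_ok=True)
    for name, calls in callsets.items():
        prof = next(p for p in config.profiles if p.name == name)
        io.write_sv_vcf(calls, d / "callers" / f"{name}.vcf",
                        caller=name, strategy=prof.strategy, contigs=contigs)

    gwas_flags = simulate_gwas_labels(
        panel, fraction=config.gwas_fraction,
        ld_enrichment=config.gwas_ld_enrichment, seed=config.seed + 3)
    snps = [v for v in panel.variants if v.vtype == "SNP"]
    catalog = pd.DataFrame({
        "snp": [s.id for s, f in zip(snps, gwas_flags) if f],
        "chrom": [s.chrom for s, f in zip(snps, gwas_flags) if f],
        "pos": [s.start for s, f in zip(snps, gwas_flags) if f],
        "trait": "simulated_trait",
    })
    io.write_gwas_catalog(catalog, d / "gwas_catalog.tsv")

    rng = np.random.default_rng(config.seed + 4)
    annotation, mask = _synthetic_annotation(panel, rng)
    io.write_bed(annotation, d / "annotation.bed")
    io.write_bed(mask, d / "mask.bed")

    counters = {
        "n_samples": len(panel.samples),
        "n_families": config.synthetic.n_families,
        "n_target_samples": len(targets),
        "n_variants": panel.n_variants,
        "n_snps": len(snps),
        "n_svs": int((~panel.is_snp).sum()),
        "n_gwas_snps": int(np.asarray(gwas_flags).sum()),
        "calls_per_caller": {k: len(v) for k, v in callsets.items()},
    }
    logger.info("simulate: %d variants, %d samples", panel.n_variants,
                len(panel.samples))
    return {"panel": panel, "callsets": callsets, "gwas_flags": gwas_flags,
            "annotation": annotation, "mask": mask, "counters": counters}


def _stage_merge(config: RunConfig, outdir: Path, sim: dict) -> dict:
    panel: TruthPanel = sim["panel"]
    all_calls = [c for calls in sim["callsets"].values() for c in calls]
    consensus = mergemod.merge_callsets(all_calls, min_ro=config.merge_min_ro)
    d = outdir / "merge"
    d.mkdir(parents=True, exist_ok=True)
    io.write_sv_vcf(
        consensus, d / "consensus.vcf",
        extra_info=[{
            "SUPP": len(c.supporting_calls),
            "STRATEGIES": ",".join(sorted({s for _, s in c.supporting_calls})),
            "BOUNDARY_SOURCE": c.boundary_source,
        } for c in consensus],
        contigs=dict(panel.config.genome))

    # recall against the carried truth SVs (diagnostic: the truth is known)
    carried = panel.genotypes.sum(axis=1) > 0
    truth = [v for v, keep, s in zip(panel.variants, carried, ~panel.is_snp)
             if keep and s]
    recovered = 0
    cons_small = {(c.chrom, c.start, c.end, c.vtype, c.length)
                  for c in consensus if c.length <= 20}
    cons_large = [c for c in consensus if c.length > 20]
    for v in truth:
        if v.length <= 20:
            recovered += (v.chrom, v.start, v.end, v.vtype, v.length) in cons_small
        else:
            recovered += any(mergemod.calls_linked(v, c, config.merge_min_ro)
                             for c in cons_large)
    counters = {
        "calls_in": len(all_calls),
        "consensus_out": len(consensus),
        "truth_carried_svs": len(truth),
        "truth_recovered": int(recovered),
        "recall_pct": round(100 * recovered / len(truth), 2) if truth else None,
    }
    logger.info("merge: %d calls -> %d consensus", len(all_calls),
                len(consensus))
    return {"consensus": consensus, "counters": counters}


def _stage_spectrum(config: RunConfig, outdir: Path, sim: dict) -> dict:
    panel: TruthPanel = sim["panel"]
    fam, _ = _family_and_target_samples(panel)
    fam_idx = [panel.sample_index(s) for s in fam]
    gt = panel.genotypes[:, fam_idx]
    d = outdir / "spectrum"
    d.mkdir(parents=True, exist_ok=True)

    af_table = spec.compute_allele_frequencies(
        gt, fam, panel.variants, pedigree=panel.pedigree)
    sv_table = af_table.loc[[v.vtype != "SNP" for v in panel.variants]]
    sv_table, boundaries = spec.assign_quartiles(sv_table.copy())

    svs = [v for v in panel.variants if v.vtype != "SNP"]
    rng = np.random.default_rng(config.seed + 5)
    known_idx = set(np.flatnonzero(rng.random(len(svs)) < 0.6))
    known_sets: dict[str, list] = {}
    for i in known_idx:
        known_sets.setdefault(svs[i].vtype, []).append(svs[i])
    novel = spec.annotate_novelty(svs, known_sets)
    sv_table = sv_table.assign(novel=novel)
    sv_table.to_csv(d / "af_table.tsv", sep="\t", index=False,
                    float_format="%.6g")

    dels = [v for v in svs if v.vtype == "DEL"]
    enr = spec.annotation_enrichment_test(
        dels, sim["annotation"], sim["mask"],
        n_perm=config.enrichment_permutations, side="depletion",
        seed=config.seed + 6)

    load = spec.haplotype_load(panel.variants,
                               panel.haplotypes[:, fam_idx, :], fam)
    load.per_sample.to_csv(d / "load_per_sample.tsv", sep="\t",
                           float_format="%.6g")

    fam_ped = panel.subset_samples(fam).pedigree
    sv_idx = np.flatnonzero(~panel.is_snp)
    tdt_table = spec.tdt(gt[sv_idx], fam, svs, fam_ped,
                         af=panel.af[sv_idx])
    tdt_table.to_csv(d / "tdt.tsv", sep="\t", index=False,
                     float_format="%.6g")
    tdt_ok = tdt_table["p"].notna()
    tdt_hits = int(np.sum(
        ldmod.bh_fdr(tdt_table.loc[tdt_ok, "p"], config.fdr_q))) \
        if tdt_ok.any() else 0

    summary = {
        "quartile_boundaries": {k: list(v) for k, v in boundaries.items()},
        "novel_fraction": round(float(np.mean(novel)), 4),
        "exonic_deletions_observed": enr.observed,
        "exonic_depletion_p": enr.p,
        "exonic_depletion_printed": enr.printed,
        "load": load.to_dict(),
        "tdt_significant": tdt_hits,
    }
    (d / "summary.json").write_text(json.dumps(summary, indent=2,
                                               sort_keys=True))
    logger.info("spectrum: %d SVs, exonic depletion %s", len(svs),
                enr.printed)
    return {"af_table": af_table, "sv_table": sv_table, "enrichment": enr,
            "load": load, "tdt": tdt_table, "counters": {
                "n_svs": len(svs),
                "tdt_significant": tdt_hits,
                "novel_fraction": summary["novel_fraction"]}}


def _stage_ld(config: RunConfig, outdir: Path, sim: dict,
              af_table: pd.DataFrame) -> dict:
    panel: TruthPanel = sim["panel"]
    d = outdir / "ld"
    d.mkdir(parents=True, exist_ok=True)
    fhap = panel.founder_haplotype_matrix()
    hap_by_id = {v.id: fhap[i] for i, v in enumerate(panel.variants)}

    snps = [v for v in panel.variants if v.vtype == "SNP"]
    snp_df = pd.DataFrame({"snp": [s.id for s in snps],
                           "chrom": [s.chrom for s in snps],
                           "pos": [s.start for s in snps]})
    dels = [v for v in panel.variants if v.vtype == "DEL"]
    pairs = ldmod.enumerate_pairs(snp_df, dels,
                                  max_distance=config.ld_max_distance)
    gwas_snps = {s.id for s, f in zip(snps, sim["gwas_flags"]) if f}
    table = ldmod.pair_ld_table(pairs, hap_by_id, q=config.fdr_q,
                                gwas_snps=gwas_snps)
    maf_by_snp = dict(zip(af_table["variant"], af_table["maf"]))
    table["snp_maf"] = table["snp"].map(maf_by_snp)
    table.to_csv(d / "pairs.tsv", sep="\t", index=False,
                 float_format="%.6g")

    result = None
    usable = table.loc[table["fisher_p"].notna()]
    if usable["gwas"].any() and (~usable["gwas"]).any():
        result = ldmod.gwas_matched_sampling(
            table, repetitions=config.ld_repetitions, q=config.fdr_q,
            seed=config.seed + 7)
        (d / "matched_sampling.json").write_text(
            json.dumps(result.to_dict(), indent=2, sort_keys=True))

    common = [v for v in panel.variants
              if v.vtype in ("DEL", "MEI") and v.id in hap_by_id]
    tags = ldmod.tag_snp_table(common, snp_df, hap_by_id,
                               r2_min=config.tag_r2_min,
                               maf_min=config.tag_maf_min,
                               max_distance=config.ld_max_distance)
    tags.to_csv(d / "tag_snps.tsv", sep="\t", index=False,
                float_format="%.6g")
    counters = {
        "n_pairs": len(table),
        "n_gwas_pairs": int(table["gwas"].sum()),
        "significant_pct": round(100 * float(table["significant"].mean()), 2)
        if len(table) else None,
        "n_tag_snp_pairs": len(tags),
    }
    if result is not None:
        counters["matched_sampling_z"] = round(result.z, 3)
    logger.info("ld: %d pairs, %d tag-SNP pairs", len(table), len(tags))
    return {"pairs": table, "matched": result, "tags": tags,
            "counters": counters}


def _stage_imputation(config: RunConfig, outdir: Path, sim: dict) -> dict:
    panel: TruthPanel = sim["panel"]
    fam, targets = _family_and_target_samples(panel)
    d = outdir / "imputation"
    d.mkdir(parents=True, exist_ok=True)
    if not targets:
        (d / "summary.json").write_text(json.dumps(
            {"skipped": "no held-out target samples configured"}))
        return {"counters": {"skipped": True}}

    target_idx = np.array([panel.sample_index(s) for s in targets])
    sv_idx = np.flatnonzero(~panel.is_snp)
    snp_idx = np.flatnonzero(panel.is_snp)
    svs = [panel.variants[i] for i in sv_idx]
    snps = [panel.variants[i] for i in snp_idx]

    # step 1-2: read-based genotyping of the targets, gold-standard filter
    gl = simulate_genotype_likelihoods(
        panel, depth=config.gold_depth, error_rate=config.gl_error_rate,
        seed=config.seed + 8, variant_indices=sv_idx,
        sample_indices=target_idx)
    gl = imp.regularize_gl(gl)
    gold = imp.extract_gold_standard(gl, svs, config.gold_thresholds)

    # step 3: array-like SNP genotypes for the targets
    array_rows = np.arange(0, len(snps), config.array_snp_stride)
    array_snps = [snps[i] for i in array_rows]
    target_snp_gt = panel.genotypes[snp_idx][array_rows][:, target_idx]

    # step 4: haplotype-copying imputation from the family reference panel
    founder_idx = [panel.sample_index(s) for s in panel.pedigree.founders
                   if s in fam]
    ref_snp_hap = panel.haplotypes[snp_idx][array_rows][:, founder_idx, :]
    ref_snp_hap = ref_snp_hap.reshape(len(array_rows), -1)
    ref_sv_hap = panel.haplotypes[sv_idx][:, founder_idx, :]
    ref_sv_hap = ref_sv_hap.reshape(len(sv_idx), -1)
    imputed, no_flank = imp.haplotype_copy_imputer(
        target_snp_gt, array_snps, ref_snp_hap, svs, ref_sv_hap,
        window_snps=config.window_snps,
        mismatch_rate=config.imputer_mismatch_rate)

    # step 5: cutoff sweep and MAF stratification
    curve = imp.threshold_sweep(imputed, gold, svs, config.gl_cutoffs)
    curve.table.to_csv(d / "sweep.tsv", sep="\t", index=False,
                       float_format="%.6g")
    panel_af = ref_sv_hap.mean(axis=1)
    strata = imp.stratify_by_maf(imputed, gold, svs, panel_af,
                                 cutoff=config.report_cutoff,
                                 bin_width=config.maf_bin_width)
    strata.to_csv(d / "maf_strata.tsv", sep="\t", index=False,
                  float_format="%.6g")
    strata_rare = imp.stratify_by_maf(imputed, gold, svs, panel_af,
                                      cutoff=config.report_cutoff,
                                      bin_width=config.maf_bin_width,
                                      rare_allele_only=True)
    strata_rare.to_csv(d / "maf_strata_rare.tsv", sep="\t", index=False,
                       float_format="%.6g")

    at_report = curve.table.loc[curve.table["cutoff"] == config.report_cutoff]
    summary = {
        "gold_counts_per_class": gold.counts_per_class,
        "n_gold_calls": gold.n_retained,
        "reduction_pct_first_to_last_cutoff": curve.reductions,
        "discordance_at_report_cutoff": {
            r["vclass"]: round(float(r["discordance"]), 5)
            for _, r in at_report.iterrows()
            if np.isfinite(r["discordance"])},
        "n_svs_without_flanking_snps": int(no_flank.sum()),
        "flags": curve.flags,
    }
    (d / "summary.json").write_text(json.dumps(summary, indent=2,
                                               sort_keys=True))
    logger.info("imputation: %d gold calls, reductions %s",
                gold.n_retained, curve.reductions)
    return {"gold": gold, "imputed": imputed, "curve": curve,
            "strata": strata, "counters": {
                "n_gold_calls": gold.n_retained,
                "reductions": curve.reductions}}


def run_end_to_end(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk).

    Any stage failure aborts the run with the stage name in the exception.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": _config_to_dict(config),
        "stages": {},
    }
    try:
        sim = _stage_simulate(config, outdir)
        manifest["stages"]["simulate"] = sim["counters"]
        merged = _stage_merge(config, outdir, sim)
        manifest["stages"]["merge"] = merged["counters"]
        spect = _stage_spectrum(config, outdir, sim)
        manifest["stages"]["spectrum"] = spect["counters"]
        ld_out = _stage_ld(config, outdir, sim, spect["af_table"])
        manifest["stages"]["ld"] = ld_out["counters"]
        imp_out = _stage_imputation(config, outdir, sim)
        manifest["stages"]["imputation"] = imp_out["counters"]
    except Exception as exc:
        stage = len(manifest["stages"])
        names = ["simulate", "merge", "spectrum", "ld", "imputation"]
        raise RuntimeError(
            f"pipeline failed in stage "
            f"{names[min(stage, len(names) - 1)]}: {exc}") from exc
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def _config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["profiles"] = [dataclasses.asdict(p) for p in config.profiles]
    return d
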