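"""SNP-SV linkage disequilibrium, FDR control, and the matched-sampling null.

All LD statistics are computed directly from phased haplotypes (no EM
estimation): for two biallelic loci with haplotype frequencies pA, pB and
joint frequency pAB,

    D  = pAB - pA * pB
    r2 = D^2 / (pA (1 - pA) pB (1 - pB))

Significance per pair comes from a two-sided Fisher's exact test on the
2x2 haplotype-count table, with Benjamini-Hochberg FDR control across a
pair set.  The matched-sampling procedure compares the significant fraction
among GWAS SNP-SV pairs against repeated draws of non-GWAS pairs matched on
potential confounders (by default SNP minor-allele frequency and SNP-SV
distance), reporting the observed fraction, the null mean and s.d., and a
z-score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import VariantRecord

__all__ = [
    "MonomorphicLocusError",
    "MatchedSamplingResult",
    "pairwise_r2",
    "r2_against_many",
    "fisher_ld_test",
    "bh_fdr",
    "enumerate_pairs",
    "pair_ld_table",
    "default_matcher",
    "gwas_matched_sampling",
    "tag_snp_table",
]


class MonomorphicLocusError(ValueError):
    """LD is undefined (not zero) when either locus is monomorphic."""


def _check_pair(hapA, hapB) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(hapA, dtype=float)
    b = np.asarray(hapB, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size != b.size:
        raise ValueError("haplotype vectors must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least two haplotypes")
    if not (set(np.unique(a)) <= {0.0, 1.0} and set(np.unique(b)) <= {0.0, 1.0}):
        raise ValueError("haplotype vectors must be binary")
    if a.min() == a.max() or b.min() == b.max():
        raise MonomorphicLocusError("monomorphic locus: LD undefined")
    return a, b


def pairwise_r2(hapA: Sequence[int], hapB: Sequence[int]) -> tuple[float, float]:
    """(r2, D) between two loci from phased binary haplotype vectors."""
    a, b = _check_pair(hapA, hapB)
    pA = a.mean()
    pB = b.mean()
    pAB = (a * b).mean()
    D = pAB - pA * pB
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return float(r2), float(D)


def r2_against_many(hap: np.ndarray, haps: np.ndarray) -> np.ndarray:
    """r2 of one locus against each row of ``haps``; NaN where monomorphic."""
    a = np.asarray(hap, dtype=float)
    Y = np.asarray(haps, dtype=float)
    pA = a.mean()
    pB = Y.mean(axis=1)
    pAB = Y @ a / a.size
    with np.errstate(divide="ignore", invalid="ignore"):
        D = pAB - pA * pB
        denom = pA * (1 - pA) * pB * (1 - pB)
        r2 = np.where(denom > 0, D * D / denom, np.nan)
    if pA in (0.0, 1.0):
        r2[:] = np.nan
    return r2


def haplotype_table(hapA, hapB) -> np.ndarray:
    """2x2 haplotype-count table [[n11, n10], [n01, n00]]."""
    a = np.asarray(hapA, dtype=int)
    b = np.asarray(hapB, dtype=int)
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    return np.array([[n11, n10], [n01, n00]])


def fisher_ld_test(hapA: Sequence[int], hapB: Sequence[int]) -> float:
    """Two-sided Fisher's exact test p-value on the haplotype-count table."""
    _check_pair(hapA, hapB)
    table = haplotype_table(hapA, hapB)
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``q``.

    Flags are a function of the multiset of p-values, hence stable under
    permutation of the input.
    """
    p = np.asarray(pvalues, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def interval_distance(pos: int, start: int, end: int) -> int:
    """Minimum distance from a point to a half-open interval (0 inside)."""
    if end <= start:  # anchored insertion
        return abs(pos - start)
    return max(start - pos, pos - (end - 1), 0)


def enumerate_pairs(
    snps: pd.DataFrame,
    svs: Sequence[VariantRecord],
    max_distance: int = 1_000_000,
) -> pd.DataFrame:
    """All same-chromosome SNP-SV pairs within ``max_distance``.

    ``snps`` needs columns ``snp`` (id), ``chrom`` and ``pos`` (internal
    0-based).  Returns one row per candidate pair with the point-to-interval
    distance.
    """
    rows = []
    snps_sorted = snps.sort_values(["chrom", "pos"], kind="mergesort")
    by_chrom = {c: g for c, g in snps_sorted.groupby("chrom", sort=False)}
    for sv in svs:
        g = by_chrom.get(sv.chrom)
        if g is None:
            continue
        pos = g["pos"].to_numpy()
        lo = np.searchsorted(pos, sv.start - max_distance, side="left")
        hi = np.searchsorted(pos, max(sv.end, sv.start + 1) + max_distance,
                             side="right")
        for k in range(lo, hi):
            d = interval_distance(int(pos[k]), sv.start, sv.end)
            if d <= max_distance:
                rows.append((g["snp"].iloc[k], sv.id, d))
    return pd.DataFrame(rows, columns=["snp", "sv", "distance"])


def pair_ld_table(
    pairs: pd.DataFrame,
    haplotypes: dict[str, np.ndarray],
    q: float = 0.05,
    gwas_snps: set[str] | None = None,
) -> pd.DataFrame:
    """Per-pair LD statistics, Fisher p-values and BH significance flags.

    ``haplotypes`` maps variant id to its phased binary allele vector (one
    entry per haplotype, identically ordered across variants).  Pairs with
    a monomorphic locus get NaN statistics, are excluded from FDR control
    and are never flagged significant.
    """
    out = pairs.copy()
    r2s, Ds, ps, mono = [], [], [], []
    for snp_id, sv_id in zip(out["snp"], out["sv"]):
        a = haplotypes[snp_id]
        b = haplotypes[sv_id]
        try:
            r2, D = pairwise_r2(a, b)
            p = fisher_ld_test(a, b)
            r2s.append(r2)
            Ds.append(D)
            ps.append(p)
            mono.append(False)
        except MonomorphicLocusError:
            r2s.append(np.nan)
            Ds.append(np.nan)
            ps.append(np.nan)
            mono.append(True)
    out["r2"] = r2s
    out["D"] = Ds
    out["fisher_p"] = ps
    out["monomorphic"] = mono
    out["significant"] = False
    ok = ~out["monomorphic"].to_numpy()
    if ok.any():
        out.loc[ok, "significant"] = bh_fdr(out.loc[ok, "fisher_p"], q)
    out["gwas"] = out["snp"].isin(gwas_snps or set())
    return out


@dataclass
class MatchedSamplingResult:
    """Outcome of the matched-resampling GWAS null."""

    observed_fraction: float
    null_fractions: list[float]
    null_mean: float
    null_sd: float
    z: float
    n_gwas_pairs: int
    n_candidate_pairs: int
    fallback_count: int = 0
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "observed_fraction": self.observed_fraction,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "n_gwas_pairs": self.n_gwas_pairs,
            "n_candidate_pairs": self.n_candidate_pairs,
            "fallback_count": self.fallback_count,
            "repetitions": len(self.null_fractions),
            "flags": list(self.flags),
        }


def default_matcher(pairs: pd.DataFrame, maf_bin: float = 0.05,
                    distance_bin: int = 100_000) -> np.ndarray:
    """Default confounder bins: SNP MAF (width 0.05) x distance (100 kb).

    Needs a ``snp_maf`` column; the exact confounder list is a pluggable
    choice, so any callable mapping the pair table to bin labels can stand
    in for this one.
    """
    maf = np.minimum(pairs["snp_maf"].to_numpy(dtype=float), 0.5 - 1e-12)
    dist = pairs["distance"].to_numpy(dtype=float)
    return np.stack([np.floor(maf / maf_bin),
                     np.floor(dist / distance_bin)], axis=1)


def gwas_matched_sampling(
    pairs: pd.DataFrame,
    repetitions: int = 1000,
    q: float = 0.05,
    matcher: Callable[[pd.DataFrame], np.ndarray] = default_matcher,
    seed: int | None = None,
) -> MatchedSamplingResult:
    """Matched-resampling test of GWAS-pair LD enrichment.

    The observed statistic is the share of GWAS SNP-SV pairs significant
    after Fisher + BH.  Each repetition draws, for every GWAS pair, one
    non-GWAS pair from the same confounder bin (without replacement within
    the repetition, with replacement across repetitions), reruns the
    identical Fisher + BH analysis on the matched set and records its
    significant share.  An empty confounder bin falls back to the nearest
    non-empty bin; fallbacks are counted.
    """
    rng = np.random.default_rng(seed)
    usable = pairs.loc[np.isfinite(pairs["fisher_p"].to_numpy(dtype=float))]
    gwas_mask = usable["gwas"].to_numpy(dtype=bool)
    if gwas_mask.sum() == 0 or (~gwas_mask).sum() == 0:
        raise ValueError("need both GWAS and non-GWAS pairs")
    p = usable["fisher_p"].to_numpy(dtype=float)
    bins = np.asarray(matcher(usable), dtype=float)
    flags: list[str] = []

    observed = float(np.mean(bh_fdr(p[gwas_mask], q)))

    # candidate pools per bin (non-GWAS only)
    bin_keys = [tuple(b) for b in bins]
    pool: dict[tuple, np.ndarray] = {}
    cand_idx = np.flatnonzero(~gwas_mask)
    for i in cand_idx:
        pool.setdefault(bin_keys[i], [])
    for i in cand_idx:
        pool[bin_keys[i]].append(i)
    pool = {k: np.asarray(v) for k, v in pool.items()}
    pool_keys = np.array(list(pool.keys()), dtype=float)

    # demand per bin from the GWAS pairs
    demand: dict[tuple, int] = {}
    for i in np.flatnonzero(gwas_mask):
        demand[bin_keys[i]] = demand.get(bin_keys[i], 0) + 1

    def nearest_pools(key: tuple) -> np.ndarray:
        d = np.abs(pool_keys - np.asarray(key)).sum(axis=1)
        return np.argsort(d, kind="stable")

    fallback_count = 0
    null_fractions: list[float] = []
    for _ in range(repetitions):
        available = {k: rng.permutation(v) for k, v in pool.items()}
        taken: list[np.ndarray] = []
        for key in sorted(demand):
            need = demand[key]
            got = []
            if key in available and available[key].size:
                take = min(need, available[key].size)
                got.append(available[key][:take])
                available[key] = available[key][take:]
                need -= take
            if need > 0:
                fallback_count += need
                order = nearest_pools(key)
                keys_list = list(pool.keys())
                for oi in order:
                    k2 = keys_list[oi]
                    if available[k2].size == 0:
                        continue
                    take = min(need, available[k2].size)
                    got.append(available[k2][:take])
                    available[k2] = available[k2][take:]
                    need -= take
                    if need == 0:
                        break
            taken.append(np.concatenate(got) if got else np.array([], int))
        sample = np.concatenate(taken)
        null_fractions.append(float(np.mean(bh_fdr(p[sample], q))))

    null = np.asarray(null_fractions)
    null_mean = float(null.mean())
    if repetitions < 2:
        null_sd = float("nan")
        z = float("nan")
        flags.append("null_sd undefined with fewer than 2 repetitions")
    else:
        null_sd = float(null.std(ddof=1))
        if null_sd == 0:
            z = float("nan")
            flags.append("null sd is zero; z undefined")
        else:
            z = (observed - null_mean) / null_sd
    return MatchedSamplingResult(
        observed_fraction=observed, null_fractions=list(null_fractions),
        null_mean=null_mean, null_sd=null_sd, z=z,
        n_gwas_pairs=int(gwas_mask.sum()),
        n_candidate_pairs=int((~gwas_mask).sum()),
        fallback_count=fallback_count, flags=flags)


def tag_snp_table(
    svs: Sequence[VariantRecord],
    snps: pd.DataFrame,
    haplotypes: dict[str, np.ndarray],
    r2_min: float = 0.8,
    maf_min: float = 0.04,
    max_distance: int = 1_000_000,
) -> pd.DataFrame:
    """Tag-SNP candidates: high-LD SNPs for every sufficiently common SV.

    For each SV with MAF above ``maf_min``, lists all SNPs within
    ``max_distance`` whose r2 with the SV is at least ``r2_min``, sorted by
    descending r2 within SV.
    """
    rows = []
    for sv in svs:
        hap_sv = np.asarray(haplotypes[sv.id])
        af = hap_sv.mean()
        maf = min(af, 1 - af)
        if maf <= maf_min:
            continue
        cand = enumerate_pairs(snps, [sv], max_distance)
        for snp_id in cand["snp"]:
            try:
                r2, _ = pairwise_r2(haplotypes[snp_id], hap_sv)
            except MonomorphicLocusError:
                continue
            if r2 >= r2_min:
                d = int(cand.loc[cand["snp"] == snp_id, "distance"].iloc[0])
                rows.append((sv.id, snp_id, d, r2, maf))
    df = pd.DataFrame(rows, columns=["sv", "snp", "distance", "r2", "sv_maf"])
    return df.sort_values(["sv", "r2"], ascending=[True, False],
                          kind="mergesort").reset_index(drop=True)
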