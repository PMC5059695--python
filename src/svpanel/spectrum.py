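"""Allele-frequency, novelty, enrichment, load and transmission analyses.

Operates on a genotyped (optionally phased) consensus panel.  Allele
frequencies are computed over founders only by default, which avoids
double-counting transmitted alleles in a family cohort; an all-samples mode
is available.  Size classes partition lengths into short (1-20 bp),
mid (21-100 bp) and large (>100 bp) with no gaps or overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .merge import calls_linked
from .records import Pedigree, VariantRecord

__all__ = [
    "compute_allele_frequencies",
    "stratify_quartiles",
    "assign_quartiles",
    "annotate_novelty",
    "EnrichmentResult",
    "annotation_enrichment_test",
    "LoadSummary",
    "haplotype_load",
    "tdt",
]

#: variant classes counted as (simple or complex) indels in load summaries;
#: everything else except SNPs counts as a structural variant.
def _is_indel(v: VariantRecord) -> bool:
    if v.vtype == "COMPLEX_INDEL":
        return True
    return v.vtype in ("DEL", "INS") and v.length <= 20


def compute_allele_frequencies(
    genotypes: np.ndarray,
    samples: Sequence[str],
    variants: Sequence[VariantRecord],
    pedigree: Pedigree | None = None,
    founders_only: bool = True,
) -> pd.DataFrame:
    """Per-variant allele frequencies from hard genotype calls.

    AF is the alternate-allele count divided by twice the number of
    non-missing genotyped individuals (founders only by default; pass
    ``founders_only=False`` to use every sample).  Missing genotypes
    (encoded -1) are excluded from the denominator.  Variants with no
    called genotype get ``af_defined=False`` and NaN frequencies.
    """
    gt = np.asarray(genotypes)
    if founders_only:
        if pedigree is None:
            raise ValueError("founders_only requires a pedigree")
        keep = [i for i, s in enumerate(samples)
                if pedigree.is_founder(s)]
        gt = gt[:, keep]
    called = gt >= 0
    n_called = called.sum(axis=1)
    alt = np.where(called, gt, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(n_called > 0, alt / (2 * n_called), np.nan)
    maf = np.minimum(af, 1 - af)
    return pd.DataFrame({
        "variant": [v.id for v in variants],
        "vtype": [v.vtype for v in variants],
        "size_class": [v.size_class for v in variants],
        "length": [v.length for v in variants],
        "af": af,
        "maf": maf,
        "af_defined": n_called > 0,
        "n_called": n_called,
    })


def stratify_quartiles(mafs: Sequence[float]) -> tuple[tuple[float, float, float],
                                                       np.ndarray]:
    """Quartile boundaries and assignments for one variant class.

    Boundaries are the empirical 25/50/75 percentiles of MAF; values tied
    with a boundary fall into the lower quartile.  Returns
    ``((q25, q50, q75), quartile)`` with quartiles coded 1..4, so results
    like "first quartile means MAF below the reported q25" are reproducible
    on the data at hand.
    """
    x = np.asarray(mafs, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 variants to form quartiles")
    if np.any(~np.isfinite(x)):
        raise ValueError("MAFs must be finite")
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    quart = np.full(x.size, 4, dtype=int)
    quart[x <= q75] = 3
    quart[x <= q50] = 2
    quart[x <= q25] = 1
    return (float(q25), float(q50), float(q75)), quart


def assign_quartiles(af_table: pd.DataFrame,
                     group_col: str = "vtype") -> tuple[pd.DataFrame, dict]:
    """Add a ``quartile`` column per variant class; returns boundaries too.

    Classes with fewer than 4 variants with defined MAF keep quartile 0
    (unassigned).  Quartiles are per class, not global.
    """
    out = af_table.copy()
    out["quartile"] = 0
    boundaries: dict[str, tuple[float, float, float]] = {}
    for key, grp in out.groupby(group_col, sort=True):
        ok = grp.index[grp["af_defined"] & np.isfinite(grp["maf"])]
        if ok.size < 4:
            continue
        b, quart = stratify_quartiles(out.loc[ok, "maf"].to_numpy())
        boundaries[key] = b
        out.loc[ok, "quartile"] = quart
    return out, boundaries


def annotate_novelty(
    variants: Sequence[VariantRecord],
    known_sets: dict[str, Sequence[VariantRecord]],
) -> np.ndarray:
    """``novel`` flag per variant against same-type known call collections.

    A variant is known when any same-type known record matches it: exact
    coordinates for events of 20 bp and smaller, 50% reciprocal overlap
    (anchor-distance rule for insertions) for larger events.
    """
    by_chrom: dict[tuple[str, str], list[VariantRecord]] = {}
    for vtype, recs in known_sets.items():
        for r in recs:
            by_chrom.setdefault((vtype, r.chrom), []).append(r)
    for lst in by_chrom.values():
        lst.sort(key=lambda r: r.start)

    novel = np.ones(len(variants), dtype=bool)
    for i, v in enumerate(variants):
        cands = by_chrom.get((v.vtype, v.chrom), ())
        for k in cands:
            if v.length <= 20:
                if (k.start, k.end, k.length) == (v.start, v.end, v.length):
                    novel[i] = False
                    break
            elif k.length > 20 and calls_linked(v, k):
                novel[i] = False
                break
    return novel


@dataclass
class EnrichmentResult:
    observed: int
    n_perm: int
    side: str
    p: float
    p_depletion: float
    p_enrichment: float
    null_mean: float
    null_sd: float

    @property
    def printed(self) -> str:
        """Reporting convention: p below 1/n_perm prints as an inequality."""
        if self.p < 1.0 / self.n_perm:
            return f"P<{1.0 / self.n_perm:g}"
        return f"P={self.p:.4g}"


def _merge_intervals(ivals):
    merged = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _overlaps_annotation(chrom_arrays, chroms, starts, ends):
    """Vectorized: does [start, end) on chrom intersect the annotation?"""
    out = np.zeros(starts.size, dtype=bool)
    for c in np.unique(chroms):
        arr = chrom_arrays.get(c)
        sel = chroms == c
        if arr is None:
            continue
        a_starts, a_ends = arr
        lo = np.searchsorted(a_starts, ends[sel], side="left")
        hi = np.searchsorted(a_ends, starts[sel], side="right")
        out[sel] = lo > hi
    return out


def annotation_enrichment_test(
    variants: Sequence[VariantRecord],
    annotation: dict[str, list[tuple[int, int]]],
    mask: dict[str, list[tuple[int, int]]],
    n_perm: int = 10_000,
    side: str = "depletion",
    seed: int | None = None,
    mode: str = "placement",
    universe: Sequence[VariantRecord] | None = None,
) -> EnrichmentResult:
    """Permutation test of annotation overlap against size-matched nulls.

    The statistic is the number of variants intersecting the annotation.
    In ``placement`` mode the null redraws, ``n_perm`` times, one
    length-matched interval per variant uniformly within the mappable-region
    mask; in ``resample`` mode each null set draws size-class-matched
    variants from ``universe`` instead.  The empirical p-value uses the
    add-one rule ``(1 + #extreme) / (n_perm + 1)`` in the stated direction.
    """
    if side not in ("depletion", "enrichment"):
        raise ValueError("side must be 'depletion' or 'enrichment'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    segs = [(c, s, e) for c, ivals in mask.items()
            for s, e in _merge_intervals(ivals)]
    if not segs:
        raise ValueError("empty mappable-region mask")
    rng = np.random.default_rng(seed)

    ann_arrays = {}
    for c, ivals in annotation.items():
        merged = _merge_intervals(ivals)
        if merged:
            ann_arrays[c] = (np.array([s for s, _ in merged]),
                             np.array([e for _, e in merged]))

    spans = np.array([max(v.span, 1) for v in variants])
    v_chroms = np.array([v.chrom for v in variants], dtype=object)
    v_starts = np.array([v.start for v in variants])
    v_ends = np.array([max(v.end, v.start + 1) for v in variants])
    observed = int(_overlaps_annotation(ann_arrays, v_chroms, v_starts,
                                        v_ends).sum())

    null_counts = np.zeros(n_perm, dtype=int)
    if mode == "placement":
        seg_chrom = np.array([c for c, _, _ in segs], dtype=object)
        seg_start = np.array([s for _, s, _ in segs])
        seg_len = np.array([e - s for _, s, e in segs])
        for i in range(len(variants)):
            L = spans[i]
            room = seg_len - L + 1
            ok = room > 0
            if not ok.any():
                raise ValueError(
                    f"no mask segment can hold a {L} bp interval")
            w = np.where(ok, room, 0).astype(float)
            w /= w.sum()
            seg_idx = rng.choice(len(segs), size=n_perm, p=w)
            offs = rng.integers(0, room[seg_idx])
            starts = seg_start[seg_idx] + offs
            hits = _overlaps_annotation(ann_arrays, seg_chrom[seg_idx],
                                        starts, starts + L)
            null_counts += hits
    elif mode == "resample":
        if universe is None:
            raise ValueError("resample mode requires a universe of variants")
        by_class: dict[str, list[VariantRecord]] = {}
        for u in universe:
            by_class.setdefault(u.size_class, []).append(u)
        for v in variants:
            if v.size_class not in by_class:
                raise ValueError(f"universe has no {v.size_class} variants")
        for r in range(n_perm):
            count = 0
            for v in variants:
                cands = by_class[v.size_class]
                u = cands[int(rng.integers(0, len(cands)))]
                hit = _overlaps_annotation(
                    ann_arrays, np.array([u.chrom], dtype=object),
                    np.array([u.start]),
                    np.array([max(u.end, u.start + 1)]))
                count += int(hit[0])
            null_counts[r] = count
    else:
        raise ValueError(f"unknown mode {mode!r}")

    p_dep = (1 + int((null_counts <= observed).sum())) / (n_perm + 1)
    p_enr = (1 + int((null_counts >= observed).sum())) / (n_perm + 1)
    return EnrichmentResult(
        observed=observed, n_perm=n_perm, side=side,
        p=p_dep if side == "depletion" else p_enr,
        p_depletion=p_dep, p_enrichment=p_enr,
        null_mean=float(null_counts.mean()),
        null_sd=float(null_counts.std(ddof=1)) if n_perm > 1 else float("nan"))


@dataclass
class LoadSummary:
    """Affected-bp load per haplotype and homozygous load per individual."""

    per_sample: pd.DataFrame
    mean_haplotype_indel_bp: float
    mean_haplotype_sv_bp: float
    mean_hom_indel_bp: float
    mean_hom_sv_bp: float

    def to_dict(self) -> dict:
        return {
            "mean_haplotype_indel_bp": self.mean_haplotype_indel_bp,
            "mean_haplotype_sv_bp": self.mean_haplotype_sv_bp,
            "mean_hom_indel_bp": self.mean_hom_indel_bp,
            "mean_hom_sv_bp": self.mean_hom_sv_bp,
        }


def haplotype_load(
    variants: Sequence[VariantRecord],
    haplotypes: np.ndarray | None,
    samples: Sequence[str],
) -> LoadSummary:
    """Affected base pairs per haplotype and homozygous load per individual.

    Deletions contribute deleted bp, insertions inserted bp, complex indels
    the larger of the two segments, duplications/inversions their span.
    The homozygous load of an individual sums variants carried on both
    haplotypes, so it never exceeds either haplotype load.  SNPs are
    excluded.
    """
    if haplotypes is None:
        raise ValueError(
            "haplotype_load requires phased haplotypes; for unphased data "
            "compute per-individual load from hard calls instead "
            "(genotype==2 gives the homozygous load)")
    keep = np.array([v.vtype != "SNP" for v in variants], dtype=bool)
    lengths = np.array([v.affected_bp for v in variants], dtype=float)[keep]
    indel = np.array([_is_indel(v) for v in variants], dtype=bool)[keep]
    hap = np.asarray(haplotypes)[keep]

    rows = {}
    for label, mask in (("indel", indel), ("sv", ~indel)):
        w = lengths[mask]
        h = hap[mask]
        rows[f"hap0_{label}_bp"] = (h[:, :, 0] * w[:, None]).sum(axis=0)
        rows[f"hap1_{label}_bp"] = (h[:, :, 1] * w[:, None]).sum(axis=0)
        hom = (h[:, :, 0] * h[:, :, 1]) * w[:, None]
        rows[f"hom_{label}_bp"] = hom.sum(axis=0)
    per_sample = pd.DataFrame(rows, index=list(samples))
    hap_indel = np.concatenate([per_sample["hap0_indel_bp"],
                                per_sample["hap1_indel_bp"]])
    hap_sv = np.concatenate([per_sample["hap0_sv_bp"],
                             per_sample["hap1_sv_bp"]])
    return LoadSummary(
        per_sample=per_sample,
        mean_haplotype_indel_bp=float(hap_indel.mean()) if hap_indel.size else 0.0,
        mean_haplotype_sv_bp=float(hap_sv.mean()) if hap_sv.size else 0.0,
        mean_hom_indel_bp=float(per_sample["hom_indel_bp"].mean())
        if len(per_sample) else 0.0,
        mean_hom_sv_bp=float(per_sample["hom_sv_bp"].mean())
        if len(per_sample) else 0.0)


def tdt(
    genotypes: np.ndarray,
    samples: Sequence[str],
    variants: Sequence[VariantRecord],
    pedigree: Pedigree,
    af: np.ndarray | None = None,
) -> pd.DataFrame:
    """Transmission disequilibrium test per variant over all trios.

    Counts transmissions ``b`` and non-transmissions ``c`` of the minor
    allele from heterozygous parents, using the McNemar-form statistic
    ``chi2 = (b - c)^2 / (b + c)`` with a chi-square(1) two-sided p-value.
    Trio-variant combinations that are Mendelian-inconsistent or contain a
    missing genotype are excluded and counted in ``n_excluded``.
    Variants with ``b + c == 0`` get NaN statistics.
    """
    gt = np.asarray(genotypes)
    trios = pedigree.trios()
    idx = {s: i for i, s in enumerate(samples)}
    if not trios:
        raise ValueError("pedigree contains no complete trios")
    fa = gt[:, [idx[f] for f, _, _ in trios]].T  # (n_trios, n_variants)
    mo = gt[:, [idx[m] for _, m, _ in trios]].T
    ch = gt[:, [idx[c] for _, _, c in trios]].T

    present = (fa >= 0) & (mo >= 0) & (ch >= 0)
    lo = (fa == 2).astype(int) + (mo == 2).astype(int)
    hi = (fa >= 1).astype(int) + (mo >= 1).astype(int)
    consistent = (ch >= lo) & (ch <= hi)
    valid = present & consistent
    n_excluded = (present & ~consistent).sum(axis=0)

    b = np.zeros(gt.shape[0])
    c = np.zeros(gt.shape[0])
    # one het parent, other parent homozygous: transmitted allele resolved
    for het, hom in ((fa, mo), (mo, fa)):
        m = valid & (het == 1) & (hom != 1)
        t = np.where(m, ch - hom // 2, 0)
        b += (m & (t == 1)).sum(axis=0)
        c += (m & (t == 0)).sum(axis=0)
    # both parents het: child genotype fixes the transmission counts
    both = valid & (fa == 1) & (mo == 1)
    b += 2 * (both & (ch == 2)).sum(axis=0) + (both & (ch == 1)).sum(axis=0)
    c += 2 * (both & (ch == 0)).sum(axis=0) + (both & (ch == 1)).sum(axis=0)

    if af is not None:
        flip = np.asarray(af) > 0.5
        b, c = np.where(flip, c, b), np.where(flip, b, c)

    total = b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(total > 0, (b - c) ** 2 / np.where(total > 0, total, 1),
                        np.nan)
    p = np.where(total > 0, stats.chi2.sf(chi2, df=1), np.nan)
    return pd.DataFrame({
        "variant": [v.id for v in variants],
        "b": b.astype(int),
        "c": c.astype(int),
        "chi2": chi2,
        "p": p,
        "n_excluded": n_excluded.astype(int),
    })
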