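"""Synthetic family cohorts with the statistical structure the pipeline assumes.

The generator emulates a trio-based population panel: founder haplotypes
carrying SNPs and structural variants under a rare-heavy, neutral-like
allele-frequency spectrum, linkage disequilibrium from block-wise copying of
a small pool of ancestral haplotypes, offspring produced by Mendelian
transmission with Poisson-distributed crossovers, per-strategy caller error
profiles (breakpoint jitter, false positives/negatives) and depth-calibrated
genotype likelihoods.  Every stage of the analysis pipeline can therefore be
exercised end-to-end with a known truth, without any controlled-access data.

The allele-frequency spectrum default places probability proportional to
1/x on the discrete grid of possible founder frequencies, truncated to
[1/H, 0.5] for H founder haplotypes.  This reproduces the rare-heavy shape
of an equilibrium neutral site-frequency spectrum without claiming
demographic realism.

LD arises from block-wise copying: within each block every founder
haplotype copies one of a small pool of ancestral block haplotypes.  A
configurable fraction of SVs additionally ride the ancestral haplotype of
their nearest SNP, which creates the high-LD SNP-SV pairs (tag SNPs) that
the LD stage looks for.  Setting ``ld_pool_haplotypes = 0`` disables the
pool and draws every founder haplotype independently per variant, which
makes founder allele frequencies exactly binomial around their targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .merge import DEFAULT_STRATEGY_RANKS, CallerCall
from .records import (
    Pedigree,
    PedigreeSample,
    VariantRecord,
    _chrom_key_of,
    size_class,
)

__all__ = [
    "SimulationConfig",
    "CallerProfile",
    "TruthPanel",
    "DEFAULT_SV_COUNTS",
    "DEFAULT_CALLER_PROFILES",
    "simulate_truth_panel",
    "simulate_caller_callsets",
    "simulate_genotype_likelihoods",
    "simulate_gwas_labels",
    "snps_in_high_ld_with_sv",
]

#: default composition of the simulated SV/indel panel, loosely following
#: the observed mix in population panels: short deletions and insertions
#: dominate, mid-sized (21-100 bp) deletions are common, MEIs make up a
#: sizeable share of the >20 bp events.
DEFAULT_SV_COUNTS: dict[str, dict[str, int]] = {
    "DEL": {"short": 350, "mid": 120, "large": 100},
    "INS": {"short": 220},
    "MEI": {"large": 60},
    "COMPLEX_INDEL": {"short": 80},
    "DUP": {"large": 25},
    "INV": {"large": 8},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    ``recomb_rate`` is in crossovers per Mb per meiosis (human-like default
    0.01, i.e. ~1 cM/Mb).  ``n_unrelated`` adds founder-style singleton
    samples sharing the cohort's LD structure; they serve as held-out
    imputation targets.
    """

    n_families: int = 30
    n_unrelated: int = 0
    genome: tuple[tuple[str, int], ...] = (("1", 10_000_000),)
    snp_density: float = 100.0            # SNPs per Mb
    sv_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SV_COUNTS.items()})
    recomb_rate: float = 0.01             # crossovers per Mb per meiosis
    ld_block_bp: int = 50_000
    ld_pool_haplotypes: int = 12          # 0 disables LD (independent draws)
    sv_tag_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 0 or self.n_unrelated < 0:
            raise ValueError("sample counts must be >= 0")
        if not self.genome or any(length <= 0 for _, length in self.genome):
            raise ValueError("every chromosome must have positive length")
        for vtype, classes in self.sv_counts.items():
            if any(c < 0 for c in classes.values()):
                raise ValueError(f"negative count for {vtype}")
        if not 0 <= self.sv_tag_fraction <= 1:
            raise ValueError("sv_tag_fraction must be in [0, 1]")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")


@dataclass(frozen=True)
class CallerProfile:
    """Error profile of one simulated SV caller.

    ``sensitivity`` is tabulated per size class (short/mid/large);
    ``fdr`` is the expected fraction of emitted calls that are false;
    ``breakpoint_sd`` the standard deviation of the (rounded) Gaussian
    breakpoint jitter in bp.  ``accuracy_rank`` defaults to the rank of the
    caller's strategy (assembly best, read-depth worst).
    """

    name: str
    strategy: str
    breakpoint_sd: float = 0.0
    fdr: float = 0.0
    sensitivity: dict[str, float] = field(
        default_factory=lambda: {"short": 1.0, "mid": 1.0, "large": 1.0})
    accuracy_rank: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.fdr < 1:
            raise ValueError("fdr must be in [0, 1)")
        if any(not 0 <= s <= 1 for s in self.sensitivity.values()):
            raise ValueError("sensitivity values must be in [0, 1]")

    @property
    def rank(self) -> int:
        if self.accuracy_rank is not None:
            return self.accuracy_rank
        return DEFAULT_STRATEGY_RANKS[self.strategy]

    def sensitivity_at(self, length: int) -> float:
        return self.sensitivity.get(size_class(length), 1.0)


DEFAULT_CALLER_PROFILES = (
    CallerProfile("asmtool", "assembly", breakpoint_sd=0.0, fdr=0.02,
                  sensitivity={"short": 0.85, "mid": 0.8, "large": 0.6}),
    CallerProfile("splitter", "split-read", breakpoint_sd=2.0, fdr=0.03,
                  sensitivity={"short": 0.9, "mid": 0.85, "large": 0.7}),
    CallerProfile("pairview", "read-pair", breakpoint_sd=25.0, fdr=0.05,
                  sensitivity={"short": 0.05, "mid": 0.5, "large": 0.9}),
    CallerProfile("depthscan", "read-depth", breakpoint_sd=120.0, fdr=0.08,
                  sensitivity={"short": 0.0, "mid": 0.1, "large": 0.75}),
)


@dataclass
class TruthPanel:
    """Truth variants, phased haplotypes and pedigree of a simulated cohort.

    ``haplotypes`` has shape ``(n_variants, n_samples, 2)`` with 0/1 alleles;
    variants are sorted by (chrom, start).
    """

    variants: list[VariantRecord]
    af: np.ndarray
    haplotypes: np.ndarray
    pedigree: Pedigree
    samples: list[str]
    config: SimulationConfig

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def is_snp(self) -> np.ndarray:
        return np.array([v.vtype == "SNP" for v in self.variants])

    @property
    def genotypes(self) -> np.ndarray:
        """(n_variants, n_samples) hard genotypes 0/1/2."""
        return self.haplotypes.sum(axis=2)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    @property
    def founder_indices(self) -> np.ndarray:
        founders = set(self.pedigree.founders)
        return np.array([i for i, s in enumerate(self.samples) if s in founders])

    def founder_haplotype_matrix(self) -> np.ndarray:
        """(n_variants, 2 * n_founders) founder haplotype alleles."""
        idx = self.founder_indices
        return self.haplotypes[:, idx, :].reshape(self.n_variants, -1)

    def subset_samples(self, keep: list[str]) -> "TruthPanel":
        """Panel restricted to the named samples (pedigree links pruned)."""
        idx = [self.sample_index(s) for s in keep]
        kept = set(keep)
        ped = Pedigree(samples=[
            PedigreeSample(
                sample=s.sample,
                father=s.father if s.father in kept else None,
                mother=s.mother if s.mother in kept else None,
                family=s.family,
            )
            for s in self.pedigree.samples if s.sample in kept
        ])
        return TruthPanel(
            variants=self.variants, af=self.af,
            haplotypes=self.haplotypes[:, idx, :],
            pedigree=ped, samples=list(keep), config=self.config,
        )


_MEI_LENGTHS = np.array([300, 1500, 6000])     # Alu, SVA, L1
_MEI_WEIGHTS = np.array([0.65, 0.10, 0.25])


def _sample_length(rng, vtype: str, sclass: str) -> int:
    if vtype == "MEI":
        return int(rng.choice(_MEI_LENGTHS, p=_MEI_WEIGHTS))
    if sclass == "short":
        return int(rng.integers(1, 21))
    if sclass == "mid":
        return int(rng.integers(21, 101))
    # large: log-uniform over 101..10000
    return int(np.round(np.exp(rng.uniform(np.log(101), np.log(10_000)))))


def _place_variants(rng, config: SimulationConfig):
    """Choose positions/lengths for SNPs and SVs; same-reference-span SVs
    are kept mutually disjoint so that distinct truth variants cannot merge
    into one consensus."""
    chrom_lengths = dict(config.genome)
    chroms = sorted(chrom_lengths, key=_chrom_key_of)
    total = sum(chrom_lengths.values())
    per_chrom: dict[str, list[VariantRecord]] = {c: [] for c in chroms}
    counter = 0

    # SVs first (they need disjoint placement), chromosome chosen by length
    from bisect import bisect_left

    occ_starts: dict[str, list[int]] = {c: [] for c in chroms}
    occ_ends: dict[str, list[int]] = {c: [] for c in chroms}

    def _free(chrom: str, s: int, e: int) -> bool:
        starts, ends = occ_starts[chrom], occ_ends[chrom]
        k = bisect_left(starts, e)
        return k == 0 or ends[k - 1] <= s

    def _occupy(chrom: str, s: int, e: int) -> None:
        k = bisect_left(occ_starts[chrom], s)
        occ_starts[chrom].insert(k, s)
        occ_ends[chrom].insert(k, e)

    probs = np.array([chrom_lengths[c] / total for c in chroms])
    for vtype in sorted(config.sv_counts):
        for sclass in sorted(config.sv_counts[vtype]):
            for _ in range(config.sv_counts[vtype][sclass]):
                length = _sample_length(rng, vtype, sclass)
                for _attempt in range(200):
                    chrom = chroms[rng.choice(len(chroms), p=probs)]
                    L = chrom_lengths[chrom]
                    if vtype in ("INS", "MEI"):
                        start = int(rng.integers(1, L))
                        end = start
                        # reserve the merge tolerance around the anchor so
                        # distinct truth insertions stay distinguishable
                        tol = length // 2 + 1
                        span = (max(0, start - tol), start + tol + 1)
                    elif vtype == "COMPLEX_INDEL":
                        ref_span = int(rng.integers(2, 11))
                        start = int(rng.integers(1, L - ref_span))
                        end = start + ref_span
                        span = (start, end)
                    else:
                        if length >= L:
                            continue
                        start = int(rng.integers(1, L - length))
                        end = start + length
                        span = (start, end)
                    if not _free(chrom, span[0], span[1]):
                        continue
                    _occupy(chrom, span[0], span[1])
                    alt_seq = None
                    if vtype == "COMPLEX_INDEL":
                        length = int(rng.integers(1, 12))
                        alt_seq = "".join(
                            rng.choice(list("ACGT"), size=length))
                    elif vtype == "INS" and length <= 30:
                        alt_seq = "".join(
                            rng.choice(list("ACGT"), size=length))
                    per_chrom[chrom].append(VariantRecord(
                        chrom=chrom, start=start, end=end, vtype=vtype,
                        length=length, id=f"truth_{vtype}_{counter:05d}",
                        alt_seq=alt_seq))
                    counter += 1
                    break

    # SNPs at distinct free positions
    for chrom in chroms:
        L = chrom_lengths[chrom]
        n_snp = int(round(config.snp_density * L / 1e6))
        taken = {v.start for v in per_chrom[chrom]}
        pos = rng.choice(L, size=min(3 * n_snp + 10, L), replace=False)
        pos = [int(p) for p in pos if p not in taken][:n_snp]
        for k, p in enumerate(sorted(pos)):
            per_chrom[chrom].append(VariantRecord(
                chrom=chrom, start=p, end=p + 1, vtype="SNP", length=1,
                id=f"snp_{chrom}_{p}"))

    variants: list[VariantRecord] = []
    for chrom in chroms:
        variants.extend(sorted(per_chrom[chrom], key=lambda v: v.sort_key()))
    return variants


def _make_pedigree(config: SimulationConfig) -> Pedigree:
    samples = []
    for i in range(config.n_families):
        fam = f"fam{i:03d}"
        samples.append(PedigreeSample(f"{fam}_f", None, None, fam))
        samples.append(PedigreeSample(f"{fam}_m", None, None, fam))
        samples.append(PedigreeSample(f"{fam}_c", f"{fam}_f", f"{fam}_m", fam))
    for i in range(config.n_unrelated):
        samples.append(PedigreeSample(f"ind{i:03d}", None, None, f"ind{i:03d}"))
    return Pedigree(samples=samples)


def _founder_haplotypes(rng, config: SimulationConfig,
                        variants: list[VariantRecord], af: np.ndarray,
                        n_hap: int) -> np.ndarray:
    """(n_variants, n_hap) founder haplotype alleles with optional LD."""
    n_v = len(variants)
    hap = np.zeros((n_v, n_hap), dtype=np.int8)
    K = config.ld_pool_haplotypes

    # choose which SVs ride the ancestral haplotype of their nearest SNP
    tagged: dict[int, int] = {}
    if config.sv_tag_fraction > 0:
        snp_idx_by_chrom: dict[str, list[int]] = {}
        for i, v in enumerate(variants):
            if v.vtype == "SNP":
                snp_idx_by_chrom.setdefault(v.chrom, []).append(i)
        for i, v in enumerate(variants):
            if v.vtype == "SNP":
                continue
            if rng.random() >= config.sv_tag_fraction:
                continue
            snps = snp_idx_by_chrom.get(v.chrom)
            if not snps:
                continue
            pos = np.array([variants[j].start for j in snps])
            j = snps[int(np.argmin(np.abs(pos - v.start)))]
            if K > 0:
                # pool copying only links variants within one block
                if variants[j].start // config.ld_block_bp != \
                        v.start // config.ld_block_bp:
                    continue
            tagged[i] = j

    if K <= 0:
        draw = rng.random((n_v, n_hap))
        hap[:] = (draw < af[:, None]).astype(np.int8)
        for i, j in tagged.items():
            hap[i] = hap[j]
        return hap

    # block-wise copying from a pool of K ancestral block haplotypes
    chrom_of = np.array([_chrom_key_of(v.chrom) for v in variants], dtype=object)
    block_of = np.array([v.start // config.ld_block_bp for v in variants])
    keys = [(tuple(chrom_of[i]), block_of[i]) for i in range(n_v)]
    blocks: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        blocks.setdefault(key, []).append(i)
    for key in sorted(blocks):
        idx = np.array(blocks[key])
        pool = (rng.random((K, idx.size)) < af[idx][None, :]).astype(np.int8)
        local = {v: c for c, v in enumerate(idx)}
        for i in idx:
            if i in tagged:
                pool[:, local[i]] = pool[:, local[tagged[i]]]
        choice = rng.integers(0, K, size=n_hap)
        hap[idx[:, None], np.arange(n_hap)[None, :]] = pool[choice, :].T
    return hap


def _meiosis(rng, parent_haps: np.ndarray, positions: np.ndarray,
             chrom_index: np.ndarray, chrom_lengths_mb: list[float],
             rate: float) -> np.ndarray:
    """One gamete: recombinant of the parent's two haplotypes.

    ``parent_haps`` is (n_variants, 2); chromosomes recombine independently
    with Poisson(rate * length_Mb) crossovers at uniform positions.
    """
    gamete = np.empty(parent_haps.shape[0], dtype=np.int8)
    for c, length_mb in enumerate(chrom_lengths_mb):
        mask = chrom_index == c
        pos = positions[mask]
        n_cross = rng.poisson(rate * length_mb)
        cuts = np.sort(rng.uniform(0, length_mb * 1e6, size=n_cross))
        phase0 = int(rng.integers(0, 2))
        seg = np.searchsorted(cuts, pos, side="right")
        phase = (phase0 + seg) % 2
        rows = parent_haps[mask]
        gamete[mask] = rows[np.arange(rows.shape[0]), phase]
    return gamete


def simulate_truth_panel(config: SimulationConfig) -> TruthPanel:
    """Simulate the truth panel: variants, phased haplotypes, pedigree.

    Deterministic under ``config.seed``.  Founder haplotypes are i.i.d.
    draws from the (optionally LD-structured) generating process; children
    are Mendelian recombinants of their parents' haplotypes.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_place, rng_af, rng_hap, rng_mei = [
        np.random.default_rng(s) for s in ss.spawn(4)]

    variants = _place_variants(rng_place, config)
    n_v = len(variants)
    pedigree = _make_pedigree(config)
    samples = pedigree.sample_ids
    founders = pedigree.founders
    n_hap = 2 * len(founders)

    # neutral-like AF spectrum: P(AF = j/H) proportional to 1/j, truncated
    # to [1/H, 0.5]
    H = max(n_hap, 4)
    j = np.arange(1, H // 2 + 1)
    weights = 1.0 / j
    weights /= weights.sum()
    af = rng_af.choice(j, size=n_v, p=weights) / H

    fhap = _founder_haplotypes(rng_hap, config, variants, af, n_hap)

    haplotypes = np.zeros((n_v, len(samples), 2), dtype=np.int8)
    founder_pos = {s: k for k, s in enumerate(founders)}
    for s in founders:
        k = founder_pos[s]
        i = samples.index(s)
        haplotypes[:, i, 0] = fhap[:, 2 * k]
        haplotypes[:, i, 1] = fhap[:, 2 * k + 1]

    chroms = sorted({v.chrom for v in variants}, key=_chrom_key_of)
    chrom_lengths = dict(config.genome)
    chrom_lengths_mb = [chrom_lengths[c] / 1e6 for c in chroms]
    chrom_pos = {c: k for k, c in enumerate(chroms)}
    chrom_index = np.array([chrom_pos[v.chrom] for v in variants])
    positions = np.array([v.start for v in variants])

    for father, mother, child in pedigree.trios():
        fi = samples.index(father)
        mi = samples.index(mother)
        ci = samples.index(child)
        haplotypes[:, ci, 0] = _meiosis(
            rng_mei, haplotypes[:, fi, :], positions, chrom_index,
            chrom_lengths_mb, config.recomb_rate)
        haplotypes[:, ci, 1] = _meiosis(
            rng_mei, haplotypes[:, mi, :], positions, chrom_index,
            chrom_lengths_mb, config.recomb_rate)

    return TruthPanel(variants=variants, af=af, haplotypes=haplotypes,
                      pedigree=pedigree, samples=samples, config=config)


def simulate_caller_callsets(
    panel: TruthPanel,
    profiles: tuple[CallerProfile, ...] = DEFAULT_CALLER_PROFILES,
    seed: int | None = None,
) -> dict[str, list[CallerCall]]:
    """Emit one jittered, incomplete call set per caller profile.

    A true SV carried by at least one sample is emitted by caller *c* with
    probability ``sensitivity_c(length)``; breakpoints receive rounded
    Gaussian jitter with the caller's sd; false calls are added so that the
    expected false fraction of the call set equals the caller's ``fdr``.
    """
    if not profiles:
        raise ValueError("at least one caller profile is required")
    seed = panel.config.seed + 1 if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(len(profiles))]
    carried = panel.genotypes.sum(axis=1) > 0
    sv_mask = ~panel.is_snp
    truth = [v for v, c, s in zip(panel.variants, carried, sv_mask) if c and s]
    chrom_lengths = dict(panel.config.genome)

    out: dict[str, list[CallerCall]] = {}
    for prof, rng in zip(profiles, rngs):
        calls: list[CallerCall] = []
        for v in truth:
            if rng.random() >= prof.sensitivity_at(v.length):
                continue
            start, end, length, alt_seq = v.start, v.end, v.length, v.alt_seq
            if prof.breakpoint_sd > 0:
                jit_s = int(np.round(rng.normal(0, prof.breakpoint_sd)))
                jit_e = int(np.round(rng.normal(0, prof.breakpoint_sd)))
                if v.vtype in ("INS", "MEI"):
                    start = max(0, v.start + jit_s)
                    end = start
                else:
                    start = max(0, v.start + jit_s)
                    end = max(start + 1, v.end + jit_e)
                    if v.vtype == "DEL":
                        length = end - start
            calls.append(CallerCall(
                chrom=v.chrom, start=start, end=end, vtype=v.vtype,
                length=length, id=f"{prof.name}_{len(calls):05d}",
                alt_seq=alt_seq, caller=prof.name, strategy=prof.strategy,
                accuracy_rank=prof.rank))
        if prof.fdr > 0 and calls:
            n_false = rng.poisson(prof.fdr / (1 - prof.fdr) * len(calls))
            templates = truth if truth else panel.variants
            for _ in range(n_false):
                t = templates[int(rng.integers(0, len(templates)))]
                L = chrom_lengths[t.chrom]
                if t.vtype in ("INS", "MEI"):
                    start = end = int(rng.integers(1, L))
                else:
                    start = int(rng.integers(1, max(2, L - t.length)))
                    end = start + t.span
                calls.append(CallerCall(
                    chrom=t.chrom, start=start, end=end, vtype=t.vtype,
                    length=t.length, id=f"{prof.name}_{len(calls):05d}",
                    alt_seq=t.alt_seq, caller=prof.name,
                    strategy=prof.strategy, accuracy_rank=prof.rank))
        calls.sort(key=lambda c: c.sort_key())
        out[prof.name] = calls
    return out


def simulate_genotype_likelihoods(
    panel: TruthPanel,
    depth: float = 12.0,
    error_rate: float = 0.02,
    seed: int | None = None,
    variant_indices: np.ndarray | None = None,
    sample_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Depth-calibrated genotype-probability triplets per sample x variant.

    Reads per site are Poisson(depth); each read reports the alternate
    allele with probability ``g/2`` flipped by ``error_rate``.  The returned
    triplet is the normalized product of per-read likelihoods under each of
    the three genotypes, i.e. the posterior under a uniform genotype prior,
    which is calibrated by construction.  Sites with zero reads return the
    uniform triplet.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(
        panel.config.seed + 2 if seed is None else seed)
    gt = panel.genotypes
    if variant_indices is not None:
        gt = gt[variant_indices]
    if sample_indices is not None:
        gt = gt[:, sample_indices]
    n_v, n_s = gt.shape
    d = rng.poisson(depth, size=(n_v, n_s))
    p_true = gt / 2 * (1 - error_rate) + (1 - gt / 2) * error_rate
    k = rng.binomial(d, p_true)

    out = np.empty((n_v, n_s, 3))
    with np.errstate(divide="ignore", invalid="ignore"):
        for g in range(3):
            p_g = g / 2 * (1 - error_rate) + (1 - g / 2) * error_rate
            logp = k * np.log(p_g) if p_g > 0 else \
                np.where(k > 0, -np.inf, 0.0)
            logq = (d - k) * np.log(1 - p_g) if p_g < 1 else \
                np.where(d - k > 0, -np.inf, 0.0)
            out[:, :, g] = logp + logq
    out -= out.max(axis=2, keepdims=True)
    out = np.exp(out)
    out /= out.sum(axis=2, keepdims=True)
    out[d == 0] = 1.0 / 3.0
    return out


def snps_in_high_ld_with_sv(
    panel: TruthPanel,
    high_ld_r2: float = 0.8,
    max_distance: int = 100_000,
) -> np.ndarray:
    """Per SNP (panel order): lies within ``max_distance`` of an SV with
    which it is in high LD (r^2 >= ``high_ld_r2``) among founder
    haplotypes."""
    from .ld import r2_against_many  # local import to avoid a cycle

    is_snp = panel.is_snp
    snp_idx = np.flatnonzero(is_snp)
    sv_idx = np.flatnonzero(~is_snp)
    fhap = panel.founder_haplotype_matrix()
    positions = np.array([v.start for v in panel.variants])
    chrom = np.array([v.chrom for v in panel.variants], dtype=object)

    in_high_ld = np.zeros(snp_idx.size, dtype=bool)
    for j in sv_idx:
        near = np.flatnonzero(
            (chrom[snp_idx] == chrom[j])
            & (np.abs(positions[snp_idx] - positions[j]) <= max_distance))
        if near.size == 0:
            continue
        r2 = r2_against_many(fhap[j], fhap[snp_idx[near]])
        in_high_ld[near] |= np.nan_to_num(r2, nan=0.0) >= high_ld_r2
    return in_high_ld


def simulate_gwas_labels(
    panel: TruthPanel,
    fraction: float = 0.05,
    ld_enrichment: float = 1.0,
    seed: int | None = None,
    high_ld_r2: float = 0.8,
    max_distance: int = 100_000,
    in_high_ld: np.ndarray | None = None,
) -> np.ndarray:
    """GWAS flags per SNP (aligned with the panel's SNP variants, in order).

    Each SNP is flagged with probability ``fraction``, multiplied by
    ``ld_enrichment`` (capped at 1) when the SNP lies within
    ``max_distance`` of an SV with which it is in high LD
    (r^2 >= ``high_ld_r2`` among founder haplotypes).  With
    ``ld_enrichment = 1`` the flags are independent of SV proximity, so the
    null of equal significant fractions in the matched-sampling test holds.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(
        panel.config.seed + 3 if seed is None else seed)
    if in_high_ld is None:
        in_high_ld = snps_in_high_ld_with_sv(panel, high_ld_r2, max_distance)
    p = np.where(in_high_ld, min(1.0, fraction * ld_enrichment), fraction)
    return rng.random(in_high_ld.size) < p
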