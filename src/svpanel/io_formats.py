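"""Readers and writers for the interchange formats the pipeline touches.

VCF is the interchange format for every call set (per-caller calls, the
consensus set, genotype-likelihood sets and the phased panel), PED carries
the pedigree, tab-separated tables carry the GWAS catalog, and BED carries
annotation intervals.  All conversion between VCF's 1-based inclusive
coordinates and the internal 0-based half-open convention happens here and
nowhere else.

Caller provenance travels in two reserved INFO keys, ``CALLER`` and
``STRATEGY``; standard VCF has no equivalent field and the consensus merge
is strategy-aware, so per-caller VCFs written by this package always carry
them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .records import (
    INSERTION_TYPES,
    Pedigree,
    PedigreeSample,
    VariantRecord,
    VTYPES,
    _chrom_key_of,
)

__all__ = [
    "SVParseError",
    "CallSet",
    "read_sv_vcf",
    "write_sv_vcf",
    "read_pedigree",
    "write_pedigree",
    "read_gwas_catalog",
    "write_gwas_catalog",
    "read_bed",
    "write_bed",
]


class SVParseError(ValueError):
    """Raised for malformed input files."""


@dataclass
class CallSet:
    """A set of variant records plus optional per-sample genotype data.

    ``genotype_probs`` holds normalized probability triplets over
    (hom-ref, het, hom-alt) with shape ``(n_records, n_samples, 3)``;
    ``genotypes`` holds hard calls in ``{-1 (missing), 0, 1, 2}``;
    ``haplotypes`` holds phased alleles with shape
    ``(n_records, n_samples, 2)`` when every genotype was phased.
    """

    records: list[VariantRecord] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)
    genotype_probs: np.ndarray | None = None
    genotypes: np.ndarray | None = None
    haplotypes: np.ndarray | None = None
    caller: list[str | None] = field(default_factory=list)
    strategy: list[str | None] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def _probs_from_pl(pl) -> np.ndarray | None:
    vals = np.asarray([v for v in pl], dtype=float)
    if vals.size != 3 or not np.all(np.isfinite(vals)):
        return None
    p = np.power(10.0, -vals / 10.0)
    return p / p.sum()


def _probs_from_gl(gl) -> np.ndarray | None:
    vals = np.asarray([v for v in gl], dtype=float)
    if vals.size != 3 or not np.all(np.isfinite(vals)):
        return None
    vals = vals - vals.max()
    p = np.power(10.0, vals)
    return p / p.sum()


def _info_get(rec, key):
    """INFO lookup tolerant of keys absent from the header declaration."""
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _infer_from_alleles(ref: str, alt: str) -> tuple[str, int] | None:
    """Classify a literal REF/ALT pair; returns (vtype, length)."""
    if re.fullmatch(r"[ACGTN]+", ref or "") is None:
        return None
    if re.fullmatch(r"[ACGTN]+", alt or "") is None:
        return None
    if len(ref) == 1 and len(alt) == 1:
        return ("SNP", 1)
    if len(alt) == 1 and len(ref) > 1:
        return ("DEL", len(ref) - 1)
    if len(ref) == 1 and len(alt) > 1:
        return ("INS", len(alt) - 1)
    return ("COMPLEX_INDEL", len(alt))


def read_sv_vcf(path: str) -> CallSet:
    """Read a VCF 4.x call set into internal coordinates.

    1-based POS becomes a 0-based start; the END INFO field (1-based
    inclusive) becomes the 0-based exclusive end.  PL and GL FORMAT fields
    are converted to normalized probability triplets.  Records are returned
    sorted by (chrom, start).  Symbolic records without an SVTYPE are
    collected into ``CallSet.errors`` rather than silently dropped.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except Exception as exc:  # pysam raises several types on bad headers
        raise SVParseError(f"{path}: malformed VCF header: {exc}") from exc

    samples = list(vcf.header.samples)
    records: list[VariantRecord] = []
    probs: list[np.ndarray] = []
    gts: list[np.ndarray] = []
    haps: list[np.ndarray] = []
    callers: list[str | None] = []
    strategies: list[str | None] = []
    errors: list[str] = []
    all_phased = True
    any_probs = False
    any_gt = False

    for i, rec in enumerate(vcf):
        alts = rec.alts or ()
        if len(alts) != 1:
            errors.append(f"{path} record {i + 1} ({rec.chrom}:{rec.pos}): "
                          f"expected exactly one ALT allele")
            continue
        alt = alts[0]
        symbolic = alt.startswith("<")
        svtype = _info_get(rec, "SVTYPE")
        alt_seq = None
        if svtype is None:
            if symbolic:
                errors.append(
                    f"{path} record {i + 1} ({rec.chrom}:{rec.pos}): "
                    f"symbolic allele {alt} without SVTYPE"
                )
                continue
            inferred = _infer_from_alleles(rec.ref, alt)
            if inferred is None:
                errors.append(f"{path} record {i + 1} ({rec.chrom}:{rec.pos}): "
                              f"cannot classify alleles {rec.ref}>{alt}")
                continue
            svtype, length = inferred
            if svtype == "SNP":
                start, end = rec.start, rec.start + 1
            elif svtype == "DEL":
                start, end = rec.start + 1, rec.start + len(rec.ref)
            elif svtype == "INS":
                start = end = rec.start + 1
                alt_seq = alt[1:]
            else:  # COMPLEX_INDEL
                start, end = rec.start, rec.start + len(rec.ref)
                alt_seq = alt
        else:
            if svtype not in VTYPES:
                errors.append(f"{path} record {i + 1} ({rec.chrom}:{rec.pos}): "
                              f"unknown SVTYPE {svtype}")
                continue
            svlen = _info_get(rec, "SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            start = rec.start
            if svtype in INSERTION_TYPES:
                end = start
                length = abs(int(svlen)) if svlen is not None else None
                alt_seq = _info_get(rec, "INSSEQ")
                if length is None and alt_seq is not None:
                    length = len(alt_seq)
                if length is None:
                    errors.append(f"{path} record {i + 1}: insertion without "
                                  f"SVLEN or INSSEQ")
                    continue
            else:
                end = rec.stop
                if svlen is not None:
                    length = abs(int(svlen))
                else:
                    length = end - start
                if svtype == "COMPLEX_INDEL":
                    alt_seq = _info_get(rec, "INSSEQ")
        vid = rec.id or f"{rec.chrom}_{rec.pos}_{svtype}_{i}"
        try:
            vrec = VariantRecord(
                chrom=rec.chrom, start=start, end=end, vtype=svtype,
                length=int(length), id=vid, alt_seq=alt_seq,
            )
        except ValueError as exc:
            errors.append(f"{path} record {i + 1}: {exc}")
            continue

        callers.append(_info_get(rec, "CALLER"))
        strategies.append(_info_get(rec, "STRATEGY"))

        rec_probs = np.full((len(samples), 3), np.nan)
        rec_gt = np.full(len(samples), -1, dtype=np.int8)
        rec_hap = np.full((len(samples), 2), -1, dtype=np.int8)
        for j, name in enumerate(samples):
            smp = rec.samples[name]
            pl = smp.get("PL") if "PL" in smp else None
            gl = smp.get("GL") if "GL" in smp else None
            if pl is not None and pl[0] is not None:
                p = _probs_from_pl(pl)
                if p is not None:
                    rec_probs[j] = p
                    any_probs = True
            elif gl is not None and gl[0] is not None:
                p = _probs_from_gl(gl)
                if p is not None:
                    rec_probs[j] = p
                    any_probs = True
            alleles = smp.get("GT") if "GT" in smp else None
            if alleles is not None and None not in alleles and len(alleles) == 2:
                rec_gt[j] = sum(alleles)
                any_gt = True
                if smp.phased:
                    rec_hap[j] = alleles
                else:
                    all_phased = False
            else:
                all_phased = False
        records.append(vrec)
        probs.append(rec_probs)
        gts.append(rec_gt)
        haps.append(rec_hap)

    order = sorted(range(len(records)), key=lambda k: records[k].sort_key())
    callset = CallSet(
        records=[records[k] for k in order],
        samples=samples,
        caller=[callers[k] for k in order],
        strategy=[strategies[k] for k in order],
        errors=errors,
    )
    if records and samples:
        if any_probs:
            callset.genotype_probs = np.stack([probs[k] for k in order])
        if any_gt:
            callset.genotypes = np.stack([gts[k] for k in order])
            if all_phased:
                callset.haplotypes = np.stack([haps[k] for k in order])
    return callset


_EXTRA_INFO_FIELDS = {
    "SUPP": ("1", "Integer", "Number of supporting calls"),
    "STRATEGIES": ("1", "String",
                   "Comma-separated supporting detection strategies"),
    "BOUNDARY_SOURCE": ("1", "String", "Caller whose breakpoints were adopted"),
    "AF": ("A", "Float", "Alternate allele frequency"),
}


_chrom_key = _chrom_key_of


def _build_header(records, samples, contigs, with_gl, with_gt):
    header = pysam.VariantHeader()
    if contigs is None:
        contigs = {}
        for r in records:
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.end + 1000)
    else:
        missing = {r.chrom for r in records} - set(contigs)
        if missing:
            raise SVParseError(
                f"records on chromosome(s) {sorted(missing)} absent from the "
                f"supplied contig list; cannot order output"
            )
    for chrom in sorted(contigs, key=_chrom_key):
        header.contigs.add(chrom, length=int(contigs[chrom]))
    for ident, num, typ, desc in [
        ("SVTYPE", "1", "String", "Variant class"),
        ("END", "1", "Integer", "1-based inclusive end of the variant"),
        ("SVLEN", "1", "Integer", "Inserted length for INS/MEI/COMPLEX_INDEL"),
        ("INSSEQ", "1", "String", "Inserted sequence"),
        ("CALLER", "1", "String", "Name of the emitting caller"),
        ("STRATEGY", "1", "String", "Detection strategy of the emitting caller"),
    ]:
        header.add_meta("INFO", items=[("ID", ident), ("Number", num),
                                       ("Type", typ), ("Description", desc)])
    for ident, (num, typ, desc) in _EXTRA_INFO_FIELDS.items():
        header.add_meta("INFO", items=[("ID", ident), ("Number", num),
                                       ("Type", typ), ("Description", desc)])
    if with_gt or with_gl:
        header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                         ("Type", "String"),
                                         ("Description", "Genotype")])
    if with_gl:
        header.add_meta("FORMAT", items=[("ID", "GL"), ("Number", "G"),
                                         ("Type", "Float"),
                                         ("Description",
                                          "log10 genotype likelihoods")])
    for s in samples or []:
        header.add_sample(s)
    return header


def write_sv_vcf(
    records: list[VariantRecord],
    path: str,
    *,
    samples: list[str] | None = None,
    genotype_probs: np.ndarray | None = None,
    genotypes: np.ndarray | None = None,
    haplotypes: np.ndarray | None = None,
    caller: list[str | None] | str | None = None,
    strategy: list[str | None] | str | None = None,
    extra_info: list[dict] | None = None,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write records (and optional genotype data) as an uncompressed VCF.

    Internal 0-based half-open coordinates are converted back to 1-based
    POS/END exactly; ``write_sv_vcf`` followed by :func:`read_sv_vcf` is the
    identity on the internal model.
    """
    n = len(records)
    if isinstance(caller, str):
        caller = [caller] * n
    if isinstance(strategy, str):
        strategy = [strategy] * n
    with_gt = samples is not None and (genotypes is not None or haplotypes is not None)
    with_gl = samples is not None and genotype_probs is not None
    header = _build_header(records, samples or [], contigs, with_gl, with_gt)

    order = sorted(range(n), key=lambda k: (_chrom_key(records[k].chrom),
                                            records[k].sort_key()))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for k in order:
            r = records[k]
            if r.vtype == "SNP":
                ref, alt = "A", "C"
            else:
                ref, alt = "N", f"<{r.vtype}>"
            stop_1 = r.end if r.end > r.start else r.start + 1
            rec = out.new_record(contig=r.chrom, start=r.start, stop=stop_1,
                                 alleles=(ref, alt), id=r.id)
            rec.info["SVTYPE"] = r.vtype
            # SVLEN only where the span does not define the length: htslib
            # derives the record length of symbolic DEL/DUP/INV from SVLEN,
            # which would fight the explicit END
            if r.vtype in ("INS", "MEI", "COMPLEX_INDEL"):
                rec.info["SVLEN"] = r.length
            if r.alt_seq is not None:
                rec.info["INSSEQ"] = r.alt_seq
            if caller is not None and caller[k] is not None:
                rec.info["CALLER"] = caller[k]
            if strategy is not None and strategy[k] is not None:
                rec.info["STRATEGY"] = strategy[k]
            if extra_info is not None:
                for key, val in extra_info[k].items():
                    if key not in _EXTRA_INFO_FIELDS:
                        raise SVParseError(f"undeclared INFO key {key!r}")
                    rec.info[key] = val
            # htslib recomputes the length of symbolic records from SVLEN,
            # so END must be (re)asserted after every INFO assignment
            rec.stop = stop_1
            if samples:
                for j, name in enumerate(samples):
                    smp = rec.samples[name]
                    if haplotypes is not None:
                        smp["GT"] = tuple(int(a) for a in haplotypes[k, j])
                        smp.phased = True
                    elif genotypes is not None:
                        g = int(genotypes[k, j])
                        smp["GT"] = (None, None) if g < 0 else \
                            [(0, 0), (0, 1), (1, 1)][g]
                    if genotype_probs is not None:
                        p = np.maximum(np.asarray(genotype_probs[k, j], float),
                                       1e-300)
                        if np.all(np.isfinite(p)):
                            smp["GL"] = tuple(np.round(np.log10(p), 6))
            out.write(rec)


def read_pedigree(path: str) -> Pedigree:
    """Read a 6-column PED file (family, sample, father, mother, sex, pheno).

    A parent id of ``0`` (or ``.``) means unknown.  Founders are the samples
    whose parents are both absent from the file.
    """
    samples = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise SVParseError(
                    f"{path} line {ln}: expected 6 PED columns, got {len(parts)}"
                )
            fam, sid, father, mother = parts[:4]
            samples.append(PedigreeSample(
                sample=sid,
                father=None if father in ("0", ".") else father,
                mother=None if mother in ("0", ".") else mother,
                family=fam,
            ))
    return Pedigree(samples=samples)


def write_pedigree(ped: Pedigree, path: str) -> None:
    with open(path, "w") as fh:
        for s in ped.samples:
            fh.write(f"{s.family}\t{s.sample}\t{s.father or 0}\t"
                     f"{s.mother or 0}\t0\t-9\n")


_GWAS_COLUMNS = ("snp", "chrom", "pos", "trait")


def read_gwas_catalog(path: str) -> pd.DataFrame:
    """Read a tab-separated GWAS catalog (snp, chrom, pos, trait).

    Positions are converted from 1-based to the internal 0-based convention
    and duplicate (snp, trait) rows are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _GWAS_COLUMNS:
        if col not in df.columns:
            raise SVParseError(f"{path}: missing required column {col!r}")
    df = df.loc[:, list(_GWAS_COLUMNS)].drop_duplicates(subset=["snp", "trait"])
    df["pos"] = df["pos"].astype(int) - 1
    return df.reset_index(drop=True)


def write_gwas_catalog(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def read_bed(path: str) -> dict[str, list[tuple[int, int]]]:
    """Read BED intervals (already 0-based half-open) grouped by chromosome."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SVParseError(f"{path} line {ln}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise SVParseError(f"{path} line {ln}: empty interval")
            out.setdefault(chrom, []).append((start, end))
    for ivals in out.values():
        ivals.sort()
    return out


def write_bed(intervals: dict[str, list[tuple[int, int]]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals, key=_chrom_key):
            for start, end in sorted(intervals[chrom]):
                fh.write(f"{chrom}\t{start}\t{end}\n")
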