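"""Core in-memory records shared by every pipeline stage.

All genomic coordinates held in memory are 0-based half-open ``[start, end)``.
Conversion to and from the 1-based inclusive convention of VCF happens only
at the I/O boundary (:mod:`svpanel.io_formats`).

Insertions (``INS``, ``MEI``) are anchored points: ``start == end`` marks the
insertion site and ``length`` is the number of inserted bases.  Reference-
consuming types (``DEL``, ``DUP``, ``INV``, ``COMPLEX_INDEL``, ``SNP``) span
``[start, end)`` on the reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "VTYPES",
    "INSERTION_TYPES",
    "STRATEGIES",
    "VariantRecord",
    "PedigreeSample",
    "Pedigree",
    "size_class",
    "SIZE_CLASSES",
]

VTYPES = ("DEL", "INS", "DUP", "INV", "MEI", "COMPLEX_INDEL", "SNP")

#: variant types that do not consume reference sequence
INSERTION_TYPES = frozenset({"INS", "MEI"})

#: detection strategies of SV callers (algorithmic families)
STRATEGIES = ("split-read", "read-pair", "read-depth", "assembly")

#: size classes used throughout: short indel-scale, mid-sized, large
SIZE_CLASSES = ("short", "mid", "large")


def _chrom_key_of(chrom: str):
    """Sort key placing numeric chromosomes first, in numeric order."""
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
    return (0, int(m.group(1)), "") if m else (1, 0, chrom)


def size_class(length: int) -> str:
    """Map an affected/inserted length in bp to its size class.

    short: 1-20 bp, mid: 21-100 bp, large: >100 bp.  The three classes
    partition the positive integers with no gaps or overlap.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if length <= 20:
        return "short"
    if length <= 100:
        return "mid"
    return "large"


@dataclass(frozen=True)
class VariantRecord:
    """One variant in internal coordinates.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open interval on the reference.  ``start == end`` for
        anchored insertions.
    vtype : str
        One of :data:`VTYPES`.
    length : int
        Affected (reference-consuming types) or inserted (``INS``/``MEI``,
        and the inserted side of a ``COMPLEX_INDEL``) base pairs.
    id : str
        Stable identifier.
    alt_seq : str, optional
        Inserted sequence, when known.
    """

    chrom: str
    start: int
    end: int
    vtype: str
    length: int
    id: str
    alt_seq: str | None = None

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise ValueError(f"unknown variant type {self.vtype!r}")
        if self.length < 1:
            raise ValueError(f"{self.id}: length must be >= 1, got {self.length}")
        if self.start < 0:
            raise ValueError(f"{self.id}: negative start {self.start}")
        if self.vtype in INSERTION_TYPES:
            if self.start != self.end:
                raise ValueError(
                    f"{self.id}: insertion must be an anchored point "
                    f"(start == end), got [{self.start}, {self.end})"
                )
        else:
            if self.end <= self.start:
                raise ValueError(
                    f"{self.id}: end must exceed start for {self.vtype}, "
                    f"got [{self.start}, {self.end})"
                )
        if self.vtype == "DEL" and self.length != self.end - self.start:
            raise ValueError(
                f"{self.id}: deletion length {self.length} != span "
                f"{self.end - self.start}"
            )
        if self.vtype == "SNP" and self.length != 1:
            raise ValueError(f"{self.id}: SNP length must be 1")

    @property
    def span(self) -> int:
        """Reference bases consumed (0 for anchored insertions)."""
        return self.end - self.start

    @property
    def affected_bp(self) -> int:
        """Sequence affected by carrying this variant, in bp.

        Deletions count deleted bases, insertions inserted bases, complex
        indels the larger of the replaced and replacing segment; duplications
        and inversions count their reference span.
        """
        return max(self.span, self.length)

    @property
    def size_class(self) -> str:
        return size_class(self.length)

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.vtype, self.length, self.id)


@dataclass(frozen=True)
class PedigreeSample:
    sample: str
    father: str | None
    mother: str | None
    family: str


@dataclass
class Pedigree:
    """A set of samples with (optional) parent links.

    Founders are samples whose parents are both absent from the pedigree.
    """

    samples: list[PedigreeSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample id(s) in pedigree: {dup}")
        self._by_id = {s.sample: s for s in self.samples}
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # walk ancestor chains; a sample reappearing on its own chain is a cycle
        for s in self.samples:
            seen = {s.sample}
            frontier = [p for p in (s.father, s.mother) if p in self._by_id]
            while frontier:
                cur = frontier.pop()
                if cur in seen:
                    raise ValueError(f"cyclic parentage involving {cur!r}")
                seen.add(cur)
                rec = self._by_id[cur]
                frontier.extend(
                    p for p in (rec.father, rec.mother) if p in self._by_id
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample for s in self.samples]

    def is_founder(self, sample: str) -> bool:
        rec = self._by_id[sample]
        return rec.father not in self._by_id and rec.mother not in self._by_id

    @property
    def founders(self) -> list[str]:
        return [s.sample for s in self.samples if self.is_founder(s.sample)]

    @property
    def offspring(self) -> list[str]:
        return [s.sample for s in self.samples if not self.is_founder(s.sample)]

    def trios(self) -> list[tuple[str, str, str]]:
        """(father, mother, child) triples where both parents are present."""
        out = []
        for s in self.samples:
            if s.father in self._by_id and s.mother in self._by_id:
                out.append((s.father, s.mother, s.sample))
        return out
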