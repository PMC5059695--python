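"""Algorithm-aware consensus merging of multi-caller SV call sets.

Calls are merged per variant type.  Calls larger than 20 bp cluster by
single-linkage under a 50% reciprocal overlap; a cluster becomes a consensus
variant only when it is supported by at least two distinct detection
strategies, and its boundaries are copied from the supporting call whose
caller has the best (lowest) breakpoint-accuracy rank.  Calls of 20 bp and
smaller must match exactly and require support from at least two distinct
callers (small-indel callers are all alignment-based, so requiring distinct
strategies would be vacuous there).

Insertions are anchored points, for which reciprocal overlap is undefined;
two insertion calls >20 bp are linked when their anchor points lie within
half the smaller inserted length of each other.

Single-linkage (transitive) clustering is used because it is independent of
input order; clique-based merging is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .io_formats import CallSet
from .records import INSERTION_TYPES, STRATEGIES, VariantRecord, _chrom_key_of

__all__ = [
    "CallerCall",
    "ConsensusVariant",
    "DEFAULT_STRATEGY_RANKS",
    "reciprocal_overlap",
    "calls_linked",
    "merge_callsets",
    "brute_force_merge_oracle",
    "callset_to_calls",
]

#: default breakpoint-accuracy rank per strategy (1 = most accurate
#: breakpoints).  Assembly resolves breakpoints at base resolution,
#: split-read almost so, read-pair within the insert-size spread, and
#: read-depth only to window resolution.
DEFAULT_STRATEGY_RANKS = {
    "assembly": 1,
    "split-read": 2,
    "read-pair": 3,
    "read-depth": 4,
}

#: calls at or below this length (bp) require exact coordinate identity
SMALL_VARIANT_BP = 20


@dataclass(frozen=True)
class CallerCall(VariantRecord):
    """A single call from one caller, with its provenance."""

    caller: str = "unknown"
    strategy: str = "split-read"
    accuracy_rank: int = 1

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"{self.id}: unknown strategy {self.strategy!r}; "
                f"expected one of {STRATEGIES}"
            )
        if self.accuracy_rank < 1:
            raise ValueError(f"{self.id}: accuracy_rank must be >= 1")


@dataclass(frozen=True)
class ConsensusVariant(VariantRecord):
    """A merged variant with its supporting calls.

    ``supporting_calls`` holds (caller, strategy) pairs; ``boundary_source``
    names the caller whose breakpoints were adopted.
    """

    supporting_calls: tuple[tuple[str, str], ...] = ()
    boundary_source: str = ""


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Reciprocal overlap of two half-open intervals.

    Returns ``min(|a ∩ b| / |a|, |a ∩ b| / |b|)``; symmetric in its
    arguments and 0 for disjoint intervals.
    """
    a0, a1 = a
    b0, b1 = b
    if a1 <= a0 or b1 <= b0:
        raise ValueError("reciprocal overlap is undefined for empty intervals")
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return min(inter / (a1 - a0), inter / (b1 - b0))


def calls_linked(a: VariantRecord, b: VariantRecord, min_ro: float = 0.5) -> bool:
    """Whether two >20 bp calls of the same type belong to one cluster."""
    if a.chrom != b.chrom or a.vtype != b.vtype:
        return False
    if a.vtype in INSERTION_TYPES:
        tol = min_ro * min(a.length, b.length)
        return abs(a.start - b.start) <= tol
    return reciprocal_overlap((a.start, a.end), (b.start, b.end)) >= min_ro


def _small_key(c: VariantRecord):
    return (c.chrom, c.start, c.end, c.vtype, c.length, c.alt_seq)


def _boundary_member(cluster: list[CallerCall]) -> CallerCall:
    return min(cluster, key=lambda c: (c.accuracy_rank, c.caller, c.sort_key()))


def _consensus_from_cluster(cluster: list[CallerCall], small: bool
                            ) -> ConsensusVariant | None:
    if small:
        if len({c.caller for c in cluster}) < 2:
            return None
    else:
        if len({c.strategy for c in cluster}) < 2:
            return None
    src = _boundary_member(cluster)
    support = tuple(sorted({(c.caller, c.strategy) for c in cluster}))
    return ConsensusVariant(
        chrom=src.chrom, start=src.start, end=src.end, vtype=src.vtype,
        length=src.length, id=src.id, alt_seq=src.alt_seq,
        supporting_calls=support, boundary_source=src.caller,
    )


def _finalize(consensus: list[ConsensusVariant]) -> list[ConsensusVariant]:
    consensus.sort(key=lambda c: (_chrom_key_of(c.chrom), c.sort_key()))
    out = []
    for k, c in enumerate(consensus):
        out.append(ConsensusVariant(
            chrom=c.chrom, start=c.start, end=c.end, vtype=c.vtype,
            length=c.length, id=f"CONS_{k:06d}", alt_seq=c.alt_seq,
            supporting_calls=c.supporting_calls,
            boundary_source=c.boundary_source,
        ))
    return out


def merge_callsets(calls: list[CallerCall], min_ro: float = 0.5
                   ) -> list[ConsensusVariant]:
    """Merge per-caller calls into a consensus call set.

    The output is sorted and deterministic, and invariant under permutation
    of the input.
    """
    small = [c for c in calls if c.length <= SMALL_VARIANT_BP]
    large = [c for c in calls if c.length > SMALL_VARIANT_BP]
    consensus: list[ConsensusVariant] = []

    # small calls: exact-identity grouping, >=2 distinct callers
    groups: dict[tuple, list[CallerCall]] = {}
    for c in small:
        groups.setdefault(_small_key(c), []).append(c)
    for cluster in groups.values():
        cons = _consensus_from_cluster(cluster, small=True)
        if cons is not None:
            consensus.append(cons)

    # large calls: single-linkage clustering via a sorted sweep + union-find
    by_type: dict[tuple[str, str], list[CallerCall]] = {}
    for c in large:
        by_type.setdefault((c.vtype, c.chrom), []).append(c)
    for group in by_type.values():
        group.sort(key=lambda c: c.sort_key())
        parent = list(range(len(group)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, ci in enumerate(group):
            # any partner j > i must start before i's reach
            if ci.vtype in INSERTION_TYPES:
                reach = ci.start + min_ro * ci.length
            else:
                reach = ci.end
            for j in range(i + 1, len(group)):
                if group[j].start > reach:
                    break
                if calls_linked(ci, group[j], min_ro):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
        clusters: dict[int, list[CallerCall]] = {}
        for i in range(len(group)):
            clusters.setdefault(find(i), []).append(group[i])
        for cluster in clusters.values():
            cons = _consensus_from_cluster(cluster, small=False)
            if cons is not None:
                consensus.append(cons)

    return _finalize(consensus)


def brute_force_merge_oracle(calls: list[CallerCall], min_ro: float = 0.5,
                             max_calls: int = 500) -> list[ConsensusVariant]:
    """Naive O(n^2) re-derivation of the consensus set, for testing.

    Builds the all-pairs linkage graph explicitly, takes connected
    components, and applies the same support and boundary rules.  Intended
    as an independent cross-check of :func:`merge_callsets` on small inputs.
    """
    if len(calls) > max_calls:
        raise ValueError(f"oracle capped at {max_calls} calls")
    consensus: list[ConsensusVariant] = []

    small = [c for c in calls if c.length <= SMALL_VARIANT_BP]
    g = nx.Graph()
    g.add_nodes_from(range(len(small)))
    for i in range(len(small)):
        for j in range(i + 1, len(small)):
            a, b = small[i], small[j]
            if (a.chrom, a.start, a.end, a.vtype, a.length, a.alt_seq) == \
               (b.chrom, b.start, b.end, b.vtype, b.length, b.alt_seq):
                g.add_edge(i, j)
    for comp in nx.connected_components(g):
        cluster = [small[i] for i in comp]
        cons = _consensus_from_cluster(cluster, small=True)
        if cons is not None:
            consensus.append(cons)

    large = [c for c in calls if c.length > SMALL_VARIANT_BP]
    g = nx.Graph()
    g.add_nodes_from(range(len(large)))
    for i in range(len(large)):
        for j in range(i + 1, len(large)):
            a, b = large[i], large[j]
            if a.chrom != b.chrom or a.vtype != b.vtype:
                continue
            if a.vtype in INSERTION_TYPES:
                linked = abs(a.start - b.start) <= min_ro * min(a.length, b.length)
            else:
                inter = min(a.end, b.end) - max(a.start, b.start)
                linked = inter > 0 and \
                    inter / (a.end - a.start) >= min_ro and \
                    inter / (b.end - b.start) >= min_ro
            if linked:
                g.add_edge(i, j)
    for comp in nx.connected_components(g):
        cluster = [large[i] for i in comp]
        cons = _consensus_from_cluster(cluster, small=False)
        if cons is not None:
            consensus.append(cons)

    return _finalize(consensus)


def callset_to_calls(callset: CallSet, caller: str | None = None,
                     strategy: str | None = None,
                     ranks: dict[str, int] | None = None) -> list[CallerCall]:
    """Attach caller provenance to the records of a :class:`CallSet`.

    Per-record CALLER/STRATEGY INFO values take precedence over the
    file-level defaults; the accuracy rank comes from ``ranks`` (keyed by
    strategy) and defaults to :data:`DEFAULT_STRATEGY_RANKS`.
    """
    ranks = dict(DEFAULT_STRATEGY_RANKS, **(ranks or {}))
    out = []
    for rec, c, s in zip(callset.records, callset.caller, callset.strategy):
        c = c or caller
        s = s or strategy
        if c is None or s is None:
            raise ValueError(f"{rec.id}: no caller/strategy tag available")
        out.append(CallerCall(
            chrom=rec.chrom, start=rec.start, end=rec.end, vtype=rec.vtype,
            length=rec.length, id=rec.id, alt_seq=rec.alt_seq,
            caller=c, strategy=s, accuracy_rank=ranks[s],
        ))
    return out
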