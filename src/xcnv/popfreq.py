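"""Population allele frequencies for CNVs.

Allele frequency here is carrier frequency: the fraction of samples in a
population group that carry the (unified) CNV.  A query CNV inherits the
frequency of a reference-database entry when the two share at least 70%
reciprocal overlap in size and location; with no qualifying entry the query
is assigned frequency zero (treated as unobserved in the population).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

from intervaltree import IntervalTree

from .core import CNVType, EthnicGroup, Interval, UnifiedCNV, overlap_bp

DEFAULT_RO_AF = 0.7


def reciprocal_overlap(a, b) -> float:
    """min over the two intervals of shared-bp / interval-length; symmetric."""
    ov = overlap_bp(a, b)
    if ov == 0:
        return 0.0
    la = a.end - a.start + 1
    lb = b.end - b.start + 1
    return min(ov / la, ov / lb)


@dataclass(frozen=True)
class AFEntry:
    """One reference CNV with its carrier frequencies."""

    interval: Interval
    cnv_type: CNVType
    af_overall: float
    af_by_group: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.af_overall <= 1.0:
            raise ValueError(f"af_overall outside [0,1]: {self.af_overall}")


@dataclass
class AFDatabase:
    """Reference CNV frequency database with per-group sample counts."""

    entries: list
    group_sizes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.group_sizes = {
            EthnicGroup.coerce(g): int(n) for g, n in self.group_sizes.items()
        }
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        self._trees = None

    def _tree_for(self, chrom: str, cnv_type: CNVType) -> IntervalTree:
        if self._trees is None:
            trees = defaultdict(IntervalTree)
            for e in self.entries:
                # half-open tree coordinates: [start, end + 1)
                trees[(e.interval.chrom, e.cnv_type)].addi(
                    e.interval.start, e.interval.end + 1, e
                )
            self._trees = dict(trees)
        return self._trees.get((chrom, cnv_type), IntervalTree())


def lookup_af(query, db: AFDatabase, ro_min: float = DEFAULT_RO_AF) -> float:
    """Carrier frequency of the best reciprocal-overlap match, or 0.0.

    Candidates are database entries of the same chromosome and CNV type with
    reciprocal overlap >= ``ro_min``; the entry with the highest overlap wins,
    ties going to the higher frequency.
    """
    if not 0.0 < ro_min <= 1.0:
        raise ValueError(f"ro_min must lie in (0, 1], got {ro_min}")
    qiv = Interval(query.chrom, query.start, query.end)
    best = None
    for hit in db._tree_for(qiv.chrom, CNVType.coerce(query.cnv_type)):
        entry = hit.data
        ro = reciprocal_overlap(qiv, entry.interval)
        if ro >= ro_min:
            key = (ro, entry.af_overall)
            if best is None or key > best[0]:
                best = (key, entry)
    return best[1].af_overall if best else 0.0


def group_allele_frequency(u: UnifiedCNV, group_sizes: dict) -> dict:
    """Per-group carrier fraction for a unified CNV.

    Raises if a member's group has no declared sample count or a declared
    count is zero (the frequency would be undefined).
    """
    sizes = {EthnicGroup.coerce(g): int(n) for g, n in group_sizes.items()}
    out = {}
    for g, n in sizes.items():
        if n <= 0:
            raise ValueError(f"group {g.value} has non-positive size {n}")
        out[g] = u.carriers_by_group.get(g, 0) / n
    missing = set(u.carriers_by_group) - set(sizes)
    if missing:
        names = ", ".join(sorted(g.value for g in missing))
        raise ValueError(f"no sample size declared for group(s): {names}")
    return out


def build_af_database(unified: list, group_sizes: dict) -> AFDatabase:
    """Assemble an AFDatabase from unified CNVs, computing frequencies."""
    sizes = {EthnicGroup.coerce(g): int(n) for g, n in group_sizes.items()}
    total = sum(sizes.values())
    entries = []
    for u in unified:
        af_by_group = group_allele_frequency(u, sizes)
        entries.append(
            AFEntry(
                interval=u.representative,
                cnv_type=u.cnv_type,
                af_overall=min(1.0, u.n_carriers / total) if total else 0.0,
                af_by_group=af_by_group,
            )
        )
    return AFDatabase(entries=entries, group_sizes=sizes)
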