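"""Contig profiling and multipartite replicon assignment.

Classifies each contig as mapped or excluded from its alignment hits and
guarantees that a contig is assigned to at most one replicon (the assignment
criterion is maximal aligned bp, ties broken lexicographically).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .align import AlignmentHit
from .io_formats import SequenceRecord

__all__ = [
    "ProfileThresholds",
    "ContigProfile",
    "UnalignedRegion",
    "interval_union_length",
    "profile_contig",
    "assign_replicon",
    "unaligned_reference_regions",
]

STATUS_MAPPED = "mapped"
STATUS_EXCLUDED_NO_HIT = "excluded_no_hit"
STATUS_EXCLUDED_LOW_COVERAGE = "excluded_low_coverage"
STATUS_EXCLUDED_SHORT = "excluded_short"


@dataclass(frozen=True)
class ProfileThresholds:
    """Cutoffs deciding mapped vs excluded status."""

    min_contig_length: int = 1000
    min_coverage: float = 0.20


@dataclass
class ContigProfile:
    contig_id: str
    length: int
    coverage_by_replicon: Dict[str, float] = field(default_factory=dict)
    aligned_bp_by_replicon: Dict[str, int] = field(default_factory=dict)
    best_replicon: Optional[str] = None
    status: str = STATUS_EXCLUDED_NO_HIT

    @property
    def best_coverage(self) -> float:
        return max(self.coverage_by_replicon.values(), default=0.0)


@dataclass(frozen=True)
class UnalignedRegion:
    """A reference interval with no hit coverage (0-based half-open)."""

    replicon_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def interval_union_length(intervals: Sequence[Tuple[int, int]]) -> int:
    """Total length of the union of 0-based half-open intervals."""
    total = 0
    right = None
    for s, e in sorted(intervals):
        if e <= s:
            continue
        if right is None or s > right:
            total += e - s
            right = e
        elif e > right:
            total += e - right
            right = e
    return total


def profile_contig(
    contig: SequenceRecord,
    hits: Sequence[AlignmentHit],
    thresholds: ProfileThresholds = ProfileThresholds(),
) -> ContigProfile:
    """Compute per-replicon coverage and mapped/excluded status for one contig.

    Status precedence: too short, then no hits, then below-coverage, else
    mapped (with ``best_replicon`` filled by :func:`assign_replicon`).
    """
    length = len(contig.sequence)
    prof = ContigProfile(contig_id=contig.id, length=length)
    by_rep: Dict[str, List[Tuple[int, int]]] = {}
    for h in hits:
        if h.contig_id != contig.id:
            raise ValueError(
                f"hit for contig {h.contig_id!r} passed while profiling {contig.id!r}"
            )
        by_rep.setdefault(h.replicon_id, []).append((h.qstart, h.qend))
    for rid, ivs in by_rep.items():
        aligned = interval_union_length(ivs)
        prof.aligned_bp_by_replicon[rid] = aligned
        prof.coverage_by_replicon[rid] = aligned / length
    if length < thresholds.min_contig_length:
        prof.status = STATUS_EXCLUDED_SHORT
    elif not by_rep:
        prof.status = STATUS_EXCLUDED_NO_HIT
    elif prof.best_coverage < thresholds.min_coverage:
        prof.status = STATUS_EXCLUDED_LOW_COVERAGE
    else:
        prof.status = STATUS_MAPPED
        prof.best_replicon = assign_replicon(prof)
    return prof


def assign_replicon(profile: ContigProfile) -> Optional[str]:
    """The single replicon this contig belongs to (max aligned bp, then id).

    Returns ``None`` for excluded contigs — the at-most-one-replicon
    guarantee of the pipeline rests on this function being a function.
    """
    if profile.status != STATUS_MAPPED or not profile.aligned_bp_by_replicon:
        return None
    return min(
        profile.aligned_bp_by_replicon,
        key=lambda rid: (-profile.aligned_bp_by_replicon[rid], rid),
    )


def unaligned_reference_regions(
    hits: Sequence[AlignmentHit],
    replicon_length: int,
    min_region_length: int = 1000,
    replicon_id: Optional[str] = None,
) -> List[UnalignedRegion]:
    """Reference intervals not covered by any hit, at least ``min_region_length`` long."""
    if replicon_id is None:
        replicon_id = hits[0].replicon_id if hits else ""
    ivs = sorted((h.sstart, h.send) for h in hits)
    regions: List[UnalignedRegion] = []
    cursor = 0
    for s, e in ivs:
        if s > cursor and s - cursor >= min_region_length:
            regions.append(UnalignedRegion(replicon_id, cursor, min(s, replicon_length)))
        cursor = max(cursor, e)
    if replicon_length - cursor >= min_region_length:
        regions.append(UnalignedRegion(replicon_id, cursor, replicon_length))
    return regions
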