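"""Order, orient and concatenate mapped contigs into an N-gapped pseudocontig.

Each contig assigned to a replicon gets a :class:`Placement` (orientation from
the majority strand of its hits, anchor = projected left edge of the best
hit).  Contigs spanning the origin of a circular reference are split in two,
with the start-matching part pinned to the head of the molecule and the
end-matching part to the tail.  Gaps between consecutive placements are
estimated from the reference projections and filled with Ns (at least
``min_spacer`` of them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .align import AlignmentHit, reverse_complement
from .io_formats import SequenceRecord

__all__ = [
    "Placement",
    "PseudoContig",
    "determine_orientation",
    "anchor_position",
    "detect_origin_spanning",
    "split_origin_contig",
    "order_contigs",
    "estimate_gap",
    "build_pseudocontig",
    "scaffold_replicon",
]

DEFAULT_MIN_SPACER = 100
DEFAULT_ORIGIN_WINDOW = 30000

SPLIT_NONE = "none"
SPLIT_LEFT = "left"  # start-matching part, pinned to the molecule head
SPLIT_RIGHT = "right"  # end-matching part, pinned to the molecule tail


@dataclass
class Placement:
    """One contig (or split part) placed on its assigned replicon.

    ``sequence`` is the oriented sequence actually pasted into the
    pseudocontig (reverse-complemented already when ``orientation == '-'``).
    ``anchor`` is the projected 0-based left edge on the reference.
    """

    contig_id: str
    replicon_id: str
    orientation: str
    anchor: int
    sequence: str
    order_index: Optional[int] = None
    split_part: str = SPLIT_NONE
    pseudo_start: Optional[int] = None
    pseudo_end: Optional[int] = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def label(self) -> str:
        if self.split_part == SPLIT_NONE:
            return self.contig_id
        return f"{self.contig_id}_{self.split_part}"


@dataclass
class PseudoContig:
    replicon_id: str
    sequence: str
    placements: List[Placement]
    gaps: List[Tuple[int, int, int]]  # (after_order_index, n_count, estimated_gap_bp)


def determine_orientation(hits: Sequence[AlignmentHit]) -> str:
    """Strand carrying the larger total of matched bases; ties go to '+'."""
    if not hits:
        raise ValueError("cannot orient a contig with no hits")
    plus = sum(h.matched for h in hits if h.strand == "+")
    minus = sum(h.matched for h in hits if h.strand == "-")
    return "-" if minus > plus else "+"


def anchor_position(
    hits: Sequence[AlignmentHit],
    orientation: str,
    contig_length: int,
    replicon_length: int,
) -> int:
    """Projected left edge of the (oriented) contig on the reference.

    Takes the highest-scoring hit on the chosen strand (falling back to the
    overall best) and subtracts the oriented query offset from its subject
    start, clamped to the replicon.
    """
    if not hits:
        raise ValueError("cannot anchor a contig with no hits")
    stranded = [h for h in hits if h.strand == orientation]
    best = max(stranded or hits, key=lambda h: (h.score, -h.qstart))
    if best.strand == "+":
        pos = best.sstart - best.qstart
    else:
        pos = best.sstart - (contig_length - best.qend)
    return max(0, min(pos, replicon_length - 1))


def detect_origin_spanning(
    hits: Sequence[AlignmentHit],
    replicon_length: int,
    circular: bool = True,
    min_hit_len: int = 100,
    origin_window: int = DEFAULT_ORIGIN_WINDOW,
) -> bool:
    """True iff the contig matches both ends of a circular reference.

    Requires hits of at least ``min_hit_len`` in the first and last
    ``origin_window`` bp with disjoint query intervals.
    """
    if not circular:
        return False
    w = min(origin_window, replicon_length // 2)
    head = [h for h in hits if h.span >= min_hit_len and h.sstart < w]
    tail = [h for h in hits if h.span >= min_hit_len and h.send > replicon_length - w]
    for h in head:
        for t in tail:
            if h is t:
                continue
            if min(h.qend, t.qend) <= max(h.qstart, t.qstart):
                return True
    return False


def _oriented_q(h: AlignmentHit, contig_length: int, orientation: str) -> Tuple[int, int]:
    """Query interval of a hit in oriented-contig coordinates."""
    if orientation == "+":
        return h.qstart, h.qend
    return contig_length - h.qend, contig_length - h.qstart


def split_origin_contig(
    contig: SequenceRecord,
    hits: Sequence[AlignmentHit],
    replicon_length: int,
    min_hit_len: int = 100,
    origin_window: int = DEFAULT_ORIGIN_WINDOW,
) -> Optional[Tuple[Placement, Placement]]:
    """Cut an origin-spanning contig into head/tail placements.

    The cut falls on the boundary between the query interval matching the
    reference end and the one matching the reference start; on the oriented
    contig the end-matching part comes first.  The start-matching ("left")
    part is pinned to the molecule head, the end-matching ("right") part to
    the tail.  Returns ``None`` when the cut is ambiguous (overlapping query
    intervals), in which case the caller should place the contig whole.
    """
    orientation = determine_orientation(hits)
    L = len(contig.sequence)
    w = min(origin_window, replicon_length // 2)
    stranded = [h for h in hits if h.strand == orientation and h.span >= min_hit_len]
    near_start = [h for h in stranded if h.sstart < w]
    near_end = [h for h in stranded if h.send > replicon_length - w]
    if not near_start or not near_end:
        return None
    hs = max(near_start, key=lambda h: h.score)
    he = max(near_end, key=lambda h: h.score)
    if hs is he:
        return None
    qs = _oriented_q(hs, L, orientation)
    qe = _oriented_q(he, L, orientation)
    if qe[1] > qs[0]:  # overlapping or out of order: ambiguous
        return None
    cut = qe[1]
    oriented = contig.sequence if orientation == "+" else reverse_complement(contig.sequence)
    tail_seq = oriented[:cut]
    head_seq = oriented[cut:]
    head = Placement(
        contig_id=contig.id,
        replicon_id=hs.replicon_id,
        orientation=orientation,
        anchor=max(0, hs.sstart - (qs[0] - cut)),
        sequence=head_seq,
        split_part=SPLIT_LEFT,
    )
    tail = Placement(
        contig_id=contig.id,
        replicon_id=he.replicon_id,
        orientation=orientation,
        anchor=max(0, min(he.sstart - qe[0], replicon_length - 1)),
        sequence=tail_seq,
        split_part=SPLIT_RIGHT,
    )
    return head, tail


def order_contigs(placements: Sequence[Placement]) -> List[Placement]:
    """Assign order indices: anchors ascending, ties by contig id.

    Origin-split parts are pinned: the start-matching part first, the
    end-matching part last.
    """
    heads = sorted((p for p in placements if p.split_part == SPLIT_LEFT),
                   key=lambda p: (p.anchor, p.contig_id))
    tails = sorted((p for p in placements if p.split_part == SPLIT_RIGHT),
                   key=lambda p: (p.anchor, p.contig_id))
    middle = sorted((p for p in placements if p.split_part == SPLIT_NONE),
                    key=lambda p: (p.anchor, p.contig_id))
    ordered = heads + middle + tails
    for i, p in enumerate(ordered):
        p.order_index = i
    return ordered


def estimate_gap(
    prev: Placement,
    nxt: Placement,
    min_spacer: int = DEFAULT_MIN_SPACER,
) -> Tuple[int, int]:
    """(estimated_gap_bp, n_count) between two consecutive placements.

    The estimate is the distance between the reference projections; it can be
    negative when projections overlap, but at least ``min_spacer`` Ns are
    always inserted so contigs never merge.
    """
    est = nxt.anchor - (prev.anchor + prev.length)
    return est, max(est, min_spacer)


def build_pseudocontig(
    ordered: Sequence[Placement],
    gaps: Sequence[Tuple[int, int, int]],
) -> PseudoContig:
    """Concatenate oriented placements with N runs; fill pseudo coordinates."""
    if not ordered:
        raise ValueError("no placements to build a pseudocontig from")
    n_by_index = {after: n for after, n, _ in gaps}
    parts: List[str] = []
    pos = 0
    for i, p in enumerate(ordered):
        p.pseudo_start = pos
        parts.append(p.sequence)
        pos += p.length
        p.pseudo_end = pos
        if i < len(ordered) - 1:
            n = n_by_index[i]
            parts.append("N" * n)
            pos += n
    return PseudoContig(
        replicon_id=ordered[0].replicon_id,
        sequence="".join(parts),
        placements=list(ordered),
        gaps=list(gaps),
    )


def scaffold_replicon(
    replicon: SequenceRecord,
    contigs: Dict[str, SequenceRecord],
    hits_by_contig: Dict[str, List[AlignmentHit]],
    circular: bool = True,
    origin_window: int = DEFAULT_ORIGIN_WINDOW,
    min_spacer: int = DEFAULT_MIN_SPACER,
    min_hit_len: int = 100,
) -> PseudoContig:
    """Full per-replicon scaffolding: orient, anchor, split, order, gap-fill.

    ``hits_by_contig`` must contain, for each assigned contig, its hits on
    *this* replicon only.
    """
    L = len(replicon.sequence)
    placements: List[Placement] = []
    for cid in sorted(contigs):
        contig = contigs[cid]
        hits = hits_by_contig[cid]
        orientation = determine_orientation(hits)
        split = None
        if circular and detect_origin_spanning(hits, L, circular, min_hit_len, origin_window):
            split = split_origin_contig(contig, hits, L, min_hit_len, origin_window)
        if split is not None:
            placements.extend(split)
        else:
            oriented = (contig.sequence if orientation == "+"
                        else reverse_complement(contig.sequence))
            placements.append(
                Placement(
                    contig_id=cid,
                    replicon_id=replicon.id,
                    orientation=orientation,
                    anchor=anchor_position(hits, orientation, len(contig.sequence), L),
                    sequence=oriented,
                )
            )
    ordered = order_contigs(placements)
    gaps = []
    for i in range(len(ordered) - 1):
        est, n = estimate_gap(ordered[i], ordered[i + 1], min_spacer)
        gaps.append((i, n, est))
    return build_pseudocontig(ordered, gaps)
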