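"""Gap-closure PCR primer design with a genome-wide uniqueness guarantee.

For every N-gap in a pseudocontig, candidate left primers are enumerated
exhaustively from the last ``window`` bp of the upstream contig and candidate
right primers from the reverse complement of the first ``window`` bp of the
downstream contig.  Candidates must pass length/Tm/GC/homopolymer/3'-self-
complementarity filters and occur exactly once (counting both strands) across
*all* input contigs.  The emitted pair minimises |Tm_left - Tm_right|, then
product size; gaps with no valid pair are reported unpaired.

Tm is the zero-parameter GC approximation ``64.9 + 41 * (nGC - 16.4) / len``
rounded to 0.01 degC — a deliberate, documented stand-in for thermodynamic
nearest-neighbour models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .align import reverse_complement
from .io_formats import SequenceRecord
from .scaffold import PseudoContig, Placement

__all__ = [
    "PrimerConstraints",
    "PrimerPair",
    "gc_fraction",
    "melting_temperature",
    "passes_filters",
    "occurrence_count",
    "design_gap_primers",
    "count_putatively_closed",
]

#: Maximum Tm difference tolerated within a pair, degC.
MAX_PAIR_TM_DIFF = 5.0


@dataclass(frozen=True)
class PrimerConstraints:
    min_length: int = 18
    max_length: int = 25
    min_tm: float = 57.0
    max_tm: float = 63.0
    min_gc: float = 30.0  # percent
    max_gc: float = 70.0  # percent
    max_homopolymer: int = 4
    max_three_prime_complementarity: int = 3
    window: int = 500
    max_product_size: int = 4000

    def __post_init__(self) -> None:
        if self.min_length > self.max_length or self.min_tm > self.max_tm:
            raise ValueError("empty length or Tm range")
        if self.window < self.max_length:
            raise ValueError("window must be at least the maximum primer length")


@dataclass
class PrimerPair:
    """A gap-flanking pair.  The right primer is on the minus strand.

    ``left_start`` is the 0-based pseudocontig coordinate of the left
    primer's 5' base; ``right_start`` that of the right primer's 5' base
    (its rightmost plus-strand position).  ``product_size`` spans the two
    5' ends inclusive and therefore includes the whole N gap.
    """

    gap_id: str
    left_seq: str
    right_seq: str
    left_start: int
    right_start: int
    tm_left: float
    tm_right: float
    gc_left: float
    gc_right: float
    product_size: int
    unique: bool = True
    left_contig: str = ""
    right_contig: str = ""


def gc_fraction(seq: str) -> float:
    """(G+C) / length of a DNA string."""
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(seq: str) -> float:
    """GC-count Tm approximation, valid for 10-40 nt oligos."""
    if not 10 <= len(seq) <= 40:
        raise ValueError(f"Tm formula valid for 10-40 nt, got {len(seq)}")
    n_gc = seq.count("G") + seq.count("C")
    return round(64.9 + 41.0 * (n_gc - 16.4) / len(seq), 2)


def _max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


_PAIRS = {"A": "T", "T": "A", "C": "G", "G": "C"}


def three_prime_complementarity(a: str, b: str) -> int:
    """Longest run of consecutive complementary pairs anchored at a's 3' base.

    Models antiparallel annealing of the 3' end of ``a`` onto ``b``: in a run
    of length r starting with b[j], ``a[-1-d]`` pairs with ``b[j+d]`` for
    d = 0..r-1.  ``b = a`` gives the self score.
    """
    best = 0
    la, lb = len(a), len(b)
    for j in range(lb):
        r = 0
        while r < la and j + r < lb and _PAIRS.get(a[-1 - r]) == b[j + r]:
            r += 1
        best = max(best, r)
    return best


def passes_filters(seq: str, constraints: PrimerConstraints = PrimerConstraints()) -> bool:
    """All per-primer constraints: length, Tm, GC%, homopolymer, 3' self-comp, no N."""
    c = constraints
    if not c.min_length <= len(seq) <= c.max_length:
        return False
    if "N" in seq:
        return False
    gc = gc_fraction(seq) * 100.0
    if not c.min_gc <= gc <= c.max_gc:
        return False
    tm = melting_temperature(seq)
    if not c.min_tm <= tm <= c.max_tm:
        return False
    if _max_homopolymer_run(seq) > c.max_homopolymer:
        return False
    if three_prime_complementarity(seq, seq) > c.max_three_prime_complementarity:
        return False
    return True


def _count_overlapping(haystack: str, needle: str) -> int:
    n = 0
    i = haystack.find(needle)
    while i != -1:
        n += 1
        i = haystack.find(needle, i + 1)
    return n


def occurrence_count(primer: str, contigs: Sequence[SequenceRecord]) -> int:
    """Exact occurrences of the primer on both strands across all contigs.

    Overlapping occurrences count; a palindromic primer is counted on each
    strand.  Uniqueness requires this to be exactly 1.
    """
    if not primer:
        raise ValueError("empty primer")
    rc = reverse_complement(primer)
    total = 0
    for c in contigs:
        total += _count_overlapping(c.sequence, primer)
        total += _count_overlapping(c.sequence, rc)
    return total


def _occurrence_count_joined(primer: str, joined: str) -> int:
    # joined = contigs concatenated with a separator absent from the alphabet,
    # so counts agree with occurrence_count over the record list.
    return _count_overlapping(joined, primer) + _count_overlapping(
        joined, reverse_complement(primer)
    )


def _enumerate_side(
    region: str,
    region_start: int,
    is_left: bool,
    constraints: PrimerConstraints,
) -> List[Tuple[str, int, float]]:
    """Filter-passing candidates from one gap flank (uniqueness checked later).

    For the left flank the candidate is the plus-strand substring itself; for
    the right flank it is the reverse complement of the substring (a
    minus-strand primer).  Returns (sequence, five_prime_coord, tm) tuples.
    """
    out: List[Tuple[str, int, float]] = []
    n = len(region)
    for length in range(constraints.min_length, constraints.max_length + 1):
        for i in range(n - length + 1):
            site = region[i : i + length]
            primer = site if is_left else reverse_complement(site)
            if not passes_filters(primer, constraints):
                continue
            five_prime = region_start + i if is_left else region_start + i + length - 1
            out.append((primer, five_prime, melting_temperature(primer)))
    return out


def design_gap_primers(
    pseudocontig: PseudoContig,
    contigs: Sequence[SequenceRecord],
    constraints: PrimerConstraints = PrimerConstraints(),
) -> List[PrimerPair]:
    """One best primer pair per inter-contig gap, where one exists.

    ``contigs`` is the *complete* input contig set (mapped and excluded alike);
    uniqueness is enforced against all of it.  Selection is deterministic:
    minimise |dTm|, then product size, then coordinates.
    """
    joined = "\x00".join(c.sequence for c in contigs)
    unique_cache: Dict[str, bool] = {}
    pairs: List[PrimerPair] = []
    placements = pseudocontig.placements
    seq = pseudocontig.sequence
    for after, n_count, _est in pseudocontig.gaps:
        up: Placement = placements[after]
        down: Placement = placements[after + 1]
        gap_id = f"{pseudocontig.replicon_id}_gap_{after + 1}"
        w_up = min(constraints.window, up.length)
        w_down = min(constraints.window, down.length)
        left_region_start = up.pseudo_end - w_up
        left_cands = _enumerate_side(
            seq[left_region_start : up.pseudo_end], left_region_start, True,
            constraints,
        )
        right_cands = _enumerate_side(
            seq[down.pseudo_start : down.pseudo_start + w_down], down.pseudo_start,
            False, constraints,
        )
        best = _select_pair(left_cands, right_cands, constraints, joined, unique_cache)
        if best is None:
            continue
        (lseq, lpos, ltm), (rseq, rpos, rtm) = best
        pairs.append(
            PrimerPair(
                gap_id=gap_id,
                left_seq=lseq,
                right_seq=rseq,
                left_start=lpos,
                right_start=rpos,
                tm_left=ltm,
                tm_right=rtm,
                gc_left=round(gc_fraction(lseq) * 100, 1),
                gc_right=round(gc_fraction(rseq) * 100, 1),
                product_size=rpos - lpos + 1,
                unique=True,
                left_contig=up.contig_id,
                right_contig=down.contig_id,
            )
        )
    return pairs


def _select_pair(
    left_cands: List[Tuple[str, int, float]],
    right_cands: List[Tuple[str, int, float]],
    constraints: PrimerConstraints,
    joined: str,
    unique_cache: Dict[str, bool],
) -> Optional[Tuple[Tuple[str, int, float], Tuple[str, int, float]]]:
    """Best feasible pair in (|dTm|, product, coords) order, or None.

    Uniqueness is checked lazily in selection order (with a cache), which
    yields the same pair as filtering every candidate up front but scans the
    genome only a handful of times per gap.
    """
    if not left_cands or not right_cands:
        return None

    def is_unique(primer: str) -> bool:
        got = unique_cache.get(primer)
        if got is None:
            got = _occurrence_count_joined(primer, joined) == 1
            unique_cache[primer] = got
        return got

    ltm = np.array([t for _, _, t in left_cands])
    rtm = np.array([t for _, _, t in right_cands])
    lpos = np.array([p for _, p, _ in left_cands])
    rpos = np.array([p for _, p, _ in right_cands])
    dtm = np.abs(ltm[:, None] - rtm[None, :])
    product = rpos[None, :] - lpos[:, None] + 1
    feasible = (dtm <= MAX_PAIR_TM_DIFF) & (product <= constraints.max_product_size) & (product > 0)
    if not feasible.any():
        return None
    li, ri = np.nonzero(feasible)
    order = np.lexsort((rpos[ri], lpos[li], product[li, ri], np.round(dtm[li, ri], 6)))
    for idx in order:
        i, j = int(li[idx]), int(ri[idx])
        lseq, rseq = left_cands[i][0], right_cands[j][0]
        if not is_unique(lseq) or not is_unique(rseq):
            continue
        if three_prime_complementarity(lseq, rseq) > constraints.max_three_prime_complementarity:
            continue
        if three_prime_complementarity(rseq, lseq) > constraints.max_three_prime_complementarity:
            continue
        return left_cands[i], right_cands[j]
    return None


def count_putatively_closed(
    placements: Sequence[Placement],
    pairs: Sequence[PrimerPair],
    adjacency: Set[frozenset],
) -> int:
    """Gaps whose flanking contigs are truly adjacent AND received a pair.

    ``adjacency`` is a set of frozensets of contig-id pairs that are adjacent
    on the reference (or in the synthetic ground truth).
    """
    paired = {(p.left_contig, p.right_contig) for p in pairs}
    ordered = sorted(placements, key=lambda p: p.order_index or 0)
    n = 0
    for a, b in zip(ordered, ordered[1:]):
        if a.contig_id == b.contig_id:
            continue
        if frozenset((a.contig_id, b.contig_id)) in adjacency and (
            (a.contig_id, b.contig_id) in paired
        ):
            n += 1
    return n
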