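"""Seed-and-chain local alignment of contigs against reference replicons.

The aligner is deliberately simple and fully deterministic: exact k-mer seeds
are extended to maximal exact matches, then chained per strand with a sparse
dynamic program.  Identity is an exact-match proxy (chained matched bases over
the chain span), which is sufficient for contig profiling and placement.

Defaults: k=15, max_gap=1000, max_diag_drift=200, min_hit_len=100,
min_identity=0.80, and k-mers occurring more than 50 times in the reference
are skipped during seeding (repeat guard).  All are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .io_formats import SequenceRecord

__all__ = [
    "SeedIndex",
    "Anchor",
    "AlignmentHit",
    "reverse_complement",
    "build_index",
    "find_anchors",
    "chain_anchors",
    "align_contig",
]

DEFAULT_K = 15
DEFAULT_MAX_GAP = 1000
DEFAULT_MAX_DIAG_DRIFT = 200
DEFAULT_MIN_HIT_LEN = 100
DEFAULT_MIN_IDENTITY = 0.80
DEFAULT_MAX_KMER_OCC = 50

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)
_IUPAC = frozenset("ACGTRYSWKMBDHVNacgtryswkmbdhvn")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string; IUPAC ambiguity codes supported."""
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError("non-IUPAC character(s): " + ", ".join(sorted(bad)))
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeedIndex:
    """Exact k-mer index of one reference replicon (N-containing k-mers skipped)."""

    k: int
    positions: Dict[str, List[int]]
    replicon_id: str
    replicon_length: int
    sequence: str = ""


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match between a contig strand and the reference.

    ``q`` is the 0-based offset on the *oriented* contig (i.e. on the
    reverse complement when ``strand == '-'``), so that q and s always run in
    the same direction within an anchor.
    """

    q: int
    s: int
    len: int
    strand: str


@dataclass
class AlignmentHit:
    """One chained local alignment of a contig region to a reference region.

    Query coordinates are 0-based half-open on the *forward* contig; subject
    coordinates are 0-based half-open on the reference.
    """

    contig_id: str
    replicon_id: str
    qstart: int
    qend: int
    sstart: int
    send: int
    strand: str
    matched: int
    identity: float
    score: int

    @property
    def span(self) -> int:
        return self.qend - self.qstart

    @property
    def s_span(self) -> int:
        return self.send - self.sstart


def build_index(replicon: SequenceRecord, k: int = DEFAULT_K) -> SeedIndex:
    """Index every N-free k-mer of the replicon with all its offsets."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    seq = replicon.sequence
    if len(seq) < k:
        raise ValueError(
            f"replicon {replicon.id!r} shorter ({len(seq)}) than k ({k})"
        )
    positions: Dict[str, List[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        positions.setdefault(kmer, []).append(i)
    return SeedIndex(k=k, positions=positions, replicon_id=replicon.id,
                     replicon_length=len(seq), sequence=seq)


def _anchors_one_strand(
    oriented: str, index: SeedIndex, strand: str, max_kmer_occ: int
) -> List[Anchor]:
    k = index.k
    ref = index.sequence
    ref_len = index.replicon_length
    n = len(oriented)
    covered: Dict[int, int] = {}  # diagonal -> q already extended through
    out: List[Anchor] = []
    get = index.positions.get
    for q in range(n - k + 1):
        offs = get(oriented[q : q + k])
        if offs is None or len(offs) > max_kmer_occ:
            continue
        for s in offs:
            diag = s - q
            if covered.get(diag, -1) >= q:
                continue
            ql, sl = q, s
            while ql > 0 and sl > 0 and oriented[ql - 1] == ref[sl - 1]:
                ql -= 1
                sl -= 1
            qr, sr = q + k, s + k
            while qr < n and sr < ref_len and oriented[qr] == ref[sr]:
                qr += 1
                sr += 1
            covered[diag] = qr
            out.append(Anchor(q=ql, s=sl, len=qr - ql, strand=strand))
    return out


def find_anchors(
    contig: SequenceRecord,
    index: SeedIndex,
    max_kmer_occ: int = DEFAULT_MAX_KMER_OCC,
) -> List[Anchor]:
    """All maximal exact extensions of shared k-mer seeds, both strands.

    Duplicates (the same maximal match reached from several seeds) are
    collapsed.  Returns an empty list when nothing matches.
    """
    if len(contig.sequence) < index.k:
        return []
    fwd = contig.sequence
    anchors = _anchors_one_strand(fwd, index, "+", max_kmer_occ)
    anchors += _anchors_one_strand(reverse_complement(fwd), index, "-", max_kmer_occ)
    # collapse exact duplicates, deterministic order
    uniq = sorted(set(anchors), key=lambda a: (a.strand, a.q, a.s, a.len))
    return uniq


def _chainable(a: Anchor, b: Anchor, max_gap: int, max_diag_drift: int) -> bool:
    if b.q <= a.q or b.s <= a.s:
        return False
    if b.q - (a.q + a.len) > max_gap:
        return False
    if b.s - (a.s + a.len) > max_gap:
        return False
    return abs((b.s - b.q) - (a.s - a.q)) <= max_diag_drift


def chain_anchors(
    anchors: Sequence[Anchor],
    max_gap: int = DEFAULT_MAX_GAP,
    max_diag_drift: int = DEFAULT_MAX_DIAG_DRIFT,
) -> List[List[Anchor]]:
    """Greedy extraction of disjoint best-scoring co-linear chains per strand.

    Two anchors chain iff both q and s strictly increase, neither gap exceeds
    ``max_gap`` and the diagonal drifts by at most ``max_diag_drift``.  Chain
    score is the sum of anchor lengths.  Chains are returned in descending
    score order.
    """
    chains: List[List[Anchor]] = []
    for strand in "+-":
        pool = sorted(
            (a for a in anchors if a.strand == strand),
            key=lambda a: (a.q, a.s, a.len),
        )
        while pool:
            n = len(pool)
            score = [a.len for a in pool]
            prev = [-1] * n
            for i in range(n):
                ai = pool[i]
                best = score[i]
                for j in range(i):
                    if _chainable(pool[j], ai, max_gap, max_diag_drift):
                        cand = score[j] + ai.len
                        if cand > best:
                            best = cand
                            prev[i] = j
                score[i] = best
            top = max(range(n), key=lambda i: (score[i], -pool[i].q, -pool[i].s))
            chain: List[Anchor] = []
            i = top
            while i != -1:
                chain.append(pool[i])
                i = prev[i]
            chain.reverse()
            chains.append(chain)
            used = set(map(id, chain))
            pool = [a for a in pool if id(a) not in used]
    chains.sort(key=lambda c: (-sum(a.len for a in c), c[0].strand, c[0].q))
    return chains


def chain_score(chain: Sequence[Anchor]) -> int:
    return sum(a.len for a in chain)


def _union_length(intervals: List[Tuple[int, int]]) -> int:
    total = 0
    end = -1
    for s, e in sorted(intervals):
        if s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def _chain_to_hit(
    chain: Sequence[Anchor], contig_id: str, contig_len: int, replicon_id: str
) -> AlignmentHit:
    strand = chain[0].strand
    q0, q1 = chain[0].q, chain[-1].q + chain[-1].len
    s0, s1 = chain[0].s, chain[-1].s + chain[-1].len
    mq = _union_length([(a.q, a.q + a.len) for a in chain])
    ms = _union_length([(a.s, a.s + a.len) for a in chain])
    matched = min(mq, ms)
    if strand == "-":
        qstart, qend = contig_len - q1, contig_len - q0
    else:
        qstart, qend = q0, q1
    identity = matched / max(q1 - q0, s1 - s0)
    return AlignmentHit(
        contig_id=contig_id,
        replicon_id=replicon_id,
        qstart=qstart,
        qend=qend,
        sstart=s0,
        send=s1,
        strand=strand,
        matched=matched,
        identity=identity,
        score=matched,
    )


def align_contig(
    contig: SequenceRecord,
    index: SeedIndex,
    min_hit_len: int = DEFAULT_MIN_HIT_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_gap: int = DEFAULT_MAX_GAP,
    max_diag_drift: int = DEFAULT_MAX_DIAG_DRIFT,
    max_kmer_occ: int = DEFAULT_MAX_KMER_OCC,
) -> List[AlignmentHit]:
    """Align one contig against an indexed replicon.

    Each extracted chain becomes one :class:`AlignmentHit`; hits shorter than
    ``min_hit_len`` (query span) or below ``min_identity`` are dropped.  Hits
    are sorted by score descending (ties by coordinates, deterministic).
    """
    anchors = find_anchors(contig, index, max_kmer_occ=max_kmer_occ)
    if not anchors:
        return []
    hits = []
    for chain in chain_anchors(anchors, max_gap=max_gap, max_diag_drift=max_diag_drift):
        hit = _chain_to_hit(chain, contig.id, len(contig.sequence), index.replicon_id)
        if hit.span < min_hit_len or hit.identity < min_identity:
            continue
        hits.append(hit)
    hits.sort(key=lambda h: (-h.score, h.qstart, h.sstart, h.strand))
    return hits
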