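"""Synthetic reference genomes and derived draft-contig sets with ground truth.

Everything every pipeline stage needs to be tested offline: multi-replicon
random genomes, fragmentation into ordered contigs separated by geometric
gaps, optional inversions, point mutations, origin-spanning fragments and
rejection-sampled contaminants guaranteed to share no seed k-mer with the
reference.  Fully deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .align import reverse_complement
from .io_formats import SequenceRecord, write_fasta

__all__ = [
    "ContigTruth",
    "AdjacentGap",
    "TruthTable",
    "generate_genome",
    "fragment_genome",
    "write_fixture",
]

CONTAMINANT_KMER = 15  # contaminants share no k-mer of this size with the reference
MIN_FRAGMENT = 1500


@dataclass(frozen=True)
class ContigTruth:
    """Where one contig really came from.

    ``start``/``end`` are 0-based half-open on the source replicon; an
    origin-spanning contig has ``start > end`` (it wraps).  Contaminants have
    no source replicon.
    """

    contig_id: str
    replicon_id: Optional[str]
    start: int
    end: int
    strand: str
    contaminant: bool = False
    origin_spanning: bool = False


@dataclass(frozen=True)
class AdjacentGap:
    replicon_id: str
    left_id: str
    right_id: str
    gap_bp: int


@dataclass
class TruthTable:
    contigs: Dict[str, ContigTruth] = field(default_factory=dict)
    adjacent_gaps: List[AdjacentGap] = field(default_factory=list)

    def true_order(self, replicon_id: str) -> List[str]:
        """Non-spanning contig ids of one replicon in ascending start order."""
        rows = [
            t for t in self.contigs.values()
            if t.replicon_id == replicon_id and not t.origin_spanning
        ]
        rows.sort(key=lambda t: t.start)
        return [t.contig_id for t in rows]

    def adjacency_set(self) -> Set[frozenset]:
        return {frozenset((g.left_id, g.right_id)) for g in self.adjacent_gaps}

    def gap_between(self, a: str, b: str) -> Optional[int]:
        key = frozenset((a, b))
        for g in self.adjacent_gaps:
            if frozenset((g.left_id, g.right_id)) == key:
                return g.gap_bp
        return None


_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def generate_genome(
    replicon_lengths: Sequence[int],
    gc: float = 0.5,
    seed: int = 0,
) -> List[SequenceRecord]:
    """I.i.d. random replicons with the requested GC content."""
    rng = np.random.default_rng(seed)
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    records = []
    for i, length in enumerate(replicon_lengths):
        if length < 10_000:
            raise ValueError("replicon lengths below 10 kb make poor fixtures")
        idx = rng.choice(4, size=length, p=p)
        seq = _ALPHABET[idx].tobytes().decode()
        records.append(SequenceRecord(id=f"replicon_{i + 1:02d}", description="synthetic", sequence=seq))
    return records


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size == 0:
        return seq
    cur = _BASE_INDEX[arr[hit]]
    shift = rng.integers(1, 4, size=hit.size)
    arr[hit] = _ALPHABET[(cur + shift) % 4]
    return arr.tobytes().decode()


def _reference_kmers(replicons: Sequence[SequenceRecord], k: int) -> Set[str]:
    kmers: Set[str] = set()
    for rep in replicons:
        s = rep.sequence
        for i in range(len(s) - k + 1):
            kmers.add(s[i : i + k])
    return kmers


def _sample_contaminant(
    rng: np.random.Generator, ref_kmers: Set[str], k: int
) -> str:
    for _ in range(100):
        length = int(rng.integers(1200, 3000))
        idx = rng.integers(0, 4, size=length)
        seq = _ALPHABET[idx].tobytes().decode()
        rc = reverse_complement(seq)
        if any(seq[i : i + k] in ref_kmers for i in range(length - k + 1)):
            continue
        if any(rc[i : i + k] in ref_kmers for i in range(length - k + 1)):
            continue
        return seq
    raise RuntimeError("could not sample a reference-free contaminant")


def _apportion(n_contigs: int, lengths: Sequence[int]) -> List[int]:
    total = sum(lengths)
    counts = [max(2, round(n_contigs * L / total)) for L in lengths]
    # fix rounding so the total is exact; adjust the largest replicon
    biggest = int(np.argmax(lengths))
    counts[biggest] += n_contigs - sum(counts)
    if counts[biggest] < 2:
        raise ValueError("n_contigs too small for the number of replicons")
    return counts


def fragment_genome(
    genome: Sequence[SequenceRecord],
    n_contigs: int,
    gap_mean: int = 300,
    inversion_prob: float = 0.0,
    mutation_rate: float = 0.0,
    n_contaminants: int = 0,
    origin_spanner: bool = False,
    seed: int = 0,
    min_fragment: int = MIN_FRAGMENT,
) -> Tuple[List[SequenceRecord], TruthTable]:
    """Fragment a genome into a shuffled draft contig set with ground truth.

    ``n_contigs`` is the total across replicons (apportioned by length, at
    least 2 each).  Inter-fragment gaps are geometric with mean ``gap_mean``
    (0 means abutting fragments).  Each fragment is independently
    reverse-complemented with ``inversion_prob`` and point-mutated at
    ``mutation_rate``.  With ``origin_spanner`` the first replicon gets one
    extra contig wrapping its origin.  Contaminants share no
    ``CONTAMINANT_KMER``-mer with the reference on either strand.
    """
    rng = np.random.default_rng(seed)
    truth = TruthTable()
    contigs: List[SequenceRecord] = []
    counts = _apportion(n_contigs, [len(r.sequence) for r in genome])
    serial = 0

    def next_id() -> str:
        nonlocal serial
        serial += 1
        return f"contig_{serial:04d}"

    for rep_i, (rep, n) in enumerate(zip(genome, counts)):
        L = len(rep.sequence)
        spanner_here = origin_spanner and rep_i == 0
        region_start, region_end = 0, L
        spanner_id = None
        head_gap = tail_gap = 0
        if spanner_here:
            a = int(rng.integers(800, 2500))  # tail portion length
            b = int(rng.integers(800, 2500))  # head portion length
            head_gap = max(1, int(rng.geometric(1.0 / max(gap_mean, 1))))
            tail_gap = max(1, int(rng.geometric(1.0 / max(gap_mean, 1))))
            region_start = b + head_gap
            region_end = L - a - tail_gap
            seq = rep.sequence[L - a :] + rep.sequence[:b]
            strand = "-" if rng.random() < inversion_prob else "+"
            if strand == "-":
                seq = reverse_complement(seq)
            seq = _mutate(seq, mutation_rate, rng)
            spanner_id = next_id()
            contigs.append(SequenceRecord(spanner_id, "origin spanner", seq))
            truth.contigs[spanner_id] = ContigTruth(
                spanner_id, rep.id, L - a, b, strand, origin_spanning=True
            )
        if gap_mean > 0:
            gaps = [max(1, int(rng.geometric(1.0 / gap_mean))) for _ in range(n - 1)]
        else:
            gaps = [0] * (n - 1)
        avail = (region_end - region_start) - sum(gaps) - n * min_fragment
        if avail < 0:
            raise ValueError(
                f"replicon {rep.id}: gaps plus minimum fragment sizes exceed its length"
            )
        extra = rng.multinomial(avail, [1.0 / n] * n)
        pos = region_start
        prev_id = None
        prev_gap = None
        for i in range(n):
            frag_len = min_fragment + int(extra[i])
            start, end = pos, pos + frag_len
            frag = rep.sequence[start:end]
            strand = "-" if rng.random() < inversion_prob else "+"
            if strand == "-":
                frag = reverse_complement(frag)
            frag = _mutate(frag, mutation_rate, rng)
            cid = next_id()
            contigs.append(SequenceRecord(cid, f"from {rep.id}", frag))
            truth.contigs[cid] = ContigTruth(cid, rep.id, start, end, strand)
            if prev_id is not None:
                truth.adjacent_gaps.append(AdjacentGap(rep.id, prev_id, cid, prev_gap))
            prev_id, prev_gap = cid, gaps[i] if i < n - 1 else None
            pos = end + (gaps[i] if i < n - 1 else 0)
        if spanner_here and spanner_id is not None:
            first_id = truth.true_order(rep.id)[0]
            truth.adjacent_gaps.append(AdjacentGap(rep.id, spanner_id, first_id, head_gap))
            truth.adjacent_gaps.append(AdjacentGap(rep.id, prev_id, spanner_id, tail_gap))

    if n_contaminants > 0:
        ref_kmers = _reference_kmers(genome, CONTAMINANT_KMER)
        for _ in range(n_contaminants):
            seq = _sample_contaminant(rng, ref_kmers, CONTAMINANT_KMER)
            cid = next_id()
            contigs.append(SequenceRecord(cid, "contaminant", seq))
            truth.contigs[cid] = ContigTruth(cid, None, 0, 0, "+", contaminant=True)

    order = rng.permutation(len(contigs))
    contigs = [contigs[i] for i in order]
    return contigs, truth


def write_fixture(
    genome: Sequence[SequenceRecord],
    contigs: Sequence[SequenceRecord],
    truth: TruthTable,
    outdir: Union[str, Path],
) -> None:
    """Write a fixture to disk: contigs.fasta, one reference FASTA, truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(contigs, outdir / "contigs.fasta")
    for rep in genome:
        write_fasta([rep], outdir / f"{rep.id}.fasta")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("contig_id\treplicon_id\tstart\tend\tstrand\tcontaminant\torigin_spanning\n")
        for t in sorted(truth.contigs.values(), key=lambda t: t.contig_id):
            fh.write(
                f"{t.contig_id}\t{t.replicon_id or '-'}\t{t.start}\t{t.end}\t"
                f"{t.strand}\t{int(t.contaminant)}\t{int(t.origin_spanning)}\n"
            )
    with open(outdir / "truth_gaps.tsv", "w") as fh:
        fh.write("replicon_id\tleft_id\tright_id\tgap_bp\n")
        for g in truth.adjacent_gaps:
            fh.write(f"{g.replicon_id}\t{g.left_id}\t{g.right_id}\t{g.gap_bp}\n")
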