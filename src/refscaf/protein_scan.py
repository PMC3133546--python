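"""Six-frame protein scan of excluded contigs.

Reference proteins lying wholly inside unaligned reference regions are
Smith-Waterman aligned (BLOSUM62, affine gaps 11/1) against all six reading
frames of every excluded contig.  No seeding — the excluded set is small by
construction.  Stop codons render as '*' and score -4 against everything via
the matrix, so they simply depress alignments that cross them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .align import reverse_complement
from .io_formats import ProteinFeature, SequenceRecord, TabFeature
from .profiling import UnalignedRegion

__all__ = [
    "FrameTranslation",
    "ProteinHit",
    "six_frame_translate",
    "select_unmapped_proteins",
    "local_align_protein",
    "scan_excluded_contigs",
]

DEFAULT_MIN_SCORE = 50
FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass
class FrameTranslation:
    """One reading frame of a contig, with aa -> nucleotide coordinate mapping."""

    contig_id: str
    frame: int  # +1..+3 forward, -1..-3 on the reverse complement
    aa_sequence: str
    contig_length: int

    def nt_interval(self, aa_index: int) -> Tuple[int, int]:
        """0-based half-open interval on the *forward* contig for one residue."""
        offset = abs(self.frame) - 1
        start = offset + 3 * aa_index
        end = start + 3
        if self.frame > 0:
            return start, end
        return self.contig_length - end, self.contig_length - start

    def nt_span(self, aa_start: int, aa_end: int) -> Tuple[int, int]:
        """Forward-contig interval covering residues [aa_start, aa_end)."""
        a = self.nt_interval(aa_start)
        b = self.nt_interval(aa_end - 1)
        return min(a[0], b[0]), max(a[1], b[1])


@dataclass
class ProteinHit:
    pid: str
    contig_id: str
    frame: int
    aa_start: int  # 0-based half-open on the query protein
    aa_end: int
    nt_start: int  # 0-based half-open on the forward contig
    nt_end: int
    score: int
    identity: float


def six_frame_translate(contig: SequenceRecord) -> List[FrameTranslation]:
    """Translate all six frames under the bacterial genetic code (table 11)."""
    if len(contig.sequence) < 3:
        raise ValueError(f"contig {contig.id!r} shorter than one codon")
    out = []
    fwd = contig.sequence
    rev = reverse_complement(fwd)
    for frame in FRAMES:
        src = fwd if frame > 0 else rev
        offset = abs(frame) - 1
        n_codons = (len(src) - offset) // 3
        chunk = src[offset : offset + 3 * n_codons]
        aa = str(Seq(chunk).translate(table=11)) if n_codons else ""
        out.append(
            FrameTranslation(
                contig_id=contig.id,
                frame=frame,
                aa_sequence=aa,
                contig_length=len(fwd),
            )
        )
    return out


def select_unmapped_proteins(
    features: Sequence[ProteinFeature],
    regions: Sequence[UnalignedRegion],
) -> List[ProteinFeature]:
    """Features lying wholly inside some unaligned reference region."""
    selected = []
    for f in features:
        s0, e0 = f.start - 1, f.end  # to 0-based half-open
        for r in regions:
            if r.start <= s0 and e0 <= r.end:
                selected.append(f)
                break
    return selected


def _make_aligner(gap_open: int, gap_extend: int, matrix_name: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align_protein(
    query: str,
    target: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> Tuple[int, List[Tuple[Tuple[int, int], Tuple[int, int]]], float]:
    """Optimal Smith-Waterman score, aligned blocks and identity.

    A gap of length g costs ``gap_open + (g - 1) * gap_extend``.  Returns
    ``(score, blocks, identity)`` where blocks pair 0-based half-open query
    and target intervals; identity is identical residues over aligned
    (non-gap) columns.  A non-positive optimum returns ``(0, [], 0.0)``.
    """
    if not query or not target:
        raise ValueError("empty protein sequence")
    aligner = _make_aligner(gap_open, gap_extend, matrix)
    score = aligner.score(query, target)
    if score <= 0:
        return 0, [], 0.0
    aln = next(iter(aligner.align(query, target)))
    q_blocks, t_blocks = aln.aligned
    blocks = []
    same = 0
    cols = 0
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        blocks.append(((int(qs), int(qe)), (int(ts), int(te))))
        for a, b in zip(query[qs:qe], target[ts:te]):
            cols += 1
            if a == b:
                same += 1
    identity = same / cols if cols else 0.0
    return int(score), blocks, identity


def scan_excluded_contigs(
    proteins: Sequence[ProteinFeature],
    excluded: Sequence[SequenceRecord],
    min_score: int = DEFAULT_MIN_SCORE,
) -> Tuple[List[ProteinHit], List[TabFeature]]:
    """Align each selected protein against all six frames of each excluded contig.

    Emits one :class:`ProteinHit` per (protein, contig, frame) whose best
    local score reaches ``min_score``, plus reference-coordinate tab features
    naming the matching contig for the viewer.
    """
    hits: List[ProteinHit] = []
    translations = {c.id: six_frame_translate(c) for c in excluded}
    for prot in proteins:
        if not prot.aa_sequence:
            continue
        for contig in excluded:
            for ft in translations[contig.id]:
                if not ft.aa_sequence:
                    continue
                score, blocks, identity = local_align_protein(prot.aa_sequence, ft.aa_sequence)
                if score < min_score or not blocks:
                    continue
                aa_start = blocks[0][0][0]
                aa_end = blocks[-1][0][1]
                t_start = blocks[0][1][0]
                t_end = blocks[-1][1][1]
                nt_start, nt_end = ft.nt_span(t_start, t_end)
                hits.append(
                    ProteinHit(
                        pid=prot.pid,
                        contig_id=contig.id,
                        frame=ft.frame,
                        aa_start=aa_start,
                        aa_end=aa_end,
                        nt_start=nt_start,
                        nt_end=nt_end,
                        score=score,
                        identity=identity,
                    )
                )
    hits.sort(key=lambda h: (-h.score, h.pid, h.contig_id, h.frame))
    by_pid: Dict[str, ProteinFeature] = {p.pid: p for p in proteins}
    features = [
        TabFeature(
            key="misc_feature",
            start=by_pid[h.pid].start,
            end=by_pid[h.pid].end,
            strand=by_pid[h.pid].strand,
            qualifiers=[
                ("label", h.pid),
                ("colour", 7),
                ("note", f"hit in excluded contig {h.contig_id} frame {h.frame} "
                         f"score {h.score} identity {h.identity:.2f}"),
            ],
        )
        for h in hits
    ]
    return hits, features
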