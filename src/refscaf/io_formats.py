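"""Readers and writers for the on-disk formats the pipeline touches.

Covers multi-record FASTA, the NCBI PTT protein-table dialect, ACT/MSPcrunch
comparison files and EMBL-style feature tables (Artemis ``.tab`` entries).

Coordinate convention: everything held in memory is 0-based half-open;
everything on disk is 1-based inclusive.  The conversion happens exactly once,
in the ``from_internal`` constructors / the writers below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "ProteinFeature",
    "CrunchHit",
    "TabFeature",
    "read_fasta",
    "write_fasta",
    "read_ptt",
    "write_crunch",
    "read_crunch",
    "write_tab",
]

#: Valid single-letter DNA codes (IUPAC ambiguity codes included).
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")


@dataclass
class SequenceRecord:
    """A named DNA sequence (the first header word is the id)."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(f"whitespace inside sequence of record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinFeature:
    """One CDS row from a PTT table, with its translated product."""

    ref_id: str
    start: int  # 1-based inclusive, as printed in the ptt
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    pid: str
    gene: str = ""
    product: str = ""
    aa_sequence: str = ""

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class CrunchHit:
    """One line of an ACT comparison (MSPcrunch) file.

    Coordinates are stored 1-based inclusive, i.e. exactly as printed.  A
    minus-strand match is encoded with ``sstart > send``; the query interval
    always has ``qstart <= qend``.
    """

    score: int
    percent_id: float
    qstart: int
    qend: int
    q_id: str
    sstart: int
    send: int
    s_id: str

    @classmethod
    def from_internal(
        cls,
        score: int,
        percent_id: float,
        q_interval: Tuple[int, int],
        q_id: str,
        s_interval: Tuple[int, int],
        s_id: str,
        strand: str = "+",
    ) -> "CrunchHit":
        """Build a hit from 0-based half-open intervals on both molecules.

        ``strand == '-'`` flips the printed subject coordinates.
        """
        q0, q1 = q_interval
        s0, s1 = s_interval
        if q0 >= q1 or s0 >= s1:
            raise ValueError("intervals must be non-empty half-open pairs")
        sstart, send = (s1, s0 + 1) if strand == "-" else (s0 + 1, s1)
        return cls(int(score), float(percent_id), q0 + 1, q1, q_id, sstart, send, s_id)


@dataclass
class TabFeature:
    """A feature destined for an EMBL-style .tab entry file.

    Coordinates are 1-based inclusive (on-disk semantics).  Qualifiers are an
    ordered list of ``(name, value)``; a value of ``None`` renders a bare
    ``/name`` flag, integers render unquoted, everything else is quoted.
    """

    key: str
    start: int
    end: int
    strand: str = "+"
    qualifiers: List[Tuple[str, Optional[Union[str, int]]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @classmethod
    def from_internal(
        cls,
        key: str,
        interval: Tuple[int, int],
        strand: str = "+",
        qualifiers: Optional[List[Tuple[str, Optional[Union[str, int]]]]] = None,
    ) -> "TabFeature":
        s, e = interval
        if s >= e:
            raise ValueError("interval must be a non-empty half-open pair")
        return cls(key, s + 1, e, strand, list(qualifiers or []))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> List[SequenceRecord]:
    """Read a (multi-)FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and validated against the IUPAC DNA alphabet.
    An empty file yields an empty list.
    """
    path = Path(path)
    text = path.read_text().lstrip()  # leading blank lines are legal
    if not text:
        return []
    records: List[SequenceRecord] = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains non-IUPAC character(s): "
                + ", ".join(sorted(bad))
            )
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, description=desc, sequence=seq))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: Union[str, Path], width: int = 60
) -> None:
    """Write records as wrapped FASTA (``width`` bases per sequence line)."""
    if width < 1:
        raise ValueError("width must be positive")
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# NCBI PTT
# ---------------------------------------------------------------------------

def read_ptt(
    path: Union[str, Path],
    reference: Optional[SequenceRecord] = None,
) -> List[ProteinFeature]:
    """Parse an NCBI-dialect PTT protein table.

    Expects two free-text header lines followed by a tab-separated column
    header beginning with ``Location``.  Rows whose Location cannot be parsed
    are skipped with a warning, as are rows whose span is not a multiple of 3
    (pseudogenes are common in real tables).

    If ``reference`` is given, each feature's protein sequence is derived by
    translating the reference span (bacterial code, table 11), with the
    trailing stop removed.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    ref_id = path.stem
    header_idx = None
    for i, line in enumerate(lines):
        if line.startswith("Location") and "\t" in line:
            header_idx = i
            break
    if header_idx is None:
        raise ValueError(f"{path}: no PTT column header line (expected 'Location\\t...')")
    columns = lines[header_idx].rstrip("\n").split("\t")
    try:
        i_loc = columns.index("Location")
        i_strand = columns.index("Strand")
        i_pid = columns.index("PID")
    except ValueError as exc:
        raise ValueError(f"{path}: PTT column header missing required column: {exc}")
    i_gene = columns.index("Gene") if "Gene" in columns else None
    i_prod = columns.index("Product") if "Product" in columns else None

    features: List[ProteinFeature] = []
    for lineno, line in enumerate(lines[header_idx + 1 :], header_idx + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        loc = fields[i_loc]
        try:
            s_txt, e_txt = loc.split("..")
            start, end = int(s_txt), int(e_txt)
        except (ValueError, IndexError):
            warnings.warn(f"{path}:{lineno}: unparsable Location {loc!r}, row skipped")
            continue
        if start > end:
            warnings.warn(f"{path}:{lineno}: Location {loc!r} has start > end, row skipped")
            continue
        if (end - start + 1) % 3 != 0:
            warnings.warn(
                f"{path}:{lineno}: span of {loc!r} not a multiple of 3, row skipped"
            )
            continue
        strand = fields[i_strand].strip()
        if strand not in "+-":
            warnings.warn(f"{path}:{lineno}: bad strand {strand!r}, row skipped")
            continue
        feat = ProteinFeature(
            ref_id=ref_id,
            start=start,
            end=end,
            strand=strand,
            pid=fields[i_pid].strip() if i_pid < len(fields) else "",
            gene=fields[i_gene].strip() if i_gene is not None and i_gene < len(fields) else "",
            product=fields[i_prod].strip() if i_prod is not None and i_prod < len(fields) else "",
        )
        if reference is not None:
            if end > len(reference.sequence):
                warnings.warn(f"{path}:{lineno}: {loc!r} beyond reference end, row skipped")
                continue
            feat.ref_id = reference.id
            nt = reference.sequence[start - 1 : end]
            if strand == "-":
                nt = str(Seq(nt).reverse_complement())
            aa = str(Seq(nt).translate(table=11))
            feat.aa_sequence = aa[:-1] if aa.endswith("*") else aa
        features.append(feat)
    return features


# ---------------------------------------------------------------------------
# ACT crunch comparison files
# ---------------------------------------------------------------------------

def write_crunch(hits: Iterable[CrunchHit], path: Union[str, Path]) -> None:
    """Write hits in MSPcrunch format, one space-separated line per hit."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.score} {h.percent_id:.1f} {h.qstart} {h.qend} {h.q_id} "
                f"{h.sstart} {h.send} {h.s_id}\n"
            )


def read_crunch(path: Union[str, Path]) -> List[CrunchHit]:
    """Parse a crunch file written by :func:`write_crunch`."""
    hits = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split()
        if len(f) != 8:
            raise ValueError(f"malformed crunch line: {line!r}")
        hits.append(
            CrunchHit(int(f[0]), float(f[1]), int(f[2]), int(f[3]), f[4],
                      int(f[5]), int(f[6]), f[7])
        )
    return hits


# ---------------------------------------------------------------------------
# EMBL feature tables (.tab)
# ---------------------------------------------------------------------------

_FT_PREFIX = "FT   "  # 'FT' + 3 blanks: feature key starts at column 6
_KEY_WIDTH = 16  # location starts at column 22, as in EMBL flat files


def _render_qualifier(name: str, value: Optional[Union[str, int]]) -> str:
    if value is None:
        return f"/{name}"
    if isinstance(value, int):
        return f"/{name}={value}"
    return f'/{name}="{value}"'


def write_tab(features: Iterable[TabFeature], path: Union[str, Path]) -> None:
    """Write an Artemis-loadable EMBL feature table.

    Each feature is a ``FT`` key/location line followed by one ``FT``
    continuation line per qualifier.  Minus-strand features use
    ``complement(start..end)``.
    """
    with open(path, "w") as fh:
        for feat in features:
            loc = f"{feat.start}..{feat.end}"
            if feat.strand == "-":
                loc = f"complement({loc})"
            fh.write(f"{_FT_PREFIX}{feat.key:<{_KEY_WIDTH}}{loc}\n")
            for name, value in feat.qualifiers:
                fh.write(f"{_FT_PREFIX}{'':<{_KEY_WIDTH}}{_render_qualifier(name, value)}\n")
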