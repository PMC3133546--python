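"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (per-base masks, exhaustive
enumeration, naive scans, a hand-rolled affine aligner) so that it shares no
code path with the package implementation it checks.
"""

from __future__ import annotations

import re
from typing import Dict, List, Sequence, Set, Tuple

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# k-mer index / maximal exact matches
# ---------------------------------------------------------------------------

def brute_kmer_positions(seq: str, k: int) -> Dict[str, List[int]]:
    """All N-free k-mers with all their offsets, by linear scan."""
    out: Dict[str, List[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        out.setdefault(kmer, []).append(i)
    return out


def brute_maximal_matches(query: str, ref: str, k: int) -> Set[Tuple[int, int, int]]:
    """All maximal exact matches of length >= k as (q, s, length) triples.

    O(|query| * |ref|) per-diagonal scan; a match is maximal when it cannot
    be extended on either side.
    """
    out: Set[Tuple[int, int, int]] = set()
    nq, nr = len(query), len(ref)
    for diag in range(-nq + 1, nr):
        q = max(0, -diag)
        s = q + diag
        run_start = None
        while q <= nq and s <= nr:
            inside = q < nq and s < nr and query[q] == ref[s]
            if inside and run_start is None:
                run_start = q
            if not inside and run_start is not None:
                length = q - run_start
                if length >= k:
                    out.add((run_start, run_start + diag, length))
                run_start = None
            q += 1
            s += 1
    return out


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def best_chain_score_exhaustive(
    anchors: Sequence, max_gap: int, max_diag_drift: int
) -> int:
    """Best co-linear chain score by depth-first enumeration of all chains."""

    def feasible(a, b) -> bool:
        if b.q <= a.q or b.s <= a.s:
            return False
        if b.q - (a.q + a.len) > max_gap or b.s - (a.s + a.len) > max_gap:
            return False
        return abs((b.s - b.q) - (a.s - a.q)) <= max_diag_drift

    best = 0

    def dfs(last, score, remaining):
        nonlocal best
        best = max(best, score)
        for i, a in enumerate(remaining):
            if last is None or feasible(last, a):
                dfs(a, score + a.len, remaining[i + 1 :])

    by_strand: Dict[str, list] = {}
    for a in anchors:
        by_strand.setdefault(a.strand, []).append(a)
    overall = 0
    for group in by_strand.values():
        best = 0
        dfs(None, 0, sorted(group, key=lambda a: (a.q, a.s)))
        overall = max(overall, best)
    return overall


# ---------------------------------------------------------------------------
# interval arithmetic by per-base boolean masks
# ---------------------------------------------------------------------------

def mask_union_length(intervals: Sequence[Tuple[int, int]], length: int) -> int:
    mask = [False] * length
    for s, e in intervals:
        for i in range(max(0, s), min(e, length)):
            mask[i] = True
    return sum(mask)


def mask_complement(
    intervals: Sequence[Tuple[int, int]], length: int, min_len: int
) -> List[Tuple[int, int]]:
    mask = [False] * length
    for s, e in intervals:
        for i in range(max(0, s), min(e, length)):
            mask[i] = True
    out = []
    i = 0
    while i < length:
        if not mask[i]:
            j = i
            while j < length and not mask[j]:
                j += 1
            if j - i >= min_len:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# primer helpers
# ---------------------------------------------------------------------------

def naive_occurrence_count(primer: str, sequences: Sequence[str]) -> int:
    """Sliding-window exact occurrence count of primer + its revcomp."""
    rc = naive_revcomp(primer)
    n = 0
    for seq in sequences:
        for i in range(len(seq) - len(primer) + 1):
            window = seq[i : i + len(primer)]
            if window == primer:
                n += 1
            if window == rc:
                n += 1
    return n


# ---------------------------------------------------------------------------
# affine-gap local alignment (independent Gotoh implementation)
# ---------------------------------------------------------------------------

def gotoh_local_score(
    query: str, target: str, matrix, gap_open: int = 11, gap_extend: int = 1
) -> int:
    """Smith-Waterman with affine gaps: a gap of length g costs open+(g-1)*extend.

    Plain-Python dynamic program, no traceback, written independently of the
    package's aligner.
    """
    n, m = len(query), len(target)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (target consumed)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            sub = matrix[query[i - 1], target[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


# ---------------------------------------------------------------------------
# EMBL feature-table grammar
# ---------------------------------------------------------------------------

_FT_LOCATION = re.compile(r"^(?:complement\()?\d+\.\.\d+\)?$")
_FT_QUALIFIER = re.compile(r'^/[A-Za-z_]+(?:=(?:\d+|"[^"]*"))?$')


def check_embl_feature_table(text: str) -> int:
    """Strict grammar check of a .tab feature table; returns feature count.

    Rules: every line starts with 'FT' + 3 blanks; a feature line has a key
    at column 6 and a location at column 22 matching ``[complement(]a..b[)]``
    with a <= b; continuation lines are blank through column 21 and carry a
    single /qualifier[=value]; the file must not start with a continuation.
    """
    n_features = 0
    saw_feature = False
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.startswith("FT   "):
            raise AssertionError(f"line {lineno}: does not start with 'FT   '")
        body = line[5:]
        if body[:16].strip():  # key present -> feature line
            key = body[:16].strip()
            if not re.fullmatch(r"[A-Za-z0-9_'-]+", key):
                raise AssertionError(f"line {lineno}: bad feature key {key!r}")
            loc = body[16:].strip()
            if not _FT_LOCATION.fullmatch(loc):
                raise AssertionError(f"line {lineno}: bad location {loc!r}")
            if loc.startswith("complement(") != loc.endswith(")"):
                raise AssertionError(f"line {lineno}: unbalanced complement() in {loc!r}")
            a, b = map(int, re.findall(r"\d+", loc)[:2])
            if not 1 <= a <= b:
                raise AssertionError(f"line {lineno}: location not 1-based ordered")
            n_features += 1
            saw_feature = True
        else:
            if not saw_feature:
                raise AssertionError(f"line {lineno}: continuation before any feature")
            qual = body[16:].strip()
            if not _FT_QUALIFIER.fullmatch(qual):
                raise AssertionError(f"line {lineno}: bad qualifier {qual!r}")
    return n_features


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------

def kendall_tau(order_a: Sequence[str], order_b: Sequence[str]) -> float:
    """Kendall rank correlation between two orderings of the same ids."""
    assert set(order_a) == set(order_b) and len(order_a) > 1
    rank_b = {x: i for i, x in enumerate(order_b)}
    seq = [rank_b[x] for x in order_a]
    concordant = discordant = 0
    for i in range(len(seq)):
        for j in range(i + 1, len(seq)):
            if seq[i] < seq[j]:
                concordant += 1
            else:
                discordant += 1
    total = concordant + discordant
    return (concordant - discordant) / total
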