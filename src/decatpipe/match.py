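"""Edit-distance kernel: Levenshtein distance, approximate substring search
and reverse complementation.

Every stage of the pipeline tolerates residual CCS errors (substitutions,
insertions and deletions alike), so all tolerances throughout the package are
full Levenshtein edit distance.  Pairwise distance is delegated to Biopython's
C ``PairwiseAligner`` (unit costs make the negated alignment score equal the
Levenshtein distance); occurrence search is a numpy semi-global dynamic
programme because no installed library exposes bounded all-occurrence search.

Coordinates are 0-based, half-open everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

__all__ = [
    "SubMatch",
    "edit_distance",
    "reverse_complement",
    "find_approx",
    "find_best",
]

_DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=0,
    mismatch_score=-1,
    open_gap_score=-1,
    extend_gap_score=-1,
)


@dataclass(frozen=True)
class SubMatch:
    """An approximate occurrence of a pattern inside a text.

    ``text[start:end]`` is the matched substring; ``dist`` is its Levenshtein
    distance to the pattern.
    """

    pattern_id: str
    start: int
    end: int
    dist: int


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance between two strings (unit sub/ins/del costs)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return int(-_aligner.score(a, b))


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (N maps to N)."""
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _end_distances(pattern: np.ndarray, text: np.ndarray) -> np.ndarray:
    """R[j] = min over s<=j of dist(pattern, text[s:j]) (free start, fixed end).

    Row-wise DP over the pattern; the within-row left dependency
    cur[j] = min(e[j], cur[j-1]+1) is resolved with a running-minimum scan:
    cur[j] = j + min_{k<=j}(e[k] - k).
    """
    n = text.size
    idx = np.arange(n + 1, dtype=np.int32)
    prev = np.zeros(n + 1, dtype=np.int32)
    for i in range(pattern.size):
        e = np.empty(n + 1, dtype=np.int32)
        e[0] = i + 1
        e[1:] = np.minimum(prev[:-1] + (pattern[i] != text), prev[1:] + 1)
        prev = np.minimum.accumulate(e - idx) + idx
    return prev


def _prefix_distances(pattern: np.ndarray, text: np.ndarray) -> np.ndarray:
    """row[c] = dist(pattern, text[:c]) for every prefix length c."""
    n = text.size
    idx = np.arange(n + 1, dtype=np.int32)
    prev = idx.astype(np.int32).copy()
    for i in range(pattern.size):
        e = np.empty(n + 1, dtype=np.int32)
        e[0] = i + 1
        e[1:] = np.minimum(prev[:-1] + (pattern[i] != text), prev[1:] + 1)
        prev = np.minimum.accumulate(e - idx) + idx
    return prev


def _candidates(
    pattern: str, text: str, max_err: int, window: tuple[int, int] | None
) -> list[tuple[int, int, int]]:
    """All (dist, start, end) with dist <= max_err, within the search window."""
    if not pattern:
        raise ValueError("empty pattern")
    if max_err < 0:
        raise ValueError("max_err must be >= 0")
    ws, we = (0, len(text)) if window is None else window
    if not (0 <= ws <= we <= len(text)):
        raise ValueError(f"window {(ws, we)} outside text bounds")
    sub = text[ws:we]
    if not sub:
        return []
    p = _encode(pattern)
    t = _encode(sub)
    ends = _end_distances(p, t)
    m = len(pattern)
    out: list[tuple[int, int, int]] = []
    rev_p = p[::-1]
    for j in np.nonzero(ends <= max_err)[0]:
        j = int(j)
        lo = max(0, j - m - max_err)
        # distances of pattern vs every suffix of sub[lo:j], via reversal
        row = _prefix_distances(rev_p, t[lo:j][::-1])
        for c in np.nonzero(row <= max_err)[0]:
            c = int(c)
            if c == 0 and m > max_err:
                continue
            out.append((int(row[c]), ws + j - c, ws + j))
    return out


def find_approx(
    pattern: str,
    text: str,
    max_err: int,
    window: tuple[int, int] | None = None,
    pattern_id: str = "",
) -> list[SubMatch]:
    """All minimal-distance, non-overlapping occurrences with dist <= max_err.

    Candidates are selected greedily best-first (smallest dist, then smallest
    start, then smallest end); a candidate overlapping an already selected
    occurrence is discarded.  The result is ordered by start.
    """
    cand = _candidates(pattern, text, max_err, window)
    cand.sort()
    chosen: list[tuple[int, int, int]] = []
    for d, s, e in cand:
        if all(e <= cs or s >= ce for _, cs, ce in chosen):
            chosen.append((d, s, e))
    chosen.sort(key=lambda x: x[1])
    return [SubMatch(pattern_id, s, e, d) for d, s, e in chosen]


def find_best(
    pattern: str,
    text: str,
    max_err: int,
    window: tuple[int, int] | None = None,
    pattern_id: str = "",
) -> SubMatch | None:
    """Single best occurrence under the (dist, start, end) tie-break, or None."""
    cand = _candidates(pattern, text, max_err, window)
    if not cand:
        return None
    d, s, e = min(cand)
    return SubMatch(pattern_id, s, e, d)
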