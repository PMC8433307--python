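"""Independent brute-force oracles used only by the test suite.

These deliberately avoid every code path of the package under test: plain
quadratic dynamic programming for Levenshtein distance, and exhaustive
substring enumeration for approximate occurrence search.
"""

from __future__ import annotations


def lev(a: str, b: str) -> int:
    """Textbook O(len(a)·len(b)) Levenshtein DP."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j - 1] + (a[i - 1] != b[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return prev[n]


def revcomp(seq: str) -> str:
    return "".join({"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[c] for c in reversed(seq))


def approx_occurrences(pattern, text, max_err, window=None):
    """All (dist, start, end) candidates by exhaustive substring scoring."""
    ws, we = (0, len(text)) if window is None else window
    m = len(pattern)
    out = []
    for s in range(ws, we + 1):
        for e in range(s, min(we, s + m + max_err) + 1):
            if e - s < m - max_err:
                continue
            if e == s and m > max_err:
                continue
            d = lev(pattern, text[s:e])
            if d <= max_err:
                out.append((d, s, e))
    return out


def greedy_best_nonoverlapping(candidates):
    """Best-first (dist, start, end) selection of non-overlapping occurrences."""
    chosen = []
    for d, s, e in sorted(candidates):
        if all(e <= cs or s >= ce for _, cs, ce in chosen):
            chosen.append((d, s, e))
    return sorted(chosen, key=lambda x: x[1])
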