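"""Demultiplexing: assign pooled reads to samples via terminal barcode pairs.

Each sample is encoded by a (forward, reverse) 16 nt barcode pair.  A read is
tried in the forward interpretation (forward barcode near the 5' end, the
paired reverse barcode near the 3' end) and in the reverse interpretation
(reverse complements of the pair, swapped ends); the winning interpretation
assigns the read to Set 1 (forward) or Set 2 (reverse) of its sample, with
both barcodes — and anything outside them — trimmed off.

Barcode pairs may share barcodes across samples (the original design encoded
nine samples with ten barcodes), so assignment always requires the *paired*
mate, never a single barcode.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .io import Read, StageLog
from .match import find_best, reverse_complement

__all__ = [
    "BarcodeTable",
    "DemuxResult",
    "Unassigned",
    "NO_5PRIME_BARCODE",
    "NO_3PRIME_MATE",
    "TOO_SHORT",
    "assign",
    "demux_pool",
]

NO_5PRIME_BARCODE = "no_5prime_barcode"
NO_3PRIME_MATE = "no_3prime_mate"
TOO_SHORT = "too_short"

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class BarcodeTable:
    """sample_id -> (forward barcode, reverse barcode).

    All barcodes in a table have equal length and every (fwd, rev) pair is
    unique; individual barcodes may be reused across pairs.
    """

    entries: dict

    def __post_init__(self):
        if not self.entries:
            raise ValueError("barcode table is empty")
        lengths = {len(b) for pair in self.entries.values() for b in pair}
        if len(lengths) != 1:
            raise ValueError(f"barcode lengths differ within table: {sorted(lengths)}")
        pairs = list(self.entries.values())
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (forward, reverse) barcode pair across samples")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.entries.values()))[0])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeTable":
        """Read a TSV with columns sample_id, forward_barcode, reverse_barcode."""
        entries = {}
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row or row[0].startswith("#") or row[0] == "sample_id":
                    continue
                sample, fwd, rev = row[0], row[1].upper(), row[2].upper()
                entries[sample] = (fwd, rev)
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tforward_barcode\treverse_barcode\n")
            for sample, (fwd, rev) in self.entries.items():
                fh.write(f"{sample}\t{fwd}\t{rev}\n")


@dataclass(frozen=True)
class DemuxResult:
    sample_id: str
    orientation: str  # "forward" (Set 1) or "reverse" (Set 2)
    payload: Read     # read with both barcodes (and anything outside) trimmed
    fwd_dist: int
    rev_dist: int


@dataclass(frozen=True)
class Unassigned:
    reason: str


def _window(read_len: int, barcode_len: int, tol_f: int, tol_r: int, override: int | None) -> int:
    if override is not None:
        return min(override, read_len)
    return min(barcode_len + 2 * max(tol_f, tol_r) + 8, read_len)


def assign(
    read: Read,
    table: BarcodeTable,
    tol_f: int = 2,
    tol_r: int = 2,
    window: int | None = None,
    min_payload: int = 1,
) -> DemuxResult | Unassigned:
    """Assign one read to a (sample, orientation) bin, or explain why not.

    Searches are restricted to terminal windows (default barcode length +
    2·tolerance + 8); ``window=len(read.seq)`` makes the search global.  When
    both interpretations succeed the lower total edit distance wins, ties
    going to the forward interpretation.
    """
    blen = table.barcode_length
    if tol_f >= blen or tol_r >= blen:
        raise ValueError("barcode tolerance must be smaller than the barcode length")
    seq = read.seq
    L = len(seq)
    if L < 2 * blen + min_payload:
        return Unassigned(TOO_SHORT)
    wlen = _window(L, blen, tol_f, tol_r, window)
    head = (0, wlen)
    tail = (L - wlen, L)

    best = {FORWARD: None, REVERSE: None}
    saw_head_hit = False
    for sample, (fwd, rev) in table.entries.items():
        for orient, p5, p3, t5, t3 in (
            (FORWARD, fwd, rev, tol_f, tol_r),
            (REVERSE, reverse_complement(rev), reverse_complement(fwd), tol_r, tol_f),
        ):
            h5 = find_best(p5, seq, t5, window=head)
            if h5 is None:
                continue
            saw_head_hit = True
            h3 = find_best(p3, seq, t3, window=tail)
            if h3 is None or h3.start < h5.end:
                continue
            # per-read barcode distances: (5' fwd-side, 3' rev-side) mapped
            # back to the table's forward/reverse barcodes
            fd, rd = (h5.dist, h3.dist) if orient == FORWARD else (h3.dist, h5.dist)
            cand = (h5.dist + h3.dist, sample, h5, h3, fd, rd)
            if best[orient] is None or cand[0] < best[orient][0]:
                best[orient] = cand

    pick = None
    for orient in (FORWARD, REVERSE):  # tie goes to forward
        c = best[orient]
        if c is not None and (pick is None or c[0] < pick[0][0]):
            pick = (c, orient)
    if pick is None:
        return Unassigned(NO_3PRIME_MATE if saw_head_hit else NO_5PRIME_BARCODE)

    (total, sample, h5, h3, fd, rd), orient = pick
    payload = seq[h5.end : h3.start]
    if len(payload) < min_payload:
        return Unassigned(TOO_SHORT)
    return DemuxResult(sample, orient, Read(read.id, payload), fd, rd)


def demux_pool(
    reads: Iterable[Read],
    table: BarcodeTable,
    tol_f: int = 2,
    tol_r: int = 2,
    window: int | None = None,
    min_payload: int = 1,
) -> tuple[dict, StageLog, list]:
    """Demultiplex a pool into per-sample (Set 1, Set 2) bins.

    Returns ``(bins, log, unassigned)`` where ``bins[sample] = (set1, set2)``
    holds payload Reads per orientation, ``log`` carries per-sample
    demultiplexed counts, and ``unassigned`` is a list of (Read, reason).
    Every input read lands in exactly one bin.
    """
    bins = {sample: ([], []) for sample in table.entries}
    unassigned: list[tuple[Read, str]] = []
    n_input = 0
    for read in reads:
        n_input += 1
        res = assign(read, table, tol_f=tol_f, tol_r=tol_r, window=window, min_payload=min_payload)
        if isinstance(res, Unassigned):
            unassigned.append((read, res.reason))
        elif res.orientation == FORWARD:
            bins[res.sample_id][0].append(res.payload)
        else:
            bins[res.sample_id][1].append(res.payload)
    log = StageLog(total_input=n_input)
    for sample, (s1, s2) in bins.items():
        log.set(sample, "demultiplexed", len(s1) + len(s2))
    return bins, log, unassigned
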