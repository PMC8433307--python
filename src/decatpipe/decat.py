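"""Deconcatenation: split demultiplexed payloads into their five genes.

Each gene in a forward-strand concatemer reads
``fwd_const (40 nt) + variable region + revcomp(rev_const) (22 nt)``, with a
4 nt Golden-Gate scar between consecutive genes.  Forward-orientation
payloads (Set 1) are split on approximate occurrences of the forward
constant; reverse-orientation payloads (Set 2) on the reverse constant
verbatim (which is how the gene-leading anchor reads on the reverse strand).
After splitting, sub-11 nt adapter-remnant artefacts are dropped, the
trailing constant (plus any scar behind it) is trimmed from each fragment,
and the trimmed variable regions are length-filtered.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .match import find_approx, find_best, reverse_complement

__all__ = [
    "ConstantRegions",
    "LengthBounds",
    "Variant",
    "split_payload",
    "remove_artifacts",
    "trim_tail",
    "length_filter",
    "audit_variants",
    "ARTIFACT_MAX_LEN",
]

FWD_CONST = "CGACTCACTATAGGGACAATTACTATTTACAATTACAATG"
REV_CONST = "GGCCAGATCCAGACATTCCCAT"

#: adapter-remnant artefacts of 1-10 nt are removed after splitting
ARTIFACT_MAX_LEN = 10

_SCAR_LEN = 4


@dataclass(frozen=True)
class ConstantRegions:
    """The two constant regions flanking every library variant.

    ``fwd_const`` is the 40 nt 5' constant as it appears in forward reads;
    ``rev_const`` is the 22 nt 3' constant in its canonical printed form,
    which appears in forward reads as its reverse complement.
    """

    fwd_const: str = FWD_CONST
    rev_const: str = REV_CONST

    def __post_init__(self):
        if not self.fwd_const or not self.rev_const:
            raise ValueError("constant regions must be non-empty")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConstantRegions":
        """Read a two-row TSV: ``forward\\t<seq>`` and ``reverse\\t<seq>``."""
        vals = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, seq = line.split("\t")
                vals[name.lower()] = seq.upper()
        return cls(fwd_const=vals["forward"], rev_const=vals["reverse"])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"forward\t{self.fwd_const}\nreverse\t{self.rev_const}\n")


@dataclass(frozen=True)
class LengthBounds:
    """Inclusive length window for trimmed variants (5% around the design length)."""

    nt_min: int = 707
    nt_max: int = 825
    aa_min_exclusive: int = 247

    def __post_init__(self):
        if self.nt_min > self.nt_max:
            raise ValueError("nt_min must be <= nt_max")


@dataclass(frozen=True)
class Variant:
    """A trimmed variable region recovered from one concatemer slot."""

    seq: str
    source_read: str
    slot: int | None  # 1-5 position within the amplicon, when unambiguous
    orientation: str


def split_payload(
    payload: str,
    orientation: str,
    consts: ConstantRegions | None = None,
    tol_f: int = 4,
    tol_r: int = 2,
) -> list[str]:
    """Split a payload into raw gene fragments on its constant-region anchors.

    Forward payloads anchor on the forward constant (tolerance ``tol_f``);
    reverse payloads anchor on the reverse constant (tolerance ``tol_r``).
    Anchors are removed; each fragment spans from one anchor's end to the next
    anchor's start (the last runs to the payload end).  A non-empty leading
    span before the first anchor is emitted too and left for the artefact and
    length filters.  Zero anchors yield the whole payload as one fragment.
    """
    consts = consts or ConstantRegions()
    if orientation == "forward":
        anchor, tol = consts.fwd_const, tol_f
    elif orientation == "reverse":
        anchor, tol = consts.rev_const, tol_r
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if not payload:
        return []
    hits = find_approx(anchor, payload, tol)
    if not hits:
        return [payload]
    frags: list[str] = []
    if hits[0].start > 0:
        frags.append(payload[: hits[0].start])
    for h, nxt in zip(hits, hits[1:]):
        frags.append(payload[h.end : nxt.start])
    frags.append(payload[hits[-1].end :])
    return frags


def remove_artifacts(fragments: list[str], max_len: int = ARTIFACT_MAX_LEN) -> list[str]:
    """Drop adapter-remnant fragments of length <= ``max_len`` (default 10)."""
    return [f for f in fragments if len(f) > max_len]


def trim_tail(
    fragment: str,
    orientation: str,
    consts: ConstantRegions | None = None,
    tol_f: int = 4,
    tol_r: int = 2,
    window: int | None = None,
) -> str | None:
    """Trim the trailing constant (and anything behind it) off a fragment.

    Forward fragments end in revcomp(rev_const) + optional scar; reverse
    fragments end in revcomp(fwd_const) + optional scar.  The tail is searched
    in a terminal window (default: tail length + 2·tolerance + scar + 8) and
    the fragment truncated at the best occurrence's start.  Restricting the
    search to the fragment end keeps fused multi-gene fragments long, so the
    length filter can reject them instead of silently salvaging their first
    gene.  Returns None (rejected) when no tail is found within tolerance.
    """
    consts = consts or ConstantRegions()
    if orientation == "forward":
        tail, tol = reverse_complement(consts.rev_const), tol_r
    elif orientation == "reverse":
        tail, tol = reverse_complement(consts.fwd_const), tol_f
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    wlen = window if window is not None else len(tail) + 2 * tol + _SCAR_LEN + 8
    lo = max(0, len(fragment) - wlen)
    hit = find_best(tail, fragment, tol, window=(lo, len(fragment)))
    if hit is None:
        return None
    return fragment[: hit.start]


def length_filter(variants: list, bounds: LengthBounds | None = None) -> list:
    """Keep variants whose length lies within the inclusive [nt_min, nt_max] window."""
    bounds = bounds or LengthBounds()
    def _len(v):
        return len(v.seq) if isinstance(v, Variant) else len(v)
    return [v for v in variants if bounds.nt_min <= _len(v) <= bounds.nt_max]


def audit_variants(
    variants: list[str],
    orientation: str,
    consts: ConstantRegions | None = None,
    tol_f: int = 4,
    tol_r: int = 2,
) -> list[str]:
    """Return variants still containing a constant region within tolerance.

    A clean deconcatenation output returns an empty list; survivors indicate
    incomplete splitting or trimming.
    """
    consts = consts or ConstantRegions()
    if orientation == "forward":
        probes = [(consts.fwd_const, tol_f), (reverse_complement(consts.rev_const), tol_r)]
    else:
        probes = [(consts.rev_const, tol_r), (reverse_complement(consts.fwd_const), tol_f)]
    dirty = []
    for v in variants:
        if any(find_best(p, v, t) is not None for p, t in probes):
            dirty.append(v)
    return dirty
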