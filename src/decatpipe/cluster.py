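"""Dereplication and greedy abundance-ordered centroid clustering.

Set 2 variants are reverse-complemented and merged with Set 1, dereplicated
into unique sequences with read counts, and clustered into families: walking
uniques in descending abundance, each sequence joins the first existing
family whose centre lies at Levenshtein distance strictly below the cutoff,
otherwise it founds a new family with itself as centre.  The centre is
therefore always its family's most abundant member, and ambiguous sequences
(within the cutoff of several centres) go to the earliest-founded, i.e. most
abundant, family.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .match import edit_distance, reverse_complement

__all__ = ["CountedSeq", "Family", "orient_merge", "dereplicate", "cluster_families", "family_curve"]


@dataclass(frozen=True)
class CountedSeq:
    """A unique sequence with its read count."""

    seq: str
    count: int

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class Family:
    """A cluster of sequences all within d_cutoff of the centre sequence."""

    family_id: int
    centre: CountedSeq
    members: list
    total_count: int
    d_cutoff: int


def orient_merge(set1: Iterable[str], set2: Iterable[str]) -> list[str]:
    """Merge orientation sets: Set 2 entries are reverse-complemented first."""
    return list(set1) + [reverse_complement(s) for s in set2]


def dereplicate(seqs: Iterable[str]) -> list[CountedSeq]:
    """Collapse to unique sequences with counts, sorted by descending count
    (ties broken lexicographically by sequence)."""
    counts = Counter(seqs)
    return [
        CountedSeq(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def _check_sorted(counted: Sequence[CountedSeq]) -> None:
    keys = [(-cs.count, cs.seq) for cs in counted]
    if keys != sorted(keys):
        raise ValueError("input must be abundance-sorted (dereplicate() output)")


def cluster_families(counted: Sequence[CountedSeq], d_cutoff: int) -> list[Family]:
    """Greedy centroid clustering in descending-abundance order.

    Membership requires distance to the centre strictly below ``d_cutoff``
    (so cutoff 0 puts every unique sequence in its own family).  Families are
    reported in founding order; every input appears in exactly one family.
    """
    if d_cutoff < 0:
        raise ValueError("d_cutoff must be >= 0")
    _check_sorted(counted)
    families: list[Family] = []
    for cs in counted:
        n = len(cs.seq)
        for fam in families:
            # |len(a)-len(b)| lower-bounds the Levenshtein distance: skip
            # centres that cannot possibly be within the cutoff
            if d_cutoff > 0 and abs(n - len(fam.centre.seq)) < d_cutoff \
                    and edit_distance(cs.seq, fam.centre.seq) < d_cutoff:
                fam.members.append(cs)
                fam.total_count += cs.count
                break
        else:
            families.append(Family(len(families) + 1, cs, [cs], cs.count, d_cutoff))
    return families


def family_curve(counted: Sequence[CountedSeq], cutoffs: Iterable[int]) -> dict[int, int]:
    """Number of families as a function of the distance cutoff."""
    return {c: len(cluster_families(counted, c)) for c in cutoffs}
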