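"""Dereplication and greedy centroid clustering."""

import numpy as np
import pytest

from decatpipe.cluster import (
    CountedSeq,
    cluster_families,
    dereplicate,
    family_curve,
    orient_merge,
)

from _oracles import lev


def test_orient_merge_examples():
    assert orient_merge(["ACGT"], ["ACGT"]) == ["ACGT", "ACGT"]  # palindrome
    assert orient_merge([], ["AAAA"]) == ["TTTT"]
    assert orient_merge(["AC"], []) == ["AC"]


def test_dereplicate_examples():
    assert dereplicate(["AC", "AC", "GT"]) == [CountedSeq("AC", 2), CountedSeq("GT", 1)]
    assert dereplicate([]) == []
    # equal counts tie-break lexicographically
    assert dereplicate(["GT", "AC"]) == [CountedSeq("AC", 1), CountedSeq("GT", 1)]


def test_dereplicate_multinomial_fixture():
    rng = np.random.default_rng(3)
    planted = ["AACCGGTT", "ACGTACGT", "TTTTAAAA"]
    draws = [planted[i] for i in rng.integers(0, 3, size=1000)]
    counted = dereplicate(draws)
    assert len(counted) == 3
    assert sum(cs.count for cs in counted) == 1000
    assert [cs.count for cs in counted] == sorted((cs.count for cs in counted), reverse=True)


def _mutate(seq, n):
    """n substitutions at distinct positions, each to a different base."""
    out = list(seq)
    for i in range(n):
        pos = (7 * i + 3) % len(seq)
        out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


def test_cluster_families_worked_example():
    rng = np.random.default_rng(5)
    a = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
    b = _mutate(a, 3)
    c = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
    assert lev(a, b) == 3
    assert lev(a, c) > 9 and lev(b, c) > 9
    counted = [CountedSeq(a, 10), CountedSeq(b, 7), CountedSeq(c, 5)]
    fams = cluster_families(counted, d_cutoff=9)
    assert len(fams) == 2
    assert fams[0].centre.seq == a and [m.seq for m in fams[0].members] == [a, b]
    assert fams[0].total_count == 17
    assert fams[1].centre.seq == c and fams[1].total_count == 5


def test_cluster_cutoff_zero_and_identical_pool():
    counted = dereplicate(["AAAA", "CCCC", "GGGG"])
    assert len(cluster_families(counted, 0)) == 3
    fams = cluster_families([CountedSeq("AAAA", 42)], 5)
    assert len(fams) == 1 and fams[0].total_count == 42


def test_cluster_requires_sorted_input():
    with pytest.raises(ValueError):
        cluster_families([CountedSeq("A", 1), CountedSeq("C", 5)], 3)


def test_cluster_contract_and_conservation():
    rng = np.random.default_rng(9)
    centres = ["".join("ACGT"[i] for i in rng.integers(0, 4, 50)) for _ in range(4)]
    seqs = []
    for c in centres:
        seqs += [c] * 5 + [_mutate(c, 2)] * 2 + [_mutate(c, 4)]
    counted = dereplicate(seqs)
    total = sum(cs.count for cs in counted)
    for cutoff in (0, 3, 5, 9):
        fams = cluster_families(counted, cutoff)
        assert sum(f.total_count for f in fams) == total
        seen = []
        for fam in fams:
            assert fam.centre in fam.members
            assert fam.centre.count == max(m.count for m in fam.members)
            for m in fam.members:
                seen.append(m.seq)
                if cutoff > 0:
                    assert lev(m.seq, fam.centre.seq) < cutoff
        assert sorted(seen) == sorted(cs.seq for cs in counted)


def test_greedy_equals_forced_assignment_when_unambiguous():
    """On instances where no sequence is within the cutoff of two potential
    centres, the clustering is fully forced and the greedy pass must find it."""
    rng = np.random.default_rng(21)
    cutoff = 5
    trials = 0
    while trials < 10:
        centres = ["".join("ACGT"[i] for i in rng.integers(0, 4, 40)) for _ in range(3)]
        if min(lev(a, b) for i, a in enumerate(centres) for b in centres[i + 1:]) <= 2 * cutoff:
            continue  # centres too close: membership could be ambiguous
        trials += 1
        seqs = []
        for k, c in enumerate(centres):
            seqs += [c] * (10 - k) + [_mutate(c, 2)] * 2
        counted = dereplicate(seqs)
        fams = cluster_families(counted, cutoff)
        assert len(fams) == 3
        # forced partition: every member belongs with its generating centre
        for fam in fams:
            for m in fam.members:
                dists = [lev(m.seq, c) for c in centres]
                assert min(dists) == lev(m.seq, fam.centre.seq)


def test_family_curve_monotone():
    rng = np.random.default_rng(13)
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
    seqs = [base] * 4
    for n in (1, 2, 3, 6, 9):
        seqs += [_mutate(base, n)]
    counted = dereplicate(seqs)
    cutoffs = list(range(0, 12))
    curve = family_curve(counted, cutoffs)
    assert curve[0] == len(counted)
    ns = [curve[c] for c in cutoffs]
    assert all(a >= b for a, b in zip(ns, ns[1:]))
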