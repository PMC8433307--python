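"""The synthetic concatemer-pool generator."""

import numpy as np
import pytest

from decatpipe.decat import ConstantRegions
from decatpipe.match import reverse_complement
from decatpipe.simulate import (
    DEFAULT_SCARS,
    SimParams,
    build_amplicon,
    corrupt,
    make_barcode_table,
    simulate_pool,
)

from _oracles import lev


def test_barcode_table_paper_mode_nine_pairs_from_ten():
    table = make_barcode_table(9, 10, min_pairwise_dist=6, seed=1)
    assert len(table.entries) == 9
    barcodes = {b for pair in table.entries.values() for b in pair}
    assert len(barcodes) == 10  # barcodes shared across pairs
    assert all(len(b) == 16 for b in barcodes)
    bl = sorted(barcodes)
    assert min(lev(a, b) for i, a in enumerate(bl) for b in bl[i + 1:]) >= 6


def test_barcode_table_unique_mode_eighteen_barcodes():
    table = make_barcode_table(9, 18, min_pairwise_dist=6, seed=1)
    barcodes = [b for pair in table.entries.values() for b in pair]
    assert len(set(barcodes)) == 18  # every barcode used exactly once


def test_barcode_table_infeasible_constraint_errors():
    with pytest.raises(ValueError):
        make_barcode_table(4, 4, min_pairwise_dist=5, seed=1, barcode_len=4)


def test_build_amplicon_length_formula():
    table = make_barcode_table(2, 4, min_pairwise_dist=2, seed=2)
    vs = ["A" * 766] * 5
    amp = build_amplicon("S1", vs, table)
    assert len(amp) == 2 * 16 + 5 * (40 + 766 + 22) + 4 * 4  # = 4188
    # degenerate single-gene amplicon
    one = build_amplicon("S1", ["ACGTAC"], table)
    fwd, rev = table.entries["S1"]
    consts = ConstantRegions()
    tail = reverse_complement(consts.rev_const)
    assert one == fwd + consts.fwd_const + "ACGTAC" + tail + rev
    with pytest.raises(ValueError):
        build_amplicon("S1", [], table)


def test_build_amplicon_junction_audit():
    table = make_barcode_table(2, 4, min_pairwise_dist=2, seed=2)
    vs = [b * 100 for b in ("AACCG", "AAGGC", "AATTC", "ACCGG", "ACGGT")]
    amp = build_amplicon("S1", vs, table)
    consts = ConstantRegions()
    assert amp.count(consts.fwd_const) == 5
    assert amp.count(reverse_complement(consts.rev_const)) == 5
    for scar in DEFAULT_SCARS:
        assert amp.count(scar) >= 1


def test_corrupt_zero_rates_identity():
    rng = np.random.default_rng(0)
    seq = "ACGT" * 100
    out, edits = corrupt(seq, 0.0, 0.0, 0.0, rng)
    assert out == seq and edits == []


def test_corrupt_forced_substitution():
    rng = np.random.default_rng(0)
    seq = "ACGT" * 25
    out, edits = corrupt(seq, 1.0, 0.0, 0.0, rng)
    assert len(out) == len(seq)
    assert all(a != b for a, b in zip(seq, out))
    assert len(edits) == len(seq)


def test_corrupt_substitution_rate_binomial():
    rng = np.random.default_rng(42)
    seq = "ACGT" * 2500  # 10,000 nt
    _, edits = corrupt(seq, 0.01, 0.0, 0.0, rng)
    n_sub = sum(e[0] == "sub" for e in edits)
    sigma = (10000 * 0.01 * 0.99) ** 0.5
    assert abs(n_sub - 100) < 3 * sigma


def test_corrupt_records_reconstruct_lengths():
    rng = np.random.default_rng(7)
    seq = "ACGT" * 1000
    out, edits = corrupt(seq, 0.01, 0.005, 0.005, rng)
    n_ins = sum(e[0] == "ins" for e in edits)
    n_del = sum(e[0] == "del" for e in edits)
    assert len(out) == len(seq) + n_ins - n_del


def test_simulate_pool_deterministic():
    a = simulate_pool(SimParams(n_samples=3, reads_per_sample=4, seed=5))
    b = simulate_pool(SimParams(n_samples=3, reads_per_sample=4, seed=5))
    assert [r.seq for r in a.reads] == [r.seq for r in b.reads]
    assert a.manifest.equals(b.manifest)


def test_simulate_pool_truncation_exact_count():
    pool = simulate_pool(SimParams(
        n_samples=5, reads_per_sample=20, truncation_fraction=0.2, seed=3,
        sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
    ))
    assert int(pool.manifest.truncated.sum()) == 20
    # truncated reads really lost their 3' barcode (at least 40 nt cut)
    reads = {r.id: r for r in pool.reads}
    for _, row in pool.manifest.query("truncated").iterrows():
        vs = [pool.variants[row.sample_id][int(j)] for j in row.slots.split(",")]
        amp_len = 2 * 16 + 5 * (40 + 22) + sum(len(v) for v in vs) + 4 * 4
        assert len(reads[row.read_id].seq) <= amp_len - 40


def test_simulate_pool_layout_matches_manifest(clean_pool):
    man = clean_pool.manifest
    reads = {r.id: r for r in clean_pool.reads}
    for _, row in man.sample(10, random_state=0).iterrows():
        vs = [clean_pool.variants[row.sample_id][int(j)] for j in row.slots.split(",")]
        amp = build_amplicon(row.sample_id, vs, clean_pool.table, clean_pool.consts)
        expected = amp if row.orientation == "forward" else reverse_complement(amp)
        assert reads[row.read_id].seq == expected
        L = sum(len(v) for v in vs)
        assert len(amp) == 2 * 16 + 5 * (40 + 22) + L + 4 * 4


def test_simulate_pool_write(tmp_path, clean_pool):
    clean_pool.write(tmp_path)
    for name in ("reads.fasta", "manifest.tsv", "barcodes.tsv", "constants.tsv", "variants.tsv"):
        assert (tmp_path / name).exists()
    first = (tmp_path / "reads.fasta").read_text().splitlines()[:2]
    assert first[0] == f">{clean_pool.reads[0].id}"
    assert first[1] == clean_pool.reads[0].seq


def test_sim_params_validation():
    with pytest.raises(ValueError):
        SimParams(sub_rate=1.5)
    with pytest.raises(ValueError):
        SimParams(genes_per_amplicon=0)
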