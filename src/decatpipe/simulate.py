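"""Synthetic concatemer CCS pool generator with ground-truth manifests.

Emulates the amplicon architecture of the fivefold Golden-Gate concatemer
design: a 16 nt sample barcode, five genes — each 40 nt forward constant +
variable region + 22 nt trailing constant — joined by 4 nt scars, and the
reverse barcode at the 3' end.  Reads are emitted in both orientations, with
a per-base substitution/insertion/deletion error model (defaults totalling
~1%, the Q20 floor of CCS consensus reads) and optional truncation artefacts
that leave only a single barcode.  A fixed seed makes pools byte-identical
across runs, and the manifest is sufficient to score any stage exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decat import ConstantRegions
from .demux import BarcodeTable
from .io import Read
from .match import edit_distance, reverse_complement

__all__ = [
    "SimParams",
    "SimPool",
    "DEFAULT_SCARS",
    "make_barcode_table",
    "build_amplicon",
    "corrupt",
    "simulate_pool",
]

#: four arbitrary distinct Golden-Gate scar 4-mers (configurable)
DEFAULT_SCARS = ("ACTG", "GTCA", "TGAC", "CAGT")

_BASES = b"ACGT"


@dataclass(frozen=True)
class SimParams:
    """Generative parameters; defaults mirror the published design."""

    n_samples: int = 9
    reads_per_sample: int = 50
    n_distinct_variants: int = 10
    variable_length: tuple[int, int] = (707, 825)  # uniform, inclusive
    barcode_len: int = 16
    n_unique_barcodes: int = 10
    barcode_min_dist: int = 6
    scar_len: int = 4
    genes_per_amplicon: int = 5
    sub_rate: float = 0.007
    ins_rate: float = 0.0015
    del_rate: float = 0.0015
    truncation_fraction: float = 0.0
    reverse_orientation_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for r in (self.sub_rate, self.ins_rate, self.del_rate,
                  self.truncation_fraction, self.reverse_orientation_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates/fractions must lie in [0, 1]")
        if self.genes_per_amplicon < 1:
            raise ValueError("genes_per_amplicon must be >= 1")


@dataclass
class SimPool:
    """A simulated pool: reads plus everything needed to score the pipeline."""

    reads: list
    manifest: pd.DataFrame
    table: BarcodeTable
    consts: ConstantRegions
    variants: dict            # sample_id -> list of planted variable regions
    errors: dict = field(default_factory=dict)  # read_id -> list of injected edits

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "reads.fasta", "w") as fh:
            for r in self.reads:
                fh.write(f">{r.id}\n{r.seq}\n")
        self.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
        self.table.to_tsv(outdir / "barcodes.tsv")
        self.consts.to_tsv(outdir / "constants.tsv")
        rows = [
            {"sample_id": s, "variant_index": i, "sequence": v}
            for s, vs in self.variants.items()
            for i, v in enumerate(vs)
        ]
        pd.DataFrame(rows).to_csv(outdir / "variants.tsv", sep="\t", index=False)


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(np.frombuffer(_BASES, dtype=np.uint8)[rng.integers(0, 4, length)]).decode()


def make_barcode_table(
    n_samples: int = 9,
    n_unique_barcodes: int = 10,
    min_pairwise_dist: int = 6,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    barcode_len: int = 16,
) -> BarcodeTable:
    """Random barcode table with a guaranteed pairwise edit-distance floor.

    The unique-barcode pool is split into forward and reverse halves and
    (fwd, rev) pairs are taken along shifted diagonals, so a pool smaller
    than 2×n_samples reuses barcodes across pairs (the published design used
    ten barcodes for nine pairs) while a pool of 2×n_samples yields fully
    unique pairing.
    """
    if n_unique_barcodes < 2:
        raise ValueError("need at least two unique barcodes")
    if rng is None:
        rng = np.random.default_rng(seed)
    for _ in range(200):
        bcs = [_rand_seq(rng, barcode_len) for _ in range(n_unique_barcodes)]
        if len(set(bcs)) == n_unique_barcodes and all(
            edit_distance(a, b) >= min_pairwise_dist
            for i, a in enumerate(bcs)
            for b in bcs[i + 1 :]
        ):
            break
    else:
        raise ValueError(
            f"could not draw {n_unique_barcodes} barcodes with pairwise "
            f"distance >= {min_pairwise_dist} after 200 attempts"
        )
    nf = (n_unique_barcodes + 1) // 2
    forwards, reverses = bcs[:nf], bcs[nf:]
    if n_samples > nf * len(reverses):
        raise ValueError("too few unique barcodes for the requested sample count")
    entries = {}
    for k in range(n_samples):
        f = forwards[k % nf]
        r = reverses[(k + k // nf) % len(reverses)]
        entries[f"S{k + 1}"] = (f, r)
    if len(set(entries.values())) != n_samples:
        raise ValueError("barcode pairing scheme produced duplicate pairs")
    return BarcodeTable(entries)


def build_amplicon(
    sample_id: str,
    variants: list[str],
    table: BarcodeTable,
    consts: ConstantRegions | None = None,
    scars: tuple[str, ...] = DEFAULT_SCARS,
) -> str:
    """Assemble one forward-strand concatemer amplicon.

    Layout: fwd_barcode + [fwd_const + variant + revcomp(rev_const)] per gene,
    genes joined by scars, + rev_barcode.  For g genes of equal length L the
    total length is 2·16 + g·(40 + L + 22) + (g−1)·4.
    """
    consts = consts or ConstantRegions()
    if len(variants) < 1:
        raise ValueError("need at least one variant")
    if len(scars) < len(variants) - 1:
        raise ValueError(f"need {len(variants) - 1} scars, got {len(scars)}")
    fwd_bc, rev_bc = table.entries[sample_id]
    tail = reverse_complement(consts.rev_const)
    parts = [fwd_bc]
    for i, v in enumerate(variants):
        parts.append(consts.fwd_const + v + tail)
        if i < len(variants) - 1:
            parts.append(scars[i])
    parts.append(rev_bc)
    return "".join(parts)


def corrupt(
    seq: str,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
) -> tuple[str, list[tuple]]:
    """Apply per-base independent substitution/insertion/deletion events.

    Insertions place a random base before the affected position; a deletion
    at a position overrides a substitution there.  Returns the corrupted
    sequence and the list of injected edits as (op, position, ref, alt)
    tuples in original coordinates.  Zero rates return the input unchanged.
    """
    n = len(seq)
    if n == 0 or (sub_rate == 0 and ins_rate == 0 and del_rate == 0):
        return seq, []
    u = rng.random((3, n))
    dels = u[0] < del_rate
    subs = u[1] < sub_rate
    inss = u[2] < ins_rate
    hit = np.nonzero(dels | subs | inss)[0]
    if hit.size == 0:
        return seq, []
    parts: list[str] = []
    edits: list[tuple] = []
    prev = 0
    for i in hit.tolist():
        parts.append(seq[prev:i])
        ref = seq[i]
        if inss[i]:
            base = chr(_BASES[rng.integers(0, 4)])
            parts.append(base)
            edits.append(("ins", i, "", base))
        if dels[i]:
            edits.append(("del", i, ref, ""))
        elif subs[i]:
            alts = "ACGT".replace(ref, "") if ref in "ACGT" else "ACGT"
            alt = alts[rng.integers(0, len(alts))]
            parts.append(alt)
            edits.append(("sub", i, ref, alt))
        else:
            parts.append(ref)
        prev = i + 1
    parts.append(seq[prev:])
    return "".join(parts), edits


def _scars_for(params: SimParams, rng: np.random.Generator) -> tuple[str, ...]:
    need = params.genes_per_amplicon - 1
    if need <= len(DEFAULT_SCARS) and params.scar_len == 4:
        return DEFAULT_SCARS[:need]
    scars: list[str] = []
    while len(scars) < need:
        s = _rand_seq(rng, params.scar_len)
        if s not in scars:
            scars.append(s)
    return tuple(scars)


def simulate_pool(params: SimParams | None = None, **overrides) -> SimPool:
    """Generate a deterministic simulated pool under ``params``.

    Reverse-orientation reads are emitted as reverse complements; an exact
    ``round(truncation_fraction × n_reads)`` subset of reads is cut short at
    a random interior point, removing the 3' barcode.
    """
    if params is None:
        params = SimParams(**overrides)
    elif overrides:
        raise TypeError("pass either params or keyword overrides, not both")
    rng = np.random.default_rng(params.seed)
    table = make_barcode_table(
        params.n_samples,
        params.n_unique_barcodes,
        params.barcode_min_dist,
        rng=rng,
        barcode_len=params.barcode_len,
    )
    consts = ConstantRegions()
    scars = _scars_for(params, rng)
    lo, hi = params.variable_length
    variants = {
        sample: [
            _rand_seq(rng, int(rng.integers(lo, hi + 1)))
            for _ in range(params.n_distinct_variants)
        ]
        for sample in table.entries
    }

    reads: list[Read] = []
    rows: list[dict] = []
    errors: dict[str, list] = {}
    idx = 0
    for sample in table.entries:
        n = params.reads_per_sample
        n_rev = int(round(params.reverse_orientation_fraction * n))
        rev_set = set(rng.choice(n, size=n_rev, replace=False).tolist()) if n_rev else set()
        for k in range(n):
            slots = rng.integers(0, params.n_distinct_variants, size=params.genes_per_amplicon)
            vs = [variants[sample][j] for j in slots.tolist()]
            amp = build_amplicon(sample, vs, table, consts, scars)
            seq, edits = corrupt(amp, params.sub_rate, params.ins_rate, params.del_rate, rng)
            orientation = "reverse" if k in rev_set else "forward"
            if orientation == "reverse":
                seq = reverse_complement(seq)
            read_id = f"read_{idx:06d}"
            reads.append(Read(read_id, seq))
            errors[read_id] = edits
            rows.append(
                {
                    "read_id": read_id,
                    "sample_id": sample,
                    "orientation": orientation,
                    "truncated": False,
                    "slots": ",".join(map(str, slots.tolist())),
                    "n_sub": sum(e[0] == "sub" for e in edits),
                    "n_ins": sum(e[0] == "ins" for e in edits),
                    "n_del": sum(e[0] == "del" for e in edits),
                }
            )
            idx += 1

    n_trunc = int(round(params.truncation_fraction * len(reads)))
    if n_trunc:
        for i in rng.choice(len(reads), size=n_trunc, replace=False).tolist():
            r = reads[i]
            # cut inside the read body so only the 5' barcode survives
            keep = int(rng.integers(20, max(21, len(r.seq) - 40)))
            reads[i] = Read(r.id, r.seq[:keep])
            rows[i]["truncated"] = True

    return SimPool(reads, pd.DataFrame(rows), table, consts, variants, errors)
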