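"""Sequence I/O, count tables and the per-stage run log.

FASTQ qualities are parsed and validated but ignored downstream: the CCS
consensus quality filter happens upstream of this pipeline, so FASTA and
FASTQ inputs are treated identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = ["Read", "StageLog", "read_sequences", "write_counts", "read_counts", "write_log"]

_FASTA_EXT = {".fa", ".fasta", ".fna", ".ffn"}
_FASTQ_EXT = {".fq", ".fastq"}


@dataclass(frozen=True)
class Read:
    """One sequencing record: identifier, sequence, optional quality string."""

    id: str
    seq: str
    qual: str | None = None


def _detect_format(path: Path) -> str:
    ext = path.suffix.lower()
    if ext in _FASTA_EXT:
        return "fasta"
    if ext in _FASTQ_EXT:
        return "fastq"
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line.startswith("@") else "fasta"
    return "fasta"  # empty file: format is moot


def read_sequences(path: str | Path, format: str = "auto") -> Iterator[Read]:
    """Stream records from a FASTA or FASTQ file in file order.

    Sequences are uppercased; ids (full header lines) are preserved verbatim.
    A malformed record raises ``ValueError`` naming its 0-based index.
    An empty file yields nothing.
    """
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    with open(path) as fh:
        if format == "fasta":
            it = SimpleFastaParser(fh)
            for i, (title, seq) in enumerate(it):
                if not seq:
                    raise ValueError(f"malformed record at index {i}: empty sequence")
                yield Read(title, seq.upper())
        else:
            it = FastqGeneralIterator(fh)
            i = 0
            while True:
                try:
                    title, seq, qual = next(it)
                except StopIteration:
                    break
                except ValueError as exc:
                    raise ValueError(f"malformed record at index {i}: {exc}") from exc
                if len(qual) != len(seq):
                    raise ValueError(
                        f"malformed record at index {i}: quality length "
                        f"{len(qual)} != sequence length {len(seq)}"
                    )
                if not seq:
                    raise ValueError(f"malformed record at index {i}: empty sequence")
                yield Read(title, seq.upper(), qual)
                i += 1


def write_counts(counted: Iterable, fasta_path: str | Path, tsv_path: str | Path | None = None) -> None:
    """Write dereplicated sequences as FASTA plus a TSV twin.

    Records are ranked by descending count (ties broken lexicographically by
    sequence) and labelled ``sequence_X`` where X is the 1-based rank; the
    FASTA header carries ``sequence_X count=N`` and the TSV columns are
    (label, sequence, count).
    """
    items = []
    for cs in counted:
        seq, count = (cs.seq, cs.count) if hasattr(cs, "seq") else (cs[0], cs[1])
        if count < 1:
            raise ValueError(f"count must be >= 1, got {count} for {seq!r}")
        items.append((seq, int(count)))
    items.sort(key=lambda x: (-x[1], x[0]))
    fasta_path = Path(fasta_path)
    if tsv_path is None:
        tsv_path = fasta_path.with_suffix(".tsv")
    with open(fasta_path, "w") as fa, open(tsv_path, "w") as tsv:
        tsv.write("label\tsequence\tcount\n")
        for rank, (seq, count) in enumerate(items, start=1):
            fa.write(f">sequence_{rank} count={count}\n{seq}\n")
            tsv.write(f"sequence_{rank}\t{seq}\t{count}\n")


def read_counts(tsv_path: str | Path) -> list[tuple[str, int]]:
    """Read back a count TSV written by :func:`write_counts` as (seq, count)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"label": str, "sequence": str, "count": int})
    return list(zip(df["sequence"], df["count"]))


@dataclass
class StageLog:
    """Per-sample record counts along the pipeline stages.

    ``counts[sample]`` holds ``{"demultiplexed": n, "deconcatenated": n,
    "length_filtered": n}``.  ``inputs`` optionally records the number of
    pool reads expected per sample (known for simulated pools) so a
    demultiplexing recovery percentage can be reported.  ``multiplicity`` is
    the number of genes per concatemer: deconcatenation recovery is computed
    against multiplicity × the demultiplexed count, since each concatemer
    should yield that many genes.
    """

    counts: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    total_input: int | None = None
    multiplicity: int = 5

    _STAGES = ("demultiplexed", "deconcatenated", "length_filtered")

    def set(self, sample: str, stage: str, n: int) -> None:
        if stage not in self._STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if n < 0:
            raise ValueError("counts are non-negative")
        self.counts.setdefault(sample, {s: 0 for s in self._STAGES})[stage] = int(n)

    def get(self, sample: str, stage: str) -> int:
        return self.counts.get(sample, {}).get(stage, 0)

    def total(self, stage: str) -> int:
        return sum(row.get(stage, 0) for row in self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        """One row per sample plus a Total row, with % recovered per stage."""
        rows = []
        samples = sorted(self.counts)
        for name in samples + ["Total"]:
            if name == "Total":
                dm = self.total("demultiplexed")
                dc = self.total("deconcatenated")
                lf = self.total("length_filtered")
                inp = self.total_input
                if inp is None and self.inputs:
                    inp = sum(self.inputs.values())
            else:
                row = self.counts[name]
                dm, dc, lf = (row[s] for s in self._STAGES)
                inp = self.inputs.get(name)
            rows.append(
                {
                    "sample": name,
                    "input": inp if inp is not None else "",
                    "demultiplexed": dm,
                    "demux_pct": round(100.0 * dm / inp, 1) if inp else "",
                    "deconcatenated": dc,
                    "deconcat_pct": round(100.0 * dc / (self.multiplicity * dm), 1) if dm else 0.0,
                    "length_filtered": lf,
                    "length_pct": round(100.0 * lf / dc, 1) if dc else 0.0,
                }
            )
        return pd.DataFrame(rows)


def write_log(log: StageLog, path: str | Path) -> None:
    """Write the stage log as TSV (one row per sample plus a Total row)."""
    log.to_frame().to_csv(path, sep="\t", index=False)
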