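"""End-to-end orchestration: demultiplex -> deconcatenate -> trim -> length
filter -> orientation merge -> dereplicate -> (cluster) -> (translate).

``process_reads`` is the in-memory core; ``run_pipeline`` adds file I/O
around it for the command line.
"""

from __future__ import annotations

import sys
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .cluster import CountedSeq, Family, cluster_families, dereplicate, orient_merge
from .decat import (
    ConstantRegions,
    LengthBounds,
    Variant,
    length_filter,
    remove_artifacts,
    split_payload,
    trim_tail,
)
from .demux import BarcodeTable, demux_pool
from .io import Read, StageLog, read_sequences, write_counts, write_log
from .translate import PeptideCount, translate, translate_families

__all__ = ["PipelineConfig", "PipelineResult", "process_reads", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All user-facing parameters of a pipeline run."""

    input: str
    barcodes: str
    out: str
    constants: str | None = None
    tol_bc_f: int = 2
    tol_bc_r: int = 2
    bc_window: int | None = None
    tol_const_f: int = 4
    tol_const_r: int = 2
    nt_min: int = 707
    nt_max: int = 825
    aa_min_exclusive: int = 247
    d_cutoff: int | None = None
    translate: bool = False
    multiplicity: int = 5

    def __post_init__(self):
        for t in (self.tol_bc_f, self.tol_bc_r, self.tol_const_f, self.tol_const_r):
            if t < 0:
                raise ValueError("tolerances must be >= 0")
        if self.nt_min > self.nt_max:
            raise ValueError("nt_min must be <= nt_max")


@dataclass
class PipelineResult:
    log: StageLog
    unassigned: list                     # (Read, reason) pairs
    variants: dict                       # sample -> (set1 Variants, set2 Variants), trimmed
    filtered: dict                       # sample -> (set1 Variants, set2 Variants), length-passed
    unique: dict                         # sample -> list of CountedSeq
    families: dict = field(default_factory=dict)   # sample -> list of Family (if clustered)
    peptides: dict = field(default_factory=dict)   # sample -> list of PeptideCount (if translated)
    rejects: dict = field(default_factory=dict)    # sample -> {"artifact": n, "no_tail": n}


def _deconcat_set(payloads, orientation, consts, tol_f, tol_r, multiplicity):
    variants: list[Variant] = []
    rejects = Counter()
    for payload in payloads:
        frags = split_payload(payload.seq, orientation, consts, tol_f, tol_r)
        kept = remove_artifacts(frags)
        rejects["artifact"] += len(frags) - len(kept)
        exact = len(kept) == multiplicity
        for si, frag in enumerate(kept):
            trimmed = trim_tail(frag, orientation, consts, tol_f, tol_r)
            if trimmed is None:
                rejects["no_tail"] += 1
                continue
            if exact:
                slot = si + 1 if orientation == "forward" else multiplicity - si
            else:
                slot = None
            variants.append(Variant(trimmed, payload.id, slot, orientation))
    return variants, rejects


def process_reads(
    reads,
    table: BarcodeTable,
    consts: ConstantRegions | None = None,
    config: PipelineConfig | None = None,
    sample_inputs: dict | None = None,
) -> PipelineResult:
    """Run every pipeline stage on an in-memory read collection.

    ``sample_inputs`` optionally maps sample ids to the number of pool reads
    expected for that sample (known for simulated pools), enabling a
    demultiplexing-recovery percentage in the stage log.
    """
    cfg = config or PipelineConfig(input="", barcodes="", out="")
    consts = consts or ConstantRegions()
    bounds = LengthBounds(cfg.nt_min, cfg.nt_max, cfg.aa_min_exclusive)

    bins, log, unassigned = demux_pool(
        reads, table, tol_f=cfg.tol_bc_f, tol_r=cfg.tol_bc_r, window=cfg.bc_window
    )
    log.multiplicity = cfg.multiplicity
    if sample_inputs:
        log.inputs.update(sample_inputs)

    result = PipelineResult(log, unassigned, {}, {}, {})
    for sample, (set1, set2) in bins.items():
        v1, rej1 = _deconcat_set(set1, "forward", consts, cfg.tol_const_f, cfg.tol_const_r, cfg.multiplicity)
        v2, rej2 = _deconcat_set(set2, "reverse", consts, cfg.tol_const_f, cfg.tol_const_r, cfg.multiplicity)
        log.set(sample, "deconcatenated", len(v1) + len(v2))
        f1 = length_filter(v1, bounds)
        f2 = length_filter(v2, bounds)
        log.set(sample, "length_filtered", len(f1) + len(f2))
        merged = orient_merge([v.seq for v in f1], [v.seq for v in f2])
        unique = dereplicate(merged)
        result.variants[sample] = (v1, v2)
        result.filtered[sample] = (f1, f2)
        result.unique[sample] = unique
        result.rejects[sample] = dict(rej1 + rej2)
        if cfg.d_cutoff is not None:
            result.families[sample] = cluster_families(unique, cfg.d_cutoff)
        if cfg.translate:
            if cfg.d_cutoff is not None:
                result.peptides[sample] = translate_families(
                    result.families[sample], cfg.aa_min_exclusive
                )
            else:
                # no nucleotide-level clustering requested: dereplicate
                # peptides across the whole sample as one pool
                counts: Counter = Counter()
                for cs in unique:
                    counts[translate(cs.seq)] += cs.count
                result.peptides[sample] = [
                    PeptideCount(0, aa, n)
                    for aa, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
                    if len(aa) > cfg.aa_min_exclusive
                ]
    return result


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: read inputs, process, write all outputs."""
    table = BarcodeTable.from_tsv(config.barcodes)
    consts = ConstantRegions.from_tsv(config.constants) if config.constants else ConstantRegions()
    reads = read_sequences(config.input)
    result = process_reads(reads, table, consts, config)

    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    if result.log.total("demultiplexed") == 0:
        print("warning: zero reads assigned to any sample", file=sys.stderr)
    for sample, unique in result.unique.items():
        write_counts(unique, outdir / f"{sample}_unique.fasta", outdir / f"{sample}_unique.tsv")
    if result.families:
        with open(outdir / "families.tsv", "w") as fh:
            fh.write("sample\tfamily_id\td_cutoff\ttotal_count\tn_members\tcentre_sequence\n")
            for sample, fams in result.families.items():
                for fam in fams:
                    fh.write(
                        f"{sample}\t{fam.family_id}\t{fam.d_cutoff}\t"
                        f"{fam.total_count}\t{len(fam.members)}\t{fam.centre.seq}\n"
                    )
    if result.peptides:
        with open(outdir / "peptides.tsv", "w") as fh:
            fh.write("sample\tfamily_id\tpeptide\tcount\n")
            for sample, peps in result.peptides.items():
                for p in peps:
                    fh.write(f"{sample}\t{p.family_id}\t{p.aa_seq}\t{p.count}\n")
    with open(outdir / "unassigned.tsv", "w") as fh:
        fh.write("read_id\treason\n")
        for read, reason in result.unassigned:
            fh.write(f"{read.id}\t{reason}\n")
    write_log(result.log, outdir / "stage_log.tsv")
    return result
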