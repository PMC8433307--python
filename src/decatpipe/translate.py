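"""Translation of clustered nucleotide variants and within-family peptide
dereplication.

Variants are translated in frame 0 from the trimmed start (the trimming
boundary is the in-frame junction defined by the constant regions of the
library design).  Stop codons are rendered '*' and translation continues;
codons containing N (or any non-ACGT symbol) yield 'X'.  Peptides are
dereplicated within each nucleotide-level family, pooling counts across
synonymous or sequencing-error nucleotide variants, then filtered to
lengths strictly greater than the protein-length floor (247 aa by default).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from Bio.Data.CodonTable import standard_dna_table

__all__ = ["PeptideCount", "translate", "translate_families"]

_CODE = dict(standard_dna_table.forward_table)
_CODE.update({c: "*" for c in standard_dna_table.stop_codons})


@dataclass(frozen=True)
class PeptideCount:
    family_id: int
    aa_seq: str
    count: int


def translate(seq: str, frame: int = 0) -> str:
    """Translate with the standard genetic code; trailing partial codon dropped."""
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    s = seq[frame:]
    if len(s) < 3:
        raise ValueError("sequence shorter than one codon after frame offset")
    return "".join(_CODE.get(s[i : i + 3], "X") for i in range(0, len(s) - len(s) % 3, 3))


def translate_families(families: Iterable, aa_min_exclusive: int = 247) -> list[PeptideCount]:
    """Translate every family member, dereplicate peptides within the family,
    and keep peptides longer than ``aa_min_exclusive`` residues.

    Before the length filter, peptide counts within a family sum exactly to
    the family's total count.
    """
    out: list[PeptideCount] = []
    for fam in families:
        counts: Counter = Counter()
        for member in fam.members:
            counts[translate(member.seq)] += member.count
        for aa, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            if len(aa) > aa_min_exclusive:
                out.append(PeptideCount(fam.family_id, aa, n))
    return out
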