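# Methods

## Amplicon model

The pipeline assumes reads are consensus (CCS) sequences of concatemer
amplicons with the layout

```
bcF · [ fwd_const · variable_i · rc(rev_const) ]  joined by scar_i  · bcR
        40 nt        ~707–825 nt    22 nt            4 nt
```

for genes i = 1…5, where `bcF`/`bcR` are the sample's 16 nt forward/reverse
barcodes and `rc(·)` is reverse complementation. The two constant regions are
stored in their canonical printed forms,

- forward: `CGACTCACTATAGGGACAATTACTATTTACAATTACAATG`
- reverse: `GGCCAGATCCAGACATTCCCAT`

and every searched string is derived from them: forward-orientation reads are
split on the forward constant and tail-trimmed on `rc(rev_const)`
(`ATGGGAATGTCTGGATCTGGCC`); reverse-orientation reads are split on the
reverse constant verbatim (that is how the gene-leading anchor reads on the
reverse strand) and tail-trimmed on `rc(fwd_const)`. This is the only
geometry in which all four searched sequences are mutually consistent.

## Matching semantics

All tolerances are full Levenshtein edit distance — the error model of CCS
residual noise includes indels, so a pure-mismatch (Hamming) interpretation
would undercount real barcode and constant-region hits. Pairwise distance is
computed by Biopython's `PairwiseAligner` with match 0 / mismatch −1 /
gap −1 (the negated optimal score is exactly the Levenshtein distance);
approximate substring search is a semi-global dynamic programme vectorised
with numpy, returning all minimal-distance non-overlapping occurrences under
a deterministic tie-break (smallest distance, then smallest start, then
smallest end). Coordinates are 0-based half-open throughout.

Key tunables (all exposed on the CLI):

| parameter | default | meaning |
|---|---|---|
| `bc_tol_fwd`, `bc_tol_rev` | 2 | edit tolerance per 16 nt barcode |
| `bc_window` | barcode + 2·tol + 8 | terminal window for barcode search |
| `const_tol_fwd` | 4 | tolerance for the 40 nt forward constant |
| `const_tol_rev` | 2 | tolerance for the 22 nt reverse constant |
| `len_min`, `len_max` | 707, 825 | inclusive trimmed-variant length window |
| `aa_min` | 247 | exclusive peptide length floor |
| `d_cutoff` | — | strict Levenshtein radius for family membership |

## Design choices where the procedure was open

- **Windowed barcode search.** Barcodes are terminal by construction, so the
  search is restricted to terminal windows (size `len(barcode)+2·tol+8` by
  default, configurable up to whole-read). This prevents spurious internal
  hits in 4 kb of sequence; whether the original implementation windowed its
  search is not documented, so the window is a parameter.
- **Windowed tail trimming.** The trailing constant is searched only within
  a terminal window of each fragment (`len(tail)+2·tol+scar+8`). A global
  best-occurrence trim would silently salvage the first gene of a fused
  double-gene fragment (produced when an anchor carries more errors than the
  split tolerance); windowed trimming leaves such fragments ~1.6 kb long so
  the length filter rejects them, keeping the output uniformly structured.
  Fragments with no tail within tolerance are rejected, not passed through
  untrimmed — an untrimmed fragment would be ~26 nt too long yet still pass
  the length filter and pollute clustering.
- **Both-orientation resolution.** If a read admits both a forward and a
  reverse interpretation (possible only for pathological barcode sets), the
  lower total barcode distance wins; ties go to forward.
- **Inclusive length bounds.** "between 707–825" is read as a closed
  interval.
- **Greedy abundance-ordered clustering.** Only the centre definition (most
  abundant member) and the radius constraint (strict `< d_cutoff`) are
  inherent to the family concept; the greedy descending-abundance pass makes
  centres emerge in abundance order and sends ambiguous sequences to the
  earliest-founded family. Ties in abundance are broken lexicographically.
  An exact length-difference lower bound (`|len(a)−len(b)| ≤ dist`) prunes
  centre comparisons without changing results.
- **Translation.** Frame 0 from the trimmed variant start (the trim boundary
  is the in-frame junction of the library design); internal stops are kept
  as `*` rather than filtered, and codons containing N translate to `X`.
- **Count labels.** Output ranks (`sequence_X`) are assigned by descending
  count with lexicographic tie-break, making files deterministic.

## The simulator: what it emulates, and what it does not

`simulate_pool` generates the stated world the pipeline is tested in:
barcode tables with a pairwise edit-distance floor (ten barcodes for nine
pairs by default, mirroring the published pairing scheme, or fully unique
pairs when the pool is large enough), uniform 707–825 nt random variable
regions (ten distinct variants per sample by default — desk scale, chosen so
dereplication and clustering structure is observable in pools of tens of
reads), per-base independent substitution/insertion/deletion errors with
defaults 0.007/0.0015/0.0015 (≈1 % total, the Q20 consensus floor), a 50/50
orientation mix, and an exact-count fraction of truncation artefacts that
cut reads ahead of the 3′ barcode.

It does **not** emulate: context-dependent or homopolymer-biased CCS error,
chimeric joins between samples, the short repetitive adapter artefacts seen
in real runs (truncations stand in for them), sample-to-sample degradation
differences, or realistic protein-coding variable regions (random sequences
translate to peptides full of stops — fine for count accounting, not for
biological interpretation). A green round-trip test therefore establishes
the correctness of the string processing, not the field performance of the
laboratory protocol; dataset-level recovery percentages from real runs are
not reproducible from simulation and are not asserted anywhere.

## Numerical and degenerate-input conventions

- Empty input files, empty payloads and zero-anchor payloads are handled
  without error (empty stream / empty fragment list / single pass-through
  fragment, respectively); fragments of ≤ 10 nt are artefact-dropped.
- Stage percentages with a zero denominator render as 0.0, not NaN.
- Deconcatenation recovery is reported against 5 × the demultiplexed count
  (each concatemer should yield five genes).
- `d_cutoff = 0` places every unique sequence in its own family (strict
  inequality); clustering requires abundance-sorted input and raises
  otherwise.
- All simulator randomness flows from a single integer seed; pools are
  byte-identical across reruns.

## Known limitations

- The greedy clustering is order-dependent by design; it is the family
  definition here, not an approximation of a global optimum.
- Demultiplexing evaluates every sample's pair per read; for hundreds of
  samples a trie/seed index would be preferable.
- A destroyed *first* anchor leaves a leading fragment whose trimmed form
  (constant remnant + gene) can pass the length filter; this mirrors the
  anchor-driven splitting rule rather than attempting error correction.
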