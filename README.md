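# kmerpolish

Alignment-free polishing of genome assemblies from k-mer counts, with a
k-mer-derived assembly quality value (QV) and a synthetic-data harness for
truth-based validation.

## The problem

Long-read assemblies (e.g. from nanopore data) are highly contiguous but
carry residual consensus errors — single-base substitutions and small
indels.  Polishing corrects these using accurate reads (Illumina or HiFi)
from the same sample.  Most polishers align the reads to the assembly,
which is expensive.  This package instead uses only the exact counts of
canonical k-mers in the reads: a consensus error creates a run of assembly
k-mers that are rare or absent in the reads, and the length of that run
tells you what kind of error it is and how to fix it.

## The method

Let N(C) be the number of distinct read k-mers with count C.  The histogram
is a mixture of an error distribution E(C) (low counts) and a genomic
distribution R(C) (centred near coverage); their crossing point C_eq is the
histogram's local minimum, where a k-mer is equally likely to be erroneous
or genuine.  Two cutoffs are derived:

    R_t = floor(0.5 * C_eq),   A_t = round(0.5 * R_t),   A_t < R_t < C_eq

Walking each contig, a k-mer with count below A_t is unreliable; a count in
[A_t, R_t) is unreliable only after a sharp (more than two-fold) drop from
the previous k-mer — separating errors from smooth coverage dips.  Once a
run starts, it extends while counts stay below R_t.  A maximal run of L
unreliable k-mers is then repaired according to L (with k-mer length K):

- **L = K** — a substitution or novel-base insertion at the single base
  covered by all K run k-mers: try the three other bases, then deletion;
- **L > K** — several errors within K bases of each other: rebuild the
  interior by a breadth-first k-mer-graph walk between the flanking
  anchors, following only k-mers with count ≥ R_t (giving up above 5,000
  simultaneous paths);
- **L < K** — a deleted base, a same-base (homopolymer) insertion, a
  haplotype phasing error, or a truncated homopolymer: candidate edits are
  tried sequentially.

An edit is accepted only if **every** k-mer spanning the modified region
reaches count ≥ R_t afterwards; otherwise nothing is changed (an unreliable
k-mer is not necessarily wrong).  Passes are repeated (default 2); fixes
from one pass can enable fixes in the next, and the process converges
without introducing new errors.

The assembly QV is Phred-scaled from the unreliable-k-mer rate:

    E_k = unreliable k-mers / k-mer positions
    E_b = 1 - (1 - E_k)^(1/K)
    QV  = -10 * log10(E_b)

## Worked example

`examples/02_polish_toy_assembly.py` polishes a 9 bp assembly with one
substitution, using counts from 30 copies of the truth `AAACCCGGG`:

```
window counts: [30, 30, 0, 0, 0, 60, 60]
flags:         RRUUURR
run: start=2 L=3 span=ACTCG anchors=AAC/CGG
correction: substitution at base 4: 'T' -> 'C'
polished: AAACCCGGG  (matches truth: True)
```

The three zero-count windows are the run of L = K = 3 unreliable k-mers;
the error is the one base all three cover (index 4), and substituting `C`
makes every spanning count (30, 60, 60) clear R_t = 15.

At scale, `examples/03_simulate_and_evaluate.py` corrupts a 200 kb genome
with 195 substitutions/indels, polishes with counts from simulated 30x
2x150 bp reads (1% error), and scores against the known truth:

```
thresholds: C_eq=4 R_t=2 A_t=1
corrections per pass: [195, 0, 0]
tp=195 fp=0 fn=0
sensitivity=1.0000 precision=1.0000
polished sequence equals clean genome: True
```

`examples/04_assembly_qv.py` shows the QV rising from 30.1 (one error per
kilobase) to 47.2 after polishing, and reproduces the worked QV example
(100 unreliable 37-mers in 1 Mbp → E_k = 1e-4, QV = 55.7).

## Library layout

| module | contents |
| --- | --- |
| `kmerpolish.kmerdb` | exact canonical k-mer counting, queries, histogram, TSV dump |
| `kmerpolish.thresholds` | C_eq detection, R_t/A_t derivation |
| `kmerpolish.scanner` | per-k-mer reliability flags, unreliable-run extraction |
| `kmerpolish.corrector` | the three fixers, multi-pass driver, QV |
| `kmerpolish.simgen` | synthetic genomes, error injection, read simulation, truth-based scoring |
| `kmerpolish.pipeline` | file-level entry points (`run_polish`, `run_qv`, `run_simulate`) over FASTA/FASTQ (plain or gzipped) |

## Acceptance script

`scripts/acceptance.py` regenerates the full computation from scratch: a
seeded 500 kb genome, injected errors at the standard rates, simulated 30x
reads at 1% error, k-mer counting, threshold derivation, a three-pass
polish, truth-based sensitivity/precision, and the before/after QV.  Run it
from the repository root:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
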