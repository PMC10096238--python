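# Methods

This note records the model, the parameter choices, the numerical decisions
taken where the design was genuinely open, and what the synthetic-data tests
do and do not establish.

## Model and assumptions

Polishing treats the read k-mer spectrum as the sole evidence about the
assembly consensus.  The assumptions are:

1. the polishing reads cover the genome deeply and roughly uniformly, so
   genuine assembly k-mers have counts near the k-mer coverage
   `c_k ≈ coverage * (1 - (K-1)/read_len)`;
2. read errors are rare enough that erroneous k-mers pile up at low counts,
   producing a bimodal count histogram with a valley at C_eq;
3. a consensus error makes the overlapping assembly k-mers absent (or rare)
   in the reads, producing a sharp, contiguous run of low counts.

Exact counts are kept (no Bloom filter or count saturation) because the
sharp-drop rule compares a count against half the previous count, which a
solid/weak bit cannot express.

## Parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `K` | 37 | k-mer length (odd, ≥ 3). Long enough to be specific in Mbp-scale genomes, short enough that coverage per k-mer stays high. The graph search needs K ≥ 5 (5-base termination anchors). |
| `C_eq` | from histogram | local minimum of N(C); requires ≥ 4, else the data is rejected as unsuitable for polishing. Manually overridable for degenerate histograms. |
| `R_t` | floor(C_eq/2) | relative threshold: run continuation/termination cutoff and the post-edit acceptance bar. |
| `A_t` | round(R_t/2) | absolute threshold: counts below it are unreliable regardless of context. Rounding is half-away-from-zero. |
| `passes` | 2 | fixes in one pass can enable fixes in the next; empirically converges by pass 3 and never regresses. |
| `max_paths` | 5000 | path cap in the L > K graph search; prevents exponential blowup in repeats. |
| repeat limiter | 50× | a run of K or K-1 k-mers inside very-high-count context (mean of the previous K counts > 50·R_t) is only kept if its max count is 50-fold below that mean. |

## Numerical and tie-break decisions

- **C_eq search.** First local minimum scanning C = 2 upward on the raw
  bins (missing bins are zero), ties broken toward the smaller C — the
  conservative side, marking fewer k-mers unreliable.  A centred
  moving-average smoothing is available (`smooth_window`) but off by
  default: on deep-coverage histograms the valley is orders of magnitude
  deep and raw scanning is exact, while smoothing distorts the earliest
  minima.  No upper search cap is imposed: a first-minimum scan cannot land
  in the high-count repeat tail when an error valley exists, and capping at
  twice the argmax misfires on realistic 30x/1%-error histograms, where
  N(2) of the error tail can exceed the genomic peak height.
- **Reliability boundary.** A count equal to R_t is reliable and terminates
  a run (the conservative reading: fewer modifications).
- **Sharp-drop rule.** "Previous k-mer" is the immediately preceding window
  position; at position 0 or after a non-ACGT window there is no usable
  previous count and the rule cannot trigger.
- **Candidate order.** For L = K: substitutions in A,C,G,T order before
  deletion; first verified candidate wins.  Multiple candidates can verify
  (e.g. both a substitution and a deletion inside a homopolymer-adjacent
  context), so a deterministic order is part of the contract.  For L < K
  the four strategies run in the order insertion, same-base deletion,
  phasing substitution, homopolymer multi-insertion; insertion offsets are
  tried left to right with bases in A,C,G,T order.
- **Graph search.** Breadth-first, path cap checked per extension step.
  Among paths terminating (and verifying) at the same step, the winner has
  the largest minimum spanning-k-mer count; ties break lexicographically.
  A winning path identical to the existing interior is reported as no edit
  (the run was a coverage hole, not an error).
- **Acceptance comparisons** use ≥ R_t uniformly, for the edit-local
  windows (L = K), the whole modified span (L < K), and the 5-base junction
  windows (L > K).
- **Rescan after an edit** resumes K-1 windows before the edit position, so
  k-mers created by the edit are re-examined within the same pass.  A
  verified edit leaves all its spanning counts ≥ R_t, so rescanning cannot
  re-trigger the same run and the pass always progresses.
- **QV.** `genome_size` in E_k is the number of evaluated k-mer positions
  (contig length − K + 1 summed, excluding non-ACGT windows); unreliable
  counts are post-limiter.  When no unreliable k-mer is observed E_b = 0
  and the QV is reported as the sentinel cap 99 rather than infinity.
- **Degenerate inputs.** Contigs shorter than K yield empty profiles and
  are passed through unchanged; runs touching a contig end or a non-ACGT
  window lack an anchor and are never edited.

## The synthetic world

`simgen` emulates the validation design used for k-mer polishers at desk
scale: a uniform random genome; injected single-base substitutions at
3.3e-4 and indels at 6.6e-4 per base (the per-base rates of the published
~120 Mbp simulated-error experiment, which used 39,635 substitutions and
78,928 indels), indels split evenly between insertions and deletions;
2x150 bp paired reads at 30x coverage with i.i.d. 1% per-base substitution
errors, fragments of 500 bp drawn uniformly.  Injected errors are kept at
least K apart except in the explicit clustered mode (pairs closer than K,
exercising the L > K regime).  Error positions avoid the outermost K bases
so every run has both anchors.

What the generator does **not** model, and hence what a green test cannot
establish: real base-composition bias and repeat structure (uniform random
genomes have essentially no repeats, so the repetitive-region limiter is
exercised only by constructed count profiles); read indel errors; coverage
bias (GC, mappability); heterozygosity.  On real genomes sensitivity is
lower — particularly for indels whose size approaches K, which k-mer
evidence inherently cannot span (the near-K-deletion test demonstrates this
asymmetry) — and spurious runs from low-coverage regions are more common.

Scoring is stricter than variant-call-based evaluation: a true positive
must revert the injected edit exactly, after mapping sequential correction
positions back to the original assembly frame and left-aligning indels in
homopolymer context.  Path replacements are decomposed into single-base
primitives before matching.

With error-free reads the histogram has no error peak, so no local minimum
exists; the validation suite then sets C_eq manually to half the modal
k-mer coverage (≈ 11 at 30x with K = 37), which is where the valley would
sit had there been an error tail.

## Known limitations

- Homopolymers (and by extension short tandem repeats) of length ≥ K are
  invisible to k-mer evidence: any copy number ≥ K yields the same k-mer
  set, so such indels are neither detectable nor correctable.
- The QV underestimates true quality: it assumes the reads contain every
  genuine k-mer and that every unreliable k-mer is an error.
- The k-mer count table is held in a Python dict; memory is roughly
  100–150 bytes per distinct k-mer, which is fine up to tens of millions
  of distinct k-mers but not for mammalian-scale read sets.
- Thread-based contig parallelism preserves exact output determinism but,
  being GIL-bound, is concurrency rather than speedup; the design keeps
  pass semantics strictly sequential within a contig.
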