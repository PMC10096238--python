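"""Assembly quality value before and after polishing.

The QV is Phred-scaled from the unreliable-k-mer rate: E_k = unreliable
k-mers / k-mer positions, the implied per-base error rate
E_b = 1 - (1 - E_k)^(1/K), and QV = -10 log10(E_b).  QV 30 means roughly
one consensus error per kilobase; each +10 is a tenfold improvement.  The
estimate is conservative: it assumes the reads contain every true k-mer and
that every unreliable k-mer is wrong.
"""

from kmerpolish import KmerParams, count_kmers, compute_qv, thresholds_from_histogram
from kmerpolish.corrector import assembly_qv, polish
from kmerpolish.simgen import (
    generate_genome,
    inject_errors,
    iter_read_sequences,
    simulate_reads,
)

# the printed worked example: 100 unreliable 37-mers in a 1 Mbp genome
rep = compute_qv(100, 1_000_000, 37)
print(f"worked example: E_k={rep.e_k:.6g} E_b={rep.e_b:.6g} QV={rep.qv:.1f}")

K = 37
genome = generate_genome(150_000, seed=21)
mutated, truth = inject_errors(genome, 3.3e-4, 6.6e-4, seed=22, k=K)
pairs = simulate_reads(genome, coverage=30, error_rate=0.01, seed=23)
table = count_kmers(iter_read_sequences(pairs), KmerParams(K))
thr = thresholds_from_histogram(table.histogram())

before = assembly_qv([("c", mutated)], table, thr)
polished, _ = polish([("c", mutated)], table, thr, passes=3, compute_qv_report=False)
after = assembly_qv(polished, table, thr)
print(f"before polishing: {before.unreliable_kmers} unreliable k-mers, QV {before.qv:.2f}")
print(f"after  polishing: {after.unreliable_kmers} unreliable k-mers, QV {after.qv:.2f}")
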