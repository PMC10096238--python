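"""Count k-mers in reads and derive the reliability thresholds.

Simulates 30x paired reads with a 1% error rate from a small random genome,
counts canonical 21-mers, and locates the error/genomic crossover C_eq in
the count histogram.  The histogram's low bins show the error tail (huge
N(1), collapsing fast) and the valley at C_eq separating it from the
genomic coverage peak; R_t and A_t are the cutoffs the polisher uses to
flag unreliable assembly k-mers.
"""

from kmerpolish import KmerParams, count_kmers, thresholds_from_histogram
from kmerpolish.simgen import generate_genome, iter_read_sequences, simulate_reads

genome = generate_genome(100_000, seed=1)
pairs = simulate_reads(genome, coverage=30, error_rate=0.01, seed=2)
table = count_kmers(iter_read_sequences(pairs), KmerParams(21))
hist = table.histogram()

print(f"reads: {2 * len(pairs)}  distinct canonical 21-mers: {len(table.counts)}")
print("histogram bins 1..12:", {c: hist.n_of_c.get(c, 0) for c in range(1, 13)})
thr = thresholds_from_histogram(hist)
print(f"C_eq = {thr.c_eq}  (local minimum of the histogram: error k-mers below,")
print(f"genomic k-mers above)  R_t = {thr.r_t}  A_t = {thr.a_t}")
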