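"""Polish a tiny hand-checkable assembly.

The 'reads' are 30 exact copies of the truth sequence AAACCCGGG; the
assembly carries one substitution (T at index 4).  The scan flags a run of
exactly K = 3 unreliable k-mers, so the fixer tries the three alternative
bases at the base covered by all run k-mers and accepts the first whose
spanning k-mer counts all reach R_t — restoring the truth.
"""

from kmerpolish import KmerParams, Thresholds, count_kmers, classify_kmers, extract_runs
from kmerpolish.corrector import polish_pass

truth = "AAACCCGGG"
assembly = "AAACTCGGG"
table = count_kmers([truth] * 30, KmerParams(3))
thr = Thresholds(c_eq=31, r_t=15, a_t=8)

profile = classify_kmers(assembly, table, thr)
print("window counts:", profile.counts)
print("flags:        ", "".join(f.value for f in profile.flags))
runs = extract_runs(profile, assembly, table, thr)
r = runs[0]
print(f"run: start={r.start} L={r.length_L} span={r.span_SL} "
      f"anchors={r.left_anchor}/{r.right_anchor}")

polished, corrections = polish_pass(assembly, table, thr)
c = corrections[0]
print(f"correction: {c.kind.value} at base {c.position}: "
      f"{c.removed!r} -> {c.added!r}")
print(f"polished: {polished}  (matches truth: {polished == truth})")
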