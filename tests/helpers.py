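"""Shared test utilities: exact-coverage tables and an independent run oracle."""

from __future__ import annotations

from kmerpolish.kmerdb import INVALID, KmerCountTable, KmerParams, count_kmers
from kmerpolish.thresholds import Thresholds


def exact_table(genome: str, k: int, depth: int = 60) -> KmerCountTable:
    """Count table as if the genome were sequenced error-free at *depth*."""
    base = count_kmers([genome], KmerParams(k))
    return KmerCountTable(
        params=base.params,
        counts={kmer: c * depth for kmer, c in base.counts.items()},
        total_kmers_counted=base.total_kmers_counted * depth,
    )


def exact_thresholds(depth: int = 60) -> Thresholds:
    """Thresholds appropriate for an exact-coverage table."""
    return Thresholds(c_eq=depth, r_t=depth // 2, a_t=depth // 4)


def oracle_flags_and_runs(counts, thr, k):
    """Brute-force re-implementation of the marking rules, written as a
    trigger-then-expand scan (deliberately structured differently from the
    package's single-pass state machine).

    Returns (flags as an R/U/X string, list of (start, length) kept runs).
    """
    n = len(counts)
    flags = ["R"] * n
    for i, c in enumerate(counts):
        if c is INVALID:
            flags[i] = "X"
    i = 0
    while i < n:
        c = counts[i]
        if c is INVALID:
            i += 1
            continue
        sharp_drop = (
            i > 0
            and counts[i - 1] is not INVALID
            and 2 * c < counts[i - 1]
        )
        if c < thr.a_t or (c < thr.r_t and sharp_drop):
            j = i
            while j < n and counts[j] is not INVALID and counts[j] < thr.r_t:
                flags[j] = "U"
                j += 1
            i = j
        else:
            i += 1
    # run extraction with the repetitive-region limiter
    runs = []
    i = 0
    while i < n:
        if flags[i] != "U":
            i += 1
            continue
        j = i
        while j < n and flags[j] == "U":
            j += 1
        length = j - i
        keep = True
        if length in (k - 1, k) and i >= k:
            before = counts[i - k : i]
            if all(c is not INVALID for c in before):
                mean = sum(before) / k
                if mean > 50 * thr.r_t and max(counts[i:j]) * 50 > mean:
                    keep = False
        if keep:
            runs.append((i, length))
        else:
            for p in range(i, j):
                flags[p] = "R"
        i = j
    return "".join(flags), runs
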