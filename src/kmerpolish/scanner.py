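"""Classify contig k-mers as reliable/unreliable and extract unreliable runs.

Walking a contig left to right, each k-mer window is looked up in the read
count table and flagged:

(a) count < A_t                      -> UNRELIABLE (starts a run)
(b) A_t <= count < R_t               -> UNRELIABLE iff count < half of the
                                        previous window's count (a sharp drop;
                                        cannot trigger at position 0 or right
                                        after a non-ACGT window)
(c) inside a run, every count < R_t  -> UNRELIABLE; the run ends at the first
                                        count >= R_t
(d) windows containing non-ACGT      -> INVALID; terminates any run

Maximal UNRELIABLE stretches become :class:`UnreliableRun` objects carrying
the spanned substring S_L and the bracketing reliable anchor k-mers.  In
highly repetitive context (mean of the K window counts before the run more
than 50x R_t) a run of exactly K or K-1 windows is kept only if its maximum
count is at least 50-fold below that mean; otherwise the stretch is demoted
to RELIABLE and no run is emitted — a repeat whose counts merely step down
is not evidence of an error.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from .kmerdb import INVALID, KmerCountTable, reverse_complement
from .thresholds import Thresholds

__all__ = [
    "Flag",
    "ContigProfile",
    "UnreliableRun",
    "window_counts",
    "flags_from_counts",
    "classify_kmers",
    "extract_runs",
]

# how many fold below the local mean a run's counts must sit to stay flagged
# in repetitive context, and the factor defining that context
REPEAT_FOLD = 50


class Flag(enum.Enum):
    RELIABLE = "R"
    UNRELIABLE = "U"
    INVALID = "X"


@dataclass
class ContigProfile:
    """Per-window counts and reliability flags for one contig."""

    contig_id: str
    counts: list  # int or INVALID per k-mer start position
    flags: List[Flag]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.flags):
            raise ValueError("counts and flags must be parallel")


@dataclass
class UnreliableRun:
    """A maximal run of L consecutive unreliable k-mers.

    ``start`` indexes the first unreliable k-mer (0-based window position);
    ``span_SL`` is the contig substring covered by the run's k-mers, i.e.
    bases [start, start + L + K - 1).  Anchors are the flanking reliable
    k-mers; a run touching a contig end (or an INVALID window) lacks the
    corresponding anchor and is not correctable.
    """

    contig_id: str
    start: int
    length_L: int
    span_SL: str
    left_anchor: Optional[str] = None
    right_anchor: Optional[str] = None
    counts: list = field(default_factory=list)

    @property
    def correctable(self) -> bool:
        return self.left_anchor is not None and self.right_anchor is not None


def window_counts(contig: str, table: KmerCountTable) -> list:
    """Read count (or INVALID) for every k-mer window of *contig*."""
    k = table.params.k
    n = len(contig)
    if n < k:
        return []
    rc = reverse_complement(contig)
    counts = table.counts
    out = []
    append = out.append
    acgt = frozenset("ACGT")
    clean = acgt.issuperset(contig)
    for i in range(n - k + 1):
        f = contig[i : i + k]
        if not clean and not acgt.issuperset(f):
            append(INVALID)
            continue
        r = rc[n - k - i : n - i]
        append(counts.get(f if f <= r else r, 0))
    return out


def flags_from_counts(counts: Sequence, thr: Thresholds) -> List[Flag]:
    """Apply marking rules (a)-(d) to a sequence of window counts."""
    r_t, a_t = thr.r_t, thr.a_t
    flags: List[Flag] = []
    append = flags.append
    in_run = False
    prev = None  # previous window's count; None when the half-rule cannot apply
    for c in counts:
        if c is INVALID:
            append(Flag.INVALID)
            in_run = False
            prev = None
            continue
        if in_run:
            if c < r_t:
                append(Flag.UNRELIABLE)
            else:
                append(Flag.RELIABLE)
                in_run = False
        else:
            if c < a_t:
                append(Flag.UNRELIABLE)
                in_run = True
            elif c < r_t and prev is not None and 2 * c < prev:
                append(Flag.UNRELIABLE)
                in_run = True
            else:
                append(Flag.RELIABLE)
        prev = c
    return flags


def classify_kmers(
    contig: str, table: KmerCountTable, thr: Thresholds, contig_id: str = ""
) -> ContigProfile:
    """Classify every k-mer window of *contig*; empty profile if len < K."""
    counts = window_counts(contig, table)
    return ContigProfile(contig_id, counts, flags_from_counts(counts, thr))


def _keep_run(counts: Sequence, start: int, length: int, k: int, r_t: int) -> bool:
    """Repetitive-region limiter.

    Applies only to runs of exactly K or K-1 windows whose K preceding
    windows all have numeric counts with mean > REPEAT_FOLD * R_t; such a
    run survives only if max(run counts) * REPEAT_FOLD <= that mean.
    """
    if length not in (k - 1, k) or start < k:
        return True
    before = counts[start - k : start]
    if any(c is INVALID for c in before):
        return True
    mean = sum(before) / k
    if mean <= REPEAT_FOLD * r_t:
        return True
    return max(counts[start : start + length]) * REPEAT_FOLD <= mean


def extract_runs(
    profile: ContigProfile,
    contig: str,
    table: KmerCountTable,
    thr: Thresholds,
) -> List[UnreliableRun]:
    """Emit maximal unreliable runs with anchors, applying the repeat limiter.

    Stretches suppressed by the limiter are demoted to RELIABLE in the
    profile (in place), so downstream unreliable-k-mer tallies (QV) see the
    post-limiter flags.
    """
    k = table.params.k
    counts, flags = profile.counts, profile.flags
    n = len(flags)
    runs: List[UnreliableRun] = []
    i = 0
    while i < n:
        if flags[i] is not Flag.UNRELIABLE:
            i += 1
            continue
        j = i
        while j < n and flags[j] is Flag.UNRELIABLE:
            j += 1
        length = j - i
        if not _keep_run(counts, i, length, k, thr.r_t):
            for p in range(i, j):
                flags[p] = Flag.RELIABLE
            i = j
            continue
        left = contig[i - 1 : i - 1 + k] if i >= 1 and flags[i - 1] is Flag.RELIABLE else None
        right = contig[j : j + k] if j < n and flags[j] is Flag.RELIABLE else None
        runs.append(
            UnreliableRun(
                contig_id=profile.contig_id,
                start=i,
                length_L=length,
                span_SL=contig[i : i + length + k - 1],
                left_anchor=left,
                right_anchor=right,
                counts=list(counts[i:j]),
            )
        )
        i = j
    return runs
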