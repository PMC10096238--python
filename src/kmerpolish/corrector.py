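"""Propose, verify and apply corrections for unreliable runs; multi-pass driver; QV.

The length L of a run of unreliable k-mers determines the putative error and
the fix strategy:

L == K  a single-base substitution or a novel-base insertion at the one base
        covered by all K run k-mers (the last base of the first unreliable
        k-mer).  Try the three alternative bases, then deletion of the base.

L > K   two or more errors less than K apart.  Rebuild the interior with a
        local k-mer-graph search: starting from the last K-1 bases of the
        left anchor, extend with every base whose resulting k-mer count is at
        least R_t, following all paths for up to L steps (giving up if more
        than ``max_paths`` paths are alive at any step).  A path terminates
        when its last 5 bases match the first 5 bases of the right anchor and
        every k-mer containing those 5 bases clears R_t.

L < K   (i) a single-base deletion somewhere in S_L (insert one base);
        (ii) an insertion of the same base as the left anchor's last base
        (delete one copy); (iii) a haplotype phasing error (substitute one of
        the two candidate bases); (iv) a multi-base homopolymer deletion
        (insert 2..K copies of the anchor's last base).  Tried sequentially.

A candidate edit is accepted only if every k-mer spanning the modified
region has a count of at least R_t afterwards; if no candidate verifies the
run is left untouched — an unreliable k-mer is not guaranteed to be wrong.
Accepted edits are applied immediately and scanning resumes K-1 positions
before the edit so newly created k-mers are re-checked within the same pass.

The assembly quality value is Phred-scaled from the unreliable-k-mer rate:
E_k = unreliable k-mers / evaluated k-mer positions, the per-base error rate
E_b = 1 - (1 - E_k)^(1/K), and QV = -10 log10(E_b).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .kmerdb import INVALID, KmerCountTable, reverse_complement
from .scanner import Flag, UnreliableRun, _keep_run, classify_kmers, extract_runs
from .thresholds import Thresholds

__all__ = [
    "CorrectionKind",
    "Correction",
    "QVReport",
    "PolishReport",
    "QV_CAP",
    "fix_run_exact_k",
    "fix_run_long",
    "fix_run_short",
    "polish_pass",
    "polish",
    "count_unreliable_kmers",
    "compute_qv",
    "assembly_qv",
]

QV_CAP = 99.0  # sentinel QV when no unreliable k-mers are observed
DEFAULT_MAX_PATHS = 5000
_BASES = "ACGT"


class CorrectionKind(enum.Enum):
    """Named by the consensus error the edit repairs."""

    SUBSTITUTION = "substitution"
    DELETION_FROM_ASSEMBLY = "deletion_from_assembly"  # repaired by inserting
    INSERTION_INTO_ASSEMBLY = "insertion_into_assembly"  # repaired by deleting
    PATH_REPLACEMENT = "path_replacement"


@dataclass
class Correction:
    """One applied edit: contig[position : position+len(removed)] -> added."""

    contig_id: str
    position: int  # 0-based base index in the contig at the time of the edit
    removed: str
    added: str
    kind: CorrectionKind
    pass_index: int = 1

    def __post_init__(self) -> None:
        if not self.removed and not self.added:
            raise ValueError("a correction must remove or add at least one base")

    def apply(self, seq: str) -> str:
        p = self.position
        if seq[p : p + len(self.removed)] != self.removed:
            raise ValueError("correction does not match the sequence")
        return seq[:p] + self.added + seq[p + len(self.removed) :]


@dataclass(frozen=True)
class QVReport:
    unreliable_kmers: int
    genome_size: int  # number of k-mer positions evaluated
    e_k: float
    e_b: float
    qv: float


@dataclass
class PolishReport:
    corrections: List[Correction] = field(default_factory=list)
    corrections_per_pass: List[int] = field(default_factory=list)
    qv_before: Optional[QVReport] = None
    qv_after: Optional[QVReport] = None
    # pass index (1-based) -> list of (contig_id, sequence) after that pass
    snapshots: Dict[int, List[Tuple[str, str]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# edit verification


def _verify_edit(
    seq: str,
    pos: int,
    removed_len: int,
    added: str,
    table: KmerCountTable,
    r_t: int,
    w_lo: int,
    w_hi: int,
) -> bool:
    """Check that windows w_lo..w_hi (edited coordinates, inclusive) all have
    count >= r_t after replacing seq[pos:pos+removed_len] with *added*.

    Only a local segment of the edited sequence is materialised, so the cost
    is O(window span), not O(contig).
    """
    k = table.params.k
    delta = len(added) - removed_len
    n_new = len(seq) + delta
    w_lo = max(0, w_lo)
    w_hi = min(w_hi, n_new - k)
    if w_hi < w_lo:
        return False
    a = w_lo  # a <= pos for every caller
    b_new = w_hi + k
    b_old = max(pos + removed_len, b_new - delta)
    local = seq[a:pos] + added + seq[pos + removed_len : b_old]
    local = local[: b_new - a]
    query = table.query
    for w in range(w_lo, w_hi + 1):
        kmer = local[w - a : w - a + k]
        if len(kmer) < k:
            return False
        c = query(kmer)
        if c is INVALID or c < r_t:
            return False
    return True


# ---------------------------------------------------------------------------
# the three fixers


def fix_run_exact_k(
    run: UnreliableRun, contig: str, table: KmerCountTable, thr: Thresholds
) -> Optional[Correction]:
    """L == K: substitution candidates (A,C,G,T order) then deletion, at the
    single base covered by all K run k-mers."""
    k = table.params.k
    if run.length_L != k or not run.correctable:
        return None
    p = run.start + k - 1
    cur = contig[p]
    r_t = thr.r_t
    for b in _BASES:
        if b == cur:
            continue
        if _verify_edit(contig, p, 1, b, table, r_t, p - k + 1, p):
            return Correction(run.contig_id, p, cur, b, CorrectionKind.SUBSTITUTION)
    if _verify_edit(contig, p, 1, "", table, r_t, p - k + 1, p - 1):
        return Correction(run.contig_id, p, cur, "", CorrectionKind.INSERTION_INTO_ASSEMBLY)
    return None


def _span_bounds(start: int, length: int, k: int, delta: int) -> Tuple[int, int]:
    # window starts covering any base of the modified span S_L
    return start - k + 1, start + length + k - 2 + delta


def fix_run_short(
    run: UnreliableRun, contig: str, table: KmerCountTable, thr: Thresholds
) -> Optional[Correction]:
    """L < K: try (i) single-base insertion, (ii) same-base deletion,
    (iii) phasing substitution, (iv) homopolymer multi-base insertion.

    Every candidate must leave all k-mers containing bases of the modified
    S_L with counts >= R_t.
    """
    k = table.params.k
    s, L = run.start, run.length_L
    if L >= k or not run.correctable:
        return None
    r_t = thr.r_t
    cid = run.contig_id

    # (i) a single base was deleted from the assembly: insert one
    w_lo, w_hi = _span_bounds(s, L, k, delta=1)
    for j in range(s + 1, s + L + k - 1):
        for b in _BASES:
            if _verify_edit(contig, j, 0, b, table, r_t, w_lo, w_hi):
                return Correction(cid, j, "", b, CorrectionKind.DELETION_FROM_ASSEMBLY)

    # (ii) the same base was inserted: delete one copy
    p = s + k - 1
    if contig[s + k - 2] == contig[p]:
        w_lo, w_hi = _span_bounds(s, L, k, delta=-1)
        if _verify_edit(contig, p, 1, "", table, r_t, w_lo, w_hi):
            return Correction(cid, p, contig[p], "", CorrectionKind.INSERTION_INTO_ASSEMBLY)

    # (iii) haplotype phasing error: exactly one of two candidate bases is wrong
    w_lo, w_hi = _span_bounds(s, L, k, delta=0)
    for p in (s + k - 1, s + L - 1):
        cur = contig[p]
        for b in _BASES:
            if b == cur:
                continue
            if _verify_edit(contig, p, 1, b, table, r_t, w_lo, w_hi):
                return Correction(cid, p, cur, b, CorrectionKind.SUBSTITUTION)

    # (iv) a homopolymer stretch was truncated: insert m copies of the
    # left anchor's last base
    base = contig[s + k - 2]
    j = s + k - 1
    for m in range(2, k + 1):
        w_lo, w_hi = _span_bounds(s, L, k, delta=m)
        if _verify_edit(contig, j, 0, base * m, table, r_t, w_lo, w_hi):
            return Correction(cid, j, "", base * m, CorrectionKind.DELETION_FROM_ASSEMBLY)
    return None


def _min_span_count(
    contig: str, s: int, L: int, interior: str, table: KmerCountTable
) -> int:
    """Minimum count over all windows of left anchor + interior + right anchor."""
    k = table.params.k
    local = contig[s - 1 : s + k - 1] + interior + contig[s + L : s + L + k]
    best = None
    for i in range(len(local) - k + 1):
        c = table.query(local[i : i + k])
        if c is INVALID:
            return -1
        if best is None or c < best:
            best = c
    return best if best is not None else -1


def fix_run_long(
    run: UnreliableRun,
    contig: str,
    table: KmerCountTable,
    thr: Thresholds,
    max_paths: int = DEFAULT_MAX_PATHS,
) -> Optional[Correction]:
    """L > K: breadth-first k-mer-graph path search between the anchors.

    Among verifying paths found at the same step, the one whose spanning
    k-mer multiset has the largest minimum count wins; ties break
    lexicographically.  Returns NONE when the path cap is exceeded, no path
    terminates, or the winning path reproduces the existing interior.
    """
    k = table.params.k
    if k < 5:
        raise ValueError("the path search termination test requires K >= 5")
    s, L = run.start, run.length_L
    if L <= k or not run.correctable:
        return None
    r_t = thr.r_t
    seed = contig[s : s + k - 1]  # last K-1 bases of the left anchor
    target5 = contig[s + L : s + L + 5]
    if len(target5) < 5:
        return None
    old_interior = contig[s + k - 1 : s + L]
    query = table.query
    paths = [""]
    for _step in range(L):
        new_paths: List[str] = []
        winners: List[str] = []
        for p in paths:
            ctx = (seed + p)[-(k - 1) :]
            for b in _BASES:
                c = query(ctx + b)
                if c is INVALID or c < r_t:
                    continue
                q = p + b
                if len(q) >= 5 and q.endswith(target5):
                    interior = q[:-5]
                    j5 = s + k - 1 + len(interior)  # matched 5-mer start, edited coords
                    if _verify_edit(
                        contig, s + k - 1, L - k + 1, interior, table, r_t,
                        j5 + 5 - k, j5,
                    ):
                        winners.append(interior)
                new_paths.append(q)
        if winners:
            best = min(winners, key=lambda it: (-_min_span_count(contig, s, L, it, table), it))
            if best == old_interior:
                return None
            return Correction(
                run.contig_id, s + k - 1, old_interior, best, CorrectionKind.PATH_REPLACEMENT
            )
        if len(new_paths) > max_paths or not new_paths:
            return None
        paths = new_paths
    return None


def _dispatch(
    run: UnreliableRun,
    contig: str,
    table: KmerCountTable,
    thr: Thresholds,
    max_paths: int,
) -> Optional[Correction]:
    k = table.params.k
    if run.length_L == k:
        return fix_run_exact_k(run, contig, table, thr)
    if run.length_L > k:
        if k < 5:
            return None
        return fix_run_long(run, contig, table, thr, max_paths=max_paths)
    return fix_run_short(run, contig, table, thr)


# ---------------------------------------------------------------------------
# pass driver


def polish_pass(
    contig: str,
    table: KmerCountTable,
    thr: Thresholds,
    contig_id: str = "",
    pass_index: int = 1,
    max_paths: int = DEFAULT_MAX_PATHS,
) -> Tuple[str, List[Correction]]:
    """One left-to-right correction pass over a single contig.

    Runs are detected with the streaming equivalent of classify/extract;
    accepted edits are applied immediately and scanning resumes K-1 windows
    before the edit site.  Runs missing an anchor are skipped.
    """
    k = table.params.k
    r_t, a_t = thr.r_t, thr.a_t
    acgt = frozenset(_BASES)
    seq = contig.upper()
    n = len(seq)
    if n < k:
        return seq, []
    rc = reverse_complement(seq)
    clean = acgt.issuperset(seq)
    counts_d = table.counts

    counts_buf: list = []
    flags_buf: List[Flag] = []
    corrections: List[Correction] = []
    pos = 0
    in_run = False
    prev = None
    run_start: Optional[int] = None
    guard = 0

    while pos <= n - k:
        f = seq[pos : pos + k]
        if not clean and not acgt.issuperset(f):
            c = INVALID
        else:
            r = rc[n - k - pos : n - pos]
            c = counts_d.get(f if f <= r else r, 0)

        if c is INVALID:
            flag = Flag.INVALID
            in_run = False
            prev = None
        elif in_run:
            if c < r_t:
                flag = Flag.UNRELIABLE
            else:
                flag = Flag.RELIABLE
                in_run = False
            prev = c
        else:
            if c < a_t or (c < r_t and prev is not None and 2 * c < prev):
                flag = Flag.UNRELIABLE
                in_run = True
            else:
                flag = Flag.RELIABLE
            prev = c

        counts_buf.append(c)
        flags_buf.append(flag)
        ended: Optional[Tuple[int, int]] = None
        if flag is Flag.UNRELIABLE:
            if run_start is None:
                run_start = pos
        elif run_start is not None:
            ended = (run_start, pos - run_start)
            run_start = None
        pos += 1
        if ended is None:
            continue

        rs, L = ended
        if flags_buf[rs + L] is not Flag.RELIABLE:  # terminated by INVALID
            continue
        if not _keep_run(counts_buf, rs, L, k, r_t):
            for q in range(rs, rs + L):
                flags_buf[q] = Flag.RELIABLE
            continue
        if rs < 1 or flags_buf[rs - 1] is not Flag.RELIABLE:
            continue
        run = UnreliableRun(
            contig_id=contig_id,
            start=rs,
            length_L=L,
            span_SL=seq[rs : rs + L + k - 1],
            left_anchor=seq[rs - 1 : rs - 1 + k],
            right_anchor=seq[rs + L : rs + L + k],
            counts=counts_buf[rs : rs + L],
        )
        corr = _dispatch(run, seq, table, thr, max_paths)
        if corr is None:
            continue
        corr.contig_id = contig_id
        corr.pass_index = pass_index
        corrections.append(corr)
        seq = corr.apply(seq)
        n = len(seq)
        rc = reverse_complement(seq)
        guard += 1
        if guard > n:  # safety net; verified edits cannot loop, but be certain
            break
        resume = max(0, corr.position - k + 1)
        del counts_buf[resume:]
        del flags_buf[resume:]
        pos = resume
        run_start = None
        in_run = resume >= 1 and flags_buf[resume - 1] is Flag.UNRELIABLE
        prev = None
        if resume >= 1 and counts_buf[resume - 1] is not INVALID:
            prev = counts_buf[resume - 1]

    return seq, corrections


def polish(
    assembly: Sequence[Tuple[str, str]],
    table: KmerCountTable,
    thr: Thresholds,
    passes: int = 2,
    max_paths: int = DEFAULT_MAX_PATHS,
    keep_snapshots: bool = False,
    compute_qv_report: bool = True,
    threads: int = 1,
) -> Tuple[List[Tuple[str, str]], PolishReport]:
    """Polish an assembly (list of (contig_id, sequence)) for *passes* passes.

    Contigs are independent work units sharing the read-only count table;
    with ``threads`` > 1 they are dispatched to a thread pool, with a
    deterministic merge in input order so output is byte-identical for any
    worker count.  Identifiers and ordering always match the input.  The
    report records corrections per pass and QV before/after;
    ``keep_snapshots`` additionally stores the sequences after every pass
    (used to study convergence).
    """
    if passes < 1:
        raise ValueError("passes must be >= 1")
    if threads < 1:
        raise ValueError("threads must be >= 1")
    report = PolishReport()
    contigs = [(cid, str(seq).upper()) for cid, seq in assembly]
    if compute_qv_report:
        report.qv_before = assembly_qv(contigs, table, thr)
    for p in range(1, passes + 1):
        n_before = len(report.corrections)
        if threads > 1 and len(contigs) > 1:
            from concurrent.futures import ThreadPoolExecutor

            with ThreadPoolExecutor(max_workers=threads) as pool:
                results = list(
                    pool.map(
                        lambda item: polish_pass(
                            item[1], table, thr, contig_id=item[0],
                            pass_index=p, max_paths=max_paths,
                        ),
                        contigs,
                    )
                )
        else:
            results = [
                polish_pass(
                    seq, table, thr, contig_id=cid, pass_index=p, max_paths=max_paths
                )
                for cid, seq in contigs
            ]
        polished: List[Tuple[str, str]] = []
        for (cid, _), (new_seq, corrs) in zip(contigs, results):
            report.corrections.extend(corrs)
            polished.append((cid, new_seq))
        contigs = polished
        report.corrections_per_pass.append(len(report.corrections) - n_before)
        if keep_snapshots:
            report.snapshots[p] = list(contigs)
    if compute_qv_report:
        report.qv_after = assembly_qv(contigs, table, thr)
    return contigs, report


# ---------------------------------------------------------------------------
# quality value


def count_unreliable_kmers(
    assembly: Sequence[Tuple[str, str]],
    table: KmerCountTable,
    thr: Thresholds,
) -> Tuple[int, int]:
    """(unreliable k-mers, evaluated k-mer positions) over the assembly.

    Flags are post-limiter: stretches suppressed by the repetitive-region
    rule do not count as unreliable.  INVALID (non-ACGT) windows are excluded
    from the evaluated positions.
    """
    unreliable = 0
    genome_size = 0
    for cid, seq in assembly:
        seq = str(seq).upper()
        profile = classify_kmers(seq, table, thr, contig_id=cid)
        extract_runs(profile, seq, table, thr)  # applies limiter demotions
        for flag in profile.flags:
            if flag is Flag.UNRELIABLE:
                unreliable += 1
                genome_size += 1
            elif flag is Flag.RELIABLE:
                genome_size += 1
    return unreliable, genome_size


def compute_qv(unreliable_kmers: int, genome_size: int, k: int) -> QVReport:
    """Phred-scaled assembly quality from the unreliable-k-mer rate.

    E_k = unreliable/genome_size, E_b = 1-(1-E_k)^(1/K), QV = -10 log10(E_b).
    With zero unreliable k-mers E_b is 0 and the QV is reported as the cap
    sentinel (no unreliable k-mers observed), not infinity.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if not 0 <= unreliable_kmers <= genome_size:
        raise ValueError("unreliable_kmers must be in [0, genome_size]")
    e_k = unreliable_kmers / genome_size
    e_b = 1.0 - (1.0 - e_k) ** (1.0 / k)
    qv = -10.0 * math.log10(e_b) if e_b > 0 else QV_CAP
    return QVReport(
        unreliable_kmers=unreliable_kmers,
        genome_size=genome_size,
        e_k=e_k,
        e_b=e_b,
        qv=min(qv, QV_CAP),
    )


def assembly_qv(
    assembly: Sequence[Tuple[str, str]],
    table: KmerCountTable,
    thr: Thresholds,
) -> QVReport:
    """QV of an assembly against a read count table."""
    u, g = count_unreliable_kmers(assembly, table, thr)
    return compute_qv(u, g, table.params.k)
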