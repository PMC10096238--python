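"""Exact canonical k-mer counting over sequencing reads.

The polishing evidence is a table mapping each canonical k-mer observed in
the reads to its exact occurrence count.  A k-mer and its reverse complement
are the same molecule read from opposite strands, so both are tallied under
the lexicographically smaller of the two ("canonical") forms; an odd k
guarantees a k-mer never equals its own reverse complement, which keeps the
canonical representative unambiguous.

Counts are stored exactly (plain dict, no Bloom filter or saturation): the
downstream half-of-previous-count rule needs true counts, not a solid/weak
bit.  Windows containing any non-ACGT character contribute nothing and query
results for such k-mers are the distinguished sentinel :data:`INVALID`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable

__all__ = [
    "INVALID",
    "KmerParams",
    "KmerCountTable",
    "CountHistogram",
    "reverse_complement",
    "canonicalize",
    "count_kmers",
    "query",
    "histogram",
    "save_table",
    "load_table",
]

_RC_TABLE = str.maketrans(
    "ACGTacgtNnRYSWKMBDHVryswkmbdhv",
    "TGCAtgcaNnYRSWMKVHDByrswmkvhdb",
)
_ACGT = frozenset("ACGT")


class _InvalidType:
    """Singleton sentinel for k-mers containing a non-ACGT character."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "INVALID"

    def __reduce__(self):
        return (_InvalidType, ())


INVALID = _InvalidType()


def reverse_complement(seq: str) -> str:
    """Reverse complement of *seq*; IUPAC ambiguity codes are complemented too."""
    return seq.translate(_RC_TABLE)[::-1]


def canonicalize(kmer: str) -> str:
    """Lexicographic minimum of *kmer* and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class KmerParams:
    """K-mer length parameter.

    k must be odd (unambiguous canonicalization) and at least 3.  The default
    of 37 is the length at which single-base consensus errors produce runs of
    exactly 37 unreliable k-mers while remaining specific in megabase-scale
    genomes.  The local k-mer-graph correction additionally requires k >= 5
    because its termination test anchors on 5-base matches; that constraint
    is enforced where the graph search runs, not here, so that tiny
    hand-checkable tables (k = 3) remain constructible.
    """

    k: int = 37

    def __post_init__(self) -> None:
        if not isinstance(self.k, int) or self.k < 3:
            raise ValueError(f"k must be an integer >= 3, got {self.k!r}")
        if self.k % 2 == 0:
            raise ValueError(f"k must be odd, got {self.k}")


@dataclass
class CountHistogram:
    """N(C): number of distinct k-mers having read count C."""

    n_of_c: Dict[int, int] = field(default_factory=dict)

    def max_count(self) -> int:
        return max(self.n_of_c) if self.n_of_c else 0

    def total_kmer_instances(self) -> int:
        """Sum over C of C * N(C) (equals total windows counted)."""
        return sum(c * n for c, n in self.n_of_c.items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountHistogram):
            return NotImplemented
        return self.n_of_c == other.n_of_c


@dataclass
class KmerCountTable:
    """Canonical k-mer -> exact occurrence count in the reads."""

    params: KmerParams = field(default_factory=KmerParams)
    counts: Dict[str, int] = field(default_factory=dict)
    total_kmers_counted: int = 0

    def query(self, kmer: str):
        """Count of the canonical form of *kmer* (0 if absent).

        Returns :data:`INVALID` if *kmer* contains a non-ACGT character.
        A wrong-length argument is a contract violation.
        """
        k = self.params.k
        if len(kmer) != k:
            raise ValueError(f"query requires a {k}-mer, got length {len(kmer)}")
        if not _ACGT.issuperset(kmer):
            return INVALID
        rc = reverse_complement(kmer)
        return self.counts.get(kmer if kmer <= rc else rc, 0)

    def histogram(self) -> CountHistogram:
        return CountHistogram(dict(Counter(self.counts.values())))


def _sequence_of(record) -> str:
    """Accept plain strings, (id, seq) pairs, or SeqRecord-like objects."""
    if isinstance(record, str):
        return record
    seq = getattr(record, "seq", None)
    if seq is not None:
        return str(seq)
    if isinstance(record, (tuple, list)) and len(record) >= 2:
        return str(record[1])
    raise TypeError(f"cannot extract a sequence from {type(record).__name__}")


def count_kmers(reads: Iterable, params: KmerParams | None = None) -> KmerCountTable:
    """Count canonical k-mers over every ACGT-only window of every read.

    Each window of ``k`` consecutive ACGT bases contributes 1 to the count of
    its canonical form; windows containing any other character are skipped.
    Reads shorter than ``k`` contribute nothing; empty input yields an empty
    table.
    """
    if params is None:
        params = KmerParams()
    k = params.k
    counts: Dict[str, int] = {}
    get = counts.get
    total = 0
    for record in reads:
        s = _sequence_of(record).upper()
        n = len(s)
        if n < k:
            continue
        rc = s.translate(_RC_TABLE)[::-1]
        if _ACGT.issuperset(s):
            for i in range(n - k + 1):
                f = s[i : i + k]
                r = rc[n - k - i : n - i]
                key = f if f <= r else r
                counts[key] = get(key, 0) + 1
            total += n - k + 1
        else:
            # walk windows, skipping any that overlap a non-ACGT character
            bad = [i for i, ch in enumerate(s) if ch not in _ACGT]
            bad.append(n + k)  # sentinel
            bi = 0
            for i in range(n - k + 1):
                while bad[bi] < i:
                    bi += 1
                if bad[bi] < i + k:
                    continue
                f = s[i : i + k]
                r = rc[n - k - i : n - i]
                key = f if f <= r else r
                counts[key] = get(key, 0) + 1
                total += 1
    return KmerCountTable(params=params, counts=counts, total_kmers_counted=total)


def query(table: KmerCountTable, kmer: str):
    """Module-level alias for :meth:`KmerCountTable.query`."""
    return table.query(kmer)


def histogram(table: KmerCountTable) -> CountHistogram:
    """Tally N(C) over the table's counts."""
    return table.histogram()


def save_table(table: KmerCountTable, path) -> None:
    """Write the table as TAB-separated ``KMER<TAB>COUNT`` lines (sorted)."""
    with open(path, "w") as fh:
        for kmer in sorted(table.counts):
            fh.write(f"{kmer}\t{table.counts[kmer]}\n")


def load_table(path, k: int | None = None) -> KmerCountTable:
    """Load a table written by :func:`save_table`.

    ``k`` is inferred from the first k-mer in the file; for an empty file the
    explicit ``k`` argument (or the default of 37) is used.  A malformed line
    raises ``ValueError`` naming the line number.
    """
    counts: Dict[str, int] = {}
    total = 0
    inferred = k
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 'KMER<TAB>COUNT'")
            kmer, count_s = parts
            try:
                count = int(count_s)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: count {count_s!r} is not an integer"
                ) from None
            if count < 1:
                raise ValueError(f"{path}: line {lineno}: count must be >= 1")
            if inferred is None:
                inferred = len(kmer)
            if len(kmer) != inferred or not _ACGT.issuperset(kmer):
                raise ValueError(f"{path}: line {lineno}: bad k-mer {kmer!r}")
            counts[kmer] = counts.get(kmer, 0) + count
            total += count
    params = KmerParams(inferred if inferred is not None else 37)
    return KmerCountTable(params=params, counts=counts, total_kmers_counted=total)
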