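"""Synthetic genomes, injected errors, simulated reads, truth-based scoring.

This is the desk-scale validation substrate for the polisher: draw a random
genome, corrupt it with single-base substitutions and indels at stated rates
(defaults mirror ~0.033% substitutions and ~0.066% indels, the per-base
rates of the large-scale simulated-error experiment the method was
characterised on), simulate 2x150 bp paired-end reads at 30x coverage with a
1% per-base substitution error rate, and score the corrections the polisher
makes against the known truth.

A correction counts as a true positive only if it exactly reverts an
injected edit (same left-normalised position, same removed/added bases) —
stricter than variant-call-based counting.  Indel positions are left-aligned
within homopolymer context before matching, since equivalent indels are
otherwise reported at different offsets.  All randomness flows from explicit
per-operation seeds; there is no global random state.
"""

from __future__ import annotations

import bisect
import difflib
import enum
from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .corrector import Correction

__all__ = [
    "EditKind",
    "TruthEdit",
    "TruthSet",
    "EvalStats",
    "ReadPair",
    "generate_genome",
    "inject_errors",
    "simulate_reads",
    "iter_read_sequences",
    "evaluate",
]

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


class EditKind(enum.Enum):
    SUB = "sub"
    INS = "ins"  # a base was inserted into the assembly
    DEL = "del"  # a base was deleted from the assembly


@dataclass(frozen=True)
class TruthEdit:
    """One injected error, located in the mutated assembly's coordinates."""

    contig_id: str
    position: int  # 0-based in the mutated assembly
    kind: EditKind
    original: str  # base(s) present in the clean genome ("" for INS)
    mutated: str  # base(s) present in the mutated assembly ("" for DEL)


@dataclass
class TruthSet:
    edits: List[TruthEdit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.edits)

    def apply_inverse(self, mutated: str) -> str:
        """Revert every edit (right to left), recovering the clean genome."""
        s = mutated
        for e in sorted(self.edits, key=lambda e: e.position, reverse=True):
            p = e.position
            if e.kind is EditKind.SUB:
                s = s[:p] + e.original + s[p + 1 :]
            elif e.kind is EditKind.INS:
                s = s[:p] + s[p + 1 :]
            else:  # DEL
                s = s[:p] + e.original + s[p:]
        return s


@dataclass
class EvalStats:
    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 1.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 1.0


@dataclass(frozen=True)
class ReadPair:
    name: str
    read1: str
    read2: str


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def generate_genome(length: int, seed: int, gc: float = 0.5) -> str:
    """Uniform-composition random genome; deterministic for a fixed seed.

    ``gc`` sets the expected G+C fraction; the realised fraction is binomially
    concentrated around it (within ~2% for lengths >= 100 kb).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be a fraction in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=length, p=[at, gc / 2.0, gc / 2.0, at]).astype(np.uint8)
    return _decode(codes)


def _sample_positions(
    rng: np.random.Generator, length: int, need: int, spacing: int, margin: int
) -> np.ndarray:
    """Distinct positions in [margin, length - margin) pairwise >= spacing apart."""
    if need == 0:
        return np.empty(0, dtype=np.int64)
    lo, hi = margin, length - margin
    if hi - lo < need * spacing:
        raise ValueError("genome too short for the requested error count/spacing")
    oversample = 4 * need
    while True:
        cand = np.sort(rng.choice(hi - lo, size=min(oversample, hi - lo), replace=False) + lo)
        kept = []
        last = -(10 * spacing)
        for p in cand:
            if p - last >= spacing:
                kept.append(int(p))
                last = p
            if len(kept) == need:
                return np.asarray(kept, dtype=np.int64)
        oversample *= 2


def inject_errors(
    genome: str,
    sub_rate: float,
    indel_rate: float,
    seed: int,
    cluster_fraction: float = 0.0,
    k: int = 37,
    contig_id: str = "contig",
) -> Tuple[str, TruthSet]:
    """Inject single-base substitutions and indels at random locations.

    Edit counts are binomial with means rate * length; indels split 50/50
    into insertions and deletions.  Errors are kept at least ``k`` bases
    apart, except that ``cluster_fraction`` of them are placed as the second
    member of a substitution pair less than ``k`` bases from its partner
    (exercising the multi-error k-mer-graph regime).  TruthSet coordinates
    refer to the mutated genome.
    """
    if not (0.0 <= sub_rate <= 0.01 and 0.0 <= indel_rate <= 0.01):
        raise ValueError("rates must be in [0, 0.01]")
    L = len(genome)
    rng = np.random.default_rng(seed)
    n_sub = int(rng.binomial(L, sub_rate)) if sub_rate > 0 else 0
    n_indel = int(rng.binomial(L, indel_rate)) if indel_rate > 0 else 0
    n_ins = n_indel // 2
    n_del = n_indel - n_ins
    total = n_sub + n_indel
    if total == 0:
        return genome, TruthSet()
    n_cluster = int(round(cluster_fraction * total))
    n_primary = total - n_cluster

    # primaries well separated; clustered errors ride within k of a primary sub
    positions = _sample_positions(rng, L, n_primary, spacing=3 * k, margin=k + 1)
    kinds = [EditKind.SUB] * n_sub + [EditKind.INS] * n_ins + [EditKind.DEL] * n_del
    kinds = kinds[:n_primary]
    order = rng.permutation(n_primary)
    planned: List[Tuple[int, EditKind]] = [
        (int(positions[i]), kinds[order[i] % len(kinds)]) for i in range(n_primary)
    ]
    # force clustered pairs to be substitutions next to substitution primaries
    sub_primaries = [i for i, (_, kd) in enumerate(planned) if kd is EditKind.SUB]
    for j in range(n_cluster):
        if not sub_primaries:
            break
        i = sub_primaries[j % len(sub_primaries)]
        base_pos = planned[i][0]
        offset = int(rng.integers(2, k))  # strictly within k bases
        planned.append((base_pos + offset, EditKind.SUB))
    planned.sort()
    # drop accidental duplicates
    seen = set()
    final: List[Tuple[int, EditKind]] = []
    for p, kd in planned:
        if p not in seen:
            seen.add(p)
            final.append((p, kd))

    pieces: List[str] = []
    edits: List[TruthEdit] = []
    last = 0
    off = 0
    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for p, kd in final:
        if kd is EditKind.SUB:
            orig = genome[p]
            mut = others[orig][int(rng.integers(3))]
            pieces.append(genome[last:p])
            pieces.append(mut)
            last = p + 1
            edits.append(TruthEdit(contig_id, p + off, EditKind.SUB, orig, mut))
        elif kd is EditKind.INS:
            b = "ACGT"[int(rng.integers(4))]
            pieces.append(genome[last:p])
            pieces.append(b)
            last = p
            edits.append(TruthEdit(contig_id, p + off, EditKind.INS, "", b))
            off += 1
        else:  # DEL
            pieces.append(genome[last:p])
            last = p + 1
            edits.append(TruthEdit(contig_id, p + off, EditKind.DEL, genome[p], ""))
            off -= 1
    pieces.append(genome[last:])
    return "".join(pieces), TruthSet(edits)


def simulate_reads(
    genome: str,
    coverage: float,
    read_len: int = 150,
    fragment_len: int = 500,
    error_rate: float = 0.01,
    seed: int = 0,
    name_prefix: str = "read",
) -> List[ReadPair]:
    """Paired-end reads: uniform fragments, mate 2 reverse-complemented,
    i.i.d. per-base substitution errors at ``error_rate``.

    Pair count = ceil(coverage * genome length / (2 * read_len)).  No read
    indels are modelled: substitution-only errors reproduce the low-count
    error tail of the k-mer histogram while keeping the truth simple.
    """
    L = len(genome)
    if not read_len <= fragment_len <= L:
        raise ValueError("need read_len <= fragment_len <= genome length")
    n_pairs = ceil(coverage * L / (2 * read_len))
    rng = np.random.default_rng(seed)
    g = _ENCODE[np.frombuffer(genome.encode("ascii"), dtype=np.uint8)]
    offsets = np.arange(read_len)
    pairs: List[ReadPair] = []
    chunk = 20_000
    made = 0
    while made < n_pairs:
        m = min(chunk, n_pairs - made)
        starts = rng.integers(0, L - fragment_len + 1, size=m)
        mat1 = g[starts[:, None] + offsets]
        mat2 = g[(starts + fragment_len - read_len)[:, None] + offsets]
        mat2 = 3 - mat2[:, ::-1]  # reverse complement of the fragment's 3' end
        if error_rate > 0:
            for mat in (mat1, mat2):
                mask = rng.random(mat.shape) < error_rate
                shifts = rng.integers(1, 4, size=int(mask.sum()))
                mat[mask] = (mat[mask] + shifts) % 4
        for i in range(m):
            pairs.append(
                ReadPair(
                    name=f"{name_prefix}_{made + i}",
                    read1=_decode(mat1[i]),
                    read2=_decode(mat2[i]),
                )
            )
        made += m
    return pairs


def iter_read_sequences(pairs: Iterable[ReadPair]) -> Iterator[str]:
    """Flatten pairs into the plain sequence stream the k-mer counter takes."""
    for p in pairs:
        yield p.read1
        yield p.read2


# ---------------------------------------------------------------------------
# truth-based evaluation


def _primitive_edits(
    removed: str, added: str, pos: int
) -> List[Tuple[int, str, str]]:
    """Decompose an edit into single-base primitives (pos, removed, added)."""
    if len(removed) == len(added) <= 1:
        return [(pos, removed, added)]
    if not removed:
        return [(pos, "", b) for b in added]
    if not added:
        return [(pos + i, b, "") for i, b in enumerate(removed)]
    out: List[Tuple[int, str, str]] = []
    sm = difflib.SequenceMatcher(a=removed, b=added, autojunk=False)
    for tag, i1, i2, j1, j2 in sm.get_opcodes():
        if tag == "equal":
            continue
        if tag == "replace":
            n = min(i2 - i1, j2 - j1)
            for t in range(n):
                out.append((pos + i1 + t, removed[i1 + t], added[j1 + t]))
            for t in range(n, i2 - i1):
                out.append((pos + i1 + t, removed[i1 + t], ""))
            for b in added[j1 + n : j2]:
                out.append((pos + i1 + n, "", b))
        elif tag == "delete":
            for t in range(i2 - i1):
                out.append((pos + i1 + t, removed[i1 + t], ""))
        else:  # insert
            for b in added[j1:j2]:
                out.append((pos + i1, "", b))
    return out


def _to_original_frame(p: int, events: List[Tuple[int, int]]) -> int:
    """Map a position in the partially-edited assembly back to the original
    mutated-assembly frame, given prior (orig_pos, length_delta) events."""
    s = 0
    for o, d in events:
        if o + s < p:
            s += d
        else:
            break
    return p - s


def _left_normalise(pos: int, removed: str, added: str, ref: Optional[str]) -> int:
    """Left-align a single-base (or homopolymer) indel in homopolymer context."""
    if ref is None:
        return pos
    indel = removed or added
    if not indel or len(set(indel)) != 1 or (removed and added):
        return pos
    c = indel[0]
    while pos > 0 and pos - 1 < len(ref) and ref[pos - 1] == c:
        pos -= 1
    return pos


def evaluate(
    corrections: Sequence[Correction],
    truth: TruthSet,
    assembly: Optional[str] = None,
    sequential: bool = True,
) -> EvalStats:
    """Score corrections against the injected truth.

    With ``sequential=True`` (the default, matching what the polisher
    returns) corrections are taken in application order and the positions of
    later corrections are mapped back through the length changes of earlier
    ones into the original mutated-assembly frame before matching.  Pass
    ``sequential=False`` when positions already refer to the original
    mutated assembly (e.g. a hand-built inverse of the truth set).

    ``assembly`` (the mutated, pre-polish sequence) enables
    left-normalisation of indel positions; without it positions are compared
    as-is.

    A correction is a true positive iff it exactly reverts a truth edit;
    anything else it does is a false positive, and unreverted truth edits are
    false negatives.
    """
    events: List[Tuple[int, int]] = []  # (orig_pos, length delta), sorted
    corr_prims: List[Tuple[int, str, str]] = []
    for corr in corrections:
        if sequential:
            orig = _to_original_frame(corr.position, events)
            bisect.insort(events, (orig, len(corr.added) - len(corr.removed)))
        else:
            orig = corr.position
        corr_prims.extend(_primitive_edits(corr.removed, corr.added, orig))

    truth_keys: dict = {}
    for e in truth.edits:
        pos = _left_normalise(e.position, e.mutated, e.original, assembly)
        key = (pos, e.mutated, e.original)
        truth_keys[key] = truth_keys.get(key, 0) + 1

    tp = fp = 0
    for pos, removed, added in corr_prims:
        pos = _left_normalise(pos, removed, added, assembly)
        key = (pos, removed, added)
        if truth_keys.get(key, 0) > 0:
            truth_keys[key] -= 1
            tp += 1
        else:
            fp += 1
    fn = sum(truth_keys.values())
    return EvalStats(tp=tp, fp=fp, fn=fn)
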