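"""Reliability thresholds derived from the k-mer count histogram.

A count histogram from low-error-rate reads is the overlay of two
distributions: erroneous k-mers piled up at low counts and genomic k-mers
centred near the sequencing coverage.  Their crossing point sits at the local
minimum of the observed curve, C_eq, where a k-mer is equally likely to be an
error or genuine.  Two cutoffs are derived from it:

    R_t = floor(0.5 * C_eq)    relative threshold
    A_t = round(0.5 * R_t)     absolute threshold (round half away from zero)

with A_t < R_t < C_eq.  Counts below A_t are outright unreliable; counts in
[A_t, R_t) are unreliable only after a sharp (>2x) drop from the previous
position, which separates sequence errors from smooth coverage dips.  The
derivation requires C_eq >= 4; below that the read data cannot support
polishing and :class:`UnsuitableDataError` is raised.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kmerdb import CountHistogram

__all__ = [
    "Thresholds",
    "NoMinimumError",
    "UnsuitableDataError",
    "find_ceq",
    "compute_thresholds",
    "thresholds_from_histogram",
]


class NoMinimumError(ValueError):
    """The histogram has no interior local minimum (no error/genomic valley)."""


class UnsuitableDataError(ValueError):
    """C_eq < 4: the read data is not suitable for polishing."""


@dataclass(frozen=True)
class Thresholds:
    """Reliability cutoffs A_t < R_t < C_eq."""

    c_eq: int
    r_t: int
    a_t: int

    def __post_init__(self) -> None:
        if not (self.a_t < self.r_t < self.c_eq):
            raise ValueError(
                f"thresholds must satisfy A_t < R_t < C_eq, got "
                f"{self.a_t} / {self.r_t} / {self.c_eq}"
            )


def _round_half_away(x: float) -> int:
    # round() in Python is banker's rounding; the threshold formula wants 2.5 -> 3
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def find_ceq(
    hist: CountHistogram,
    smooth_window: int = 1,
    max_count: int | None = None,
) -> int:
    """Locate the error/genomic crossover C_eq in a count histogram.

    Returns the smallest C >= 2 with N(C) <= N(C-1) and N(C) <= N(C+1)
    (ties broken toward the smaller C, which conservatively marks fewer
    k-mers unreliable).  Missing bins count as zero.

    ``smooth_window`` > 1 applies a centred moving average over N(C) before
    the scan, for histograms whose valley region is noisy; the default is the
    raw scan.  ``max_count`` optionally caps the search range.

    Raises :class:`NoMinimumError` when no interior minimum exists, e.g. for
    a monotone histogram with no error peak (error-free simulated reads).
    """
    if not hist.n_of_c:
        raise NoMinimumError("empty histogram")
    cmax = hist.max_count()
    # dense array over C = 1..cmax (+1 trailing zero bin)
    n = [0] * (cmax + 2)
    for c, v in hist.n_of_c.items():
        if c >= 1:
            n[c] = v
    if smooth_window > 1:
        half = smooth_window // 2
        sm = list(n)
        for c in range(1, cmax + 1):
            lo = max(1, c - half)
            hi = min(cmax, c + half)
            sm[c] = sum(n[lo : hi + 1]) / (hi - lo + 1)
        n = sm
    hi_c = cmax if max_count is None else min(cmax, max_count)
    for c in range(2, hi_c + 1):
        if n[c] <= n[c - 1] and n[c] <= n[c + 1]:
            return c
    raise NoMinimumError("histogram has no local minimum in the searched range")


def compute_thresholds(c_eq: int) -> Thresholds:
    """Derive R_t and A_t from C_eq.

    Raises :class:`UnsuitableDataError` for C_eq < 4.
    """
    if c_eq < 4:
        raise UnsuitableDataError(
            f"C_eq = {c_eq} < 4: input read data is not suitable for polishing"
        )
    r_t = int(0.5 * c_eq)  # floor: c_eq is positive
    a_t = _round_half_away(0.5 * r_t)
    return Thresholds(c_eq=c_eq, r_t=r_t, a_t=a_t)


def thresholds_from_histogram(
    hist: CountHistogram,
    c_eq: int | None = None,
    smooth_window: int = 1,
) -> Thresholds:
    """Convenience: locate C_eq (unless supplied manually) and derive cutoffs.

    A manual ``c_eq`` bypasses the histogram scan entirely — useful for
    degenerate synthetic histograms (e.g. error-free reads) that have no
    error peak and hence no local minimum.
    """
    if c_eq is None:
        c_eq = find_ceq(hist, smooth_window=smooth_window)
    return compute_thresholds(c_eq)
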