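"""Detection of microsatellite-like regions (MSRs) in nucleotide sequences.

A k-mer that recurs unusually often within a short stretch of sequence marks
a microsatellite-like region.  Significance is binomial: in random sequence
the number of occurrences of a fixed k-mer among ``t = L - k + 1`` start
positions of a window of length ``L`` is Binomial(t, p) with ``p = 1/A^k``
(A = 4 for nucleotides), so a recurrence count ``n`` is non-random when the
upper tail ``P(X >= n)`` falls below a significance level (default 1e-6).
For hexamers this yields the threshold ladder 6/1000 bp, 5/500 bp, 4/200 bp,
3/80 bp.

Occurrences of the same motif whose consecutive start-to-start intervals do
not exceed the motif length ``k`` (``I <= k``, i.e. overlapping or abutting
repeats) form candidate runs.  A run is significant when its occurrence count
meets the binomial threshold for its own span, with the span clamped to the
[80, 1000]-character window range: 1000 is the locality cap, and 80 — the
smallest window of the threshold ladder — guards against the selection effect
of judging a 2-occurrence run on its self-defined few-character span.  All k
from 1 to 6 are scanned; significant footprints closer than the motif length
are merged into single regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from scipy.stats import binom

__all__ = [
    "RecurrenceModel",
    "MsrInterval",
    "MsrAnnotation",
    "recurrence_tail_probability",
    "min_significant_count",
    "scan_sequence",
    "msr_fraction_summary",
]

NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class RecurrenceModel:
    """Parameters of the binomial recurrence test.

    ``min_window`` floors the significance window at the smallest scale of
    the threshold ladder; ``window_cap`` caps locality at 1000 characters.
    """

    alphabet_size: int = 4
    k_max: int = 6
    alpha: float = 1e-6
    window_cap: int = 1000
    min_window: int = 80

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.alphabet_size < 2 or self.k_max < 1:
            raise ValueError("invalid alphabet size or k range")
        if not (0 < self.min_window <= self.window_cap):
            raise ValueError("need 0 < min_window <= window_cap")

    def p(self, k: int) -> float:
        return float(self.alphabet_size) ** (-k)


@dataclass(frozen=True)
class MsrInterval:
    """0-based half-open interval on the nucleotide sequence."""

    start: int
    end: int
    k: int
    motif: str

    def __post_init__(self) -> None:
        if self.end - self.start < self.k:
            raise ValueError("interval shorter than its motif")


@dataclass
class MsrAnnotation:
    sequence_id: str
    length: int
    intervals: list[MsrInterval] = field(default_factory=list)

    @property
    def covered(self) -> int:
        return sum(iv.end - iv.start for iv in self.intervals)

    @property
    def msr_fraction(self) -> float:
        return self.covered / self.length if self.length else 0.0


def recurrence_tail_probability(L: int, k: int, n: int, A: int = 4) -> float:
    """Upper binomial tail ``P(X >= n)`` for k-mer recurrences in a window.

    Trials are the ``t = L - k + 1`` k-mer start positions; the per-trial
    probability is ``p = 1/A^k``.  Uses the survival function for numerical
    stability in the far tail.
    """
    if L < k:
        raise ValueError(f"window length {L} shorter than motif length {k}")
    if n < 0:
        raise ValueError("count must be non-negative")
    t = L - k + 1
    if n == 0:
        return 1.0
    if n > t:
        return 0.0
    return float(binom.sf(n - 1, t, float(A) ** (-k)))


@lru_cache(maxsize=None)
def min_significant_count(L: int, k: int, A: int = 4, alpha: float = 1e-6) -> int:
    """Smallest recurrence count with binomial tail below ``alpha``.

    Returns ``t + 1`` (an unattainable count) if no count in range is
    significant.
    """
    t = L - k + 1
    for n in range(1, t + 1):
        if recurrence_tail_probability(L, k, n, A) < alpha:
            return n
    return t + 1


def _runs(positions: list[int], k: int) -> list[list[int]]:
    """Maximal chains of occurrence starts with consecutive intervals I <= k."""
    runs: list[list[int]] = []
    current = [positions[0]]
    for p in positions[1:]:
        if p - current[-1] <= k:
            current.append(p)
        else:
            runs.append(current)
            current = [p]
    runs.append(current)
    return runs


def _significant_stretches(
    run: list[int], k: int, model: RecurrenceModel
) -> list[tuple[int, int]]:
    """Significant coverage [start, end) stretches within one occurrence run."""
    span = run[-1] + k - run[0]
    if span <= model.window_cap:
        L_eff = max(span, model.min_window)
        if len(run) >= min_significant_count(
            L_eff, k, model.alphabet_size, model.alpha
        ):
            return [(run[0], run[-1] + k)]
        return []
    # Run longer than the locality cap: judge each sliding 1000-char window of
    # occurrences; keep occurrences belonging to any significant window.
    n_min = min_significant_count(model.window_cap, k, model.alphabet_size, model.alpha)
    keep = [False] * len(run)
    j = 0
    for i in range(len(run)):
        while run[i] + k - run[j] > model.window_cap:
            j += 1
        if i - j + 1 >= n_min:
            for m in range(j, i + 1):
                keep[m] = True
    stretches: list[tuple[int, int]] = []
    start = None
    for flag, pos in zip(keep, run):
        if flag and start is None:
            start = pos
        if not flag and start is not None:
            stretches.append((start, prev + k))
            start = None
        if flag:
            prev = pos
    if start is not None:
        stretches.append((start, run[-1] + k))
    return stretches


def _merge_intervals(intervals: list[MsrInterval]) -> list[MsrInterval]:
    """Merge intervals separated by less than the motif length.

    When intervals from different k are adjacent, the larger motif length
    decides the merge distance; a merged interval carries the larger k and the
    motif of its left-most member.
    """
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged = [ordered[0]]
    for iv in ordered[1:]:
        last = merged[-1]
        if iv.start - last.end < max(iv.k, last.k):
            merged[-1] = MsrInterval(
                start=last.start,
                end=max(last.end, iv.end),
                k=max(last.k, iv.k),
                motif=last.motif,
            )
        else:
            merged.append(iv)
    return merged


def scan_sequence(
    seq: str,
    model: RecurrenceModel = RecurrenceModel(),
    sequence_id: str = "",
) -> MsrAnnotation:
    """Annotate one nucleotide sequence with merged MSR intervals.

    Motifs may overlap; all k in ``1..k_max`` are scanned and the per-k
    footprints are merged into one coverage track.  Characters outside ACGT
    never occur inside motifs and therefore break occurrence runs.
    """
    seq = seq.upper()
    n = len(seq)
    annotation = MsrAnnotation(sequence_id=sequence_id, length=n)
    raw: list[MsrInterval] = []
    for k in range(1, model.k_max + 1):
        if n < k:
            continue
        occurrences: dict[str, list[int]] = {}
        for i in range(n - k + 1):
            motif = seq[i : i + k]
            if NUCLEOTIDES.issuperset(motif):
                occurrences.setdefault(motif, []).append(i)
        for motif, positions in occurrences.items():
            for run in _runs(positions, k):
                if len(run) < 2:
                    continue
                for start, end in _significant_stretches(run, k, model):
                    raw.append(MsrInterval(start=start, end=end, k=k, motif=motif))
    annotation.intervals = _merge_intervals(raw)
    return annotation


def msr_fraction_summary(
    annotations_by_family: dict[str, list[MsrAnnotation]],
) -> dict[str, float]:
    """Per-family arithmetic mean of member MSR fractions."""
    out = {}
    for family, annotations in annotations_by_family.items():
        if not annotations:
            raise ValueError(f"family {family!r} has no annotations")
        out[family] = sum(a.msr_fraction for a in annotations) / len(annotations)
    return out
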