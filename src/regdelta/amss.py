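"""All maximal scoring subsequences (AMSS) of a real-valued sequence.

A maximal scoring subsequence (MSS) of a sequence ``x`` is a contiguous run
``x[i:j]`` such that (1) every proper contiguous subsequence of the run —
including the empty one, whose score is 0 — has a strictly lower sum, and
(2) no proper contiguous supersequence satisfies property (1).  The MSS of a
sequence are pairwise disjoint, have strictly positive scores, begin and end
on strictly positive elements, and jointly cover every positive element.

:func:`all_mss` implements the linear-time disjoint-subsequence bookkeeping
scheme of Ruzzo & Tompa; :func:`brute_force_amss` is an independent
quadratic reference used to verify it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["Mss", "subsequence_score", "all_mss", "brute_force_amss"]


@dataclass(frozen=True)
class Mss:
    """A scored subsequence ``[start, end)`` of the input (0-based, half-open)."""

    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def subsequence_score(x: Sequence[float], start: int, end: int) -> float:
    """Sum of ``x[start:end]``; the empty range ``start == end`` scores 0."""
    n = len(x)
    if not (0 <= start <= end <= n):
        raise IndexError(f"offsets [{start}, {end}) out of bounds for length {n}")
    return float(np.sum(np.asarray(x, dtype=float)[start:end]))


def all_mss(x: Sequence[float]) -> list[Mss]:
    """Return all maximal scoring subsequences of ``x``, sorted by start.

    Maintains a list of candidate subsequences, each recorded with the
    cumulative total L just before its start and the cumulative total R at
    its end.  Each strictly positive element opens a new candidate which is
    then either appended or merged leftward into the rightmost candidate
    whose L lies strictly below its own (merging only when that increases
    the candidate's R).  A previous-smaller-L chain keeps the leftward
    search amortised linear.
    """
    vals = np.asarray(x, dtype=float)
    if vals.ndim != 1:
        raise ValueError("input must be one-dimensional")
    if not np.all(np.isfinite(vals)):
        raise ValueError("input contains non-finite values")

    starts: list[int] = []
    ends: list[int] = []
    lefts: list[float] = []   # cumulative total before start
    rights: list[float] = []  # cumulative total through end
    psl: list[int] = []       # index of nearest candidate to the left with smaller L

    cum = 0.0
    for i, v in enumerate(vals):
        if v <= 0.0:
            cum += v
            continue
        left, right = cum, cum + v
        cum = right
        start, end = i, i + 1
        while True:
            # rightmost candidate j with L_j < left, via the smaller-L chain
            j = len(starts) - 1
            while j != -1 and lefts[j] >= left:
                j = psl[j]
            if j == -1 or rights[j] >= right:
                starts.append(start)
                ends.append(end)
                lefts.append(left)
                rights.append(right)
                psl.append(j)
                break
            # merge candidate j with the current run and retry from its L
            ends[j] = end
            rights[j] = right
            del starts[j + 1:], ends[j + 1:], lefts[j + 1:], rights[j + 1:], psl[j + 1:]
            start, end, left, right = starts[j], ends[j], lefts[j], rights[j]
            del starts[j:], ends[j:], lefts[j:], rights[j:], psl[j:]

    return [Mss(s, e, r - l) for s, e, l, r in zip(starts, ends, lefts, rights)]


def brute_force_amss(x: Sequence[float], guard: int = 2000) -> list[Mss]:
    """Quadratic reference for :func:`all_mss`; refuses inputs longer than ``guard``.

    An interval satisfies property (1) iff its total is positive and every
    proper nonempty prefix and suffix has a strictly positive sum (any
    interior subsequence is then the total minus a positive prefix and a
    positive suffix).  Property (2) removes intervals strictly contained in
    another property-(1) interval.
    """
    vals = np.asarray(x, dtype=float)
    n = len(vals)
    if n > guard:
        raise ValueError(f"sequence length {n} exceeds brute-force guard {guard}")
    cs = np.concatenate([[0.0], np.cumsum(vals)])

    prop1: list[tuple[int, int]] = []
    for i in range(n):
        if vals[i] <= 0.0:
            continue
        min_prefix = np.inf   # min over proper prefixes [i, l) of cs[l] - cs[i]
        max_interior = -np.inf  # max over interior l of cs[l]
        for j in range(i + 1, n + 1):
            total = cs[j] - cs[i]
            if total > 0.0 and min_prefix > 0.0 and cs[j] > max_interior:
                prop1.append((i, j))
            min_prefix = min(min_prefix, cs[j] - cs[i])
            max_interior = max(max_interior, cs[j])

    # keep intervals not strictly contained in another property-(1) interval
    prop1.sort(key=lambda ij: (ij[0], -ij[1]))
    out: list[Mss] = []
    max_end = -1
    for i, j in prop1:
        if j > max_end:
            out.append(Mss(i, j, float(cs[j] - cs[i])))
            max_end = j
    return out
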