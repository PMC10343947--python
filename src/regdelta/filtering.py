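"""Permutation-null filtering of MSS and merging of the two directions.

Even a pure-noise score sequence yields maximal scoring subsequences —
every positive element lies in one — so candidate subsequences are
compared against a permutation null: the sequence values are shuffled
(sampling without replacement) ``n_rand`` times, the maximum MSS score
over all shuffles is recorded, and only original MSS scoring strictly
above that maximum survive.  Raising ``n_rand`` can only raise the
threshold, trading sensitivity for stringency.

The per-permutation maximum MSS score equals the classical maximum
subarray sum (clipped at 0): the shortest subarray attaining the maximum
sum has strictly positive proper prefixes and suffixes, hence satisfies
the strict-subsequence property, and no higher-scoring supersequence can
exist at the global maximum.  :func:`max_mss_score` exploits this with a
vectorised cumulative-sum scan, which keeps thousands of randomizations
per window cheap; its agreement with the full MSS enumeration is checked
in the test suite.

Surviving subsequences from the two direction sequences (condition 1 >
condition 2 and vice versa) are merged: overlapping subsequences from
opposite directions are resolved by a greedy sweep in descending score
order, keeping a subsequence iff it overlaps nothing already kept.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .amss import Mss
from .density import GenomicWindow

__all__ = [
    "RegionOfChange",
    "max_mss_score",
    "randomization_threshold",
    "window_rng",
    "filter_mss",
    "merge_regions",
]

DIRECTION_12 = "c1>c2"
DIRECTION_21 = "c2>c1"


@dataclass
class RegionOfChange:
    """A direction-labelled window subinterval surviving filter and merge.

    Genomic coordinates are 0-based half-open; ``off_start``/``off_end``
    are the corresponding 5'->3' offsets within the window.  ``log2fc``
    and ``padj`` are attached later by the differential-usage test.
    """

    window_id: str
    chrom: str
    start: int
    end: int
    direction: str
    score: float
    off_start: int
    off_end: int
    log2fc: float | None = None
    pvalue: float | None = None
    padj: float | None = None


def max_mss_score(x: np.ndarray) -> float:
    """Maximum MSS score of ``x`` (= maximum subarray sum, floored at 0)."""
    z = np.empty(len(x) + 1)
    z[0] = 0.0
    np.cumsum(x, out=z[1:])
    best = float(np.max(z[1:] - np.minimum.accumulate(z[:-1])))
    return best if best > 0.0 else 0.0


def _batched_max_mss(perms: np.ndarray) -> float:
    """Max MSS score over rows of a (batch, n) matrix of permuted sequences."""
    b, n = perms.shape
    z = np.zeros((b, n + 1))
    np.cumsum(perms, axis=1, out=z[:, 1:])
    best = float(np.max(z[:, 1:] - np.minimum.accumulate(z[:, :-1], axis=1)))
    return best if best > 0.0 else 0.0


def randomization_threshold(
    x: Sequence[float],
    n_rand: int,
    rng: np.random.Generator,
    batch: int = 256,
) -> float:
    """Maximum MSS score over ``n_rand`` shuffles of ``x``; 0 if none has an MSS.

    Permutations are drawn one ``rng.permutation`` call each, so for a
    given generator state the first k shuffles of a longer run are exactly
    the shuffles of a shorter run (nested streams): the threshold is
    non-decreasing in ``n_rand``.  Scoring is batched for speed.
    """
    if n_rand < 1:
        raise ValueError(f"n_rand must be >= 1, got {n_rand}")
    vals = np.asarray(x, dtype=float)
    threshold = 0.0
    done = 0
    while done < n_rand:
        k = min(batch, n_rand - done)
        perms = np.stack([rng.permutation(vals) for _ in range(k)])
        threshold = max(threshold, _batched_max_mss(perms))
        done += k
    return threshold


def window_rng(seed: int, window_id: str, direction: str) -> np.random.Generator:
    """Reproducible per-(window, direction) random stream.

    The stream is derived from the global seed and a stable digest of the
    window id and direction, so results do not depend on window order or
    parallel scheduling.
    """
    key = f"{window_id}|{direction}".encode()
    digest = int.from_bytes(hashlib.sha256(key).digest()[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), digest]))


def filter_mss(candidates: Iterable[Mss], threshold: float) -> list[Mss]:
    """Keep candidates scoring strictly above the permutation threshold."""
    return [m for m in candidates if m.score > threshold]


def _check_disjoint(mss: Sequence[Mss], label: str) -> None:
    ordered = sorted(mss, key=lambda m: m.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"{label}: overlapping MSS [{a.start},{a.end}) and [{b.start},{b.end})")


def merge_regions(
    window: GenomicWindow, m12: Sequence[Mss], m21: Sequence[Mss]
) -> list[RegionOfChange]:
    """Merge direction-specific MSS sets into final regions of change.

    When subsequences from opposite directions overlap, only the highest
    scoring one is retained; cascading conflicts are resolved by a greedy
    sweep in descending score order.  Score ties prefer the longer
    interval, then the c1>c2 member.  Output is sorted by window offset
    and pairwise disjoint.
    """
    _check_disjoint(m12, f"window {window.id} direction {DIRECTION_12}")
    _check_disjoint(m21, f"window {window.id} direction {DIRECTION_21}")

    tagged = [(m, DIRECTION_12) for m in m12] + [(m, DIRECTION_21) for m in m21]
    tagged.sort(key=lambda t: (-t[0].score, -t[0].length, 0 if t[1] == DIRECTION_12 else 1, t[0].start))

    kept: list[tuple[Mss, str]] = []
    for m, direction in tagged:
        if all(m.end <= o.start or o.end <= m.start for o, _ in kept):
            kept.append((m, direction))
    kept.sort(key=lambda t: t[0].start)

    regions = []
    for m, direction in kept:
        gstart, gend = window.offset_to_genomic(m.start, m.end)
        regions.append(
            RegionOfChange(
                window_id=window.id,
                chrom=window.chrom,
                start=gstart,
                end=gend,
                direction=direction,
                score=m.score,
                off_start=m.start,
                off_end=m.end,
            )
        )
    return regions
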