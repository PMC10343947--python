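"""Per-window read densities and penalized score sequences.

For each genomic window w and sample, per-position read counts r(i) are
extracted from an indexed BAM file, normalized to densities d(i) = r(i) /
sum_i r(i), and averaged across replicates within each condition.  The two
condition-average densities d1, d2 are turned into a pair of directed score
sequences

    X12(i) = 100 * (d1(i) - d2(i)) - rho / |w|
    X21(i) = 100 * (d2(i) - d1(i)) - rho / |w|

on which maximal scoring subsequences are searched.  The uniform rho/|w|
subtraction acts as a linear length penalty: each score sequence sums to
exactly -rho, long zero stretches no longer bridge distant positive
elements, and larger pseudocounts rho yield shorter subsequences.

Vectors are always stored in 5'->3' window orientation: minus-strand
windows are reversed relative to genome coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicWindow",
    "CoverageVector",
    "DensityVector",
    "ScoreSequence",
    "read_bed_windows",
    "compute_coverage",
    "normalize_density",
    "average_density",
    "build_score_sequences",
]

CountMode = Literal["coverage", "end5", "end3"]


@dataclass(frozen=True)
class GenomicWindow:
    """A strand-aware half-open genomic interval; the unit of analysis."""

    id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window {self.id}: end {self.end} <= start {self.start}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"window {self.id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def offset_to_genomic(self, off_start: int, off_end: int) -> tuple[int, int]:
        """Map a 5'->3' window offset interval to genomic coordinates."""
        if not (0 <= off_start < off_end <= self.length):
            raise ValueError(
                f"window {self.id}: offsets [{off_start}, {off_end}) outside [0, {self.length})"
            )
        if self.strand == "-":
            return self.end - off_end, self.end - off_start
        return self.start + off_start, self.start + off_end


@dataclass
class CoverageVector:
    """Per-position read counts over a window, 5'->3'."""

    window_id: str
    sample_id: str
    condition: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if np.any(self.values < 0):
            raise ValueError("negative coverage")


@dataclass
class DensityVector:
    """Coverage normalized to sum to 1 over the window; ``defined`` is False
    when the window had zero total coverage (density then undefined)."""

    window_id: str
    label: str
    values: np.ndarray
    defined: bool = True


@dataclass
class ScoreSequence:
    """Directed, penalized density-difference sequence for one window."""

    window_id: str
    direction: str  # "1>2" or "2>1"
    values: np.ndarray
    rho: float


def read_bed_windows(path: str | Path) -> list[GenomicWindow]:
    """Read windows from a 3-6 column BED file.

    Column 4, when present and not ".", is used as the window id; otherwise
    an id of the form ``chrom:start-end`` is generated.  Column 6 strand is
    honored.  Ids must be unique.
    """
    windows: list[GenomicWindow] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] not in ("", ".") else f"{chrom}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            if name in seen:
                raise ValueError(f"{path}:{ln}: duplicate window id {name!r}")
            seen.add(name)
            windows.append(GenomicWindow(name, chrom, start, end, strand))
    return windows


def _read_matches_window_strand(read: pysam.AlignedSegment, strand: str) -> bool:
    if strand == ".":
        return True
    return ("-" if read.is_reverse else "+") == strand


def compute_coverage(
    alignments: pysam.AlignmentFile,
    window: GenomicWindow,
    mode: CountMode = "coverage",
    stranded: bool = False,
    sample_id: str = "",
    condition: int = 1,
) -> CoverageVector:
    """Per-position counts for one window from an indexed BAM.

    mode "coverage" adds 1 at every window position covered by an aligned
    block of a read; "end5"/"end3" add 1 only at the read's 5' or 3'
    terminal base.  With ``stranded`` set, only reads on the window's strand
    are counted (no-op for unstranded windows).  The returned vector is in
    5'->3' window orientation.  Reads that cannot be interpreted (missing
    CIGAR) are skipped and counted in a log message.
    """
    if window.chrom not in alignments.references:
        raise ValueError(
            f"window {window.id}: chromosome {window.chrom!r} absent from BAM header"
        )
    n = window.length
    cov = np.zeros(n, dtype=np.int64)
    skipped = 0
    for read in alignments.fetch(window.chrom, window.start, window.end):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if stranded and not _read_matches_window_strand(read, window.strand):
            continue
        if read.cigartuples is None:
            skipped += 1
            continue
        if mode == "coverage":
            for bstart, bend in read.get_blocks():
                lo = max(bstart, window.start) - window.start
                hi = min(bend, window.end) - window.start
                if hi > lo:
                    cov[lo:hi] += 1
        else:
            if mode == "end5":
                pos = read.reference_end - 1 if read.is_reverse else read.reference_start
            else:  # end3
                pos = read.reference_start if read.is_reverse else read.reference_end - 1
            if window.start <= pos < window.end:
                cov[pos - window.start] += 1
    if skipped:
        logger.warning("window %s: skipped %d malformed reads", window.id, skipped)
    if window.strand == "-":
        cov = cov[::-1]
    return CoverageVector(window.id, sample_id, condition, cov)


def normalize_density(cov: CoverageVector) -> DensityVector:
    """Divide counts by their total; zero-total vectors are flagged undefined."""
    total = int(cov.values.sum())
    if total == 0:
        return DensityVector(cov.window_id, cov.sample_id, np.zeros(len(cov.values)), defined=False)
    return DensityVector(cov.window_id, cov.sample_id, cov.values / total, defined=True)


def average_density(replicates: Sequence[DensityVector]) -> DensityVector:
    """Positionwise mean density across replicates of one condition.

    Undefined (zero-coverage) replicates are excluded from the mean; if no
    replicate is usable, the result is itself flagged undefined.
    """
    if not replicates:
        raise ValueError("no replicates given")
    wid = replicates[0].window_id
    n = len(replicates[0].values)
    for r in replicates:
        if r.window_id != wid:
            raise ValueError(f"mixed windows: {r.window_id!r} vs {wid!r}")
        if len(r.values) != n:
            raise ValueError(f"window {wid}: replicate length {len(r.values)} != {n}")
    usable = [r for r in replicates if r.defined]
    if not usable:
        return DensityVector(wid, "mean", np.zeros(n), defined=False)
    return DensityVector(wid, "mean", np.mean([r.values for r in usable], axis=0), defined=True)


def build_score_sequences(
    d1: DensityVector, d2: DensityVector, rho: float = 1.0
) -> tuple[ScoreSequence, ScoreSequence]:
    """Penalized directed difference sequences X12, X21 for one window.

    Each equals 100 times the density difference minus rho/n at every
    position; consequently each sums to exactly -rho and
    X12(i) + X21(i) = -2 rho / n.
    """
    if rho <= 0:
        raise ValueError(f"rho must be positive, got {rho}")
    if not (d1.defined and d2.defined):
        raise ValueError(f"window {d1.window_id}: undefined density, cannot score")
    if len(d1.values) != len(d2.values):
        raise ValueError(f"window {d1.window_id}: density lengths differ")
    n = len(d1.values)
    penalty = rho / n
    diff = 100.0 * (np.asarray(d1.values, float) - np.asarray(d2.values, float))
    x12 = ScoreSequence(d1.window_id, "1>2", diff - penalty, rho)
    x21 = ScoreSequence(d1.window_id, "2>1", -diff - penalty, rho)
    return x12, x21
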