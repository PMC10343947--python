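"""Differential relative usage of regions within their windows.

Detected regions of change only describe a difference between the two
condition-average densities; whether that difference is reproducible
across replicates is assessed with a differential-usage model in the
style of differential exon usage.  Each window plays the role of a
"gene": it is flattened into a tiling of exons — the regions of change
plus "filler" exons for the uncovered stretches before, between and
after them — reads are counted per exon per sample, and for every exon
that passes independent filtering a negative-binomial GLM is fitted to
the counts of (this exon, rest of window) pairs per sample:

    log mu = offset(size factor) + sample + bin + condition:bin

The condition x bin interaction measures the change in the exon's read
share relative to the rest of its window; its likelihood-ratio test
p-value (1 df) and its coefficient in log2 units (positive = relatively
higher usage in condition 1) are reported, with Benjamini-Hochberg
adjustment across all tested exons, regions and fillers together.

Dispersion is estimated per exon by method of moments on normalized
counts and shrunk in log space toward a 1/mean trend fitted across
exons; the shrinkage weight grows as replicate counts shrink.  This is a
deliberate reimplementation of the differential-exon-usage paradigm, not
a numerical clone of any particular package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .density import GenomicWindow
from .filtering import RegionOfChange

logger = logging.getLogger(__name__)

__all__ = [
    "FlattenedExon",
    "CountMatrix",
    "UsageResult",
    "flatten_annotation",
    "count_exon_reads",
    "compute_size_factors",
    "independent_filter",
    "test_differential_usage",
]

MIN_DISPERSION = 1e-8
MAX_DISPERSION = 10.0


@dataclass(frozen=True)
class FlattenedExon:
    """One element of a window's region/filler tiling."""

    window_id: str
    exon_index: int  # 1-based, 5'->3'
    kind: str        # "region" or "filler"
    chrom: str
    start: int
    end: int
    strand: str = "."
    direction: str | None = None  # regions only
    score: float | None = None    # MSS score, regions only

    @property
    def exon_id(self) -> str:
        return f"{self.window_id}:E{self.exon_index:03d}"


@dataclass
class CountMatrix:
    """Exon x sample read counts with condition labels and size factors."""

    counts: pd.DataFrame                 # rows: exon ids, columns: sample ids
    conditions: Mapping[str, int]        # sample id -> 1 or 2
    exons: Sequence[FlattenedExon]
    size_factors: pd.Series | None = None  # None = undefined (flagged)

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("size factors undefined")
        return self.counts / self.size_factors


@dataclass
class UsageResult:
    exon_id: str
    window_id: str
    kind: str
    direction: str | None
    log2fc: float | None
    pvalue: float | None
    padj: float | None
    tested: bool
    reason: str = ""


def flatten_annotation(
    window: GenomicWindow, regions: Sequence[RegionOfChange]
) -> list[FlattenedExon]:
    """Tile a window into region exons plus filler exons for the gaps.

    A window with two disjoint interior regions yields five exons: the two
    regions and three fillers (left of the first, between, right of the
    second).  A window with no regions is one filler exon.  Zero-length
    gaps (regions touching each other or a window edge) emit no filler.
    Exon indices run 5'->3' along the window.
    """
    for r in regions:
        if r.chrom != window.chrom or r.start < window.start or r.end > window.end:
            raise ValueError(
                f"region [{r.start},{r.end}) outside window {window.id} "
                f"[{window.start},{window.end})"
            )
    ordered = sorted(regions, key=lambda r: r.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"window {window.id}: overlapping regions")

    pieces: list[tuple[int, int, RegionOfChange | None]] = []
    cursor = window.start
    for r in ordered:
        if r.start > cursor:
            pieces.append((cursor, r.start, None))
        pieces.append((r.start, r.end, r))
        cursor = r.end
    if cursor < window.end:
        pieces.append((cursor, window.end, None))

    # exon_index follows the 5'->3' direction of the window
    if window.strand == "-":
        pieces = pieces[::-1]
    exons = []
    for idx, (start, end, region) in enumerate(pieces, 1):
        exons.append(
            FlattenedExon(
                window_id=window.id,
                exon_index=idx,
                kind="filler" if region is None else "region",
                chrom=window.chrom,
                start=start,
                end=end,
                strand=window.strand,
                direction=None if region is None else region.direction,
                score=None if region is None else region.score,
            )
        )
    return exons


def _fragment_key(read: pysam.AlignedSegment) -> str:
    return read.query_name or ""


def count_exon_reads(
    alignments: Mapping[str, pysam.AlignmentFile],
    exons: Sequence[FlattenedExon],
    conditions: Mapping[str, int],
    mode: str = "fragment",
    stranded: bool = False,
    require_nonzero: bool = True,
) -> CountMatrix:
    """Count reads per exon per sample; >=1 bp overlap assigns a read.

    A read is assigned to every exon it overlaps, so a read spanning an
    exon boundary counts in both flanking exons (exons of one window are
    the analysis unit, double assignment across them is intended).  In
    "fragment" mode the two mates of a paired read count once per exon; in
    "read" mode each alignment counts separately.  Size factors are
    computed by median-of-ratios over exons; a sample with zero total
    counts raises an error naming it unless ``require_nonzero`` is False,
    in which case size factors are left undefined.
    """
    if mode not in ("fragment", "read"):
        raise ValueError(f"unknown counting mode {mode!r}")
    exon_ids = [e.exon_id for e in exons]
    row_of = {eid: i for i, eid in enumerate(exon_ids)}
    by_window: dict[str, list[FlattenedExon]] = {}
    for e in exons:
        by_window.setdefault(e.window_id, []).append(e)

    samples = list(alignments)
    mat = np.zeros((len(exon_ids), len(samples)), dtype=np.int64)
    for col, sample in enumerate(samples):
        bam = alignments[sample]
        for wid, wexons in by_window.items():
            chrom = wexons[0].chrom
            span_start = min(e.start for e in wexons)
            span_end = max(e.end for e in wexons)
            strand = wexons[0].strand
            use_strand = stranded and strand in ("+", "-")
            # fast path: unspliced, unpaired reads as plain [start, end) spans
            starts: list[int] = []
            ends: list[int] = []
            slow: list[pysam.AlignedSegment] = []
            for read in bam.fetch(chrom, span_start, span_end):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if use_strand and ("-" if read.is_reverse else "+") != strand:
                    continue
                cig = read.cigarstring
                if cig is None:
                    continue
                if read.is_paired or "N" in cig:
                    slow.append(read)
                else:
                    starts.append(read.reference_start)
                    ends.append(read.reference_end)
            s_sorted = np.sort(np.asarray(starts, dtype=np.int64))
            e_sorted = np.sort(np.asarray(ends, dtype=np.int64))
            n_fast = len(s_sorted)
            seen: dict[str, set[str]] = {e.exon_id: set() for e in wexons} if mode == "fragment" else {}
            for e in wexons:
                # overlap iff start < exon.end and end > exon.start; the two
                # complements are disjoint because reads are nonempty
                n = n_fast
                n -= n_fast - int(np.searchsorted(s_sorted, e.end, side="left"))
                n -= int(np.searchsorted(e_sorted, e.start, side="right"))
                for read in slow:
                    blocks = read.get_blocks()
                    if any(bs < e.end and be > e.start for bs, be in blocks):
                        if mode == "fragment" and read.is_paired:
                            key = _fragment_key(read)
                            if key in seen[e.exon_id]:
                                continue
                            seen[e.exon_id].add(key)
                        n += 1
                mat[row_of[e.exon_id], col] = n

    counts = pd.DataFrame(mat, index=exon_ids, columns=samples)
    size_factors = compute_size_factors(counts, require_nonzero=require_nonzero)
    return CountMatrix(counts, dict(conditions), list(exons), size_factors)


def compute_size_factors(
    counts: pd.DataFrame, require_nonzero: bool = True
) -> pd.Series | None:
    """Median-of-ratios size factors; total-count ratios as fallback.

    Returns None (undefined) when every count is zero and
    ``require_nonzero`` is False.
    """
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        if require_nonzero:
            raise ValueError(f"sample {zero.index[0]!r} has zero total counts")
        return None
    positive = counts[(counts > 0).all(axis=1)]
    if len(positive) >= 2:
        logref = np.log(positive).mean(axis=1)
        sf = np.exp(np.median(np.log(positive).sub(logref, axis=0), axis=0))
        return pd.Series(sf, index=counts.columns)
    return totals / totals.mean()


def independent_filter(counts: CountMatrix, min_count: float = 10.0) -> set[str]:
    """Exon ids whose mean size-factor-normalized count is >= min_count.

    Low-count exons are excluded both from testing and from the BH family,
    reducing the multiple-testing burden.
    """
    norm = counts.normalized()
    means = norm.mean(axis=1)
    return set(means.index[means >= min_count])


def _mom_dispersion(norm_rows: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """Pooled method-of-moments NB dispersion from normalized counts."""
    num = 0.0
    den = 0.0
    for idx in groups:
        y = norm_rows[idx]
        if len(y) < 2:
            continue
        m = y.mean()
        if m <= 0:
            continue
        v = y.var(ddof=1)
        num += max(0.0, (v - m) / m**2) * (len(y) - 1)
        den += len(y) - 1
    if den == 0:
        return MIN_DISPERSION
    return float(np.clip(num / den, MIN_DISPERSION, MAX_DISPERSION))


def _dispersion_trend(means: np.ndarray, raws: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of dispersion ~ a0 + a1/mean, coefficients clipped >= 0."""
    ok = (means > 0) & np.isfinite(raws)
    if ok.sum() < 3:
        return float(np.median(raws[ok])) if ok.any() else MIN_DISPERSION, 0.0
    X = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
    coef, *_ = np.linalg.lstsq(X, raws[ok], rcond=None)
    return float(max(coef[0], 0.0)), float(max(coef[1], 0.0))


def test_differential_usage(
    counts: CountMatrix,
    design: Mapping[str, int] | None = None,
    alpha: float = 0.01,
    min_count: float = 10.0,
) -> list[UsageResult]:
    """NB-GLM likelihood-ratio test of condition x exon interaction per exon.

    Requires >=2 replicates per condition.  Exons failing independent
    filtering, exons of single-exon windows (no rest-of-window to compare
    against) and degenerate fits are returned flagged untested.  p-values
    are BH-adjusted across all tested exons.
    """
    design = dict(design) if design is not None else dict(counts.conditions)
    samples = list(counts.counts.columns)
    cond = np.array([design[s] for s in samples])
    for c in (1, 2):
        if (cond == c).sum() < 2:
            raise ValueError(f"need >=2 replicates for condition {c}")
    if counts.size_factors is None:
        raise ValueError("size factors undefined; cannot test")
    sf = counts.size_factors[samples].to_numpy(float)

    exons_by_window: dict[str, list[FlattenedExon]] = {}
    for e in counts.exons:
        exons_by_window.setdefault(e.window_id, []).append(e)
    testable = independent_filter(counts, min_count=min_count)

    mat = counts.counts.to_numpy(np.int64)
    row_of = {eid: i for i, eid in enumerate(counts.counts.index)}
    S = len(samples)

    # shared design columns: intercept, sample dummies, bin indicator, interaction
    # rows: S "this exon" observations then S "rest of window" observations
    sample_dummies = np.zeros((2 * S, S - 1))
    for s in range(1, S):
        sample_dummies[s, s - 1] = 1.0
        sample_dummies[S + s, s - 1] = 1.0
    bin_this = np.concatenate([np.ones(S), np.zeros(S)])
    inter = bin_this * np.concatenate([(cond == 1).astype(float)] * 2)
    X_full = np.column_stack([np.ones(2 * S), sample_dummies, bin_this, inter])
    X_red = X_full[:, :-1]
    offset = np.log(np.concatenate([sf, sf]))

    # dispersion: per-exon MoM on normalized "this" counts, then trend shrinkage
    norm = mat / sf[None, :]
    group_idx = [np.where(cond == 1)[0], np.where(cond == 2)[0]]
    raw_disp = np.array([_mom_dispersion(norm[i], group_idx) for i in range(len(mat))])
    mean_norm = norm.mean(axis=1)
    a0, a1 = _dispersion_trend(mean_norm, raw_disp)
    trend = np.clip(a0 + a1 / np.maximum(mean_norm, 1e-8), MIN_DISPERSION, MAX_DISPERSION)
    w_raw = (S - 2) / (S - 2 + 4.0)  # fewer replicates -> more trend shrinkage
    disp = np.exp(w_raw * np.log(np.maximum(raw_disp, MIN_DISPERSION))
                  + (1 - w_raw) * np.log(trend))

    results: list[UsageResult] = []
    tested_results: list[UsageResult] = []
    for wid, wexons in exons_by_window.items():
        rows = [row_of[e.exon_id] for e in wexons]
        window_totals = mat[rows].sum(axis=0)
        for e in wexons:
            r = row_of[e.exon_id]
            base = UsageResult(e.exon_id, wid, e.kind, e.direction, None, None, None, False)
            if len(wexons) < 2:
                base.reason = "single_exon"
                results.append(base)
                continue
            if e.exon_id not in testable:
                base.reason = "low_count"
                results.append(base)
                continue
            y_this = mat[r]
            y_rest = window_totals - y_this
            y = np.concatenate([y_this, y_rest]).astype(float)
            try:
                fam = sm.families.NegativeBinomial(alpha=float(disp[r]))
                full = sm.GLM(y, X_full, family=fam, offset=offset).fit(maxiter=200)
                red = sm.GLM(y, X_red, family=fam, offset=offset).fit(maxiter=200)
                lr = max(0.0, 2.0 * (full.llf - red.llf))
                pval = float(stats.chi2.sf(lr, 1))
                l2fc = float(full.params[-1] / np.log(2.0))
            except Exception as exc:  # degenerate fit
                base.reason = f"fit_failed:{type(exc).__name__}"
                results.append(base)
                continue
            if not np.isfinite(pval) or not np.isfinite(l2fc):
                base.reason = "fit_failed:nonfinite"
                results.append(base)
                continue
            res = UsageResult(e.exon_id, wid, e.kind, e.direction, l2fc, pval, None, True)
            results.append(res)
            tested_results.append(res)

    if tested_results:
        pvals = np.array([t.pvalue for t in tested_results])
        _, padj, _, _ = multipletests(pvals, method="fdr_bh")
        for t, q in zip(tested_results, padj):
            t.padj = float(q)
    return results
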