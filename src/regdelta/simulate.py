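"""Synthetic BED/BAM datasets with known density differences.

The generator emulates the signal classes that motivate targeted
window-level density comparison: a promoter-proximal occupancy peak that
shifts position between conditions (delayed polymerase pausing), on top
of a uniform background, with replicate-to-replicate depth
overdispersion.  Reads are single-end, fixed-length, and placed so their
3' end falls at the sampled position, matching nascent-transcription
(PRO-seq style) conventions and the 3'-end counting mode.

Ground truth for a window is the set of maximal intervals on which the
two generating probability profiles differ by more than a stated margin
(a fraction of the maximum absolute profile difference), labelled with
the direction of the difference.  Identical profiles yield an empty
truth list (a null dataset).

Reads are written as coordinate-sorted SAM text, converted to indexed
BAM with samtools.  For a fixed seed the generated BAM content is
byte-identical across runs: per-(sample, window) random substreams make
read placement independent of generation order.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .density import GenomicWindow

__all__ = [
    "ProfileSpec",
    "TruthRecord",
    "SimulatedDataset",
    "uniform_spec",
    "shifted_peak_spec",
    "truth_intervals",
    "simulate_windows",
    "simulate_mixture",
    "evaluate_recovery",
]


@dataclass
class ProfileSpec:
    """Generating conditions for one class of synthetic windows.

    ``profile1``/``profile2`` are per-position sampling probabilities for
    the read 3' end in conditions 1 and 2.  ``dispersion`` is the
    gamma-Poisson (negative binomial) overdispersion of per-replicate
    read depth around ``reads_per_replicate``.  ``truth_margin`` is the
    fraction of the maximum absolute profile difference above which a
    position counts as truly differential.
    """

    window_length: int
    profile1: np.ndarray
    profile2: np.ndarray
    reads_per_replicate: int = 50_000
    replicates: int = 3
    dispersion: float = 0.05
    read_length: int = 50
    truth_margin: float = 0.1

    def __post_init__(self) -> None:
        for name in ("profile1", "profile2"):
            p = np.asarray(getattr(self, name), dtype=float)
            if len(p) != self.window_length or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"{name} is not a probability vector over the window")
            setattr(self, name, p / p.sum())
        if self.replicates < 2:
            raise ValueError("need k >= 2 replicates")
        if self.reads_per_replicate < 1 or self.read_length < 1:
            raise ValueError("invalid read parameters")


@dataclass(frozen=True)
class TruthRecord:
    """True differential intervals of one window (genomic, 0-based half-open)."""

    window_id: str
    intervals: tuple[tuple[int, int, str], ...]  # (start, end, direction)


@dataclass
class SimulatedDataset:
    bed_path: Path
    bam_paths: dict[str, Path]       # sample id -> BAM
    conditions: dict[str, int]       # sample id -> 1 or 2
    windows: list[GenomicWindow]
    truth: list[TruthRecord]
    truth_path: Path


def _gaussian_peak(length: int, center: float, sigma: float) -> np.ndarray:
    x = np.arange(length)
    g = np.exp(-0.5 * ((x - center) / sigma) ** 2)
    return g / g.sum()


def uniform_spec(window_length: int = 6000, **kw) -> ProfileSpec:
    """Null spec: identical uniform profiles in both conditions."""
    u = np.full(window_length, 1.0 / window_length)
    return ProfileSpec(window_length, u, u.copy(), **kw)


def shifted_peak_spec(
    window_length: int = 6000,
    peak_center: float | None = None,
    shift: float = 200.0,
    sigma: float = 50.0,
    peak_weight: float = 0.5,
    **kw,
) -> ProfileSpec:
    """Peak-shift spec: a Gaussian occupancy peak moves by ``shift`` bp.

    Condition 1 places the peak at ``peak_center`` (window midpoint by
    default), condition 2 at ``peak_center + shift``; both mix the peak
    with a uniform background (``peak_weight`` on the peak).
    """
    if peak_center is None:
        peak_center = window_length / 2
    u = np.full(window_length, 1.0 / window_length)
    p1 = peak_weight * _gaussian_peak(window_length, peak_center, sigma) + (1 - peak_weight) * u
    p2 = peak_weight * _gaussian_peak(window_length, peak_center + shift, sigma) + (1 - peak_weight) * u
    return ProfileSpec(window_length, p1, p2, **kw)


def truth_intervals(spec: ProfileSpec) -> list[tuple[int, int, str]]:
    """Maximal window-offset runs where the profiles differ by > margin."""
    delta = spec.profile1 - spec.profile2
    peak = float(np.max(np.abs(delta)))
    if peak == 0.0:
        return []
    margin = spec.truth_margin * peak
    out: list[tuple[int, int, str]] = []
    for sign, direction in ((1, "c1>c2"), (-1, "c2>c1")):
        mask = sign * delta > margin
        edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append((int(s), int(e), direction))
    out.sort()
    return out


def _sample_names(replicates: int) -> tuple[list[str], dict[str, int]]:
    names, cond = [], {}
    for c in (1, 2):
        for r in range(1, replicates + 1):
            s = f"c{c}r{r}"
            names.append(s)
            cond[s] = c
    return names, cond


def simulate_windows(
    spec: ProfileSpec,
    n_windows: int,
    out_dir: str | Path,
    seed: int = 0,
    chrom: str = "chrSim",
    gap: int = 1000,
    prefix: str = "sim",
) -> SimulatedDataset:
    """Write BED windows, per-sample indexed BAMs and a truth TSV.

    Windows are laid out consecutively on one synthetic chromosome
    (plus strand).  Per replicate, the read count is drawn with the
    stated overdispersion around the target depth and 3'-end positions
    i.i.d. from the condition profile.
    """
    return simulate_mixture([(spec, n_windows)], out_dir, seed=seed, chrom=chrom,
                            gap=gap, prefix=prefix)


def simulate_mixture(
    specs: Sequence[tuple[ProfileSpec, int]],
    out_dir: str | Path,
    seed: int = 0,
    chrom: str = "chrSim",
    gap: int = 1000,
    prefix: str = "sim",
) -> SimulatedDataset:
    """One dataset combining several window classes (e.g. signal + null).

    Real window sets span a range of effect sizes, including many windows
    with no true change; mixing specs emulates that.  All specs must use
    the same replicate count.
    """
    if not specs:
        raise ValueError("need at least one (spec, count) pair")
    k = specs[0][0].replicates
    if any(s.replicates != k for s, _ in specs):
        raise ValueError("all specs must share the replicate count")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    margin = max(s.read_length for s, _ in specs) + 10

    windows: list[GenomicWindow] = []
    window_specs: list[ProfileSpec] = []
    cursor = margin
    i = 0
    for spec, n in specs:
        for _ in range(n):
            i += 1
            windows.append(GenomicWindow(f"{prefix}{i:04d}", chrom, cursor,
                                         cursor + spec.window_length, "+"))
            window_specs.append(spec)
            cursor += spec.window_length + gap
    chrom_len = cursor + margin

    bed_path = out_dir / "windows.bed"
    with open(bed_path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.id}\t0\t{w.strand}\n")

    spec_offsets = {id(s): truth_intervals(s) for s, _ in specs}
    truth = [
        TruthRecord(w.id, tuple((w.start + s, w.start + e, d)
                                for s, e, d in spec_offsets[id(ws)]))
        for w, ws in zip(windows, window_specs)
    ]
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("window_id\tchrom\tstart\tend\tdirection\n")
        for t in truth:
            for s, e, d in t.intervals:
                fh.write(f"{t.window_id}\t{chrom}\t{s}\t{e}\t{d}\n")

    names, conditions = _sample_names(k)
    bam_paths: dict[str, Path] = {}
    for si, sample in enumerate(names):
        sam_path = out_dir / f"{sample}.sam"
        with open(sam_path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:coordinate\n")
            fh.write(f"@SQ\tSN:{chrom}\tLN:{chrom_len}\n")
            for wi, (w, spec) in enumerate(zip(windows, window_specs)):
                profile = spec.profile1 if conditions[sample] == 1 else spec.profile2
                cigar = f"{spec.read_length}M"
                rng = np.random.default_rng(np.random.SeedSequence([int(seed), si, wi]))
                if spec.dispersion > 0:
                    lam = rng.gamma(1.0 / spec.dispersion, spec.reads_per_replicate * spec.dispersion)
                else:
                    lam = float(spec.reads_per_replicate)
                n_reads = int(rng.poisson(lam))
                pos3 = np.sort(rng.choice(spec.window_length, size=n_reads, p=profile))
                starts = w.start + pos3 - spec.read_length + 1  # 1-based SAM POS is +1
                lines = [
                    f"{sample}.{w.id}.{i}\t0\t{chrom}\t{starts[i] + 1}\t60\t{cigar}\t*\t0\t0\t*\t*\n"
                    for i in range(n_reads)
                ]
                fh.writelines(lines)
        bam_path = out_dir / f"{sample}.bam"
        subprocess.run(
            ["samtools", "view", "--no-PG", "-b", "-o", str(bam_path), str(sam_path)],
            check=True,
        )
        subprocess.run(["samtools", "index", str(bam_path)], check=True)
        sam_path.unlink()
        bam_paths[sample] = bam_path

    return SimulatedDataset(bed_path, bam_paths, conditions, windows, truth, truth_path)


def _interval_union_jaccard(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> float | None:
    """Jaccard index between two unions of genomic intervals."""
    if not a and not b:
        return None
    points = sorted({p for s, e in list(a) + list(b) for p in (s, e)})
    inter = union = 0
    for lo, hi in zip(points, points[1:]):
        in_a = any(s <= lo and hi <= e for s, e in a)
        in_b = any(s <= lo and hi <= e for s, e in b)
        if in_a and in_b:
            inter += hi - lo
        if in_a or in_b:
            union += hi - lo
    return inter / union if union else None


def evaluate_recovery(truth: Sequence[TruthRecord], regions, alpha: float = 0.01) -> dict:
    """Compare significant detected regions against simulation truth.

    ``regions`` maps window id -> list of regions (with padj attached).
    Returns mean per-(window, direction) Jaccard between the union of
    significant detected regions and the union of truth intervals, the
    fraction of significant regions whose direction matches the truth
    interval they overlap, and the fraction of significant regions whose
    log2 fold-change sign agrees with their direction label.
    """
    jaccards: list[float] = []
    dir_ok = dir_total = 0
    sign_ok = sign_total = 0
    for t in truth:
        regs = [r for r in regions.get(t.window_id, ())
                if r.padj is not None and r.padj <= alpha]
        for direction in ("c1>c2", "c2>c1"):
            det = [(r.start, r.end) for r in regs if r.direction == direction]
            tru = [(s, e) for s, e, d in t.intervals if d == direction]
            j = _interval_union_jaccard(det, tru)
            if j is not None:
                jaccards.append(j)
        for r in regs:
            hit = [d for s, e, d in t.intervals if s < r.end and e > r.start]
            if hit:
                dir_total += 1
                if r.direction in hit:
                    dir_ok += 1
            if r.log2fc is not None and r.log2fc != 0:
                sign_total += 1
                expected = 1.0 if r.direction == "c1>c2" else -1.0
                if np.sign(r.log2fc) == expected:
                    sign_ok += 1
    return {
        "mean_jaccard": float(np.mean(jaccards)) if jaccards else float("nan"),
        "n_jaccard": len(jaccards),
        "direction_accuracy": dir_ok / dir_total if dir_total else float("nan"),
        "n_direction": dir_total,
        "sign_consistency": sign_ok / sign_total if sign_total else float("nan"),
        "n_sign": sign_total,
    }
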