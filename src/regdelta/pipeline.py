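"""End-to-end orchestration: windows + BAMs in, annotated regions out.

For every input window the pipeline computes per-sample coverage,
normalizes to densities, averages within condition, builds the two
penalized score sequences, enumerates maximal scoring subsequences,
filters them against per-sequence permutation thresholds, and merges the
two directions into regions of change.  All windows are then flattened
into region/filler exons, reads are counted per exon per sample, and
differential relative usage is tested, attaching a log2 fold-change and
BH-adjusted p-value to every region.  Windows in which one condition
has no coverage are skipped and logged, not fatal.

With a fixed seed the complete run is deterministic — per-(window,
direction) random substreams make results independent of window order
and thread scheduling — so identical configurations produce identical
output files.
"""

from __future__ import annotations

import logging
import threading
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .amss import all_mss
from .clustering import occupancy_matrix
from .density import (
    GenomicWindow,
    average_density,
    build_score_sequences,
    compute_coverage,
    normalize_density,
    read_bed_windows,
)
from .filtering import (
    RegionOfChange,
    filter_mss,
    merge_regions,
    randomization_threshold,
    window_rng,
)
from .usage import (
    FlattenedExon,
    UsageResult,
    count_exon_reads,
    flatten_annotation,
    test_differential_usage,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "write_results", "read_results",
           "read_sample_sheet"]

RESULT_COLUMNS = [
    "window_id", "chrom", "start", "end", "kind", "direction",
    "mss_score", "log2fc", "pvalue", "padj", "tested", "reason",
]


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    ``samples`` maps sample id -> (BAM path, condition in {1, 2}); at
    least two replicates per condition are required.  ``count_mode``
    selects per-base coverage or single-base 5'/3'-end attribution for
    the density step; exon counting always uses >=1 bp overlap.
    """

    bed_path: str | Path
    samples: Mapping[str, tuple[str | Path, int]]
    out_dir: str | Path = "regdelta_out"
    rho: float = 1.0
    n_rand: int = 1000
    seed: int = 0
    count_mode: str = "coverage"
    stranded: bool = False
    fragment_mode: bool = True   # exon counting: mates count once
    min_count: float = 10.0
    alpha: float = 0.01
    threads: int = 1

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.n_rand < 1:
            raise ValueError("n_rand must be >= 1")
        if self.count_mode not in ("coverage", "end5", "end3"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")
        for c in (1, 2):
            k = sum(1 for _, cond in self.samples.values() if cond == c)
            if k < 2:
                raise ValueError(f"condition {c}: need >=2 replicates, found {k}")


@dataclass
class RunResult:
    windows: list[GenomicWindow]
    regions: dict[str, list[RegionOfChange]]   # window id -> merged regions
    skipped: dict[str, str]                    # window id -> reason
    exons: list[FlattenedExon]
    counts: pd.DataFrame
    size_factors: pd.Series
    usage: list[UsageResult]
    results: pd.DataFrame
    paths: dict[str, Path]

    def significant_regions(self, alpha: float = 0.01) -> list[RegionOfChange]:
        return [
            r
            for regs in self.regions.values()
            for r in regs
            if r.padj is not None and r.padj <= alpha
        ]


def read_sample_sheet(path: str | Path) -> dict[str, tuple[Path, int]]:
    """Sample sheet: BAM path <TAB> condition (1/2) [<TAB> sample id]."""
    samples: dict[str, tuple[Path, int]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: need at least 2 columns")
            bam, cond = Path(parts[0]), int(parts[1])
            sid = parts[2] if len(parts) > 2 else f"s{ln}"
            if cond not in (1, 2):
                raise ValueError(f"{path}:{ln}: condition must be 1 or 2")
            if sid in samples:
                raise ValueError(f"{path}:{ln}: duplicate sample id {sid!r}")
            samples[sid] = (bam, cond)
    return samples


def _detect_window(
    window: GenomicWindow,
    handles: Mapping[str, pysam.AlignmentFile],
    config: RunConfig,
) -> tuple[list[RegionOfChange] | None, str]:
    """Detection stage for one window; returns (regions, skip_reason)."""
    by_cond: dict[int, list] = {1: [], 2: []}
    for sid, (path, cond) in config.samples.items():
        cov = compute_coverage(
            handles[sid], window, mode=config.count_mode, stranded=config.stranded,
            sample_id=sid, condition=cond,
        )
        by_cond[cond].append(normalize_density(cov))
    d1 = average_density(by_cond[1])
    d2 = average_density(by_cond[2])
    if not d1.defined or not d2.defined:
        missing = [str(c) for c, d in ((1, d1), (2, d2)) if not d.defined]
        return None, f"zero coverage in condition(s) {','.join(missing)}"
    x12, x21 = build_score_sequences(d1, d2, rho=config.rho)
    surviving = {}
    for seq in (x12, x21):
        candidates = all_mss(seq.values)
        rng = window_rng(config.seed, window.id, seq.direction)
        thr = randomization_threshold(seq.values, config.n_rand, rng)
        surviving[seq.direction] = filter_mss(candidates, thr)
    regions = merge_regions(window, surviving["1>2"], surviving["2>1"])
    return regions, ""


def run_pipeline(config: RunConfig) -> RunResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("regdelta")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out_dir: Path) -> RunResult:
    windows = read_bed_windows(config.bed_path)
    logger.info("loaded %d windows from %s", len(windows), config.bed_path)

    local = threading.local()

    def get_handles() -> dict[str, pysam.AlignmentFile]:
        if not hasattr(local, "handles"):
            local.handles = {
                sid: pysam.AlignmentFile(str(path)) for sid, (path, _) in config.samples.items()
            }
        return local.handles

    def worker(w: GenomicWindow):
        return _detect_window(w, get_handles(), config)

    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            outcomes = list(pool.map(worker, windows))
    else:
        outcomes = [worker(w) for w in windows]

    regions: dict[str, list[RegionOfChange]] = {}
    skipped: dict[str, str] = {}
    analyzed: list[GenomicWindow] = []
    for w, (regs, reason) in zip(windows, outcomes):
        if regs is None:
            skipped[w.id] = reason
            logger.warning("window %s skipped: %s", w.id, reason)
        else:
            regions[w.id] = regs
            analyzed.append(w)
    logger.info(
        "detection: %d windows analyzed, %d skipped, %d regions of change",
        len(analyzed), len(skipped), sum(len(r) for r in regions.values()),
    )

    exons: list[FlattenedExon] = []
    for w in analyzed:
        exons.extend(flatten_annotation(w, regions[w.id]))

    handles = {sid: pysam.AlignmentFile(str(path)) for sid, (path, _) in config.samples.items()}
    conditions = {sid: cond for sid, (_, cond) in config.samples.items()}
    cm = count_exon_reads(
        handles, exons, conditions,
        mode="fragment" if config.fragment_mode else "read",
        stranded=config.stranded,
    )
    for h in handles.values():
        h.close()

    usage = test_differential_usage(cm, conditions, alpha=config.alpha, min_count=config.min_count)
    n_tested = sum(u.tested for u in usage)
    n_filtered = sum(u.reason == "low_count" for u in usage)
    logger.info("usage test: %d exons tested, %d removed by independent filtering", n_tested, n_filtered)

    # attach usage statistics to regions via their exon ids
    usage_by_id = {u.exon_id: u for u in usage}
    region_by_coords = {
        (r.window_id, r.start, r.end): r for regs in regions.values() for r in regs
    }
    for e in exons:
        if e.kind != "region":
            continue
        u = usage_by_id[e.exon_id]
        r = region_by_coords[(e.window_id, e.start, e.end)]
        r.log2fc, r.pvalue, r.padj = u.log2fc, u.pvalue, u.padj

    results = _results_frame(analyzed, exons, usage_by_id)
    paths = _write_outputs(out_dir, config, analyzed, regions, exons, cm, results)
    return RunResult(
        windows, regions, skipped, exons, cm.counts, cm.size_factors, usage, results, paths
    )


def _results_frame(
    windows: Sequence[GenomicWindow],
    exons: Sequence[FlattenedExon],
    usage_by_id: Mapping[str, UsageResult],
) -> pd.DataFrame:
    order = {w.id: i for i, w in enumerate(windows)}
    rows = []
    for e in sorted(exons, key=lambda e: (order[e.window_id], e.start)):
        u = usage_by_id[e.exon_id]
        rows.append({
            "window_id": e.window_id,
            "chrom": e.chrom,
            "start": e.start + 1,  # results TSV is 1-based inclusive
            "end": e.end,
            "kind": e.kind,
            "direction": e.direction if e.direction else ".",
            "mss_score": e.score if e.score is not None else np.nan,
            "log2fc": u.log2fc if u.log2fc is not None else np.nan,
            "pvalue": u.pvalue if u.pvalue is not None else np.nan,
            "padj": u.padj if u.padj is not None else np.nan,
            "tested": bool(u.tested),
            "reason": u.reason,
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: pd.DataFrame, path: str | Path) -> Path:
    """Write the results table; coordinates are 1-based inclusive."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# regdelta results; start/end are 1-based inclusive\n")
        results.to_csv(fh, sep="\t", index=False, na_rep="NA")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=RESULT_COLUMNS, header=0,
                     dtype={"window_id": str, "chrom": str, "direction": str, "reason": str})
    df["reason"] = df["reason"].fillna("")
    return df


def _write_outputs(out_dir, config, windows, regions, exons, cm, results) -> dict[str, Path]:
    paths = {"results": write_results(results, out_dir / "results.tsv")}

    bed = out_dir / "regions.bed"
    with open(bed, "w") as fh:
        wid_order = {w.id: i for i, w in enumerate(windows)}
        flat = sorted(
            (r for regs in regions.values() for r in regs),
            key=lambda r: (wid_order[r.window_id], r.start),
        )
        for r in flat:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.window_id}|{r.direction}\t{r.score:.6g}\t.\n")
    paths["regions_bed"] = bed

    gff = out_dir / "flattened.gff"
    by_window: dict[str, list[FlattenedExon]] = {}
    for e in exons:
        by_window.setdefault(e.window_id, []).append(e)
    with open(gff, "w") as fh:
        for w in windows:
            wexons = sorted(by_window[w.id], key=lambda e: e.start)
            strand = w.strand if w.strand in "+-" else "."
            fh.write(
                f"{w.chrom}\tregdelta\taggregate_gene\t{w.start + 1}\t{w.end}\t.\t{strand}\t.\t"
                f'gene_id "{w.id}"\n'
            )
            for e in wexons:
                fh.write(
                    f"{e.chrom}\tregdelta\texonic_part\t{e.start + 1}\t{e.end}\t.\t{strand}\t.\t"
                    f'transcripts "{w.id}"; exonic_part_number "{e.exon_index:03d}"; gene_id "{w.id}"\n'
                )
    paths["gff"] = gff

    counts_path = out_dir / "counts.tsv"
    cm.counts.rename_axis("exon_id").to_csv(counts_path, sep="\t")
    paths["counts"] = counts_path

    sf_path = out_dir / "size_factors.tsv"
    cm.size_factors.rename("size_factor").rename_axis("sample").to_csv(sf_path, sep="\t")
    paths["size_factors"] = sf_path

    occ = occupancy_matrix(windows, regions, mode="absolute", only_significant=True,
                           alpha=config.alpha)
    occ_path = out_dir / "occupancy.tsv"
    pd.DataFrame(occ.values, index=occ.window_ids).rename_axis("window_id").to_csv(
        occ_path, sep="\t"
    )
    paths["occupancy"] = occ_path
    paths["log"] = out_dir / "run.log"
    return paths
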