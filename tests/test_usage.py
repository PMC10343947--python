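"""Window flattening, exon counting, and the NB-GLM differential-usage test."""

import numpy as np
import pandas as pd
import pysam
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from regdelta.density import GenomicWindow
from regdelta.filtering import RegionOfChange
from regdelta.usage import (
    CountMatrix,
    FlattenedExon,
    compute_size_factors,
    count_exon_reads,
    flatten_annotation,
    independent_filter,
    test_differential_usage as run_usage_test,
)


def region(wid, chrom, start, end, direction="c1>c2", w=None):
    off_s = start - w.start if w else 0
    off_e = end - w.start if w else end - start
    return RegionOfChange(wid, chrom, start, end, direction, 1.0, off_s, off_e)


class TestFlatten:
    def test_two_interior_regions_make_five_exons(self):
        w = GenomicWindow("g", "chr1", 0, 100, "+")
        regs = [region("g", "chr1", 20, 40, w=w), region("g", "chr1", 60, 80, "c2>c1", w=w)]
        exons = flatten_annotation(w, regs)
        assert [(e.start, e.end, e.kind) for e in exons] == [
            (0, 20, "filler"), (20, 40, "region"), (40, 60, "filler"),
            (60, 80, "region"), (80, 100, "filler"),
        ]
        assert [e.exon_index for e in exons] == [1, 2, 3, 4, 5]

    def test_no_regions_single_filler(self):
        w = GenomicWindow("g", "chr1", 0, 100, "+")
        exons = flatten_annotation(w, [])
        assert [(e.start, e.end, e.kind) for e in exons] == [(0, 100, "filler")]

    def test_region_at_window_edge_no_empty_filler(self):
        w = GenomicWindow("g", "chr1", 0, 100, "+")
        exons = flatten_annotation(w, [region("g", "chr1", 0, 40, w=w)])
        assert [(e.start, e.end, e.kind) for e in exons] == [
            (0, 40, "region"), (40, 100, "filler"),
        ]

    def test_region_outside_window_rejected(self):
        w = GenomicWindow("g", "chr1", 10, 100, "+")
        with pytest.raises(ValueError):
            flatten_annotation(w, [region("g", "chr1", 0, 40, w=None)])

    def test_minus_strand_indices_run_5prime_to_3prime(self):
        w = GenomicWindow("g", "chr1", 0, 100, "-")
        exons = flatten_annotation(w, [RegionOfChange("g", "chr1", 70, 90, "c1>c2", 1.0, 10, 30)])
        by_index = {e.exon_index: (e.start, e.end) for e in exons}
        # 5' end of a minus-strand window is the genomic right edge
        assert by_index[1] == (90, 100)
        assert by_index[2] == (70, 90)
        assert by_index[3] == (0, 70)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.tuples(st.integers(0, 99), st.integers(1, 30)), max_size=6))
    def test_tiling_property(self, raw):
        """Exons tile the window exactly for arbitrary region configurations."""
        w = GenomicWindow("g", "chr1", 0, 100, "+")
        regions, cursor = [], 0
        for gap, length in raw:
            start = cursor + gap
            end = min(start + length, 100)
            if start >= 100 or end <= start:
                break
            regions.append(RegionOfChange("g", "chr1", start, end, "c1>c2", 1.0, start, end))
            cursor = end
        exons = sorted(flatten_annotation(w, regions), key=lambda e: e.start)
        assert exons[0].start == 0 and exons[-1].end == 100
        for a, b in zip(exons, exons[1:]):
            assert a.end == b.start  # gap-free and disjoint
        assert sum(e.kind == "region" for e in exons) == len(regions)


class TestCounting:
    def exons(self):
        return [
            FlattenedExon("g", 1, "region", "chr1", 100, 150, "+"),
            FlattenedExon("g", 2, "filler", "chr1", 150, 200, "+"),
        ]

    def test_single_read_single_exon(self, make_bam):
        bam = {"s1": pysam.AlignmentFile(make_bam([(110, "10M", False)], name="a.bam")),
               "s2": pysam.AlignmentFile(make_bam([(160, "10M", False)], name="b.bam"))}
        cm = count_exon_reads(bam, self.exons(), {"s1": 1, "s2": 2})
        assert cm.counts.loc["g:E001", "s1"] == 1
        assert cm.counts.loc["g:E002", "s1"] == 0
        assert cm.counts.loc["g:E002", "s2"] == 1

    def test_boundary_spanning_read_counted_in_both(self, make_bam):
        bam = {"s1": pysam.AlignmentFile(make_bam([(145, "10M", False)], name="a.bam")),
               "s2": pysam.AlignmentFile(make_bam([(300, "10M", False)], name="b.bam"))}
        cm = count_exon_reads(bam, self.exons(), {"s1": 1, "s2": 2}, require_nonzero=False)
        assert cm.counts.loc["g:E001", "s1"] == 1
        assert cm.counts.loc["g:E002", "s1"] == 1

    def test_zero_total_sample_error_names_sample(self, make_bam):
        bam = {"bad": pysam.AlignmentFile(make_bam([(5000, "10M", False)], name="a.bam")),
               "ok": pysam.AlignmentFile(make_bam([(110, "10M", False)], name="b.bam"))}
        with pytest.raises(ValueError, match="bad"):
            count_exon_reads(bam, self.exons(), {"bad": 1, "ok": 2})

    def test_all_zero_flagged_when_not_strict(self, make_bam):
        bam = {"s1": pysam.AlignmentFile(make_bam([(5000, "10M", False)], name="a.bam"))}
        cm = count_exon_reads(bam, self.exons(), {"s1": 1}, require_nonzero=False)
        assert cm.size_factors is None
        assert (cm.counts == 0).all().all()


class TestSizeFactors:
    def test_median_of_ratios_scaling(self):
        base = pd.DataFrame({"a": [10, 20, 40, 80], "b": [20, 40, 80, 160]})
        sf = compute_size_factors(base)
        # sample b has exactly twice the depth at identical composition
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_independent_filter_boundary_and_monotonicity(self):
        counts = pd.DataFrame({"a": [0, 10, 5], "b": [0, 10, 5]},
                              index=["e0", "e1", "e2"])
        cm = CountMatrix(counts, {"a": 1, "b": 2}, [],
                         size_factors=pd.Series([1.0, 1.0], index=["a", "b"]))
        kept = independent_filter(cm, min_count=10)
        assert kept == {"e1"}  # mean exactly at threshold is included; zeros out
        assert len(independent_filter(cm, min_count=5)) >= len(kept)


def simulate_counts(rng, n_windows, share1, share2, depth=50_000, k=3, disp=0.05):
    """Two-exon windows with given exon-1 read share per condition (NB noise)."""
    rows, index = [], []
    samples = [f"c{c}r{r}" for c in (1, 2) for r in range(1, k + 1)]
    conditions = {s: int(s[1]) for s in samples}
    exons = []
    for w in range(n_windows):
        wid = f"w{w}"
        e1 = FlattenedExon(wid, 1, "region", "chr1", 0, 100, "+", "c1>c2")
        e2 = FlattenedExon(wid, 2, "filler", "chr1", 100, 1000, "+")
        exons += [e1, e2]
        r1, r2 = [], []
        for s in samples:
            share = share1 if conditions[s] == 1 else share2
            lam = rng.gamma(1 / disp, depth * disp) if disp > 0 else depth
            total = rng.poisson(lam)
            x = rng.binomial(total, share)
            r1.append(x)
            r2.append(total - x)
        rows += [r1, r2]
        index += [e1.exon_id, e2.exon_id]
    counts = pd.DataFrame(rows, index=index, columns=samples)
    return CountMatrix(counts, conditions, exons, compute_size_factors(counts)), conditions


class TestDifferentialUsage:
    def test_requires_two_replicates_per_condition(self, rng):
        cm, cond = simulate_counts(rng, 2, 0.2, 0.2, k=2)
        bad = dict(cond)
        bad["c2r2"] = 1
        with pytest.raises(ValueError):
            run_usage_test(cm, bad)

    def test_proportional_counts_no_signal(self):
        samples = ["c1r1", "c1r2", "c2r1", "c2r2"]
        cond = {s: int(s[1]) for s in samples}
        exons = [FlattenedExon("w", 1, "region", "chr1", 0, 50, "+", "c1>c2"),
                 FlattenedExon("w", 2, "filler", "chr1", 50, 100, "+")]
        counts = pd.DataFrame(
            [[100, 200, 150, 300], [400, 800, 600, 1200]],
            index=[e.exon_id for e in exons], columns=samples,
        )
        cm = CountMatrix(counts, cond, exons, compute_size_factors(counts))
        res = {r.exon_id: r for r in run_usage_test(cm, cond)}
        r = res["w:E001"]
        assert r.tested
        assert abs(r.log2fc) < 0.05
        assert r.pvalue > 0.5

    def test_single_exon_window_untested(self):
        samples = ["c1r1", "c1r2", "c2r1", "c2r2"]
        cond = {s: int(s[1]) for s in samples}
        exons = [FlattenedExon("w", 1, "filler", "chr1", 0, 100, "+")]
        counts = pd.DataFrame([[50, 60, 55, 45]], index=["w:E001"], columns=samples)
        cm = CountMatrix(counts, cond, exons, compute_size_factors(counts))
        res = run_usage_test(cm, cond)
        assert not res[0].tested and res[0].reason == "single_exon"

    def test_parameter_recovery_threefold_density(self, rng):
        """Condition 1 with 3x the relative density in one exon: log2fc near
        log2(3), strongly significant, across 20 replicate simulations."""
        l2fcs = []
        for _ in range(20):
            cm, cond = simulate_counts(rng, 1, 0.03, 0.01)
            res = [r for r in run_usage_test(cm, cond) if r.exon_id.endswith("E001")]
            assert res[0].tested
            assert res[0].padj <= 0.01
            l2fcs.append(res[0].log2fc)
        assert np.mean(l2fcs) == pytest.approx(np.log2(3), abs=0.3)

    def test_null_type_one_error_control(self, rng):
        """Same generative distribution in both conditions: almost nothing
        reaches padj <= 0.01."""
        cm, cond = simulate_counts(rng, 500, 0.2, 0.2, depth=5000)
        res = [r for r in run_usage_test(cm, cond) if r.tested]
        assert len(res) > 500
        frac = np.mean([r.padj <= 0.01 for r in res])
        assert frac < 0.02

    def test_bh_monotonicity(self, rng):
        cm, cond = simulate_counts(rng, 100, 0.2, 0.2, depth=5000)
        res = sorted((r for r in run_usage_test(cm, cond) if r.tested),
                     key=lambda r: r.pvalue)
        for a, b in zip(res, res[1:]):
            assert a.padj <= b.padj + 1e-12
            assert a.padj >= a.pvalue - 1e-12

    def test_null_pvalues_approximately_uniform_poisson(self, rng):
        """With Poisson counts (no overdispersion) the LRT p-values are close
        to uniform under the null: KS distance < 0.1 over 2000 exons."""
        cm, cond = simulate_counts(rng, 1000, 0.3, 0.3, depth=2000, disp=0.0)
        res = [r for r in run_usage_test(cm, cond) if r.tested]
        pvals = np.array([r.pvalue for r in res])
        assert len(pvals) >= 1900
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.1
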