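import numpy as np
import pysam
import pytest


@pytest.fixture
def make_bam(tmp_path):
    """Build a tiny indexed BAM from (start, cigar, is_reverse) read tuples."""

    def _make(reads, chrom="chr1", chrom_len=10_000, name="toy.bam", paired_names=None):
        path = tmp_path / name
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": chrom, "LN": chrom_len}]}
        reads = sorted(reads, key=lambda r: r[0])
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            for i, (start, cigar, is_reverse) in enumerate(reads):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = paired_names[i] if paired_names else f"r{i}"
                a.reference_id = 0
                a.reference_start = start
                a.cigarstring = cigar
                a.mapping_quality = 60
                a.flag = 16 if is_reverse else 0
                bam.write(a)
        pysam.index(str(path))
        return path

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
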