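import numpy as np
import pytest

from pirnakit.io_model import AlignedRead, GenomicInterval


def make_read(chrom, start, end, strand, read_id="r", copy_count=1):
    return AlignedRead(GenomicInterval(chrom, start, end, strand), read_id,
                       copy_count)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bed_file(tmp_path):
    path = tmp_path / "reads.bed"
    path.write_text(
        "chr1\t100\t130\tr1\t0\t+\n"
        "chr1\t200\t226\tr2\t0\t-\n"
        "chr2\t50\t76\tr3\t0\t+\n"
    )
    return path
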