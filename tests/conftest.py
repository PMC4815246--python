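import numpy as np
import pytest

from dipseq.core import ChromSizes, GeneModel, GenomicInterval, TagLibrary


@pytest.fixture
def chrom_sizes():
    return ChromSizes({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def library_factory():
    """Build a TagLibrary from explicit per-chromosome position lists."""

    def make(positions: dict[str, list[int]], **meta) -> TagLibrary:
        defaults = dict(
            library_id="test", tissue="hippocampus", condition="sham",
            mark="5mC", replicate=1,
        )
        defaults.update(meta)
        return TagLibrary(
            positions={c: np.asarray(p, dtype=np.int64) for c, p in positions.items()},
            **defaults,
        )

    return make


@pytest.fixture
def simple_gene():
    """+ strand gene on chr1 [10000, 20000) with two exons and one intron."""
    iv = GenomicInterval("chr1", 10_000, 20_000, strand="+")
    exons = [
        GenomicInterval("chr1", 10_000, 12_000, strand="+"),
        GenomicInterval("chr1", 18_000, 20_000, strand="+"),
    ]
    return GeneModel("geneA", iv, exons)


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval, frac: float = 0.5) -> bool:
    """>= frac reciprocal overlap between two intervals."""
    if a.chrom != b.chrom:
        return False
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    return ov >= frac * a.length and ov >= frac * b.length
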