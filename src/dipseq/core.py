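"""Core genomic data types.

All coordinates are 0-based, half-open (BED convention) throughout the
package; 1-based conversions happen only at I/O boundaries (wiggle export).
Tag positions are the 5' end of the mapped read; reads are not extended to
fragment length (configurable upstream, default off).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

STRANDS = ("+", "-", ".")

TISSUES = ("hippocampus", "ventricle")
CONDITIONS = ("sham", "proton")
MARKS = ("5mC", "5hmC")

#: Closed vocabulary of repeat classes (RepBase-style coarse classes).
REPEAT_CLASSES = ("SINE", "LINE", "LTR", "satellite", "tRNA", "rRNA", "other")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span [start, end) on a named chromosome.

    The universal coordinate currency of the package: enriched domains,
    differential regions, gene bodies, exons and repeats all carry one.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap in bp between two intervals; 0 if they overlap or abut.

    Returns ``None`` for intervals on different chromosomes.  Symmetric in
    its arguments.
    """
    if a.chrom != b.chrom:
        return None
    return max(0, a.start - b.end, b.start - a.end)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping or abutting spans are merged.

    Output is sorted by (chrom, start); names/scores/strands are dropped.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or abut
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


@dataclass
class ChromSizes:
    """Map chromosome name -> length in bp (reference genome bounds)."""

    sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.sizes.items():
            if not chrom:
                raise ValueError("empty chromosome name")
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __iter__(self):
        return iter(self.sizes)

    def items(self):
        return self.sizes.items()

    @property
    def total_length(self) -> int:
        return sum(self.sizes.values())

    def contains_interval(self, iv: GenomicInterval) -> bool:
        return iv.chrom in self.sizes and iv.end <= self.sizes[iv.chrom]


@dataclass
class GeneModel:
    """A gene: transcribed interval, strand-aware TSS, exon sub-intervals.

    Exons must be non-overlapping, sorted, and contained in the
    transcribed interval.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("gene must be stranded (+ or -)")
        prev_end = self.interval.start
        for exon in self.exons:
            if exon.chrom != self.interval.chrom:
                raise ValueError("exon on different chromosome than gene")
            if exon.start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError("exon outside transcribed interval")
            prev_end = exon.end

    @property
    def tss(self) -> int:
        """Strand-aware 5' end: start on +, end-1 on -."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    def introns(self) -> list[GenomicInterval]:
        out = []
        prev_end = None
        for exon in self.exons:
            if prev_end is not None and exon.start > prev_end:
                out.append(GenomicInterval(self.chrom, prev_end, exon.start, self.strand))
            prev_end = exon.end
        return out


@dataclass
class RepeatAnnotation:
    """One repeat element: interval + coarse repeat class."""

    interval: GenomicInterval
    repeat_class: str

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(
                f"repeat class {self.repeat_class!r} not in {REPEAT_CLASSES}"
            )


@dataclass
class TagLibrary:
    """One DIP-Seq library: uniquely-mapped tag 5' positions plus metadata.

    ``positions`` maps chromosome -> sorted int64 array of 5' positions;
    ``strands`` maps chromosome -> parallel array of '+'/'-' (optional,
    empty dict if unknown).  Tags are uniquely mapped by input contract.
    """

    library_id: str
    tissue: str
    condition: str
    mark: str
    replicate: int
    positions: dict[str, np.ndarray]
    strands: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(arr) < 0):
                arr = np.sort(arr)
                if chrom in self.strands:
                    order = np.argsort(pos, kind="stable")
                    self.strands[chrom] = np.asarray(self.strands[chrom])[order]
            self.positions[chrom] = arr

    @property
    def library_size(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def check_bounds(self, chrom_sizes: ChromSizes) -> None:
        for chrom, pos in self.positions.items():
            if chrom not in chrom_sizes:
                raise ValueError(f"tags on unknown chromosome {chrom}")
            if len(pos) and (pos[0] < 0 or pos[-1] >= chrom_sizes[chrom]):
                raise ValueError(f"tag position out of bounds on {chrom}")


def pool_libraries(libraries: list[TagLibrary], library_id: str = "pooled") -> TagLibrary:
    """Pool tags from several libraries into one (e.g. replicates within a
    mark x tissue x condition cell before segmentation)."""
    if not libraries:
        raise ValueError("no libraries to pool")
    chroms = sorted({c for lib in libraries for c in lib.positions})
    positions = {}
    for chrom in chroms:
        parts = [lib.positions[chrom] for lib in libraries if chrom in lib.positions]
        positions[chrom] = np.sort(np.concatenate(parts)) if parts else np.empty(0, np.int64)
    first = libraries[0]
    return TagLibrary(
        library_id=library_id,
        tissue=first.tissue,
        condition=first.condition,
        mark=first.mark,
        replicate=-1,
        positions=positions,
    )


def median_scale_factors(library_sizes: Mapping[str, int]) -> dict[str, float]:
    """Per-library factors scaling counts to the median library size.

    Counts are compared across libraries only after this scaling,
    pipeline-wide (median-scaled tag count density).
    """
    sizes = np.array(list(library_sizes.values()), dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("library sizes must be positive")
    med = float(np.median(sizes))
    return {lib: med / float(n) for lib, n in library_sizes.items()}
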