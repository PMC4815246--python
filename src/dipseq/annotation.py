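"""Genomic-category and repeat-class annotation of tags and regions.

Tags and regions are assigned to exactly one of {TSS, exon, intron,
intergenic}; inputs overlapping several features go to the closest
annotation (midpoint-to-midpoint distance, ties broken TSS > exon >
intron).  Repeat densities are reported as counts per million
repeat-overlapping tags (CPM), tissues are compared per class with a
Welch t-test, and differential regions are mapped non-redundantly to the
nearest TSS within 50 kb (top 2000 by q).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import (
    REPEAT_CLASSES,
    GeneModel,
    GenomicInterval,
    RepeatAnnotation,
    TagLibrary,
)
from .differential import DifferentialRegion

CATEGORIES = ("TSS", "exon", "intron", "intergenic")
_PRIORITY = {"TSS": 0, "exon": 1, "intron": 2}


@dataclass
class CategoryAssignment:
    """One input's single genomic category and its distance to the
    assigned feature (midpoints); intergenic iff nothing overlapped."""

    interval: GenomicInterval
    category: str
    distance: float


@dataclass
class RepeatDensity:
    """Counts per million repeat-overlapping tags for one class."""

    repeat_class: str
    cpm: float
    library_id: str
    tissue: str
    mark: str


@dataclass
class GeneAssignment:
    """Differential region -> nearest-TSS gene, with q-rank."""

    region: DifferentialRegion
    gene_id: str
    distance: int  # signed; negative = upstream of the TSS on gene strand
    rank: int


class _FeatureIndex:
    """Interval tree over TSS windows, exons and introns of a gene set."""

    def __init__(self, genes: Sequence[GeneModel], tss_flank: int = 1000):
        if tss_flank < 0:
            raise ValueError("TSS flank must be >= 0")
        self.trees: dict[str, IntervalTree] = {}
        self.gene_spans: dict[str, IntervalTree] = {}
        for gene in genes:
            tree = self.trees.setdefault(gene.chrom, IntervalTree())
            spans = self.gene_spans.setdefault(gene.chrom, IntervalTree())
            spans[gene.interval.start : gene.interval.end] = gene.gene_id
            lo = max(0, gene.tss - tss_flank)
            hi = gene.tss + tss_flank + 1
            tree[lo:hi] = ("TSS", (lo + hi) / 2)
            for exon in gene.exons:
                tree[exon.start : exon.end] = ("exon", exon.midpoint)
            for intron in gene.introns():
                tree[intron.start : intron.end] = ("intron", intron.midpoint)

    def query(self, interval: GenomicInterval):
        tree = self.trees.get(interval.chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(interval.start, interval.end)]


def assign_category(
    interval: GenomicInterval,
    genes: Sequence[GeneModel] | _FeatureIndex,
    tss_flank: int = 1000,
) -> CategoryAssignment:
    """Assign one interval to TSS / exon / intron / intergenic.

    Candidates are all features overlapping the interval (the TSS window
    is TSS +/- flank); with several candidates the feature whose midpoint
    is closest to the interval midpoint wins, ties broken by the fixed
    priority TSS > exon > intron.
    """
    index = genes if isinstance(genes, _FeatureIndex) else _FeatureIndex(genes, tss_flank)
    hits = index.query(interval)
    if not hits:
        return CategoryAssignment(interval, "intergenic", float("inf"))
    mid = interval.midpoint
    best = min(hits, key=lambda h: (abs(h[1] - mid), _PRIORITY[h[0]]))
    return CategoryAssignment(interval, best[0], abs(best[1] - mid))


def categorize_library(
    library: TagLibrary,
    genes: Sequence[GeneModel],
    tss_flank: int = 1000,
) -> dict[str, int]:
    """Category counts over a whole tag library (tags as 1-bp intervals).

    Counts sum to the library size: every tag lands in exactly one
    category.  This is the pie-chart data.
    """
    index = _FeatureIndex(genes, tss_flank)
    counts = dict.fromkeys(CATEGORIES, 0)
    for chrom, positions in library.positions.items():
        for p in positions:
            tag = GenomicInterval(chrom, int(p), int(p) + 1)
            counts[assign_category(tag, index).category] += 1
    return counts


def intragenic_fraction(
    library: TagLibrary, genes: Sequence[GeneModel]
) -> dict[str, int]:
    """Coarse two-way split: tags inside vs outside transcribed regions."""
    spans: dict[str, IntervalTree] = {}
    for g in genes:
        spans.setdefault(g.chrom, IntervalTree())[g.interval.start : g.interval.end] = True
    inside = 0
    for chrom, positions in library.positions.items():
        tree = spans.get(chrom)
        if tree is None:
            continue
        inside += sum(1 for p in positions if tree.overlaps_point(int(p)))
    return {"intragenic": inside, "intergenic": library.library_size - inside}


def repeat_cpm(
    library: TagLibrary,
    repeats: Sequence[RepeatAnnotation],
    denominator: str = "repeat",
) -> list[RepeatDensity]:
    """Counts per million repeat sequences, per repeat class.

    A tag overlapping several repeats is matched exclusively to the
    closest one (midpoint rule).  With the default denominator the CPM
    over classes sums to 1e6 (per million repeat-overlapping tags); the
    'library' denominator normalizes by total library size instead.
    """
    if denominator not in ("repeat", "library"):
        raise ValueError("denominator must be 'repeat' or 'library'")
    trees: dict[str, IntervalTree] = {}
    for rep in repeats:
        iv = rep.interval
        trees.setdefault(iv.chrom, IntervalTree())[iv.start : iv.end] = (
            rep.repeat_class,
            iv.midpoint,
        )
    class_counts = dict.fromkeys(REPEAT_CLASSES, 0)
    assigned = 0
    for chrom, positions in library.positions.items():
        tree = trees.get(chrom)
        if tree is None:
            continue
        for p in positions:
            hits = tree.at(int(p))
            if not hits:
                continue
            mid = p + 0.5
            cls, _ = min(
                (h.data for h in hits), key=lambda d: (abs(d[1] - mid), d[0])
            )
            class_counts[cls] += 1
            assigned += 1
    if denominator == "repeat":
        if assigned == 0:
            raise ValueError("no tags overlap any repeat; CPM undefined")
        denom = assigned
    else:
        denom = library.library_size
    return [
        RepeatDensity(
            repeat_class=cls,
            cpm=1e6 * n / denom,
            library_id=library.library_id,
            tissue=library.tissue,
            mark=library.mark,
        )
        for cls, n in class_counts.items()
    ]


def repeat_cpm_table(densities: Sequence[RepeatDensity]) -> pd.DataFrame:
    """Long-format CPM table (strip-plot data): one row per library x class."""
    return pd.DataFrame(
        [
            {
                "library_id": d.library_id,
                "tissue": d.tissue,
                "mark": d.mark,
                "repeat_class": d.repeat_class,
                "cpm": d.cpm,
            }
            for d in densities
        ]
    )


def compare_tissue_density(
    cpm_a: pd.DataFrame, cpm_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-class Welch t-test of per-library CPM between two tissues.

    Inputs are long-format tables from :func:`repeat_cpm_table` (one
    tissue each, n libraries per class).  Identical groups give p = 1.
    """
    rows = []
    for cls in REPEAT_CLASSES:
        a = cpm_a.loc[cpm_a["repeat_class"] == cls, "cpm"].to_numpy(float)
        b = cpm_b.loc[cpm_b["repeat_class"] == cls, "cpm"].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 libraries per tissue per class")
        if np.var(a) == 0 and np.var(b) == 0:
            stat, p = (0.0, 1.0) if np.mean(a) == np.mean(b) else (np.inf, 0.0)
        else:
            stat, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "repeat_class": cls,
                "mean_a": float(np.mean(a)),
                "mean_b": float(np.mean(b)),
                "statistic": float(stat),
                "pvalue": float(p),
                "significant": bool(p < 0.05),
            }
        )
    return pd.DataFrame(rows)


def regions_to_genes(
    regions: Sequence[DifferentialRegion],
    genes: Sequence[GeneModel],
    max_distance: int = 50_000,
    top_k: int = 2000,
) -> list[GeneAssignment]:
    """Non-redundant nearest-TSS annotation of the top differential regions.

    Regions are ranked by q ascending (ties: |log2FC| descending, then
    coordinate); the top k are kept; regions with no TSS within
    ``max_distance`` are dropped; each remaining region goes to its
    nearest TSS and duplicate genes collapse to the best-ranked region.
    Distances are signed: negative = upstream of the TSS on the gene's
    strand; a region overlapping the TSS has distance 0.
    """
    ranked = sorted(
        regions,
        key=lambda r: (
            r.qvalue,
            -abs(r.log2_fold_change),
            r.interval.chrom,
            r.interval.start,
        ),
    )[:top_k]

    tss_by_chrom: dict[str, list[tuple[int, GeneModel]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g))
    for chrom in tss_by_chrom:
        tss_by_chrom[chrom].sort(key=lambda t: t[0])

    best_by_gene: dict[str, GeneAssignment] = {}
    for rank, region in enumerate(ranked, start=1):
        iv = region.interval
        entries = tss_by_chrom.get(iv.chrom)
        if not entries:
            continue
        positions = np.array([t for t, _ in entries])
        # unsigned distance from the region span to each TSS point
        d = np.where(
            positions < iv.start,
            iv.start - positions,
            np.where(positions >= iv.end, positions - iv.end, 0),
        )
        j = int(np.argmin(d))
        if d[j] > max_distance:
            continue
        tss, gene = entries[j]
        if tss < iv.start:
            signed = -(iv.start - tss) if gene.strand == "-" else iv.start - tss
            # region right of TSS: downstream on +, upstream on -
        elif tss >= iv.end:
            signed = -(tss - iv.end) if gene.strand == "+" else tss - iv.end
        else:
            signed = 0
        current = best_by_gene.get(gene.gene_id)
        if current is None or rank < current.rank:
            best_by_gene[gene.gene_id] = GeneAssignment(
                region=region, gene_id=gene.gene_id, distance=int(signed), rank=rank
            )
    return sorted(best_by_gene.values(), key=lambda a: a.rank)


def category_counts_table(counts: Mapping[str, int]) -> pd.DataFrame:
    total = sum(counts.values())
    return pd.DataFrame(
        [
            {"category": c, "count": counts[c], "fraction": counts[c] / total if total else 0.0}
            for c in counts
        ]
    )
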