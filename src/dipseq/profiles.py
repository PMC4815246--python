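"""Read-density profiles: expression-ranked metagene heatmaps and
background-subtracted wiggle tracks.

The metagene matrix stacks per-gene tag densities — fixed 500-bp flank
bins plus a length-normalized gene body — with rows ordered by descending
expression and minus-strand genes reversed so the 5' end is leftmost.
Heatmap color ramps are min-max scaled after clipping at the 80th
quantile of the nonzero values.  Wiggle tracks report median-scaled tag
density only in bins whose raw count clears the segmentation threshold
(enrichment above background at the segmentation FDR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ChromSizes, GeneModel, TagLibrary
from .segmentation import EnrichmentThreshold


@dataclass
class MetageneMatrix:
    """Genes x bins density matrix, rows in descending expression order.

    Columns: ``n_flank_bins`` upstream flank bins (500 bp each), then
    ``body_bins`` length-normalized gene-body bins, then the downstream
    flank.  Values are scaled tag densities (tags per million by default).
    """

    matrix: np.ndarray
    gene_ids: list[str]
    expression: np.ndarray
    n_flank_bins: int
    body_bins: int
    flank_bin_size: int = 500

    @property
    def n_columns(self) -> int:
        return 2 * self.n_flank_bins + self.body_bins

    def to_frame(self) -> pd.DataFrame:
        cols = (
            [f"up{i}" for i in range(self.n_flank_bins)]
            + [f"body{i}" for i in range(self.body_bins)]
            + [f"down{i}" for i in range(self.n_flank_bins)]
        )
        df = pd.DataFrame(self.matrix, columns=cols)
        df.insert(0, "gene_id", self.gene_ids)
        df.insert(1, "expression", self.expression)
        return df


def metagene_matrix(
    library: TagLibrary,
    genes: list[GeneModel],
    expression: dict[str, float],
    flank: int = 5000,
    body_bins: int = 40,
    bin_size: int = 500,
    scale: float | None = None,
) -> MetageneMatrix:
    """Binned tag density around every gene with an expression value.

    ``scale`` multiplies raw counts; default is tags-per-million of this
    library (pass a median-derived factor for cross-library figures).
    Genes shorter than ``body_bins`` bp are skipped with a warning.
    """
    if flank % bin_size:
        raise ValueError("flank must be a multiple of the bin size")
    if scale is None:
        scale = 1e6 / max(library.library_size, 1)
    n_flank = flank // bin_size

    usable = [g for g in genes if g.gene_id in expression]
    usable.sort(key=lambda g: -expression[g.gene_id])

    rows, ids, expr = [], [], []
    skipped = 0
    for gene in usable:
        if gene.interval.length < body_bins:
            skipped += 1
            continue
        pos = library.positions.get(gene.chrom, np.empty(0, np.int64))
        start, end = gene.interval.start, gene.interval.end
        up_edges = start + np.arange(-n_flank, 1) * bin_size
        body_edges = np.linspace(start, end, body_bins + 1)
        down_edges = end + np.arange(0, n_flank + 1) * bin_size
        edges = np.concatenate([up_edges, body_edges[1:-1], down_edges])
        counts = np.diff(np.searchsorted(pos, edges)).astype(float)
        if gene.strand == "-":
            counts = counts[::-1]
        rows.append(counts * scale)
        ids.append(gene.gene_id)
        expr.append(expression[gene.gene_id])
    if skipped:
        warnings.warn(f"skipped {skipped} genes shorter than {body_bins} bp", stacklevel=2)
    matrix = np.vstack(rows) if rows else np.empty((0, 2 * n_flank + body_bins))
    return MetageneMatrix(
        matrix=matrix,
        gene_ids=ids,
        expression=np.asarray(expr, dtype=float),
        n_flank_bins=n_flank,
        body_bins=body_bins,
        flank_bin_size=bin_size,
    )


def quantile_scale(matrix: np.ndarray, q: float = 0.8) -> np.ndarray:
    """Clip at the q-th quantile of the nonzero values, then min-max
    scale to [0, 1].  A constant matrix maps to all zeros."""
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    m = np.asarray(matrix, dtype=float)
    nonzero = m[m != 0]
    if nonzero.size == 0:
        return np.zeros_like(m)
    # "lower" keeps the cap an actual data value, making rescaling of an
    # already-scaled matrix exact (interpolated quantiles drift slightly)
    cap = float(np.quantile(nonzero, q, method="lower"))
    clipped = np.minimum(m, cap)
    lo, hi = float(clipped.min()), float(clipped.max())
    if hi == lo:
        return np.zeros_like(m)
    return (clipped - lo) / (hi - lo)


def background_subtracted_wiggle(
    library: TagLibrary,
    threshold: EnrichmentThreshold,
    chrom_sizes: ChromSizes,
    bin_size: int = 1000,
    scale: float = 1.0,
) -> dict[str, np.ndarray]:
    """Median-scaled tag density above background, per fixed bin.

    Bins whose raw tag count falls below the segmentation threshold t
    (computed at the segmentation FDR, typically 5%) are zeroed; the rest
    carry ``count * scale``.  Pass the result to
    :func:`dipseq.io.write_wiggle`.  ``bin_size`` should match the window
    the threshold was calibrated for.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    out: dict[str, np.ndarray] = {}
    for chrom, length in chrom_sizes.items():
        n_bins = -(-length // bin_size)
        pos = library.positions.get(chrom, np.empty(0, np.int64))
        counts = np.bincount(pos // bin_size, minlength=n_bins)[:n_bins].astype(float)
        counts[counts < threshold.t] = 0.0
        out[chrom] = counts * scale
    return out


def plot_metagene_heatmap(mm: MetageneMatrix, path: str, q: float = 0.8) -> None:
    """Render the quantile-scaled matrix as a PNG heatmap (rows already in
    expression order; the numeric matrix is the test surface, not this)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scaled = quantile_scale(mm.matrix, q=q)
    fig, ax = plt.subplots(figsize=(6, 8))
    ax.imshow(scaled, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.axvline(mm.n_flank_bins - 0.5, color="white", lw=0.8)
    ax.axvline(mm.n_flank_bins + mm.body_bins - 0.5, color="white", lw=0.8)
    ax.set_xlabel("flank | gene body (5'->3') | flank")
    ax.set_ylabel("genes (high -> low expression)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
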