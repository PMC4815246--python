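"""Directional spatial overlap between differential-region sets.

DMRs and DHMRs are stratified by direction of change (up/down in the
irradiated condition) and each of the four direction pairs is scored for
spatial association: a region of set A is "paired" when some region of
set B lies within a distance window (default 25 kb, edge-to-edge gap;
overlapping regions have gap 0).  Significance conditions on the universe
of all tested regions — where regions could have been called — via an
upper-tail hypergeometric probability, with a label-permutation test as a
model check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval

DIRECTION_PAIRS = (("up", "up"), ("up", "down"), ("down", "up"), ("down", "down"))


@dataclass
class OverlapTable:
    """Directional pairing counts and significance for one direction pair."""

    pair: tuple[str, str]  # (mark A direction, mark B direction)
    n_a: int
    n_b: int
    n_paired: int
    window: int
    pvalue: float
    method: str
    n_universe: int = 0
    n_universe_paired: int = 0  # K: universe-A regions paired to set B

    def __post_init__(self) -> None:
        if not (0 <= self.n_paired <= self.n_a):
            raise ValueError("require 0 <= n_paired <= n_a")
        if self.window <= 0:
            raise ValueError("window must be positive")


def _gap_matrix(a_start, a_end, b_start, b_end) -> np.ndarray:
    """Pairwise edge-to-edge gaps; 0 for overlapping/abutting intervals."""
    g1 = b_start[None, :] - a_end[:, None]
    g2 = a_start[:, None] - b_end[None, :]
    return np.maximum(0, np.maximum(g1, g2))


def _paired_mask(
    set_a: list[GenomicInterval], set_b: list[GenomicInterval], window: int
) -> tuple[np.ndarray, list[tuple[GenomicInterval, GenomicInterval]]]:
    """For each region of A: is some region of B within the window, and if
    so which is nearest (ties: first in sorted order)."""
    mask = np.zeros(len(set_a), dtype=bool)
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    b_by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for b in sorted(set_b, key=lambda iv: (iv.chrom, iv.start, iv.end)):
        b_by_chrom.setdefault(b.chrom, []).append((0, b))
    for chrom, blist in b_by_chrom.items():
        bs = np.array([b.start for _, b in blist])
        be = np.array([b.end for _, b in blist])
        idx_a = [i for i, a in enumerate(set_a) if a.chrom == chrom]
        if not idx_a:
            continue
        as_ = np.array([set_a[i].start for i in idx_a])
        ae = np.array([set_a[i].end for i in idx_a])
        gaps = _gap_matrix(as_, ae, bs, be)
        hit = gaps.min(axis=1) <= window
        nearest = gaps.argmin(axis=1)
        for k, i in enumerate(idx_a):
            if hit[k]:
                mask[i] = True
                pairs.append((set_a[i], blist[nearest[k]][1]))
    return mask, pairs


def pair_within_window(
    set_a: list[GenomicInterval],
    set_b: list[GenomicInterval],
    window: int = 25_000,
) -> tuple[int, list[tuple[GenomicInterval, GenomicInterval]]]:
    """Count regions of A with at least one region of B within ``window``
    bp (edge gap; same chromosome); also return (a, nearest b) pairs.

    Each A region counts once regardless of how many partners it has.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    mask, pairs = _paired_mask(set_a, set_b, window)
    return int(mask.sum()), pairs


def overlap_significance(
    set_a: list[GenomicInterval],
    set_b: list[GenomicInterval],
    universe_a: list[GenomicInterval],
    window: int = 25_000,
    method: str = "hypergeom",
    pair: tuple[str, str] = ("", ""),
    n_b_total: int | None = None,
    permutations: int = 10_000,
    seed: int = 0,
) -> OverlapTable:
    """Significance of directional pairing between two region sets.

    Universe-A regions are labeled paired/unpaired with respect to set B's
    positions (K paired among M).  Hypergeometric: p = P(X >= n_paired)
    when drawing |A| labels from the universe.  Permutation: the
    "significant" label is shuffled over universe regions, preserving set
    sizes; p = (1 + #{perm >= observed}) / (1 + permutations).
    """
    key = lambda iv: (iv.chrom, iv.start, iv.end)
    universe_keys = {key(iv) for iv in universe_a}
    for iv in set_a:
        if key(iv) not in universe_keys:
            raise ValueError(f"set region {iv} not contained in its universe")

    n_paired, _ = pair_within_window(set_a, set_b, window)
    u_mask, _ = _paired_mask(universe_a, set_b, window)
    big_m, big_k, n_draw = len(universe_a), int(u_mask.sum()), len(set_a)

    if len(set_a) == 0 or len(set_b) == 0:
        pvalue = 1.0
    elif method == "hypergeom":
        pvalue = float(stats.hypergeom.sf(n_paired - 1, big_m, big_k, n_draw))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(permutations):
            draw = rng.choice(big_m, size=n_draw, replace=False)
            if int(u_mask[draw].sum()) >= n_paired:
                exceed += 1
        pvalue = (1 + exceed) / (1 + permutations)
    else:
        raise ValueError("method must be 'hypergeom' or 'permutation'")

    return OverlapTable(
        pair=pair,
        n_a=len(set_a),
        n_b=len(set_b) if n_b_total is None else n_b_total,
        n_paired=n_paired,
        window=window,
        pvalue=float(pvalue),
        method=method,
        n_universe=big_m,
        n_universe_paired=big_k,
    )


def directional_overlap(
    regions_a,
    regions_b,
    universe_a,
    window: int = 25_000,
    method: str = "hypergeom",
    permutations: int = 10_000,
    seed: int = 0,
) -> list[OverlapTable]:
    """All four direction pairs between two DifferentialRegion call sets.

    ``regions_a``/``regions_b`` are significant calls carrying a
    ``direction``; ``universe_a`` is every tested region of mark A.
    """
    tables = []
    for da, db in DIRECTION_PAIRS:
        set_a = [r.interval for r in regions_a if r.direction == da]
        set_b = [r.interval for r in regions_b if r.direction == db]
        tables.append(
            overlap_significance(
                set_a,
                set_b,
                [getattr(u, "interval", u) for u in universe_a],
                window=window,
                method=method,
                pair=(da, db),
                permutations=permutations,
                seed=seed,
            )
        )
    return tables


def venn_summary(tables: list[OverlapTable]) -> pd.DataFrame:
    """Tabulate the direction pairs: Venn-style counts (A only, B only,
    paired), p-values, ranks, and a flag on the most significant pair(s).

    Ties in p share a rank and are all flagged top.
    """
    rows = []
    for t in tables:
        rows.append(
            {
                "direction_a": t.pair[0],
                "direction_b": t.pair[1],
                "n_a_only": t.n_a - t.n_paired,
                "n_b_only": t.n_b,
                "n_paired": t.n_paired,
                "n_a": t.n_a,
                "n_universe": t.n_universe,
                "pvalue": t.pvalue,
            }
        )
    df = pd.DataFrame(rows)
    df["rank"] = df["pvalue"].rank(method="min").astype(int)
    df["most_significant"] = df["rank"] == 1
    return df.sort_values(["rank", "direction_a", "direction_b"]).reset_index(drop=True)
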