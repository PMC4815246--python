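"""Differential 5mC/5hmC region calling.

Enriched domains called per condition are merged into candidate regions;
per-region tag counts are compared between conditions with either a
Pearson chi-square test on pooled counts (default) or a negative-binomial
likelihood-ratio test using replicate counts, followed by
Benjamini-Hochberg FDR adjustment.  Regions with q below the threshold
(default 0.01) become DMRs/DHMRs with a direction taken from the
median-library-scaled fold change (irradiated vs sham).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import GenomicInterval, TagLibrary, merge_intervals
from .segmentation import EnrichedDomain


@dataclass
class RegionCountMatrix:
    """Candidate regions x libraries tag-count matrix.

    Regions are the interval union of the per-condition enriched-domain
    calls; ``counts[i, j]`` is the number of tags of library j inside
    region i; ``conditions[j]`` labels each library's condition.
    """

    regions: list[GenomicInterval]
    counts: np.ndarray
    library_ids: list[str]
    library_sizes: np.ndarray
    conditions: list[str]
    mark: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if self.counts.shape != (len(self.regions), len(self.library_ids)):
            raise ValueError("count matrix shape must be regions x libraries")

    def condition_columns(self, condition: str) -> np.ndarray:
        return np.array([j for j, c in enumerate(self.conditions) if c == condition])


class TestResult(NamedTuple):
    statistic: float
    pvalue: float
    low_count: bool = False


@dataclass
class DifferentialRegion:
    """One tested region: the DMR/DHMR record."""

    interval: GenomicInterval
    mark: str
    norm_count_sham: float
    norm_count_proton: float
    log2_fold_change: float
    pvalue: float
    qvalue: float
    direction: str  # up iff log2FC > 0 (proton vs sham)
    test: str
    low_count: bool = False
    tissue: str = ""


def merge_condition_domains(
    domains_by_condition: dict[str, list[EnrichedDomain]],
) -> list[GenomicInterval]:
    """Union the enriched domains called in each condition into one sorted
    list of candidate regions (overlapping or abutting spans merged)."""
    if not domains_by_condition:
        raise ValueError("need domains from at least one condition")
    ivs = [d.interval for doms in domains_by_condition.values() for d in doms]
    if not ivs:
        return []
    return merge_intervals(ivs)


def build_count_matrix(
    regions: Sequence[GenomicInterval],
    libraries: Sequence[TagLibrary],
    mark: str = "",
    tissue: str = "",
) -> RegionCountMatrix:
    """Count each library's tags inside each candidate region."""
    counts = np.zeros((len(regions), len(libraries)), dtype=np.int64)
    for j, lib in enumerate(libraries):
        for i, region in enumerate(regions):
            pos = lib.positions.get(region.chrom)
            if pos is None:
                continue
            counts[i, j] = np.searchsorted(pos, region.end) - np.searchsorted(
                pos, region.start
            )
    return RegionCountMatrix(
        regions=list(regions),
        counts=counts,
        library_ids=[lib.library_id for lib in libraries],
        library_sizes=np.array([lib.library_size for lib in libraries]),
        conditions=[lib.condition for lib in libraries],
        mark=mark,
        tissue=tissue,
    )


def chisq_region_test(
    count_a: int, count_b: int, lib_a: int, lib_b: int
) -> TestResult:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2
    table [[count_a, lib_a - count_a], [count_b, lib_b - count_b]].

    Both counts zero -> statistic 0, p = 1.  Any expected cell < 1 flags
    the region low-count (p is still returned).
    """
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    if count_a < 0 or count_b < 0 or count_a > lib_a or count_b > lib_b:
        raise ValueError("counts must be in [0, library size]")
    if count_a == 0 and count_b == 0:
        return TestResult(0.0, 1.0, low_count=True)
    a, b = float(count_a), float(lib_a - count_a)
    c, d = float(count_b), float(lib_b - count_b)
    n = a + b + c + d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    expected = np.array([row1 * col1, row1 * col2, row2 * col1, row2 * col2]) / n
    low = bool(np.any(expected < 1))
    if col1 == 0 or col2 == 0:
        return TestResult(0.0, 1.0, low_count=low)
    stat = n * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    p = float(stats.chi2.sf(stat, df=1))
    return TestResult(float(stat), p, low_count=low)


# -- negative-binomial test -------------------------------------------------

def estimate_common_dispersion(matrix: RegionCountMatrix) -> float:
    """Method-of-moments NB dispersion shared across regions.

    Counts are scaled to the median library size; within each condition
    the per-region sample mean m and variance v (ddof=1) obey
    E[v] = m + alpha * m^2 under NB sampling, so alpha is estimated by
    pooling sum(v - m) / sum(m^2) over all regions and conditions.
    Two replicates per condition cannot support per-region estimates,
    hence the common value.  A negative estimate falls back to Poisson
    (dispersion 0) with a warning.
    """
    import warnings

    scale = np.median(matrix.library_sizes) / matrix.library_sizes
    y = matrix.counts * scale
    num = 0.0
    den = 0.0
    for condition in dict.fromkeys(matrix.conditions):
        cols = matrix.condition_columns(condition)
        if len(cols) < 2:
            raise ValueError("need >= 2 replicates per condition for dispersion")
        sub = y[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        # E[m^2] = mu^2 + Var(m); subtract v/n so the denominator targets mu^2
        den += float(np.sum(m**2 - v / len(cols)))
    if den == 0:
        return 0.0
    alpha = num / den
    if alpha < 0:
        warnings.warn(
            "moment dispersion estimate negative; falling back to Poisson",
            stacklevel=2,
        )
        return 0.0
    return alpha


_POISSON_LIMIT = 1e-6  # dispersions below this use the exact Poisson forms
# (the NB gammaln terms lose ~1e-5 of precision once 1/alpha > 1e6,
# while the analytic difference from Poisson is O(alpha))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 log-likelihood summed over the last axis (constant terms in y
    included so likelihoods are comparable across models)."""
    if alpha < _POISSON_LIMIT:
        return np.sum(y * np.log(np.where(mu > 0, mu, 1.0)) - mu - special.gammaln(y + 1), axis=-1)
    r = 1.0 / alpha
    return np.sum(
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(np.where(mu > 0, mu, 1.0) / (r + mu)),
        axis=-1,
    )


def _nb_fit_intercept(
    y: np.ndarray, offsets: np.ndarray, alpha: float, n_iter: int = 50
) -> np.ndarray:
    """MLE of the intercept of an NB GLM with log link and fixed dispersion.

    mu_ij = s_j * exp(b_i); vectorized Newton over rows (the objective is
    concave in b).  Rows with all-zero counts get b = -inf (mu = 0).
    """
    total = y.sum(axis=-1)
    s_total = np.broadcast_to(offsets, y.shape).sum(axis=-1)
    with np.errstate(divide="ignore"):
        b = np.log(total / s_total)  # Poisson MLE as start; -inf for all-zero rows
    zero_rows = total == 0
    if alpha < _POISSON_LIMIT:
        return b
    b = np.where(zero_rows, -np.inf, b)
    r = 1.0 / alpha
    for _ in range(n_iter):
        mu = offsets * np.exp(b)[..., None]
        grad = np.sum(y - (y + r) * mu / (r + mu), axis=-1)
        hess = -np.sum((y + r) * mu * r / (r + mu) ** 2, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            step = np.where(hess < 0, grad / hess, 0.0)
        step = np.clip(step, -5, 5)
        b = np.where(zero_rows, b, b - step)
        if np.all(np.abs(step[~zero_rows]) < 1e-12 if (~zero_rows).any() else True):
            break
    return b


def negbin_region_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    libs_a: np.ndarray,
    libs_b: np.ndarray,
    dispersion: float,
) -> TestResult:
    """NB likelihood-ratio test of a condition effect for one region.

    Null: one mean level (log link, offset log library size) across all
    replicates; alternative: separate levels per condition; fixed common
    dispersion; LRT referred to chi-square with 1 df.  All-zero regions
    give p = 1.
    """
    stat, p = _negbin_lrt(
        np.asarray(counts_a, float)[None, :],
        np.asarray(counts_b, float)[None, :],
        np.asarray(libs_a, float),
        np.asarray(libs_b, float),
        dispersion,
    )
    return TestResult(float(stat[0]), float(p[0]))


def _negbin_lrt(
    ya: np.ndarray, yb: np.ndarray, sa: np.ndarray, sb: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized NB LRT over regions (rows)."""
    y_all = np.concatenate([ya, yb], axis=1)
    s_all = np.concatenate([sa, sb])
    b_null = _nb_fit_intercept(y_all, s_all, alpha)
    b_a = _nb_fit_intercept(ya, sa, alpha)
    b_b = _nb_fit_intercept(yb, sb, alpha)
    with np.errstate(invalid="ignore"):
        mu_null = s_all * np.exp(b_null)[:, None]
        mu_a = sa * np.exp(b_a)[:, None]
        mu_b = sb * np.exp(b_b)[:, None]
    ll_null = _nb_loglik(y_all, mu_null, alpha)
    ll_alt = _nb_loglik(ya, mu_a, alpha) + _nb_loglik(yb, mu_b, alpha)
    stat = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    all_zero = y_all.sum(axis=1) == 0
    stat = np.where(all_zero, 0.0, stat)
    p = stats.chi2.sf(stat, df=1)
    p = np.where(all_zero, 1.0, p)
    return stat, p


def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def evaluate_regions(
    matrix: RegionCountMatrix,
    test: str = "chisq",
    pseudocount: float = 0.5,
    dispersion: float | None = None,
    sham: str = "sham",
    proton: str = "proton",
) -> list[DifferentialRegion]:
    """Test every candidate region and BH-adjust across them.

    Fold change (proton vs sham) uses per-condition count sums scaled to
    the median library size, with a pseudocount per condition sum; the
    returned list covers all regions (filter on q for calls).
    """
    if test not in ("chisq", "negbin"):
        raise ValueError("test must be 'chisq' or 'negbin'")
    cols_a = matrix.condition_columns(sham)
    cols_b = matrix.condition_columns(proton)
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError("both conditions must be present in the matrix")
    sizes = matrix.library_sizes
    results: list[TestResult] = []
    if test == "chisq":
        lib_a = int(sizes[cols_a].sum())
        lib_b = int(sizes[cols_b].sum())
        for i in range(len(matrix.regions)):
            ca = int(matrix.counts[i, cols_a].sum())
            cb = int(matrix.counts[i, cols_b].sum())
            results.append(chisq_region_test(ca, cb, lib_a, lib_b))
    else:
        if dispersion is None:
            dispersion = estimate_common_dispersion(matrix)
        stat, p = _negbin_lrt(
            matrix.counts[:, cols_a].astype(float),
            matrix.counts[:, cols_b].astype(float),
            sizes[cols_a].astype(float),
            sizes[cols_b].astype(float),
            dispersion,
        )
        results = [TestResult(float(s), float(pv)) for s, pv in zip(stat, p)]

    qvalues = adjust_fdr([r.pvalue for r in results]) if results else np.empty(0)

    med = float(np.median(sizes))
    scale = med / sizes
    out: list[DifferentialRegion] = []
    for i, (region, res, q) in enumerate(zip(matrix.regions, results, qvalues)):
        norm_a = float((matrix.counts[i, cols_a] * scale[cols_a]).sum())
        norm_b = float((matrix.counts[i, cols_b] * scale[cols_b]).sum())
        log2fc = float(np.log2((norm_b + pseudocount) / (norm_a + pseudocount)))
        out.append(
            DifferentialRegion(
                interval=region,
                mark=matrix.mark,
                norm_count_sham=norm_a,
                norm_count_proton=norm_b,
                log2_fold_change=log2fc,
                pvalue=res.pvalue,
                qvalue=float(q),
                direction="up" if log2fc > 0 else "down",
                test=test,
                low_count=res.low_count,
                tissue=matrix.tissue,
            )
        )
    return out


def call_differential(
    matrix: RegionCountMatrix,
    test: str = "chisq",
    q_threshold: float = 0.01,
    pseudocount: float = 0.5,
    dispersion: float | None = None,
) -> list[DifferentialRegion]:
    """DMRs/DHMRs: regions with FDR-adjusted p (q) below the threshold."""
    return [
        r
        for r in evaluate_regions(matrix, test=test, pseudocount=pseudocount, dispersion=dispersion)
        if r.qvalue < q_threshold
    ]
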