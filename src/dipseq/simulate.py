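"""Synthetic DIP-Seq study generator with planted truth.

Emulates the study design this pipeline targets: two tissues x two
radiation conditions x two replicate libraries per mark (5mC, 5hmC).
Background tags are homogeneous Poisson scatter; enriched domains carry an
elevated rate e*lambda0; a subset of domains are differential, with the
irradiated-condition rate multiplied (direction "up") or divided
(direction "down") by the fold change phi.  A coupling fraction kappa of
the 5hmC differential domains is placed within 25 kb of a 5mC differential
domain with a specified direction pairing, giving known truth for the
directional-overlap analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    REPEAT_CLASSES,
    ChromSizes,
    GeneModel,
    GenomicInterval,
    RepeatAnnotation,
    TagLibrary,
    interval_gap,
)

#: bp length ranges used when placing repeats of each class.
_REPEAT_LENGTHS = {
    "SINE": (100, 300),
    "LINE": (1000, 6000),
    "LTR": (300, 1000),
    "satellite": (500, 5000),
    "tRNA": (70, 90),
    "rRNA": (100, 5000),
    "other": (100, 1000),
}


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults are the study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    background_rate: float = 0.01  # lambda0, tags per bp per library
    n_enriched: int = 100  # enriched domains per tissue x mark
    domain_length: tuple[int, int] = (1000, 3000)
    min_domain_gap: int = 5000  # keeps neighbouring domains from merging
    enrichment_fold: float = 8.0  # e: domain rate = e * lambda0
    n_differential: int = 40  # differential domains per tissue x mark
    differential_fold: float = 3.0  # phi: irradiated rate multiplier
    coupling: float = 0.5  # kappa: fraction of 5hmC diff regions coupled
    coupling_window: int = 25_000
    coupled_pair: tuple[str, str] = ("down", "up")  # (5mC dir, 5hmC dir)
    replicates: int = 2
    tissues: tuple[str, ...] = ("hippocampus", "ventricle")
    conditions: tuple[str, ...] = ("sham", "proton")
    marks: tuple[str, ...] = ("5mC", "5hmC")
    n_genes: int = 200
    gene_length: tuple[int, int] = (2000, 20000)
    n_repeats: int = 400

    def __post_init__(self) -> None:
        if self.background_rate <= 0:
            raise ValueError("background rate must be positive")
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment fold must exceed 1")
        if self.n_differential and self.differential_fold == 1:
            raise ValueError("differential fold must differ from 1")
        if not (0 <= self.coupling <= 1):
            raise ValueError("coupling must be in [0, 1]")
        if self.n_differential > self.n_enriched:
            raise ValueError("cannot have more differential than enriched domains")

    def chrom_sizes(self) -> ChromSizes:
        return ChromSizes(
            {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}
        )


@dataclass
class PlantedRegion:
    """A planted differential domain with its true direction."""

    interval: GenomicInterval
    direction: str  # up or down in the irradiated condition


@dataclass
class TruthSet:
    """Ground truth of one simulation, keyed by (tissue, mark)."""

    enriched: dict[tuple[str, str], list[GenomicInterval]] = field(default_factory=dict)
    differential: dict[tuple[str, str], list[PlantedRegion]] = field(default_factory=dict)
    coupled_pairs: dict[str, list[tuple[PlantedRegion, PlantedRegion]]] = field(
        default_factory=dict
    )  # tissue -> [(5mC region, 5hmC region)]


def _place_intervals(
    rng: np.random.Generator,
    chrom_sizes: ChromSizes,
    n: int,
    length_range: tuple[int, int],
    min_gap: int,
    existing: list[GenomicInterval] | None = None,
    max_tries: int = 10_000,
) -> list[GenomicInterval]:
    """Rejection-sample n non-overlapping intervals (pairwise gap >= min_gap
    with each other and with ``existing``)."""
    placed: list[GenomicInterval] = []
    existing = existing or []
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} intervals of {length_range} bp: genome too short"
            )
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if chrom_sizes[chrom] <= length:
            continue
        start = int(rng.integers(0, chrom_sizes[chrom] - length))
        cand = GenomicInterval(chrom, start, start + length)
        ok = all(
            (g := interval_gap(cand, other)) is None or g > min_gap
            for other in placed + existing
        )
        if ok:
            placed.append(cand)
    return placed


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[ChromSizes, list[GeneModel], list[RepeatAnnotation]]:
    """Generate chromosome sizes, non-overlapping genes (1-10 exons each)
    and repeats of all seven classes.  Deterministic given the seed."""
    rng = np.random.default_rng([config.seed, 1])
    chrom_sizes = config.chrom_sizes()

    gene_spans = _place_intervals(
        rng, chrom_sizes, config.n_genes, config.gene_length, min_gap=0
    )
    genes = []
    for i, span in enumerate(sorted(gene_spans, key=lambda iv: (iv.chrom, iv.start))):
        strand = "+" if rng.random() < 0.5 else "-"
        span = GenomicInterval(span.chrom, span.start, span.end, strand=strand)
        n_exons = int(rng.integers(1, 11))
        # cut the transcribed span at 2*n_exons - 1 sorted internal points;
        # alternating pieces become exons (first and last always exonic)
        if n_exons == 1:
            exons = [span]
        else:
            cuts = np.sort(rng.choice(span.length - 1, size=2 * n_exons - 2, replace=False) + 1)
            edges = np.concatenate([[0], cuts, [span.length]]) + span.start
            exons = [
                GenomicInterval(span.chrom, int(edges[j]), int(edges[j + 1]), strand=strand)
                for j in range(0, 2 * n_exons - 1, 2)
            ]
        genes.append(GeneModel(f"gene{i + 1}", span, exons))

    repeats = []
    if config.n_repeats:
        per_class = np.full(len(REPEAT_CLASSES), config.n_repeats // len(REPEAT_CLASSES))
        per_class[: config.n_repeats % len(REPEAT_CLASSES)] += 1
        for cls, n_cls in zip(REPEAT_CLASSES, per_class):
            spans = _place_intervals(
                rng, chrom_sizes, int(n_cls), _REPEAT_LENGTHS[cls], min_gap=0
            )
            repeats.extend(RepeatAnnotation(s, cls) for s in spans)
        repeats.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return chrom_sizes, genes, repeats


def simulate_expression(
    config: SimulationConfig, genes: list[GeneModel]
) -> dict[str, float]:
    """Log-normal expression values for heatmap ranking."""
    rng = np.random.default_rng([config.seed, 2])
    return {g.gene_id: float(v) for g, v in zip(genes, rng.lognormal(2.0, 1.5, len(genes)))}


def _scatter_tags(
    rng: np.random.Generator, interval: GenomicInterval, rate: float
) -> np.ndarray:
    n = rng.poisson(rate * interval.length)
    return rng.integers(interval.start, interval.end, size=n)


def _plant_truth(
    rng: np.random.Generator, config: SimulationConfig, chrom_sizes: ChromSizes, tissue: str
) -> tuple[dict[str, list[GenomicInterval]], dict[str, list[PlantedRegion]], list]:
    """Place enriched domains and differential sub-truth for one tissue."""
    enriched: dict[str, list[GenomicInterval]] = {}
    differential: dict[str, list[PlantedRegion]] = {}
    coupled: list[tuple[PlantedRegion, PlantedRegion]] = []

    # 5mC first: uniform placement, random directions
    for mark in config.marks:
        if mark == "5hmC" and "5mC" in differential and config.n_differential:
            enriched[mark], differential[mark], coupled = _plant_coupled_mark(
                rng, config, chrom_sizes, differential["5mC"]
            )
            continue
        domains = _place_intervals(
            rng, chrom_sizes, config.n_enriched, config.domain_length, config.min_domain_gap
        )
        domains.sort(key=lambda iv: (iv.chrom, iv.start))
        enriched[mark] = domains
        if config.n_differential:
            idx = rng.choice(len(domains), size=config.n_differential, replace=False)
            directions = rng.choice(["up", "down"], size=config.n_differential)
            differential[mark] = [
                PlantedRegion(domains[i], d) for i, d in zip(sorted(idx), directions)
            ]
        else:
            differential[mark] = []
    return enriched, differential, coupled


def _plant_coupled_mark(
    rng: np.random.Generator,
    config: SimulationConfig,
    chrom_sizes: ChromSizes,
    partner_regions: list[PlantedRegion],
) -> tuple[list[GenomicInterval], list[PlantedRegion], list]:
    """Place 5hmC domains so that a kappa fraction of its differential
    domains sit within the coupling window of a 5mC differential domain of
    the paired direction (rejection sampling)."""
    dir_mc, dir_hmc = config.coupled_pair
    partners = [r for r in partner_regions if r.direction == dir_mc]
    n_coupled = int(round(config.coupling * config.n_differential))
    if n_coupled and not partners:
        raise RuntimeError(f"no 5mC differential regions with direction {dir_mc!r} to couple to")

    placed: list[GenomicInterval] = []
    coupled_regions: list[PlantedRegion] = []
    pairs = []
    tries = 0
    while len(coupled_regions) < n_coupled:
        tries += 1
        if tries > 50_000:
            raise RuntimeError("could not place coupled 5hmC regions; genome too crowded")
        partner = partners[int(rng.integers(len(partners)))]
        length = int(rng.integers(config.domain_length[0], config.domain_length[1] + 1))
        lo = max(0, partner.interval.start - config.coupling_window - length)
        hi = min(
            chrom_sizes[partner.interval.chrom] - length,
            partner.interval.end + config.coupling_window,
        )
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        cand = GenomicInterval(partner.interval.chrom, start, start + length)
        if interval_gap(cand, partner.interval) > config.coupling_window:
            continue
        too_close = any(
            (g := interval_gap(cand, o)) is not None and g <= config.min_domain_gap
            for o in placed
        )
        if too_close:
            continue
        placed.append(cand)
        region = PlantedRegion(cand, dir_hmc)
        coupled_regions.append(region)
        pairs.append((partner, region))

    free = _place_intervals(
        rng,
        chrom_sizes,
        config.n_enriched - n_coupled,
        config.domain_length,
        config.min_domain_gap,
        existing=placed,
    )
    # remaining differential domains drawn from the freely-placed ones
    n_free_diff = config.n_differential - n_coupled
    idx = rng.choice(len(free), size=n_free_diff, replace=False) if n_free_diff else []
    directions = rng.choice(["up", "down"], size=n_free_diff)
    free_diff = [PlantedRegion(free[i], d) for i, d in zip(sorted(idx), directions)]

    domains = sorted(placed + free, key=lambda iv: (iv.chrom, iv.start))
    differential = sorted(
        coupled_regions + free_diff, key=lambda r: (r.interval.chrom, r.interval.start)
    )
    return domains, differential, pairs


def simulate_libraries(
    config: SimulationConfig,
) -> tuple[list[TagLibrary], TruthSet]:
    """Generate one TagLibrary per tissue x mark x condition x replicate,
    plus the TruthSet of planted domains and differential regions.

    Rates: background lambda0 everywhere; e*lambda0 inside enriched
    domains; inside a differential domain the irradiated ("proton")
    condition rate is further multiplied by phi (up) or divided (down).
    """
    expected_domain_tags = (
        config.background_rate * config.enrichment_fold * config.domain_length[0]
    )
    if config.n_enriched and expected_domain_tags < 1:
        warnings.warn(
            "expected tags per enriched domain < 1; detection power will be ~0",
            stacklevel=2,
        )

    chrom_sizes = config.chrom_sizes()
    truth = TruthSet()
    libraries: list[TagLibrary] = []

    for ti, tissue in enumerate(config.tissues):
        rng_truth = np.random.default_rng([config.seed, 10 + ti])
        enriched, differential, coupled = _plant_truth(rng_truth, config, chrom_sizes, tissue)
        for mark in config.marks:
            truth.enriched[(tissue, mark)] = enriched[mark]
            truth.differential[(tissue, mark)] = differential[mark]
        truth.coupled_pairs[tissue] = coupled

        for mi, mark in enumerate(config.marks):
            diff_by_iv = {r.interval: r.direction for r in differential[mark]}
            for ci, condition in enumerate(config.conditions):
                for rep in range(config.replicates):
                    stream = 1000 + ti * 100 + mi * 10 + ci * 4 + rep
                    rng = np.random.default_rng([config.seed, stream])
                    parts = []
                    # homogeneous background over each chromosome
                    for chrom, length in chrom_sizes.items():
                        parts.append(
                            (
                                chrom,
                                _scatter_tags(
                                    rng,
                                    GenomicInterval(chrom, 0, length),
                                    config.background_rate,
                                ),
                            )
                        )
                    # extra tags inside domains on top of the background
                    for domain in enriched[mark]:
                        rate = config.background_rate * config.enrichment_fold
                        direction = diff_by_iv.get(domain)
                        if direction is not None and condition == "proton":
                            rate = (
                                rate * config.differential_fold
                                if direction == "up"
                                else rate / config.differential_fold
                            )
                        extra = rate - config.background_rate
                        if extra > 0:
                            parts.append((domain.chrom, _scatter_tags(rng, domain, extra)))
                    positions: dict[str, np.ndarray] = {}
                    strands: dict[str, np.ndarray] = {}
                    for chrom in chrom_sizes:
                        arrs = [p for c, p in parts if c == chrom]
                        pos = np.sort(np.concatenate(arrs)).astype(np.int64)
                        positions[chrom] = pos
                        strands[chrom] = np.where(
                            rng.random(len(pos)) < 0.5, "+", "-"
                        ).astype("U1")
                    libraries.append(
                        TagLibrary(
                            library_id=f"{tissue}_{mark}_{condition}_rep{rep + 1}",
                            tissue=tissue,
                            condition=condition,
                            mark=mark,
                            replicate=rep + 1,
                            positions=positions,
                            strands=strands,
                        )
                    )
    return libraries, truth


def null_config(config: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """A copy of ``config`` with all planted signal removed (pure
    background scatter), for calibration runs."""
    base = config or SimulationConfig()
    return replace(base, n_enriched=0, n_differential=0, coupling=0.0, **overrides)
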