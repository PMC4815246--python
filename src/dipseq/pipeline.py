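"""End-to-end orchestration: simulate -> segment -> diff -> overlap ->
annotate -> profile, with plain-file handoff between stages and a run
manifest.

Every stage writes BED/TSV artifacts with stable filenames into the output
directory, so each intermediate is inspectable and independently
re-testable; stage outputs are pure functions of (inputs, config, seed)
and a rerun with the same config reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    categorize_library,
    category_counts_table,
    regions_to_genes,
    repeat_cpm,
    repeat_cpm_table,
)
from .core import GenomicInterval, median_scale_factors, pool_libraries
from .differential import (
    DifferentialRegion,
    build_count_matrix,
    merge_condition_domains,
    evaluate_regions,
)
from .io import (
    write_bed,
    write_chrom_sizes,
    write_expression,
    write_gene_models,
    write_repeats,
    write_tags,
    write_wiggle,
)
from .overlap import directional_overlap, venn_summary
from .profiles import background_subtracted_wiggle, metagene_matrix, plot_metagene_heatmap
from .segmentation import segment_library
from .simulate import SimulationConfig, simulate_annotation, simulate_expression, simulate_libraries

logger = logging.getLogger("dipseq")

_FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    """All stage parameters plus one global seed.

    Defaults mirror the analysis this pipeline reimplements: 1000-bp
    window, segmentation FDR 5%, differential q < 0.01, 25-kb overlap
    window, 50-kb TSS distance with top 2000 regions, 500-bp heatmap bins
    scaled to the 80th quantile.
    """

    outdir: str = "dipseq_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    window: int = 1000
    step: int | None = None
    segment_fdr: float = 0.05
    iterations: int = 20
    merge_gap: int | None = None
    test: str = "chisq"
    q_threshold: float = 0.01
    pseudocount: float = 0.5
    overlap_window: int = 25_000
    overlap_method: str = "hypergeom"
    permutations: int = 10_000
    tss_flank: int = 1000
    max_tss_distance: int = 50_000
    top_k: int = 2000
    flank: int = 5000
    body_bins: int = 40
    heatmap_bin: int = 500
    heatmap_quantile: float = 0.8
    categorize_max_tags: int = 20_000  # subsample cap for the pie-chart stage

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        for key in ("domain_length", "gene_length", "coupled_pair", "tissues", "conditions", "marks"):
            if key in sim_raw and isinstance(sim_raw[key], list):
                sim_raw[key] = tuple(sim_raw[key])
        config = cls(**raw, simulation=SimulationConfig(**sim_raw))
        if "seed" in raw:
            config.simulation = dataclasses.replace(config.simulation, seed=raw["seed"])
        return config

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
    return len(df)


def differential_table(results: list[DifferentialRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "tissue": r.tissue,
                "mark": r.mark,
                "norm_count_sham": r.norm_count_sham,
                "norm_count_proton": r.norm_count_proton,
                "log2_fold_change": r.log2_fold_change,
                "pvalue": r.pvalue,
                "qvalue": r.qvalue,
                "direction": r.direction,
                "test": r.test,
                "low_count": r.low_count,
            }
            for r in results
        ],
        columns=[
            "chrom", "start", "end", "tissue", "mark", "norm_count_sham",
            "norm_count_proton", "log2_fold_change", "pvalue", "qvalue",
            "direction", "test", "low_count",
        ],
    )


def significant_bed(results: list[DifferentialRegion]) -> list[GenomicInterval]:
    out = []
    for r in results:
        score = min(1000.0, -10.0 * np.log10(max(r.qvalue, 1e-300)))
        out.append(
            GenomicInterval(
                r.interval.chrom, r.interval.start, r.interval.end,
                name=r.direction, score=round(score, 1),
            )
        )
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the output directory.

    Any stage failure aborts with the failing stage named; the manifest
    records config hash, seeds and per-stage row counts.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    manifest: dict = {
        "package": "dipseq",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    stage = "simulate"
    try:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        chrom_sizes, genes, repeats = simulate_annotation(sim)
        expression = simulate_expression(sim, genes)
        libraries, truth = simulate_libraries(sim)
        write_chrom_sizes(chrom_sizes, out / "chrom.sizes")
        write_gene_models(genes, out / "genes.tsv")
        write_repeats(repeats, out / "repeats.tsv")
        write_expression(expression, out / "expression.tsv")
        for lib in libraries:
            write_tags(lib, out / f"tags_{lib.library_id}.bed")
        truth_rows = []
        for (tissue, mark), regions in truth.differential.items():
            for r in regions:
                truth_rows.append(
                    GenomicInterval(
                        r.interval.chrom, r.interval.start, r.interval.end,
                        name=f"{tissue}:{mark}:{r.direction}", score=0,
                    )
                )
        write_bed(truth_rows, out / "truth_differential.bed")
        manifest["stages"][stage] = {
            "libraries": len(libraries),
            "genes": len(genes),
            "repeats": len(repeats),
            "planted_differential": len(truth_rows),
        }
        logger.info("simulate: %d libraries", len(libraries))

        stage = "segment"
        scale = median_scale_factors({l.library_id: l.library_size for l in libraries})
        domains_by = {}
        thresholds = {}
        threshold_rows = []
        for ti, tissue in enumerate(sim.tissues):
            for mi, mark in enumerate(sim.marks):
                for ci, condition in enumerate(sim.conditions):
                    libs = [
                        l for l in libraries
                        if l.tissue == tissue and l.mark == mark and l.condition == condition
                    ]
                    pooled = pool_libraries(libs, f"{tissue}_{mark}_{condition}")
                    seg_seed = np.random.default_rng(
                        [config.seed, 7000 + ti * 100 + mi * 10 + ci]
                    )
                    domains, thr = segment_library(
                        pooled, chrom_sizes,
                        window=config.window, step=config.step,
                        alpha=config.segment_fdr, iterations=config.iterations,
                        merge_gap=config.merge_gap, seed=seg_seed,
                    )
                    domains_by[(tissue, mark, condition)] = domains
                    thresholds[(tissue, mark, condition)] = thr
                    threshold_rows.append(
                        {
                            "tissue": tissue, "mark": mark, "condition": condition,
                            "threshold": thr.t, "expected_false": thr.expected_false,
                            "observed_windows": thr.observed,
                            "empirical_fdr": thr.empirical_fdr,
                            "n_domains": len(domains),
                        }
                    )
                    write_bed(
                        [
                            GenomicInterval(
                                d.interval.chrom, d.interval.start, d.interval.end,
                                name=f"domain{k + 1}", score=d.tag_count,
                            )
                            for k, d in enumerate(domains)
                        ],
                        out / f"domains_{tissue}_{mark}_{condition}.bed",
                    )
        _write_tsv(pd.DataFrame(threshold_rows), out / "segmentation_thresholds.tsv")
        manifest["stages"][stage] = {
            "cells": len(domains_by),
            "domains": int(sum(len(d) for d in domains_by.values())),
        }

        stage = "diff"
        all_results: dict[tuple[str, str], list[DifferentialRegion]] = {}
        significant: dict[tuple[str, str], list[DifferentialRegion]] = {}
        diff_frames = []
        for tissue in sim.tissues:
            for mark in sim.marks:
                merged = merge_condition_domains(
                    {c: domains_by[(tissue, mark, c)] for c in sim.conditions}
                )
                libs = [l for l in libraries if l.tissue == tissue and l.mark == mark]
                matrix = build_count_matrix(merged, libs, mark=mark, tissue=tissue)
                results = evaluate_regions(
                    matrix, test=config.test, pseudocount=config.pseudocount
                )
                all_results[(tissue, mark)] = results
                significant[(tissue, mark)] = [
                    r for r in results if r.qvalue < config.q_threshold
                ]
                diff_frames.append(differential_table(results))
                write_bed(
                    significant_bed(significant[(tissue, mark)]),
                    out / f"differential_{tissue}_{mark}.bed",
                )
        _write_tsv(pd.concat(diff_frames, ignore_index=True), out / "differential_all.tsv")
        manifest["stages"][stage] = {
            "tested": int(sum(len(r) for r in all_results.values())),
            "significant": int(sum(len(r) for r in significant.values())),
        }

        stage = "overlap"
        overlap_frames = []
        for tissue in sim.tissues:
            tables = directional_overlap(
                significant[(tissue, "5mC")],
                significant[(tissue, "5hmC")],
                all_results[(tissue, "5mC")],
                window=config.overlap_window,
                method=config.overlap_method,
                permutations=config.permutations,
                seed=config.seed,
            )
            summary = venn_summary(tables)
            summary.insert(0, "tissue", tissue)
            overlap_frames.append(summary)
        _write_tsv(pd.concat(overlap_frames, ignore_index=True), out / "overlap_summary.tsv")
        manifest["stages"][stage] = {"direction_pairs": int(sum(len(f) for f in overlap_frames))}

        stage = "annotate"
        pie_frames = []
        rng_sub = np.random.default_rng([config.seed, 9001])
        cpm_rows = []
        for lib in libraries:
            sub = _subsample(lib, config.categorize_max_tags, rng_sub)
            counts = categorize_library(sub, genes, tss_flank=config.tss_flank)
            tbl = category_counts_table(counts)
            tbl.insert(0, "library_id", lib.library_id)
            pie_frames.append(tbl)
            cpm_rows.extend(repeat_cpm(lib, repeats))
        _write_tsv(pd.concat(pie_frames, ignore_index=True), out / "category_counts.tsv")
        _write_tsv(repeat_cpm_table(cpm_rows), out / "repeat_cpm.tsv")
        gene_rows = []
        for (tissue, mark), sig in significant.items():
            for a in regions_to_genes(
                sig, genes, max_distance=config.max_tss_distance, top_k=config.top_k
            ):
                gene_rows.append(
                    {
                        "tissue": tissue, "mark": mark, "gene_id": a.gene_id,
                        "chrom": a.region.interval.chrom,
                        "start": a.region.interval.start,
                        "end": a.region.interval.end,
                        "direction": a.region.direction,
                        "distance_to_tss": a.distance,
                        "qvalue": a.region.qvalue, "rank": a.rank,
                    }
                )
        _write_tsv(
            pd.DataFrame(
                gene_rows,
                columns=[
                    "tissue", "mark", "gene_id", "chrom", "start", "end",
                    "direction", "distance_to_tss", "qvalue", "rank",
                ],
            ),
            out / "gene_assignments.tsv",
        )
        manifest["stages"][stage] = {"gene_assignments": len(gene_rows)}

        stage = "profile"
        lib0 = libraries[0]
        mm = metagene_matrix(
            lib0, genes, expression,
            flank=config.flank, body_bins=config.body_bins,
            bin_size=config.heatmap_bin,
        )
        _write_tsv(mm.to_frame(), out / f"metagene_{lib0.library_id}.tsv")
        plot_metagene_heatmap(
            mm, str(out / f"metagene_{lib0.library_id}.png"), q=config.heatmap_quantile
        )
        key0 = (lib0.tissue, lib0.mark, lib0.condition)
        track = background_subtracted_wiggle(
            lib0, thresholds[key0], chrom_sizes,
            bin_size=config.window, scale=scale[lib0.library_id],
        )
        write_wiggle(track, config.window, out / f"density_{lib0.library_id}.wig")
        manifest["stages"][stage] = {"metagene_genes": len(mm.gene_ids)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.removeHandler(handler)
    handler.close()
    return out


def _subsample(library, max_tags: int, rng: np.random.Generator):
    """Deterministic subsample of a tag library (speeds up per-tag
    category assignment without changing the pie proportions)."""
    n = library.library_size
    if n <= max_tags:
        return library
    keep_frac = max_tags / n
    positions = {}
    for chrom, pos in library.positions.items():
        k = int(round(len(pos) * keep_frac))
        idx = np.sort(rng.choice(len(pos), size=k, replace=False))
        positions[chrom] = pos[idx]
    return dataclasses.replace(library, positions=positions, strands={})
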