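"""Readers and writers for the plain-text formats used between stages.

All files are tab-separated UTF-8.  BED intervals are 0-based half-open
exactly as stored internally; fixedStep wiggle output converts to the
format's 1-based convention at this boundary.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ChromSizes,
    GeneModel,
    GenomicInterval,
    RepeatAnnotation,
    TagLibrary,
)


class BedParseError(ValueError):
    """Malformed BED line; message names the offending line number."""


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals, preserving order and any
    name/score/strand columns."""
    out: list[GenomicInterval] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"line {lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(
                    GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)
                )
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    """Write intervals as BED; emits BED3 when no interval carries
    name/score/strand, else BED6 with '.' placeholders."""
    ivs = list(intervals)
    bed6 = any(iv.name is not None or iv.score is not None or iv.strand != "." for iv in ivs)
    with open(path, "w", encoding="utf-8") as fh:
        for iv in ivs:
            if bed6:
                score = f"{iv.score:g}" if iv.score is not None else "0"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: str | os.PathLike) -> ChromSizes:
    sizes: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"chrom.sizes line {lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return ChromSizes(sizes)


def write_chrom_sizes(chrom_sizes: ChromSizes, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, length in chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def write_wiggle(
    values_by_chrom: Mapping[str, Sequence[float]],
    bin_size: int,
    path: str | os.PathLike,
) -> None:
    """Write fixed-width binned values as fixedStep wiggle.

    Bin i covers [i*bin_size, (i+1)*bin_size) in 0-based coordinates; the
    wiggle declaration start is therefore i*bin_size + 1 (1-based).  Runs
    of zero-valued bins are omitted.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in values_by_chrom:
            values = np.asarray(values_by_chrom[chrom], dtype=float)
            nonzero = values != 0
            if not nonzero.any():
                continue
            # maximal runs of nonzero bins -> one fixedStep block each
            idx = np.flatnonzero(nonzero)
            breaks = np.flatnonzero(np.diff(idx) > 1)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [len(idx) - 1]])
            for s, e in zip(starts, ends):
                first_bin = idx[s]
                fh.write(
                    f"fixedStep chrom={chrom} start={first_bin * bin_size + 1} "
                    f"step={bin_size} span={bin_size}\n"
                )
                for v in values[idx[s] : idx[e] + 1]:
                    fh.write(f"{v:g}\n")


def read_wiggle(path: str | os.PathLike) -> dict[str, dict[int, float]]:
    """Read fixedStep wiggle back into {chrom: {0-based bin index: value}}.

    Supports only the dialect written by :func:`write_wiggle` (step == span);
    used for round-trip checks and downstream inspection.
    """
    out: dict[str, dict[int, float]] = {}
    chrom, start, step = None, None, None
    offset = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("fixedStep"):
                kv = dict(item.split("=") for item in line.split()[1:])
                chrom = kv["chrom"]
                start = int(kv["start"]) - 1
                step = int(kv["step"])
                if int(kv.get("span", step)) != step:
                    raise ValueError("only step == span wiggle supported")
                if start % step:
                    raise ValueError("wiggle start not aligned to bin grid")
                offset = 0
                out.setdefault(chrom, {})
            else:
                if chrom is None:
                    raise ValueError("wiggle data before declaration line")
                out[chrom][start // step + offset] = float(line)
                offset += 1
    return out


# -- tabular annotation formats (TSV with header) ---------------------------

def write_gene_models(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "start": g.interval.start,
                "end": g.interval.end,
                "exon_starts": ",".join(str(e.start) for e in g.exons),
                "exon_ends": ",".join(str(e.end) for e in g.exons),
            }
        )
    pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "strand", "start", "end", "exon_starts", "exon_ends"],
    ).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"exon_starts": str, "exon_ends": str})
    genes = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), strand=row.strand)
        exons = []
        if isinstance(row.exon_starts, str) and row.exon_starts:
            starts = [int(x) for x in row.exon_starts.split(",")]
            ends = [int(x) for x in row.exon_ends.split(",")]
            exons = [
                GenomicInterval(row.chrom, s, e, strand=row.strand)
                for s, e in zip(starts, ends)
            ]
        genes.append(GeneModel(str(row.gene_id), iv, exons))
    return genes


def write_repeats(repeats: Iterable[RepeatAnnotation], path: str | os.PathLike) -> None:
    rows = [
        {
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "repeat_class": r.repeat_class,
        }
        for r in repeats
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "repeat_class"]).to_csv(
        path, sep="\t", index=False
    )


def read_repeats(path: str | os.PathLike) -> list[RepeatAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        RepeatAnnotation(
            GenomicInterval(row.chrom, int(row.start), int(row.end)), row.repeat_class
        )
        for row in df.itertuples(index=False)
    ]


def write_expression(expression: Mapping[str, float], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"gene_id": list(expression), "expression": list(expression.values())}
    ).to_csv(path, sep="\t", index=False)


def read_expression(path: str | os.PathLike) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return dict(zip(df["gene_id"], df["expression"].astype(float)))


# -- tag libraries ----------------------------------------------------------

def write_tags(library: TagLibrary, path: str | os.PathLike) -> None:
    """Write a tag library as BED6 of 1-bp tag 5' positions."""
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in sorted(library.positions):
            pos = library.positions[chrom]
            strands = library.strands.get(chrom)
            for i, p in enumerate(pos):
                strand = strands[i] if strands is not None else "."
                fh.write(f"{chrom}\t{p}\t{p + 1}\ttag\t0\t{strand}\n")


def read_tags(
    path: str | os.PathLike,
    library_id: str,
    tissue: str = "",
    condition: str = "",
    mark: str = "",
    replicate: int = 0,
) -> TagLibrary:
    """Read a BED of mapped-tag positions (5' end = BED start) into a
    TagLibrary; metadata comes from the caller (filenames/config)."""
    intervals = read_bed(path)
    positions: dict[str, list[int]] = {}
    strands: dict[str, list[str]] = {}
    for iv in intervals:
        positions.setdefault(iv.chrom, []).append(iv.start)
        strands.setdefault(iv.chrom, []).append(iv.strand)
    pos_arrays = {}
    strand_arrays = {}
    for chrom, plist in positions.items():
        arr = np.asarray(plist, dtype=np.int64)
        order = np.argsort(arr, kind="stable")
        pos_arrays[chrom] = arr[order]
        strand_arrays[chrom] = np.asarray(strands[chrom])[order]
    return TagLibrary(
        library_id=library_id,
        tissue=tissue,
        condition=condition,
        mark=mark,
        replicate=replicate,
        positions=pos_arrays,
        strands=strand_arrays,
    )
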