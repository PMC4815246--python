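import numpy as np
import pandas as pd
import pytest

from dipseq.annotation import (
    assign_category,
    categorize_library,
    compare_tissue_density,
    intragenic_fraction,
    regions_to_genes,
    repeat_cpm,
)
from dipseq.core import GeneModel, GenomicInterval, RepeatAnnotation
from dipseq.differential import DifferentialRegion


def _gene(gene_id, chrom, start, end, strand="+", exons=None):
    ivl = GenomicInterval(chrom, start, end, strand=strand)
    if exons is None:
        exons = [ivl]
    else:
        exons = [GenomicInterval(chrom, s, e, strand=strand) for s, e in exons]
    return GeneModel(gene_id, ivl, exons)


def _region(chrom, start, end, q=0.001, log2fc=1.0, direction="up"):
    return DifferentialRegion(
        interval=GenomicInterval(chrom, start, end), mark="5mC",
        norm_count_sham=10, norm_count_proton=30, log2_fold_change=log2fc,
        pvalue=q / 2, qvalue=q, direction=direction, test="chisq",
    )


class TestAssignCategory:
    def test_interval_inside_exon_only(self):
        gene = _gene("g1", "chr1", 50_000, 60_000, exons=[(50_000, 60_000)])
        res = assign_category(GenomicInterval("chr1", 55_000, 55_100), [gene])
        assert res.category == "exon"

    def test_midpoint_rule_prefers_closer_feature(self):
        # TSS window [49000, 51001), exon [51050, 59000); interval overlaps
        # both, its midpoint sits nearer the TSS-window midpoint
        gene = _gene("g1", "chr1", 50_000, 60_000, exons=[(51_050, 59_000)])
        probe = GenomicInterval("chr1", 49_500, 51_200)  # midpoint 50350
        res = assign_category(probe, [gene], tss_flank=1000)
        assert res.category == "TSS"

    def test_gene_free_chromosome_is_intergenic(self):
        gene = _gene("g1", "chr1", 50_000, 60_000)
        res = assign_category(GenomicInterval("chr9", 100, 200), [gene])
        assert res.category == "intergenic"

    def test_intron_recognized(self):
        gene = _gene("g1", "chr1", 50_000, 60_000,
                     exons=[(50_000, 51_000), (59_000, 60_000)])
        res = assign_category(GenomicInterval("chr1", 55_000, 55_010), [gene])
        assert res.category == "intron"

    def test_minus_strand_tss_at_gene_end(self):
        gene = _gene("g1", "chr1", 50_000, 60_000, strand="-")
        res = assign_category(GenomicInterval("chr1", 59_990, 60_500), [gene], tss_flank=1000)
        assert res.category == "TSS"


class TestCategorizeLibrary:
    def test_counts_conserve_library_size(self, library_factory):
        rng = np.random.default_rng(30)
        genes = [
            _gene("g1", "chr1", 10_000, 20_000, exons=[(10_000, 12_000), (18_000, 20_000)]),
            _gene("g2", "chr1", 40_000, 45_000),
        ]
        lib = library_factory({"chr1": np.sort(rng.integers(0, 90_000, 500)).tolist()})
        counts = categorize_library(lib, genes)
        assert sum(counts.values()) == 500

    def test_matches_brute_force_assignment(self, library_factory):
        rng = np.random.default_rng(31)
        genes = [
            _gene("g1", "chr1", 5_000, 15_000, exons=[(5_000, 7_000), (12_000, 15_000)]),
            _gene("g2", "chr1", 30_000, 36_000, strand="-"),
        ]
        positions = np.sort(rng.integers(0, 50_000, 300))
        lib = library_factory({"chr1": positions.tolist()})
        counts = categorize_library(lib, genes)
        brute = dict.fromkeys(("TSS", "exon", "intron", "intergenic"), 0)
        for p in positions:
            brute[assign_category(GenomicInterval("chr1", int(p), int(p) + 1), genes).category] += 1
        assert counts == brute

    def test_intragenic_split(self, library_factory):
        genes = [_gene("g1", "chr1", 1000, 2000)]
        lib = library_factory({"chr1": [500, 1500, 1999, 2000]})
        assert intragenic_fraction(lib, genes) == {"intragenic": 2, "intergenic": 2}


class TestRepeatCpm:
    def _repeats(self):
        return [
            RepeatAnnotation(GenomicInterval("chr1", 1000, 1300), "SINE"),
            RepeatAnnotation(GenomicInterval("chr1", 5000, 9000), "LINE"),
            RepeatAnnotation(GenomicInterval("chr1", 20_000, 20_080), "tRNA"),
        ]

    def test_all_tags_in_one_class(self, library_factory):
        lib = library_factory({"chr1": [1100, 1200, 1250]})
        cpm = {d.repeat_class: d.cpm for d in repeat_cpm(lib, self._repeats())}
        assert cpm["SINE"] == 1e6 and sum(cpm.values()) == 1e6

    def test_cpm_sums_to_one_million(self, library_factory):
        rng = np.random.default_rng(32)
        lib = library_factory({"chr1": np.sort(rng.integers(0, 30_000, 2000)).tolist()})
        total = sum(d.cpm for d in repeat_cpm(lib, self._repeats()))
        assert total == pytest.approx(1e6)

    def test_no_repeat_overlap_raises(self, library_factory):
        lib = library_factory({"chr1": [100, 200]})
        with pytest.raises(ValueError, match="repeat"):
            repeat_cpm(lib, self._repeats())

    def test_library_denominator_counts_all_tags(self, library_factory):
        lib = library_factory({"chr1": [100, 1100]})  # one of two in a repeat
        cpm = {d.repeat_class: d.cpm for d in repeat_cpm(lib, self._repeats(),
                                                         denominator="library")}
        assert cpm["SINE"] == 5e5

    def test_overlapping_repeats_assigned_to_closest(self, library_factory):
        reps = [
            RepeatAnnotation(GenomicInterval("chr1", 0, 1000), "LINE"),
            RepeatAnnotation(GenomicInterval("chr1", 900, 1000), "SINE"),
        ]
        lib = library_factory({"chr1": [950]})  # SINE midpoint 950, LINE 500
        cpm = {d.repeat_class: d.cpm for d in repeat_cpm(lib, reps)}
        assert cpm["SINE"] == 1e6

    def test_matches_brute_force_scan(self, library_factory):
        rng = np.random.default_rng(33)
        classes = ["SINE", "LINE", "LTR", "satellite", "tRNA", "rRNA", "other"]
        reps = [
            RepeatAnnotation(
                GenomicInterval("chr1", int(s), int(s + l)), classes[int(c)]
            )
            for s, l, c in zip(
                rng.integers(0, 95_000, 120), rng.integers(50, 2000, 120),
                rng.integers(0, 7, 120),
            )
        ]
        positions = np.sort(rng.integers(0, 100_000, 1500))
        lib = library_factory({"chr1": positions.tolist()})
        got = {d.repeat_class: d.cpm for d in repeat_cpm(lib, reps)}
        brute = dict.fromkeys(classes, 0)
        hits = 0
        for p in positions:
            mid = p + 0.5
            over = [r for r in reps if r.interval.start <= p < r.interval.end]
            if not over:
                continue
            best = min(over, key=lambda r: (abs(r.interval.midpoint - mid), r.repeat_class))
            brute[best.repeat_class] += 1
            hits += 1
        for cls in classes:
            assert got[cls] == pytest.approx(1e6 * brute[cls] / hits)


class TestCompareTissueDensity:
    def _table(self, values_by_class, tissue):
        rows = []
        for cls, vals in values_by_class.items():
            for i, v in enumerate(vals):
                rows.append({"library_id": f"{tissue}{i}", "tissue": tissue,
                             "mark": "5mC", "repeat_class": cls, "cpm": v})
        return pd.DataFrame(rows)

    def _full(self, vals):
        classes = ["SINE", "LINE", "LTR", "satellite", "tRNA", "rRNA", "other"]
        return {c: vals for c in classes}

    def test_identical_groups_give_p_one(self):
        a = self._table(self._full([100, 100, 100, 100]), "hippocampus")
        b = self._table(self._full([100, 100, 100, 100]), "ventricle")
        res = compare_tissue_density(a, b)
        assert (res["pvalue"] == 1.0).all()

    def test_label_swap_preserves_p(self):
        a = self._table(self._full([90, 100, 110, 105]), "hippocampus")
        b = self._table(self._full([140, 150, 160, 155]), "ventricle")
        p_ab = compare_tissue_density(a, b)["pvalue"]
        p_ba = compare_tissue_density(b, a)["pvalue"]
        np.testing.assert_allclose(p_ab, p_ba)

    def test_detects_planted_two_fold_trna_shift(self):
        """2x tRNA difference, n = 4, CV 10%: detected at p < 0.05 in >= 90%
        of simulations."""
        rng = np.random.default_rng(34)
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            base = {c: rng.normal(100, 10, 4) for c in
                    ["SINE", "LINE", "LTR", "satellite", "rRNA", "other"]}
            a = dict(base, tRNA=rng.normal(100, 10, 4))
            b = dict(base, tRNA=rng.normal(200, 20, 4))
            res = compare_tissue_density(
                self._table(a, "hippocampus"), self._table(b, "ventricle")
            ).set_index("repeat_class")
            if res.loc["tRNA", "pvalue"] < 0.05:
                hits += 1
        assert hits >= 90

    def test_requires_replicates(self):
        a = self._table(self._full([100]), "hippocampus")
        b = self._table(self._full([100, 110]), "ventricle")
        with pytest.raises(ValueError):
            compare_tissue_density(a, b)


class TestRegionsToGenes:
    def test_upstream_region_signed_negative(self):
        gene = _gene("g1", "chr1", 100_000, 110_000)  # TSS at 100000, + strand
        (a,) = regions_to_genes([_region("chr1", 99_000, 99_990)], [gene])
        assert a.gene_id == "g1" and a.distance == -10

    def test_downstream_of_minus_strand_gene_is_negative(self):
        gene = _gene("g1", "chr1", 100_000, 110_000, strand="-")  # TSS 109999
        (a,) = regions_to_genes([_region("chr1", 111_000, 112_000)], [gene])
        assert a.distance == -(111_000 - 109_999)

    def test_region_just_past_max_distance_dropped(self):
        gene = _gene("g1", "chr1", 100_000, 110_000)
        far = _region("chr1", 49_000, 49_999)  # TSS - end = 50,001
        near = _region("chr1", 49_001, 50_000)  # exactly 50,000
        assert regions_to_genes([far], [gene]) == []
        assert len(regions_to_genes([near], [gene])) == 1

    def test_duplicate_genes_collapse_to_best_rank(self):
        gene = _gene("g1", "chr1", 100_000, 110_000)
        worse = _region("chr1", 95_000, 96_000, q=0.009)
        better = _region("chr1", 99_000, 99_900, q=0.0001)
        (a,) = regions_to_genes([worse, better], [gene])
        assert a.region is better and a.rank == 1

    def test_top_k_truncates_by_q_rank(self):
        genes = [_gene(f"g{i}", "chr1", 100_000 * (i + 1), 100_000 * (i + 1) + 5000)
                 for i in range(5)]
        regions = [
            _region("chr1", 100_000 * (i + 1) - 2000, 100_000 * (i + 1) - 1000,
                    q=0.001 * (i + 1))
            for i in range(5)
        ]
        out = regions_to_genes(regions, genes, top_k=2)
        assert [a.gene_id for a in out] == ["g0", "g1"]

    def test_output_bounded_by_genes_and_regions(self):
        gene = _gene("g1", "chr1", 100_000, 110_000)
        regions = [_region("chr1", 99_000 - i * 10, 99_900 - i * 10) for i in range(4)]
        out = regions_to_genes(regions, [gene])
        assert len(out) <= 1
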