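import numpy as np
import pytest
from scipy import stats

from dipseq.core import GenomicInterval
from dipseq.differential import (
    RegionCountMatrix,
    adjust_fdr,
    build_count_matrix,
    call_differential,
    chisq_region_test,
    estimate_common_dispersion,
    merge_condition_domains,
    negbin_region_test,
    evaluate_regions,
)
from dipseq.segmentation import EnrichedDomain


def _domain(chrom, start, end):
    return EnrichedDomain(GenomicInterval(chrom, start, end), 0, 1)


class TestMergeConditionDomains:
    def test_overlapping_domains_union(self):
        merged = merge_condition_domains(
            {"sham": [_domain("chr1", 0, 2000)], "proton": [_domain("chr1", 1500, 3000)]}
        )
        assert merged == [GenomicInterval("chr1", 0, 3000)]

    def test_disjoint_domains_pass_through(self):
        merged = merge_condition_domains(
            {"sham": [_domain("chr1", 0, 1000)], "proton": [_domain("chr1", 5000, 6000)]}
        )
        assert [(m.start, m.end) for m in merged] == [(0, 1000), (5000, 6000)]

    def test_matches_sweep_line_union_on_random_fixtures(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            doms = {
                cond: [
                    _domain("chr1", int(s), int(s + l))
                    for s, l in zip(rng.integers(0, 5000, 20), rng.integers(1, 400, 20))
                ]
                for cond in ("sham", "proton")
            }
            mask = np.zeros(6000, dtype=bool)
            for dlist in doms.values():
                for d in dlist:
                    mask[d.interval.start : d.interval.end] = True
            edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
            expected = [
                (int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)
            ]
            assert [(m.start, m.end) for m in merge_condition_domains(doms)] == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_condition_domains({})


class TestChisq:
    def test_equal_proportions_give_zero_statistic(self):
        res = chisq_region_test(50, 50, 10**6, 10**6)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_matches_textbook_pearson_formula(self):
        """Statistic equals the independent 2x2 Pearson computation."""
        res = chisq_region_test(100, 50, 10**6, 10**6)
        table = np.array([[100, 10**6 - 100], [50, 10**6 - 50]])
        expected_stat, expected_p, _, _ = stats.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(expected_stat, abs=1e-10)
        assert res.pvalue == pytest.approx(expected_p, abs=1e-10)

    def test_statistic_grows_with_exposure_at_fixed_proportions(self):
        small = chisq_region_test(100, 50, 10**6, 10**6).statistic
        large = chisq_region_test(1000, 500, 10**7, 10**7).statistic
        assert large > small

    def test_exchangeable_in_conditions(self):
        a = chisq_region_test(120, 55, 10**6, 2 * 10**6)
        b = chisq_region_test(55, 120, 2 * 10**6, 10**6)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
        assert a.pvalue == pytest.approx(b.pvalue, rel=1e-12)

    def test_both_zero_counts_give_p_one(self):
        res = chisq_region_test(0, 0, 10**6, 10**6)
        assert res.pvalue == 1.0 and res.statistic == 0.0

    def test_low_expected_cell_flagged(self):
        assert chisq_region_test(1, 0, 10**6, 10**6).low_count
        assert not chisq_region_test(100, 50, 10**6, 10**6).low_count

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            chisq_region_test(5, 5, 0, 10)
        with pytest.raises(ValueError):
            chisq_region_test(11, 5, 10, 10)


class TestNegbin:
    def test_identical_counts_give_p_one(self):
        res = negbin_region_test([30, 30], [30, 30], np.array([1e6, 1e6]),
                                 np.array([1e6, 1e6]), dispersion=0.1)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.pvalue == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_region_gives_p_one(self):
        res = negbin_region_test([0, 0], [0, 0], np.array([1e6, 1e6]),
                                 np.array([1e6, 1e6]), dispersion=0.2)
        assert res.pvalue == 1.0

    def test_vanishing_dispersion_converges_to_poisson_lrt(self):
        """With dispersion pinned to 1e-8 the LRT matches the closed-form
        Poisson likelihood-ratio statistic to 1e-6."""
        ya, yb = np.array([40.0, 55.0]), np.array([80.0, 95.0])
        s = np.array([1e6, 1e6])
        res = negbin_region_test(ya, yb, s, s, dispersion=1e-8)

        def pois_ll(y, mu):
            # gammaln(y+1) terms cancel in the likelihood ratio
            return np.sum(y * np.log(mu) - mu)

        mu_null = np.full(4, np.concatenate([ya, yb]).mean())
        lrt = 2 * (
            pois_ll(ya, np.full(2, ya.mean())) + pois_ll(yb, np.full(2, yb.mean()))
            - pois_ll(np.concatenate([ya, yb]), mu_null)
        )
        assert res.statistic == pytest.approx(lrt, abs=1e-6)

    def test_matches_statsmodels_nb_glm_fit(self):
        """The fixed-dispersion intercept fits agree with a statsmodels
        NB GLM (log link, offset = log library size) on the same region."""
        import statsmodels.api as sm

        y = np.array([23.0, 31.0, 60.0, 52.0])
        s = np.array([9e5, 1.1e6, 1e6, 1e6])
        alpha = 0.15
        cond = np.array([0, 0, 1, 1])
        X = np.column_stack([np.ones(4), cond])
        glm_alt = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=np.log(s)
        ).fit()
        glm_null = sm.GLM(
            y, np.ones((4, 1)), family=sm.families.NegativeBinomial(alpha=alpha),
            offset=np.log(s),
        ).fit()
        lrt_sm = 2 * (glm_alt.llf - glm_null.llf)
        res = negbin_region_test(y[:2], y[2:], s[:2], s[2:], dispersion=alpha)
        assert res.statistic == pytest.approx(lrt_sm, abs=1e-5)

    def test_moment_dispersion_recovers_truth(self):
        rng = np.random.default_rng(11)
        m, mu, alpha = 3000, 80, 0.25
        r = 1 / alpha
        counts = rng.negative_binomial(r, r / (r + mu), size=(m, 4))
        mat = RegionCountMatrix(
            [GenomicInterval("chr1", 10 * i + 1, 10 * i + 5) for i in range(m)],
            counts, ["a1", "a2", "b1", "b2"], np.array([10**6] * 4),
            ["sham", "sham", "proton", "proton"],
        )
        est = estimate_common_dispersion(mat)
        assert est == pytest.approx(alpha, rel=0.15)

    def test_negative_moment_estimate_falls_back_to_poisson(self):
        # underdispersed (constant) counts force a negative moment estimate
        counts = np.tile([50, 50, 50, 50], (20, 1))
        counts[:, 1] = 50  # zero variance, mean 50 -> v - m < 0
        mat = RegionCountMatrix(
            [GenomicInterval("chr1", 10 * i + 1, 10 * i + 5) for i in range(20)],
            counts, ["a1", "a2", "b1", "b2"], np.array([10**6] * 4),
            ["sham", "sham", "proton", "proton"],
        )
        with pytest.warns(UserWarning, match="Poisson"):
            assert estimate_common_dispersion(mat) == 0.0


class TestAdjustFdr:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_boundary_identity(self):
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_fdr([0.2]), [0.2])

    def test_empty_input(self):
        assert adjust_fdr([]).size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    def test_order_invariance(self):
        rng = np.random.default_rng(12)
        p = rng.random(50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(adjust_fdr(p)[perm], adjust_fdr(p[perm]))

    def test_monotone_in_p(self):
        rng = np.random.default_rng(13)
        p = np.sort(rng.random(100))
        q = adjust_fdr(p)
        assert np.all(np.diff(q) >= -1e-12)


class TestCallDifferential:
    def _matrix(self, counts, sizes=None):
        counts = np.asarray(counts)
        m = counts.shape[0]
        return RegionCountMatrix(
            [GenomicInterval("chr1", 10_000 * i + 1, 10_000 * i + 2000) for i in range(m)],
            counts, ["s1", "s2", "p1", "p2"],
            sizes if sizes is not None else np.array([10**6] * 4),
            ["sham", "sham", "proton", "proton"], mark="5mC",
        )

    def test_empty_candidate_list_gives_empty_output(self):
        mat = RegionCountMatrix([], np.zeros((0, 2)), ["a", "b"],
                                np.array([10, 10]), ["sham", "proton"])
        assert call_differential(mat) == []

    def test_direction_follows_fold_change_sign(self):
        mat = self._matrix([[100, 100, 300, 300], [300, 300, 100, 100]])
        results = evaluate_regions(mat)
        assert results[0].direction == "up" and results[0].log2_fold_change > 0
        assert results[1].direction == "down" and results[1].log2_fold_change < 0

    def test_q_not_below_p_and_calls_shrink_with_threshold(self):
        rng = np.random.default_rng(14)
        base = rng.poisson(100, size=(50, 4))
        base[:5, 2:] *= 4
        mat = self._matrix(base)
        results = evaluate_regions(mat)
        assert all(r.qvalue >= r.pvalue - 1e-12 for r in results)
        loose = {id(r.interval) for r in call_differential(mat, q_threshold=0.05)}
        strict = {id(r.interval) for r in call_differential(mat, q_threshold=0.001)}
        assert strict <= loose

    def test_median_scaling_compensates_library_size(self):
        # proton libraries twice as deep; equal underlying rate -> no call
        mat = self._matrix(
            [[100, 100, 200, 200]], sizes=np.array([1e6, 1e6, 2e6, 2e6])
        )
        (r,) = evaluate_regions(mat)
        assert abs(r.log2_fold_change) < 0.01

    def test_negbin_mode_runs_and_agrees_on_strong_effect(self):
        mat = self._matrix([[100, 110, 500, 520], [100, 95, 102, 98]])
        res = evaluate_regions(mat, test="negbin", dispersion=0.05)
        assert res[0].pvalue < 0.01 and res[1].pvalue > 0.1


def test_build_count_matrix_counts_by_interval(library_factory):
    lib_a = library_factory({"chr1": [10, 20, 5000]}, library_id="a", condition="sham")
    lib_b = library_factory({"chr1": [15, 5001, 5002]}, library_id="b", condition="proton")
    regions = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 4900, 5100)]
    mat = build_count_matrix(regions, [lib_a, lib_b])
    np.testing.assert_array_equal(mat.counts, [[2, 1], [1, 2]])
    np.testing.assert_array_equal(mat.library_sizes, [3, 3])
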