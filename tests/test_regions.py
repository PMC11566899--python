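import numpy as np
import pytest
from scipy import stats as sps

from methyloscope.errors import ConfigError, ValidationError
from methyloscope.io_formats import SampleMetadata
from methyloscope.regions import (
    anova_per_cpg,
    associate_regions,
    attach_q_values,
    bh_fdr,
    call_dmcs,
    logistic_dmc,
    merge_runs,
    sd_per_cpg,
    top_fraction_threshold,
)


def merge_oracle(positions, gap_bp, min_count):
    """Independent chaining oracle: walk sorted positions, cut at gaps."""
    pairs = sorted(set(positions))
    runs, cur = [], []
    for p in pairs:
        if cur and (p[0] != cur[-1][0] or p[1] - cur[-1][1] > gap_bp):
            runs.append(cur)
            cur = []
        cur.append(p)
    if cur:
        runs.append(cur)
    return [
        (r[0][0], r[0][1], r[-1][1] + 1, len(r)) for r in runs if len(r) >= min_count
    ]


class TestAnova:
    def test_hand_computed_f(self):
        beta = np.array([[0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]])
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        (stat,) = anova_per_cpg(beta, labels)
        assert stat.statistic == pytest.approx(27.0)
        # oracle: SSB = 0.54 (df 2), SSW = 0.06 (df 6)
        assert stat.p_value == pytest.approx(sps.f.sf(27.0, 2, 6))

    def test_all_identical(self):
        beta = np.full((1, 9), 0.4)
        (stat,) = anova_per_cpg(beta, ["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        assert stat.statistic == 0.0 and stat.p_value == 1.0

    def test_degenerate_zero_within_variance(self):
        beta = np.array([[0.1, 0.1, 0.9, 0.9]])
        (stat,) = anova_per_cpg(beta, ["A", "A", "B", "B"])
        assert stat.p_value == 0.0 and stat.flag == "degenerate"

    def test_permutation_within_groups_invariant(self, rng):
        beta = rng.random((20, 9))
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        perm = [1, 2, 0, 4, 5, 3, 8, 6, 7]  # permutes within each group
        a = anova_per_cpg(beta, labels)
        b = anova_per_cpg(beta[:, perm], labels)
        for x, y in zip(a, b):
            assert x.statistic == pytest.approx(y.statistic, rel=1e-12)

    def test_two_groups_equals_t_squared(self, rng):
        beta = rng.random((50, 10))
        labels = ["A"] * 5 + ["B"] * 5
        stats_list = anova_per_cpg(beta, labels)
        t = sps.ttest_ind(beta[:, :5], beta[:, 5:], axis=1)
        assert np.allclose(
            [s.statistic for s in stats_list], t.statistic**2, atol=1e-10
        )
        assert np.allclose([s.p_value for s in stats_list], t.pvalue, atol=1e-10)

    def test_matches_scipy_f_oneway(self, rng):
        beta = rng.random((30, 9))
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        stats_list = anova_per_cpg(beta, labels)
        ref = sps.f_oneway(beta[:, :3], beta[:, 3:6], beta[:, 6:], axis=1)
        assert np.allclose([s.statistic for s in stats_list], ref.statistic)
        assert np.allclose([s.p_value for s in stats_list], ref.pvalue)

    def test_small_group_rejected(self):
        with pytest.raises(ConfigError):
            anova_per_cpg(np.zeros((1, 3)), ["A", "A", "B"])


class TestBhFdr:
    def test_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.3]).tolist() == [0.3]

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(500)
        q = bh_fdr(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_ref, atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.random(200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallDmcs:
    def test_strict_threshold(self):
        stats_list = attach_q_values(
            anova_per_cpg(np.random.default_rng(0).random((5, 6)),
                          ["A"] * 3 + ["B"] * 3)
        )
        from methyloscope.regions import SiteStat

        sites = [
            SiteStat("chr1", 10, 1.0, 0.01, 0.049),
            SiteStat("chr1", 20, 1.0, 0.01, 0.05),
        ]
        assert call_dmcs(sites) == [("chr1", 10)]

    def test_empty(self):
        assert call_dmcs([]) == []

    def test_threshold_one_returns_all(self):
        from methyloscope.regions import SiteStat

        sites = [SiteStat("chr1", p, 1.0, 0.5, 0.99) for p in (30, 10, 20)]
        assert call_dmcs(sites, 1.0) == [("chr1", 10), ("chr1", 20), ("chr1", 30)]


class TestMergeRuns:
    def test_hand_traced_chaining(self):
        regions = merge_runs([100, 150, 240, 500, 560, 600, 650, 700],
                             gap_bp=100, min_count=5)
        assert len(regions) == 1
        iv, n = regions[0]
        assert (iv.start, iv.end, n) == (500, 701, 5)

    def test_inclusive_gap_boundary(self):
        regions = merge_runs([0, 100, 200, 300, 400], gap_bp=100, min_count=5)
        assert len(regions) == 1
        assert regions[0][0].end == 401

    def test_gap_just_over(self):
        assert merge_runs([0, 101, 202, 303, 404], gap_bp=100, min_count=5) == []

    def test_min_count(self):
        assert merge_runs([0, 10, 20, 30], gap_bp=100, min_count=5) == []

    def test_idempotent_and_order_invariant(self, rng):
        pos = rng.integers(0, 5000, 60).tolist()
        a = merge_runs(pos, 50, 3)
        b = merge_runs(sorted(pos, reverse=True), 50, 3)
        assert a == b

    def test_chromosomes_independent(self):
        pos = [("chr1", 0), ("chr1", 50), ("chr2", 100), ("chr2", 150)]
        regions = merge_runs(pos, gap_bp=100, min_count=2)
        assert [(iv.chrom, iv.start, iv.end) for iv, _ in regions] == [
            ("chr1", 0, 51), ("chr2", 100, 151),
        ]

    def test_matches_oracle_random(self, rng):
        for _ in range(50):
            pos = [("chr1", int(p)) for p in rng.integers(0, 2000, 40)]
            gap = int(rng.integers(10, 200))
            mc = int(rng.integers(1, 6))
            got = [
                (iv.chrom, iv.start, iv.end, n) for iv, n in merge_runs(pos, gap, mc)
            ]
            assert got == merge_oracle(pos, gap, mc)


class TestSd:
    def test_constant_site(self):
        assert sd_per_cpg(np.full((1, 3), 0.5))[0] == 0.0

    def test_two_sample_formula(self):
        assert sd_per_cpg(np.array([[0.0, 1.0]]))[0] == pytest.approx(np.sqrt(0.5))

    def test_threshold_order_statistic(self):
        sds = np.array([0.01 * i for i in range(1, 101)])
        thr = top_fraction_threshold(sds, 0.01)
        assert thr == pytest.approx(1.00)
        assert int((sds >= thr).sum()) == 1

    def test_threshold_fraction_validation(self):
        with pytest.raises(ConfigError):
            top_fraction_threshold(np.array([0.1]), 0.0)


class TestAssociateRegions:
    def _metadata(self, n=10):
        return [
            SampleMetadata(f"s{i}", "akita" if i < n // 2 else "beagle",
                           "M" if i % 2 == 0 else "F", False, 3.0 + i, "healthy")
            for i in range(n)
        ]

    def test_monotone_age_rho_one(self):
        meta = self._metadata(8)
        ages = np.array([m.age_years for m in meta])
        beta = np.tile(0.05 * ages / ages.max(), (6, 1))
        regions = merge_runs(list(range(0, 60, 10)), gap_bp=100, min_count=5,
                             chrom="chr1")
        out = associate_regions(regions, ["chr1"] * 6, np.arange(0, 60, 10),
                                beta, meta)
        assert out[0].association["age_rho"] == pytest.approx(1.0)

    def test_constant_region_inert(self):
        meta = self._metadata(8)
        beta = np.full((6, 8), 0.5)
        regions = merge_runs(list(range(0, 60, 10)), gap_bp=100, min_count=5,
                             chrom="chr1")
        out = associate_regions(regions, ["chr1"] * 6, np.arange(0, 60, 10),
                                beta, meta)
        assoc = out[0].association
        assert assoc["age_p"] == 1.0
        assert assoc["sex_significant"] == 0.0

    def test_planted_sex_effect_detected(self, rng):
        meta = self._metadata(19)
        sex = np.array([1.0 if m.sex == "M" else 0.0 for m in meta])
        beta = np.clip(0.2 + 0.5 * sex + rng.normal(0, 0.02, (8, 19)), 0, 1)
        regions = merge_runs(list(range(0, 80, 10)), gap_bp=100, min_count=5,
                             chrom="chr1")
        out = associate_regions(regions, ["chr1"] * 8, np.arange(0, 80, 10),
                                beta, meta)
        assert out[0].association["sex_significant"] == 1.0


class TestLogistic:
    def test_no_variance_flagged(self):
        beta = np.full((1, 20), 0.5)
        y = [0, 1] * 10
        (stat,) = logistic_dmc(beta, y)
        assert stat.flag == "no_variance" and stat.p_value is None

    def test_perfect_separation_flagged(self):
        y = np.array([0] * 10 + [1] * 10)
        beta = np.where(y == 1, 0.9, 0.1)[None, :].astype(float)
        (stat,) = logistic_dmc(beta, y)
        assert stat.flag in ("separation", "no_convergence")
        assert stat.p_value is None

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            logistic_dmc(np.random.default_rng(0).random((1, 10)), [1] * 10)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 60
        y = rng.integers(0, 2, n).astype(float)
        y[:5], y[-5:] = 0, 1  # both classes guaranteed
        beta = rng.random((5, n))
        age = rng.uniform(3, 14, n)
        out = logistic_dmc(beta, y, covariates=age[:, None])
        for i, stat in enumerate(out):
            X = sm.add_constant(np.column_stack([beta[i], age]))
            fit = sm.Logit(y, X).fit(disp=0)
            assert stat.p_value == pytest.approx(fit.pvalues[1], abs=1e-6)

    def test_null_p_roughly_uniform(self, rng):
        n = 80
        y = np.array(([0, 1] * (n // 2)), dtype=float)
        beta = rng.random((2000, n))
        out = logistic_dmc(beta, y)
        p = np.array([s.p_value for s in out if s.p_value is not None])
        frac = (p < 0.05).mean()
        assert 0.03 < frac < 0.07
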