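import numpy as np
import pytest
from scipy import stats as sps

from methyloscope.errors import ConfigError, DataError, ValidationError
from methyloscope.io_formats import GeneModel, GenomicInterval, MethylationCountRecord
from methyloscope.methylome import (
    apply_quality_filters,
    beta_values,
    build_matrix,
    collapse_strands,
    conversion_rate,
    gene_metaprofile,
    mask_snps_and_chroms,
    pairwise_spearman,
)


def rec(pos, meth, total, strand=".", chrom="chr1"):
    return MethylationCountRecord(chrom=chrom, pos=pos, meth=meth, total=total,
                                  strand=strand)


class TestCollapse:
    def test_sums_both_strands(self):
        out = collapse_strands([rec(100, 5, 10, "+"), rec(101, 3, 10, "-")])
        assert out == [rec(100, 8, 20)]

    def test_single_strand_kept(self):
        assert collapse_strands([rec(100, 5, 10, "+")]) == [rec(100, 5, 10)]

    def test_duplicate_forward_record_errors(self):
        with pytest.raises(ValidationError, match="duplicate"):
            collapse_strands([rec(100, 5, 10, "+"), rec(100, 2, 4, "+")])

    def test_unstranded_rejected(self):
        with pytest.raises(ValidationError):
            collapse_strands([rec(100, 5, 10, ".")])


class TestBuildMatrix:
    def test_union_with_missing_cell(self):
        tables = {
            "s1": [rec(0, 1, 10), rec(5, 2, 10), rec(9, 3, 10), rec(20, 4, 10)],
            "s2": [rec(0, 1, 10), rec(5, 2, 10), rec(9, 3, 10)],
        }
        m = build_matrix(tables)
        assert m.n_sites == 4
        assert int((~m.present).sum()) == 1
        assert not m.present[3, 1]

    def test_single_sample_identity(self):
        table = [rec(0, 1, 10), rec(7, 5, 12)]
        m = build_matrix({"s1": table})
        assert m.sites() == [("chr1", 0), ("chr1", 7)]
        assert m.meth[:, 0].tolist() == [1, 5]

    def test_order_invariance(self):
        t1 = [rec(0, 1, 10), rec(7, 5, 12)]
        m1 = build_matrix({"s1": t1})
        m2 = build_matrix({"s1": list(reversed(t1))})
        assert m1.sites() == m2.sites()
        assert (m1.meth == m2.meth).all()

    def test_duplicate_sample_id(self):
        with pytest.raises(ValidationError):
            build_matrix({"s1": []}, sample_ids=["s1", "s1"])


def toy_matrix(depths_by_site, present=None):
    """One chrom, one site per row, samples = columns of depths."""
    n_sites = len(depths_by_site)
    n_samples = len(depths_by_site[0])
    total = np.array(depths_by_site)
    present_arr = (
        np.array(present) if present is not None else np.ones_like(total, bool)
    )
    from methyloscope.methylome import CpGSiteMatrix

    return CpGSiteMatrix(
        chroms=["chr1"] * n_sites,
        positions=np.arange(n_sites) * 10,
        sample_ids=[f"s{j}" for j in range(n_samples)],
        meth=np.minimum(total, 1),
        total=total,
        present=present_arr,
    )


class TestQualityFilters:
    def test_low_depth_removed(self):
        m = toy_matrix([[9, 50], [10, 50]])
        out, report = apply_quality_filters(m)
        assert out.n_sites == 1 and out.positions.tolist() == [10]
        assert report.n_low_depth_removed == 1

    def test_depth_bounds_inclusive(self):
        m = toy_matrix([[500, 500], [501, 500], [10, 10]])
        out, _ = apply_quality_filters(m)
        assert out.positions.tolist() == [0, 20]

    def test_missing_in_one_sample_removed(self):
        m = toy_matrix([[50, 50], [50, 50]], present=[[True, True], [True, False]])
        out, report = apply_quality_filters(m)
        assert out.n_sites == 1
        assert report.n_missing_removed == 1

    def test_no_missing_after_filter(self):
        m = toy_matrix([[50, 9], [50, 50]], present=[[True, True], [False, True]])
        out, _ = apply_quality_filters(m)
        assert out.present.all()

    def test_bad_bounds(self):
        with pytest.raises(ConfigError):
            apply_quality_filters(toy_matrix([[50]]), min_depth=20, max_depth=10)


class TestSnpMask:
    def test_snp_on_g_removes_site(self):
        m = toy_matrix([[50, 50]])
        out = mask_snps_and_chroms(m, [("chr1", 1)], drop_chroms=set())
        assert out.n_sites == 0  # site at pos 0, SNP at pos 1 (the G)

    def test_identity_with_no_snps(self):
        m = toy_matrix([[50, 50], [50, 50]])
        out = mask_snps_and_chroms(m, [], drop_chroms=set())
        assert out.n_sites == 2

    def test_drop_chrom(self):
        from methyloscope.methylome import CpGSiteMatrix

        m = CpGSiteMatrix(
            chroms=["chrX", "chrX"],
            positions=np.array([0, 10]),
            sample_ids=["s0"],
            meth=np.zeros((2, 1), int),
            total=np.full((2, 1), 50),
            present=np.ones((2, 1), bool),
        )
        assert mask_snps_and_chroms(m, [], drop_chroms={"chrX"}).n_sites == 0

    def test_commutes_with_depth_filter(self):
        m = toy_matrix([[9, 50], [50, 50], [50, 50]])
        snps = [("chr1", 20)]
        a, _ = apply_quality_filters(mask_snps_and_chroms(m, snps, set()))
        b = mask_snps_and_chroms(apply_quality_filters(m)[0], snps, set())
        assert a.sites() == b.sites()


class TestBeta:
    def test_formula(self):
        m = toy_matrix([[10]])
        m.meth[0, 0] = 7
        assert beta_values(m)[0, 0] == pytest.approx(0.7)

    def test_boundaries(self):
        m = toy_matrix([[10, 10]])
        m.meth[0] = [0, 10]
        b = beta_values(m)
        assert b[0, 0] == 0.0 and b[0, 1] == 1.0

    def test_missing_stays_nan(self):
        m = toy_matrix([[10, 10]], present=[[True, False]])
        assert np.isnan(beta_values(m)[0, 1])

    def test_present_zero_total_errors(self):
        m = toy_matrix([[0]])
        m.meth[0, 0] = 0
        with pytest.raises(DataError):
            beta_values(m)


class TestSpearman:
    def test_hand_value(self):
        # d = (-2, 1, 1): rho = 1 - 6*6/(3*8) = -0.5
        beta = np.array([[0.1, 0.3], [0.2, 0.1], [0.3, 0.2]])
        corr = pairwise_spearman(beta)
        assert corr[0, 1] == pytest.approx(-0.5)

    def test_unit_diagonal_and_symmetry(self, rng):
        beta = rng.random((50, 4))
        corr = pairwise_spearman(beta)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_monotone_transform_gives_one(self, rng):
        x = rng.random(30)
        beta = np.column_stack([x, np.exp(3 * x)])
        assert pairwise_spearman(beta)[0, 1] == pytest.approx(1.0)

    def test_matches_scipy_reference(self, rng):
        beta = rng.random((200, 6))
        corr = pairwise_spearman(beta)
        ref = sps.spearmanr(beta).statistic
        assert np.allclose(corr, ref, atol=1e-12)

    def test_zero_variance_flagged(self):
        beta = np.column_stack([np.full(10, 0.5), np.arange(10) / 10])
        with pytest.warns(UserWarning):
            corr = pairwise_spearman(beta)
        assert np.isnan(corr[0, 1])


class TestConversionRate:
    @pytest.mark.parametrize("conv,total,expected",
                             [(990, 1000, 0.99), (1000, 1000, 1.0), (0, 1000, 0.0)])
    def test_values(self, conv, total, expected):
        assert conversion_rate(conv, total) == pytest.approx(expected)

    def test_zero_total(self):
        with pytest.raises(ConfigError):
            conversion_rate(0, 0)


class TestMetaProfile:
    def _sites(self, positions, betas):
        return (["chr1"] * len(positions), np.array(positions),
                np.array(betas, dtype=float))

    def test_flat_profile(self):
        pos = np.arange(1000, 11000, 50)
        chroms, p, b = self._sites(pos, np.full(pos.size, 0.8))
        gene = GeneModel(GenomicInterval("chr1", 3000, 8000, "+"), "g1")
        prof = gene_metaprofile(chroms, p, b, [gene], body_bins=10, flank_bp=2000,
                                flank_bins=4)
        assert np.nanmax(np.abs(prof - 0.8)) < 1e-12

    def test_reversal_symmetry_uniform(self):
        pos = np.arange(1000, 11000, 50)
        chroms, p, b = self._sites(pos, np.full(pos.size, 0.8))
        plus = GeneModel(GenomicInterval("chr1", 3000, 8000, "+"), "g1")
        minus = GeneModel(GenomicInterval("chr1", 3000, 8000, "-"), "g1")
        prof_p = gene_metaprofile(chroms, p, b, [plus], 10, 2000, 4)
        prof_m = gene_metaprofile(chroms, p, b, [minus], 10, 2000, 4)
        assert np.allclose(prof_p, prof_m, equal_nan=True)

    def test_body_dip(self):
        pos = np.arange(1000, 11000, 50)
        betas = np.where((pos >= 3000) & (pos < 8000), 0.0, 0.8)
        chroms, p, b = self._sites(pos, betas)
        gene = GeneModel(GenomicInterval("chr1", 3000, 8000, "+"), "g1")
        prof = gene_metaprofile(chroms, p, b, [gene], 10, 2000, 4)
        assert np.allclose(prof[4:14], 0.0)
        assert np.allclose(prof[:4], 0.8) and np.allclose(prof[14:], 0.8)

    def test_short_gene_skipped(self):
        chroms, p, b = self._sites([5], [0.5])
        gene = GeneModel(GenomicInterval("chr1", 0, 5, "+"), "tiny")
        with pytest.warns(UserWarning, match="tiny"):
            prof = gene_metaprofile(chroms, p, b, [gene], body_bins=10)
        assert np.isnan(prof).all()
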