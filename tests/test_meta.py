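import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mamt import meta
from mamt.meta import (
    CHI2_1_MEDIAN,
    cochran_q,
    decorrelate_overlap,
    define_loci,
    genomic_control,
    ivw_meta,
    lambda_meta,
    meta_to_study,
    subtract_sumstats,
    variant_log10_pvalue,
    variant_pvalue,
)
from conftest import make_table


def test_chi2_median_constant_matches_quantile_function():
    assert CHI2_1_MEDIAN == pytest.approx(stats.chi2.ppf(0.5, 1), rel=1e-9)


class TestLambdaMeta:
    def test_duplicate_study_gives_zero(self):
        a = make_table([0.1, -0.2, 0.05], [0.02, 0.03, 0.01])
        assert lambda_meta(a, a).lambda_meta == 0.0

    def test_single_snp_closed_form(self):
        # T = (1-0)^2 / (0.5+0.5) = 1 -> lambda = 1/median(chi2_1)
        a = make_table([1.0], [np.sqrt(0.5)])
        b = make_table([0.0], [np.sqrt(0.5)])
        d = lambda_meta(a, b)
        assert d.n_shared == 1
        assert d.lambda_meta == pytest.approx(1 / 0.4549364231, rel=1e-6)

    def test_symmetric(self, rng):
        a = make_table(rng.normal(0, 0.02, 50), np.full(50, 0.02))
        b = make_table(rng.normal(0, 0.02, 50), np.full(50, 0.02))
        assert lambda_meta(a, b).lambda_meta == pytest.approx(lambda_meta(b, a).lambda_meta)

    def test_no_shared_variants_raises(self):
        a = make_table([0.1], [0.02], chrom="1")
        b = make_table([0.1], [0.02], chrom="2")
        with pytest.raises(ValueError, match="no shared"):
            lambda_meta(a, b)


class TestGenomicControl:
    def test_constant_half_is_exactly_one(self):
        assert genomic_control([0.5] * 11) == pytest.approx(1.0, rel=1e-9)

    def test_scaling_property(self, rng):
        chi2 = rng.chisquare(1, 200_00)
        p_inflated = stats.chi2.sf(1.2 * chi2, 1)
        lam = genomic_control(np.clip(p_inflated, 1e-300, 1))
        assert lam == pytest.approx(1.2, abs=0.03)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            genomic_control([])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            genomic_control([0.5, 0.0])


class TestIvw:
    def test_equal_weight_average(self):
        a = make_table([1.0], [1.0])
        b = make_table([3.0], [1.0])
        out = ivw_meta([a, b])
        assert out.loc[0, "BETA"] == pytest.approx(2.0)
        assert out.loc[0, "SE"] == pytest.approx(1 / np.sqrt(2))

    def test_single_study_identity(self):
        a = make_table([0.3, -0.1], [0.05, 0.02])
        out = ivw_meta([a])
        np.testing.assert_allclose(out["BETA"], a.df["BETA"])
        np.testing.assert_allclose(out["SE"], a.df["SE"])
        np.testing.assert_allclose(out["P"], a.df["P"], rtol=1e-10)

    def test_k_identical_studies_shrink_se_by_sqrt_k(self):
        k = 4
        tabs = [make_table([0.2], [0.05], study_id=f"s{i}") for i in range(k)]
        out = ivw_meta(tabs)
        assert out.loc[0, "BETA"] == pytest.approx(0.2)
        assert out.loc[0, "SE"] == pytest.approx(0.05 / np.sqrt(k))
        assert out.loc[0, "N_STUDIES"] == k

    def test_require_all_drops_partial_variants(self):
        a = make_table([0.1, 0.2], [0.02, 0.02])
        b = make_table([0.1], [0.02])
        assert len(ivw_meta([a, b], require_all=True)) == 1
        assert len(ivw_meta([a, b])) == 2

    def test_q_consistent_with_cochran(self):
        a = make_table([1.0], [1.0])
        b = make_table([3.0], [1.0])
        out = ivw_meta([a, b])
        q, df, p = cochran_q([1, 3], [1, 1])
        assert out.loc[0, "Q"] == pytest.approx(q)
        assert out.loc[0, "Q_P"] == pytest.approx(p)


class TestVariantPvalue:
    def test_null_effect(self):
        assert variant_pvalue(0.0, 1.0) == pytest.approx(1.0)

    def test_nonpositive_se_raises(self):
        with pytest.raises(ValueError):
            variant_pvalue(0.1, 0.0)

    def test_log_tail_stable_far_beyond_underflow(self):
        lp = variant_log10_pvalue(50.0, 1.0)
        assert np.isfinite(lp) and lp < -500

    def test_log_and_linear_agree_in_overlap(self):
        p = variant_pvalue(0.069, 0.0099)
        assert variant_log10_pvalue(0.069, 0.0099) == pytest.approx(np.log10(p), rel=1e-10)


class TestSubtract:
    def test_recovers_left_out_study(self, rng):
        a = make_table(rng.normal(0, 0.05, 20), rng.uniform(0.01, 0.05, 20), study_id="A")
        b = make_table(rng.normal(0, 0.05, 20), rng.uniform(0.01, 0.05, 20), study_id="B")
        pooled = meta_to_study(ivw_meta([a, b]))
        rec = subtract_sumstats(pooled, b)
        np.testing.assert_allclose(rec.df["BETA"], a.df["BETA"], rtol=1e-10)
        np.testing.assert_allclose(rec.df["SE"], a.df["SE"], rtol=1e-10)

    def test_weight_algebra_example(self):
        large = make_table([2.0], [1 / np.sqrt(2)])
        small = make_table([3.0], [1.0])
        out = subtract_sumstats(large, small)
        assert out.df.loc[0, "BETA"] == pytest.approx(1.0)
        assert out.df.loc[0, "SE"] == pytest.approx(1.0)

    def test_degenerate_nesting_raises(self):
        a = make_table([1.0], [0.5])
        with pytest.raises(ValueError, match="not nested"):
            subtract_sumstats(a, a)


class TestDecorrelate:
    def test_identity_correlation_unchanged(self):
        a = make_table([0.1, 0.2], [0.02, 0.02], study_id="A")
        b = make_table([0.3, -0.1], [0.05, 0.05], study_id="B")
        out = decorrelate_overlap([a, b], np.eye(2))
        pd.testing.assert_frame_equal(out[0].df, a.df)
        pd.testing.assert_frame_equal(out[1].df, b.df)

    def test_near_duplicate_second_study_shrinks_to_zero(self):
        eps = 1e-6
        z = np.array([2.0, -1.0, 0.5])
        a = make_table(z * 0.02, np.full(3, 0.02), study_id="A")
        b = make_table(z * 0.02, np.full(3, 0.02), study_id="B")
        out = decorrelate_overlap([a, b], np.array([[1, 1 - eps], [1 - eps, 1]]))
        z2 = (out[1].df["BETA"] / out[1].df["SE"]).to_numpy()
        assert np.all(np.abs(z2) < 0.01)

    def test_restores_lambda_meta_under_overlap(self, rng):
        n = 20_000
        C = np.array([[1.0, 0.5], [0.5, 1.0]])
        z = np.linalg.cholesky(C) @ rng.standard_normal((2, n))
        se = np.full(n, 0.01)
        a = make_table(z[0] * se, se, study_id="A")
        b = make_table(z[1] * se, se, study_id="B")
        raw = lambda_meta(a, b).lambda_meta
        ad, bd = decorrelate_overlap([a, b], C)
        fixed = lambda_meta(ad, bd).lambda_meta
        assert raw < 0.8
        assert abs(fixed - 1) < 0.05

    def test_non_pd_matrix_raises(self):
        a = make_table([0.1], [0.02])
        b = make_table([0.1], [0.02])
        with pytest.raises(ValueError):
            decorrelate_overlap([a, b], np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestCochranQ:
    def test_homogeneous(self):
        q, df, p = cochran_q([1, 1], [1, 1])
        assert q == 0 and p == 1

    def test_two_study_example(self):
        q, df, p = cochran_q([1, 3], [1, 1])
        assert q == pytest.approx(2.0)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(2, 1), rel=1e-9)

    def test_identical_effects_distinct_ses(self):
        q, _, p = cochran_q([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_single_study_raises(self):
        with pytest.raises(ValueError):
            cochran_q([1], [1])


def _hits(rows):
    return pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "P"])


class TestDefineLoci:
    def test_within_window_one_locus(self):
        loci = define_loci(_hits([("a", "1", 1_000_000, 1e-10), ("b", "1", 1_400_000, 1e-9)]))
        assert len(loci) == 1
        assert loci[0].sentinel_snp == "a"
        assert sorted(loci[0].members) == ["a", "b"]

    def test_outside_window_two_loci(self):
        loci = define_loci(_hits([("a", "1", 1_000_000, 1e-10), ("b", "1", 3_500_000, 1e-9)]))
        assert len(loci) == 2

    def test_cross_chromosome_never_merges(self):
        loci = define_loci(_hits([("a", "1", 1_000_000, 1e-10), ("b", "2", 1_000_000, 1e-9)]))
        assert len(loci) == 2

    def test_ld_mode_matches_brute_force_grouping(self):
        hits = _hits([("a", "1", 1000, 1e-10), ("b", "1", 2000, 1e-9), ("c", "1", 3000, 1e-8)])
        ld = pd.DataFrame(
            {"variant_a": ["a", "a"], "variant_b": ["b", "c"], "r2": [0.5, 0.0]}
        )
        loci = define_loci(hits, mode="ld", ld=ld)
        groups = sorted(sorted(l.members) for l in loci)
        assert groups == [["a", "b"], ["c"]]

    def test_ld_mode_without_table_raises(self):
        with pytest.raises(ValueError, match="requires"):
            define_loci(_hits([("a", "1", 1000, 1e-10)]), mode="ld")

    def test_partition_and_sentinel_minimality(self, rng):
        n = 60
        hits = _hits(
            [(f"v{i}", str(rng.integers(1, 4)), int(rng.integers(1, 10_000_000)), float(rng.uniform(1e-12, 5e-8)))
             for i in range(n)]
        )
        loci = define_loci(hits)
        members = [m for l in loci for m in l.members]
        assert sorted(members) == sorted(hits["SNP"])  # partition
        pmap = dict(zip(hits["SNP"], hits["P"]))
        for l in loci:
            assert l.pvalue <= min(pmap[m] for m in l.members) + 1e-18

    def test_novelty_classification(self):
        hits = _hits([("a", "1", 5_000_000, 1e-10), ("b", "2", 5_000_000, 1e-9)])
        loci = define_loci(hits, known_catalog=[("1", 5_500_000)])
        by = {l.sentinel_snp: l.novel for l in loci}
        assert by == {"a": False, "b": True}

    def test_tie_break_deterministic(self):
        hits = _hits([("b", "2", 100, 1e-9), ("a", "1", 100, 1e-9)])
        loci = define_loci(hits)
        assert loci[0].sentinel_snp == "a"  # (chrom, pos) order on p ties


def test_heterogeneity_flag_uses_bonferroni_over_loci():
    a = make_table([1.0, 0.1], [1.0, 0.1], pos=[1_000_000, 5_000_000])
    b = make_table([3.0, 0.1], [1.0, 0.1], pos=[1_000_000, 5_000_000])
    pooled = ivw_meta([a, b])
    loci = define_loci(pooled.rename(columns={})[["SNP", "CHR", "POS", "P"]])
    flagged = meta.flag_heterogeneous_loci(pooled, loci)
    assert set(flagged.columns) >= {"SENTINEL", "Q_P", "HETEROGENEOUS"}
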