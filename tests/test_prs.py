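import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mamt.prs import (
    PT_THRESHOLDS,
    Cohort,
    _hwe_pvalue,
    auc,
    auc_compare,
    clump_and_threshold,
    ehr_phenotype,
    fit_logistic,
    lab_binarize,
    liability_r2,
    prevalence_ratios,
    prs_score,
    qc_cohort,
    quintile_stratify,
    youden_point,
)
from mamt.simulate import sim_cohort


class TestQcCohort:
    def _cohort(self, rng, n=200, m=1500):
        freq = rng.uniform(0.1, 0.9, m)
        G = rng.binomial(2, freq, size=(n, m)).astype(float)
        dos = pd.DataFrame(G, index=[f"I{i:03d}" for i in range(n)],
                           columns=[f"rs{j}" for j in range(m)])
        return Cohort(dosages=dos)

    def test_exact_hwe_proportions_retained(self):
        geno = np.array([0] * 25 + [1] * 50 + [2] * 25, dtype=float)
        assert _hwe_pvalue(geno) == pytest.approx(1.0)

    def test_low_maf_variant_removed(self, rng):
        c = self._cohort(rng)
        c.dosages["rs_rare"] = rng.binomial(2, 0.01, len(c.dosages)).astype(float)
        out, report = qc_cohort(c)
        assert "rs_rare" not in out.dosages.columns
        assert report["variants_maf"] >= 1

    def test_duplicated_individual_removed(self, rng):
        c = self._cohort(rng)
        c.dosages.iloc[1] = c.dosages.iloc[0]
        out, report = qc_cohort(c)
        assert report["individuals_relatedness"] >= 1
        assert ("I000" in out.dosages.index) ^ ("I001" in out.dosages.index)

    def test_high_missingness_individual_removed(self, rng):
        c = self._cohort(rng)
        c.dosages.iloc[5, : len(c.dosages.columns) // 2] = np.nan
        out, report = qc_cohort(c)
        assert "I005" not in out.dosages.index
        assert report["individuals_missingness"] == 1

    def test_hwe_violating_variant_removed(self, rng):
        c = self._cohort(rng)
        # all-heterozygote column grossly violates HWE
        c.dosages["rs_het"] = 1.0
        out, report = qc_cohort(c)
        assert "rs_het" not in out.dosages.columns


class TestClumping:
    def test_no_ld_all_retained(self, rng):
        ss = pd.DataFrame({"SNP": ["a", "b"], "CHR": "1", "POS": [1000, 2000],
                           "P": [0.01, 0.5], "BETA": [0.1, 0.2]})
        out = clump_and_threshold(ss, None, thresholds=[1.0])
        assert len(out[1.0]) == 2

    def test_greedy_rule_smaller_p_survives(self):
        ss = pd.DataFrame({"SNP": ["a", "b"], "CHR": "1", "POS": [1000, 2000],
                           "P": [1e-6, 1e-4], "BETA": [0.1, 0.2]})
        ld = pd.DataFrame({"variant_a": ["a"], "variant_b": ["b"], "r2": [0.5]})
        out = clump_and_threshold(ss, ld, thresholds=[1.0])
        assert list(out[1.0]["SNP"]) == ["a"]

    def test_far_apart_pair_kept_despite_ld(self):
        ss = pd.DataFrame({"SNP": ["a", "b"], "CHR": "1", "POS": [1000, 500_000],
                           "P": [1e-6, 1e-4], "BETA": [0.1, 0.2]})
        ld = pd.DataFrame({"variant_a": ["a"], "variant_b": ["b"], "r2": [0.9]})
        out = clump_and_threshold(ss, ld, thresholds=[1.0])
        assert len(out[1.0]) == 2  # outside the 250 kb window

    def test_threshold_nesting(self, rng):
        m = 100
        ss = pd.DataFrame({"SNP": [f"v{i}" for i in range(m)], "CHR": "1",
                           "POS": rng.integers(1, 5_000_000, m),
                           "P": rng.uniform(1e-10, 1, m), "BETA": rng.normal(size=m)})
        out = clump_and_threshold(ss, None, thresholds=PT_THRESHOLDS)
        prev: set = set()
        for thr in sorted(out):
            cur = set(out[thr]["SNP"])
            assert prev <= cur
            prev = cur


class TestPrsScore:
    def test_zero_weights_zero_scores(self, rng):
        dos = pd.DataFrame(rng.integers(0, 3, (5, 3)).astype(float), columns=list("abc"))
        w = pd.DataFrame({"SNP": list("abc"), "BETA": [0.0, 0.0, 0.0]})
        assert (prs_score(dos, w) == 0).all()

    def test_simple_arithmetic(self):
        dos = pd.DataFrame({"a": [2.0]})
        w = pd.DataFrame({"SNP": ["a"], "BETA": [0.5]})
        assert prs_score(dos, w).iloc[0] == pytest.approx(1.0)

    def test_additivity_over_weight_sets(self, rng):
        dos = pd.DataFrame(rng.integers(0, 3, (10, 6)).astype(float),
                           columns=[f"v{i}" for i in range(6)])
        w1 = pd.DataFrame({"SNP": [f"v{i}" for i in range(3)], "BETA": rng.normal(size=3)})
        w2 = pd.DataFrame({"SNP": [f"v{i}" for i in range(3, 6)], "BETA": rng.normal(size=3)})
        combined = pd.concat([w1, w2], ignore_index=True)
        np.testing.assert_allclose(
            prs_score(dos, combined), prs_score(dos, w1) + prs_score(dos, w2), rtol=1e-12
        )

    def test_missing_dosage_imputed_with_eaf(self):
        dos = pd.DataFrame({"a": [np.nan]})
        w = pd.DataFrame({"SNP": ["a"], "BETA": [1.0], "EAF": [0.25]})
        assert prs_score(dos, w).iloc[0] == pytest.approx(0.5)

    def test_no_overlap_raises(self):
        dos = pd.DataFrame({"a": [1.0]})
        w = pd.DataFrame({"SNP": ["b"], "BETA": [1.0]})
        with pytest.raises(ValueError):
            prs_score(dos, w)


class TestEhrPhenotype:
    def _icd(self, sle, ssc=0, dm=0):
        return pd.DataFrame({"M32": [sle], "M34": [ssc], "M33": [dm]}, index=["I0"])

    def test_single_code_def1_not_def6(self):
        icd = self._icd(1)
        assert ehr_phenotype(icd, ["M32"], ["M34", "M33"], "Def1").iloc[0]
        assert not ehr_phenotype(icd, ["M32"], ["M34", "M33"], "Def6").iloc[0]

    def test_exclusion_code_blocks_def6(self):
        icd = self._icd(2, dm=1)
        assert not ehr_phenotype(icd, ["M32"], ["M34", "M33"], "Def6").iloc[0]

    def test_def12_requires_strict_ana(self):
        icd = self._icd(4)
        ana = pd.Series(["1:160"], index=["I0"])
        assert ehr_phenotype(icd, ["M32"], ["M34", "M33"], "Def12", ana_titer=ana).iloc[0]
        ana_low = pd.Series(["1:80"], index=["I0"])
        assert not ehr_phenotype(icd, ["M32"], ["M34", "M33"], "Def12", ana_titer=ana_low).iloc[0]

    def test_def12_missing_ana_is_control(self):
        icd = self._icd(4)
        ana = pd.Series([np.nan], index=["I0"])
        assert not ehr_phenotype(icd, ["M32"], ["M34", "M33"], "Def12", ana_titer=ana).iloc[0]


class TestLabBinarize:
    @pytest.mark.parametrize(
        "titer,expected",
        [("1:40", 0.0), ("1:80", 1.0), ("1:160", 1.0), ("1:320", 1.0), ("negative", 0.0)],
    )
    def test_ana_cutoff(self, titer, expected):
        ana, _ = lab_binarize(titer, None)
        assert ana == expected

    @pytest.mark.parametrize("val,expected", [(60, 1.0), (59.9, 0.0), ("positive", 1.0), ("negative", 0.0)])
    def test_dsdna_cutoff(self, val, expected):
        _, ds = lab_binarize("1:80", val)
        assert ds == expected

    def test_unparseable_missing(self):
        ana, ds = lab_binarize("weird", "???")
        assert np.isnan(ana) and np.isnan(ds)


class TestFitLogistic:
    def test_intercept_only_r2_zero(self, rng):
        y = rng.integers(0, 2, 200).astype(float)
        fit = fit_logistic(y, pd.DataFrame(index=range(200)))
        assert fit.nagelkerke_r2 == pytest.approx(0.0, abs=1e-8)

    def test_saturated_two_group_closed_form(self):
        # x=+1: 2 cases / 1 control; x=-1: 1 case / 2 controls -> slope log 2
        x = np.array([1, 1, 1, -1, -1, -1], float)
        y = np.array([1, 1, 0, 1, 0, 0], float)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.params["x"] == pytest.approx(np.log(2) / 1, abs=1e-6)
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-6)

    def test_consistency_at_moderate_n(self, rng):
        n = 5000
        x = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-(-1.0 + 0.8 * x)))
        y = (rng.random(n) < p).astype(float)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.params["x"] == pytest.approx(0.8, abs=0.15)

    def test_separation_raises(self):
        x = np.array([-2, -1, 1, 2.0])
        y = np.array([0, 0, 1, 1.0])
        with pytest.raises(ValueError):
            fit_logistic(y, pd.DataFrame({"x": x}))


class TestLiabilityR2:
    def test_zero_maps_to_zero(self):
        assert liability_r2(0.0, K=0.01, P=0.5) == 0.0

    def test_no_ascertainment_limit(self):
        K = 0.1
        t = stats.norm.isf(K)
        z = stats.norm.pdf(t)
        expected = 0.05 * K * (1 - K) / z**2
        assert liability_r2(0.05, K=K, P=K) == pytest.approx(expected, rel=1e-9)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            liability_r2(1.0, K=0.01, P=0.5)


class TestAuc:
    def test_perfect_separation(self):
        assert auc(np.array([3, 2, 1.0]), np.array([1, 1, 0])) == 1.0

    def test_pairwise_count_example(self):
        # cases {2,1}, controls {1.5}: one win, one loss -> 0.5
        assert auc(np.array([2, 1, 1.5]), np.array([1, 1, 0])) == 0.5

    def test_monotone_transform_invariance(self, rng):
        s = rng.standard_normal(200)
        y = rng.integers(0, 2, 200)
        y[0], y[1] = 0, 1
        assert auc(np.exp(s), y) == pytest.approx(auc(s, y), abs=1e-12)

    def test_identical_models_delong_p_one(self, rng):
        s = rng.standard_normal(100)
        y = (rng.random(100) < 0.4).astype(int)
        y[:2] = [0, 1]
        res = auc_compare(s, s, y, n_boot=10)
        assert res["delong_p"] == 1.0

    def test_delong_detects_better_model(self, rng):
        n = 600
        y = rng.integers(0, 2, n)
        good = y + rng.standard_normal(n) * 0.5
        noise = rng.standard_normal(n)
        res = auc_compare(good, noise, y, sided="one", n_boot=10)
        assert res["delong_p"] < 1e-6

    def test_bootstrap_ci_brackets_auc(self, rng):
        n = 400
        y = rng.integers(0, 2, n)
        s = y + rng.standard_normal(n)
        res = auc_compare(s, s, y, n_boot=200, seed=1)
        lo, hi = res["ci_a"]
        assert lo <= res["auc_a"] <= hi


class TestQuintiles:
    def test_or_arithmetic_example(self, rng):
        # top: 30 cases / 70 controls, bottom: 10 / 90 -> OR 3.857
        y = np.zeros(500, bool)
        prs = pd.Series(np.arange(500, dtype=float),
                        index=[f"I{i:04d}" for i in range(500)])
        y[:10] = True          # bottom quintile: first 100 ranks
        y[400:430] = True      # top quintile
        res = quintile_stratify(prs, y)
        tab = res["overall"]["table"]
        assert tab.loc[4, "odds_ratio"] == pytest.approx(30 * 90 / (70 * 10), rel=1e-9)
        assert tab.loc[0, "odds_ratio"] == 1.0

    def test_zero_cell_haldane_correction_flagged(self):
        y = np.zeros(100, bool)
        y[95:] = True  # all cases in the top quintile
        prs = pd.Series(np.arange(100, dtype=float), index=[f"I{i}" for i in range(100)])
        tab = quintile_stratify(prs, y)["overall"]["table"]
        assert tab.loc[4, "zero_cell_corrected"]
        assert np.isfinite(tab.loc[4, "odds_ratio"])

    def test_null_prs_or_near_one(self, rng):
        n = 10_000
        y = rng.random(n) < 0.2
        prs = pd.Series(rng.standard_normal(n), index=[f"I{i}" for i in range(n)])
        tab = quintile_stratify(prs, y)["overall"]["table"]
        assert np.all((tab["or_ci_low"] < 1.3) & (tab["or_ci_high"] > 0.8))

    def test_printed_prevalence_ratios(self):
        assert prevalence_ratios([0.0991, 0.12, 0.1509, 0.20, 0.2888]) == pytest.approx(
            (2.91, 1.91), abs=0.005
        )


class TestYouden:
    def test_perfect_separation(self):
        thr, sens, spec = youden_point(np.array([1, 2, 10, 11.0]), np.array([0, 0, 1, 1]))
        assert sens == 1.0 and spec == 1.0

    def test_identical_scores_j_zero(self):
        thr, sens, spec = youden_point(np.ones(6), np.array([0, 0, 0, 1, 1, 1]))
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_matches_exhaustive_scan(self, rng):
        s = rng.standard_normal(40)
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        thr, sens, spec = youden_point(s, y)
        best = max(
            (np.mean(s[y == 1] >= t) + np.mean(s[y == 0] < t) - 1) for t in np.unique(s)
        )
        assert sens + spec - 1 == pytest.approx(best, abs=1e-12)


class TestEndToEnd:
    def test_auc_increases_with_genetic_signal(self):
        aucs = []
        for r2 in (0.02, 0.3):
            cohort, truth = sim_cohort(n=3000, m_variants=100, liability_r2=r2, K=0.2, seed=21)
            score = prs_score(
                cohort.dosages,
                truth["weights"].rename("BETA").rename_axis("SNP").reset_index(),
            )
            aucs.append(auc(score.to_numpy(), cohort.phenotype.to_numpy()))
        assert aucs[1] > aucs[0] + 0.05

    def test_quintile_prevalence_monotone_with_signal(self):
        cohort, truth = sim_cohort(n=5000, m_variants=100, liability_r2=0.3, K=0.2, seed=22)
        score = prs_score(
            cohort.dosages, truth["weights"].rename("BETA").rename_axis("SNP").reset_index()
        )
        tab = quintile_stratify(score, cohort.phenotype)["overall"]["table"]
        prev = tab["prevalence"].to_numpy()
        assert np.all(np.diff(prev) > -0.02)
        assert prev[4] > prev[0]
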