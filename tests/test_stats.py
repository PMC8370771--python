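"""NB dispersion estimation, GLM LRT, BH, ANOVA, volcano export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import gammaln

import morphoflow as mf
from morphoflow.stats import (CountMatrix, anova_bh, bh_fdr,
                              estimate_common_dispersion, nb_test,
                              volcano_export)

BASE20 = np.array([0.02] * 5 + [0.05] * 10 + [0.08] * 5)
BASE20 = BASE20 / BASE20.sum()
ZERO20 = np.zeros(20)


def _cm(seed, dispersion=0.1, effect=None, n=(6, 6)):
    counts, conds = mf.simulate_count_matrix(
        20, n, BASE20, ZERO20 if effect is None else effect, dispersion, seed)
    return CountMatrix(counts, conds)


class TestDispersion:
    def test_poisson_counts_give_near_zero_dispersion(self):
        assert estimate_common_dispersion(_cm(3, dispersion=0.0)) <= 0.01

    def test_recovers_planted_dispersion(self):
        phis = [estimate_common_dispersion(_cm(100 + s, dispersion=0.3))
                for s in range(40)]
        assert 0.2 <= float(np.median(phis)) <= 0.4

    def test_two_identical_samples_guard(self):
        counts = pd.DataFrame({"s1": [5, 10, 3], "s2": [5, 10, 3]})
        cm = CountMatrix(counts, pd.Series({"s1": "A", "s2": "B"}))
        phi = estimate_common_dispersion(cm)
        assert np.isfinite(phi) and phi >= 0

    def test_all_zero_counts_rejected(self):
        counts = pd.DataFrame(np.zeros((3, 4), int),
                              columns=[f"s{i}" for i in range(4)])
        cm = CountMatrix(counts, pd.Series("A", index=counts.columns))
        with pytest.raises(ValueError, match="zero"):
            estimate_common_dispersion(cm)


def nb_loglik_oracle(y, mu, phi):
    if phi == 0:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / phi
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))))


class TestNbTest:
    def test_exact_twofold_counts_give_logfc_one(self):
        cm = CountMatrix(
            pd.DataFrame({"s1": [100, 10000], "s2": [102, 10000],
                          "s3": [200, 10000], "s4": [198, 10000]},
                         index=["c1", "c2"]),
            pd.Series({"s1": "A", "s2": "A", "s3": "B", "s4": "B"}))
        diff = nb_test(cm, phi=0.0)
        # cluster c1 doubles while the totals stay nearly constant
        assert diff.loc["c1", "logFC"] == pytest.approx(1.0, abs=0.05)

    def test_lrt_matches_grid_search_oracle(self):
        """Collapsed 2x2 toy: LRT statistic equals brute-force likelihood
        maximization over a dense mean grid."""
        y = np.array([30.0, 40.0, 80.0, 90.0])
        t = np.array([1000.0, 1100.0, 1000.0, 900.0])
        grp = np.array(["A", "A", "B", "B"])
        phi = 0.2
        cm = CountMatrix(
            pd.DataFrame([y.astype(int)], index=["c1"],
                         columns=["s1", "s2", "s3", "s4"]),
            pd.Series(grp, index=["s1", "s2", "s3", "s4"]))
        cm.counts.loc["c1"] = y.astype(int)
        # overwrite totals by adding a filler cluster
        filler = (t - y).astype(int)
        counts = pd.DataFrame([y.astype(int), filler],
                              index=["c1", "filler"],
                              columns=["s1", "s2", "s3", "s4"])
        cm = CountMatrix(counts, pd.Series(grp, index=counts.columns))
        diff = nb_test(cm, phi=phi)

        lam_grid = np.exp(np.linspace(np.log(1e-4), np.log(0.5), 20001))
        def best(sel):
            return max(nb_loglik_oracle(y[sel], lam * t[sel], phi)
                       for lam in lam_grid)
        ll_full = best(grp == "A") + best(grp == "B")
        ll_null = best(np.ones(4, bool))
        lrt_oracle = 2 * (ll_full - ll_null)
        lrt_ours = sps.chi2.isf(diff.loc["c1", "pvalue"], df=1)
        assert lrt_ours == pytest.approx(lrt_oracle, abs=1e-3)

    def test_null_type_one_error_calibrated(self):
        rej = total = 0
        for s in range(200):
            diff = nb_test(_cm(2000 + s))
            rej += int((diff["pvalue"] < 0.05).sum())
            total += len(diff)
        assert 0.03 <= rej / total <= 0.07

    def test_all_zero_cluster_flagged(self):
        counts, conds = mf.simulate_count_matrix(
            5, (3, 3), np.full(5, 0.2), np.zeros(5), 0.1, seed=1)
        counts.iloc[2] = 0
        diff = nb_test(CountMatrix(counts, conds))
        assert diff.iloc[2]["flagged"]
        assert diff.iloc[2]["pvalue"] == 1.0 and diff.iloc[2]["logFC"] == 0.0

    def test_condition_swap_negates_logfc(self):
        cm = _cm(77)
        d1 = nb_test(cm, phi=0.1)
        swapped = CountMatrix(cm.counts,
                              cm.conditions.map({"A": "B", "B": "A"}))
        d2 = nb_test(swapped, phi=0.1)
        assert np.allclose(d1["logFC"], -d2["logFC"], atol=1e-9)
        assert np.allclose(d1["pvalue"], d2["pvalue"], atol=1e-9)

    def test_doubling_counts_and_totals_preserves_logfc(self):
        cm = _cm(88)
        cm2 = CountMatrix(cm.counts * 2, cm.conditions)
        # Poisson limit: the offset makes logFC exactly scale-invariant
        d1 = nb_test(cm, phi=0.0)
        d2 = nb_test(cm2, phi=0.0)
        assert np.allclose(d1["logFC"], d2["logFC"], atol=1e-9)
        # with overdispersion the NB weights shift the MLE only marginally
        d1 = nb_test(cm, phi=0.05)
        d2 = nb_test(cm2, phi=0.05)
        assert np.allclose(d1["logFC"], d2["logFC"], atol=5e-3)


class TestBhFdr:
    def test_single_pvalue_unchanged(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_hand_computed_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_fdr(np.ones(7)), 1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        assert np.all(bh_fdr(p) >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestAnova:
    def test_identical_groups_give_p_near_one(self):
        # both groups contain the same values -> between-group MS = 0 exactly
        rel = pd.DataFrame([[0.1, 0.2, 0.3, 0.1, 0.2, 0.3]],
                           index=["c1"], columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=rel.columns)
        out = anova_bh(rel, groups)
        assert out.loc["c1", "F"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["c1", "pvalue"] == pytest.approx(1.0)

    def test_two_groups_equal_pooled_t_squared(self):
        rng = np.random.default_rng(2)
        rel = pd.DataFrame(rng.uniform(0, 1, (4, 10)),
                           columns=[f"s{i}" for i in range(10)])
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=rel.columns)
        out = anova_bh(rel, groups)
        for cl in rel.index:
            t, p = sps.ttest_ind(rel.loc[cl][:5], rel.loc[cl][5:], equal_var=True)
            assert out.loc[cl, "F"] == pytest.approx(t ** 2, rel=1e-9)
            assert out.loc[cl, "pvalue"] == pytest.approx(p, rel=1e-9)

    def test_power_matches_noncentral_f_oracle(self):
        """Empirical rejection rate under a mean shift tracks the noncentral-F
        closed form within Monte-Carlo error."""
        rng = np.random.default_rng(3)
        n, delta, sd, reps = 6, 1.0, 1.0, 800
        rejections = 0
        for _ in range(reps):
            a = rng.normal(0, sd, n)
            b = rng.normal(delta, sd, n)
            _, p = sps.f_oneway(a, b)
            rejections += p < 0.05
        lam = n * delta ** 2 / (2 * sd ** 2)  # noncentrality, 2 groups
        crit = sps.f.isf(0.05, 1, 2 * n - 2)
        power = sps.ncf.sf(crit, 1, 2 * n - 2, lam)
        assert rejections / reps == pytest.approx(power, abs=4 * np.sqrt(power * (1 - power) / reps))

    def test_zero_variance_everywhere_flagged(self):
        rel = pd.DataFrame([[0.1] * 4], index=["c1"],
                           columns=[f"s{i}" for i in range(4)])
        groups = pd.Series(["A", "A", "B", "B"], index=rel.columns)
        out = anova_bh(rel, groups)
        assert out.loc["c1", "flagged"]


class TestVolcano:
    def _toy_diff(self):
        return pd.DataFrame({
            "logFC": [1.0, -2.0, 0.1],
            "pvalue": [0.001, 0.2, 0.9],
            "fdr": [0.003, 0.3, 0.9],
        }, index=["c1", "c2", "c3"])

    def test_identity_on_toy_result(self):
        out = volcano_export(self._toy_diff())
        assert list(out["cluster"]) == ["c1", "c2", "c3"]
        assert np.allclose(out["neg_log10_fdr"],
                           -np.log10([0.003, 0.3, 0.9]))
        assert list(out["significant"]) == [True, False, False]

    def test_zero_fdr_capped(self):
        d = self._toy_diff()
        d.loc["c1", "fdr"] = 0.0
        out = volcano_export(d, max_neglog10=300.0)
        assert out.loc[0, "neg_log10_fdr"] == 300.0

    def test_csv_round_trip(self, tmp_path):
        out = volcano_export(self._toy_diff())
        p = tmp_path / "v.csv"
        out.to_csv(p, index=False)
        back = pd.read_csv(p)
        pd.testing.assert_frame_equal(out, back)
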