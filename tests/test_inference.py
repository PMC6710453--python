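"""t-tests, JZS Bayes factors, FDR, evidence classification, sensitivity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from physioarousal import inference
from physioarousal.inference import (
    classify_evidence,
    evidence_summary,
    fdr_adjust,
    jzs_bf_one_sample,
    jzs_bf_two_sample,
    one_sample_test,
    sensitivity_mdes,
    t_test_power,
    two_sample_from_stats,
    two_sample_test,
)


def _brute_force_b10(t, n_eff, df, r=1.0):
    """Independent oracle: dense log-spaced Riemann sum over the g hyperprior."""
    g = np.logspace(-8, 8, 400001)
    log_f = (-0.5 * np.log1p(n_eff * g)
             - (df + 1) / 2 * np.log1p(t * t / ((1 + n_eff * g) * df))
             + np.log(r) - 0.5 * np.log(2 * np.pi)
             - 1.5 * np.log(g) - r * r / (2 * g))
    num = np.trapezoid(np.exp(log_f), g)
    return num / (1 + t * t / df) ** (-(df + 1) / 2)


class TestFrequentistTests:
    def test_all_zero_scores(self):
        res = one_sample_test(np.zeros(20))
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_t_is_mean_over_se(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.5, 1.0, 50)
        res = one_sample_test(x)
        assert res["t"] == pytest.approx(res["estimate"] / res["se"])
        ref = stats.ttest_1samp(x, 0.0)
        assert res["t"] == pytest.approx(ref.statistic)
        assert res["p"] == pytest.approx(ref.pvalue)

    def test_reported_ratio_arithmetic(self):
        # a mean difference of 3.57 with SE 0.28 corresponds to t = 12.75
        assert 3.57 / 0.28 == pytest.approx(12.75)

    def test_identical_groups_t_zero(self):
        x = np.concatenate([np.arange(10.0), np.arange(10.0)])
        labels = np.array(["MS"] * 10 + ["DPS"] * 10)
        assert two_sample_test(x, labels)["t"] == 0.0

    def test_matches_scipy_pooled_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 30), rng.normal(0.4, 1.2, 35)
        res = two_sample_test(np.concatenate([a, b]),
                              np.array(["MS"] * 30 + ["DPS"] * 35))
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res["t"] == pytest.approx(ref.statistic)
        assert res["df"] == 63

    def test_label_permutation_centers_t_on_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 40)
        labels = np.array(["MS"] * 20 + ["DPS"] * 20)
        ts = []
        for _ in range(300):
            ts.append(two_sample_test(x, rng.permutation(labels))["t"])
        ts = np.asarray(ts)
        assert abs(np.mean(ts)) < 0.15
        assert np.mean(np.abs(ts) > stats.t.ppf(0.975, 38)) < 0.12

    def test_missing_values_reduce_n(self):
        x = np.array([1.0, np.nan, 2.0, 3.0, np.nan])
        assert one_sample_test(x)["n"] == 3

    def test_type_one_error_calibrated(self):
        """Uncorrected one-sample test rejects ~5% under the null at n=108."""
        rng = np.random.default_rng(7)
        reps, n = 1000, 108
        x = rng.standard_normal((reps, n))
        t = x.mean(1) / (x.std(1, ddof=1) / np.sqrt(n))
        rate = np.mean(2 * stats.t.sf(np.abs(t), n - 1) < 0.05)
        ci = 3 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < ci + 1e-9


class TestJzsBayesFactor:
    @pytest.mark.parametrize("t", [0.0, 0.5, 2.0, 5.0, 15.0])
    @pytest.mark.parametrize("n", [10, 108, 500])
    def test_quadrature_matches_brute_force_one_sample(self, t, n):
        quad = jzs_bf_one_sample(t, n)
        brute = _brute_force_b10(t, n, n - 1)
        assert quad == pytest.approx(brute, rel=1e-4)

    @pytest.mark.parametrize("t, n1, n2", [(0.3, 53, 55), (2.5, 20, 30), (8.0, 100, 100)])
    def test_quadrature_matches_brute_force_two_sample(self, t, n1, n2):
        quad = jzs_bf_two_sample(t, n1, n2)
        brute = _brute_force_b10(t, n1 * n2 / (n1 + n2), n1 + n2 - 2)
        assert quad == pytest.approx(brute, rel=1e-4)

    def test_sign_symmetry(self):
        assert jzs_bf_one_sample(2.3, 50) == pytest.approx(jzs_bf_one_sample(-2.3, 50))

    def test_monotone_in_magnitude(self):
        bs = [jzs_bf_one_sample(t, 108) for t in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(b2 > b1 for b1, b2 in zip(bs, bs[1:]))

    def test_small_t_floor_at_study_group_sizes(self):
        """Near-zero between-group t values bottom out around 0.15."""
        floor = jzs_bf_two_sample(0.0, 53, 55)
        assert floor == pytest.approx(0.15, abs=0.01)
        assert jzs_bf_two_sample(0.5, 53, 55) < 1 / 3

    def test_agrees_with_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        for t, n in ((0.8, 108), (3.9, 108), (12.75, 108)):
            ours = jzs_bf_one_sample(t, n)
            theirs = float(pingouin.bayesfactor_ttest(t, n, r=1.0))
            assert ours == pytest.approx(theirs, rel=1e-6)
        ours = jzs_bf_two_sample(1.4, 53, 55)
        theirs = float(pingouin.bayesfactor_ttest(1.4, 53, 55, paired=False, r=1.0))
        assert ours == pytest.approx(theirs, rel=1e-6)

    def test_scale_widens_null_support(self):
        assert jzs_bf_one_sample(0.5, 108, scale=1.0) < jzs_bf_one_sample(
            0.5, 108, scale=0.5)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            jzs_bf_one_sample(1.0, 1)
        with pytest.raises(ValueError):
            jzs_bf_two_sample(1.0, 1, 50)
        with pytest.raises(ValueError):
            jzs_bf_one_sample(1.0, 50, scale=0.0)


class TestFdrAdjust:
    def test_equal_p_values_unchanged(self):
        q = fdr_adjust([0.03, 0.03, 0.03])
        assert np.allclose(q, 0.03)

    def test_step_up_hand_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=60)
        assert np.all(fdr_adjust(p) >= p - 1e-12)

    def test_storey_no_larger_than_bh(self):
        rng = np.random.default_rng(5)
        p = np.concatenate([rng.uniform(0, 0.01, 10), rng.uniform(size=90)])
        assert np.all(fdr_adjust(p, method="storey") <= fdr_adjust(p) + 1e-12)

    def test_nan_p_values_propagate(self):
        q = fdr_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0])


class TestEvidence:
    @pytest.mark.parametrize("bf, label", [
        (5.0, "alternative"), (1.0, "inconclusive"), (0.2, "null"),
        (3.0, "inconclusive"), (1 / 3, "inconclusive")])
    def test_classification_boundaries(self, bf, label):
        assert classify_evidence(bf) == label

    def test_all_unit_bayes_factors(self):
        res = pd.DataFrame({"bf": np.ones(20)})
        summary = evidence_summary(res)
        assert summary["pct_alternative"] == 0.0
        assert summary["pct_null"] == 0.0

    def test_disagreement_count(self):
        res = pd.DataFrame({
            "bf": [5.0, 0.1, 5.0, 0.1],
            "p": [0.01, 0.8, 0.8, 0.01],
            "q": [0.01, 0.9, 0.9, 0.04],
        })
        assert evidence_summary(res)["n_disagreements"] == 2


class TestSensitivity:
    def test_zero_effect_power_is_alpha(self):
        assert t_test_power(0.0, n=108) == pytest.approx(0.05, abs=1e-6)
        assert t_test_power(0.0, n1=53, n2=55, design="between") == pytest.approx(
            0.05, abs=1e-6)

    def test_mdes_decreases_with_n(self):
        es = [sensitivity_mdes("within", n=n) for n in (20, 50, 108, 300)]
        assert all(b < a for a, b in zip(es, es[1:]))

    def test_mdes_power_round_trip(self):
        es = sensitivity_mdes("between", n1=53, n2=55)
        assert t_test_power(es, n1=53, n2=55, design="between") == pytest.approx(
            0.80, abs=1e-3)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_mdes("within", alpha=0.5, power=0.4, n=50)
        with pytest.raises(ValueError):
            sensitivity_mdes("diagonal", n=50)


class TestAnalyzeStudy:
    def test_complete_data_analysis_structure(self):
        from physioarousal import protocol, synth

        table = synth.synth_segment_study(15, 15, miss_rate=0.0, seed=31)
        scores = protocol.change_scores(table)
        res = inference.analyze_study(scores, table.condition)
        assert len(res) == 148
        assert set(res["family"]) == {"within", "between"}
        assert res["bf"].gt(0).all()
        assert res["q"].ge(res["p"] - 1e-12).all()
        assert (res.loc[res["bf"] > 3, "evidence"] == "alternative").all()
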