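"""Survival models: log-rank, Bonferroni, redundancy, Cox, bootstrap RL."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank

from fetrad.prognostic import (
    bonferroni_threshold,
    cox_score_test,
    fit_cox_signature,
    fit_rl_model,
    km_logrank,
    logrank_test,
    recurrence_location_label,
    redundancy_groups,
    run_full_pipeline,
)
from fetrad.synthetic import CohortSpec, gen_cohort

from oracles import hand_logrank


class TestLogrank:
    def test_identical_groups_null_identity(self):
        t = np.array([5, 8, 12, 20, 5, 8, 12, 20], float)
        e = np.ones(8, bool)
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1], bool)
        chi2, p = logrank_test(t, e, g)
        assert chi2 == 0.0 and p == 1.0

    def test_eight_subject_fixture_matches_hand_tabulation(self):
        t = np.array([3, 5, 7, 11, 2, 4, 6, 8], float)
        e = np.ones(8, bool)
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1], bool)
        chi2, _ = logrank_test(t, e, g)
        assert chi2 == pytest.approx(hand_logrank(t, e, g), abs=1e-12)

    def test_matches_lifelines_with_censoring_and_ties(self, rng):
        for _ in range(10):
            n = 30
            t = rng.integers(1, 15, n).astype(float)  # heavy ties
            e = rng.uniform(size=n) < 0.7
            g = rng.uniform(size=n) < 0.5
            if e.sum() == 0 or g.all() or not g.any():
                continue
            chi2, p = logrank_test(t, e, g)
            ref = ll_logrank(t[g], t[~g], e[g], e[~g])
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_median_split_ties_to_low_group(self):
        vals = np.array([1, 1, 1, 2, 3, 4], float)
        t = np.arange(1, 7, dtype=float)
        e = np.ones(6, bool)
        res = km_logrank(vals, t, e, "f")
        # median is 1.5 -> low group {1,1,1}, high {2,3,4}
        assert res.n_low == 3 and res.n_high == 3
        vals2 = np.array([1, 1, 1, 1, 3, 4], float)
        res2 = km_logrank(vals2, t, e, "f")
        # median 1: the four tied values fall in the low group
        assert res2.n_low == 4 and res2.n_high == 2

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            km_logrank(np.ones(8), np.arange(1, 9, dtype=float), np.ones(8, bool))

    def test_type_one_error_calibrated(self, rng):
        n_rep, hits = 600, 0
        for _ in range(n_rep):
            t = rng.exponential(100, 32)
            e = rng.uniform(size=32) < 0.85
            g = np.zeros(32, bool)
            g[rng.permutation(32)[:16]] = True
            if not e.any():
                continue
            _, p = logrank_test(t, e, g)
            hits += p < 0.05
        rate = hits / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,k,expected", [
        (0.05, 50, 0.001),
        (0.05, 1, 0.05),
        (0.05, 38, 0.05 / 38),  # prints as the 0.0013 family threshold
    ])
    def test_threshold_values(self, alpha, k, expected):
        assert bonferroni_threshold(alpha, k) == pytest.approx(expected)

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestRedundancyGroups:
    def _km(self, name, p):
        from fetrad.prognostic import KMResult

        return KMResult(name, 5, 5, 0.0, p, 0.0)

    def test_uncorrelated_candidates_all_retained(self, rng):
        f = pd.DataFrame(rng.normal(size=(60, 3)), columns=["A", "B", "C"])
        km = {n: self._km(n, p) for n, p in [("A", 0.01), ("B", 0.02), ("C", 0.03)]}
        assert redundancy_groups(f, km) == ["A", "B", "C"]

    def test_perfectly_correlated_pair_keeps_smaller_p(self, rng):
        a = rng.normal(size=60)
        f = pd.DataFrame({"A": a, "B": 2 * a, "C": rng.normal(size=60)})
        km = {n: self._km(n, p) for n, p in [("A", 0.04), ("B", 0.01), ("C", 0.02)]}
        assert redundancy_groups(f, km) == ["B", "C"]

    def test_transitive_chain_collapses_to_one_representative(self, rng):
        a = rng.normal(size=200)
        b = a + rng.normal(0, 0.15, 200)   # strongly tied to both A and C
        c = b + rng.normal(0, 0.15, 200)
        f = pd.DataFrame({"A": a, "B": b, "C": c})
        from scipy.stats import spearmanr

        # precondition for the chain fixture: A-B and B-C strong, A-C weaker
        assert abs(spearmanr(a, b).statistic) > 0.8
        assert abs(spearmanr(b, c).statistic) > 0.8
        km = {n: self._km(n, p) for n, p in [("A", 0.03), ("B", 0.02), ("C", 0.01)]}
        reps = redundancy_groups(f, km)
        assert reps == ["C"]

    def test_empty_candidates(self, rng):
        assert redundancy_groups(pd.DataFrame(), {}) == []


class TestCoxSignature:
    def test_binary_covariate_recovers_simulated_hazard_ratio(self, rng):
        n = 400
        g = np.repeat([0.0, 1.0], n // 2)
        lam = 0.01 * np.exp(np.log(2.0) * g)  # true HR = 2
        t = rng.exponential(1.0 / lam)
        f = pd.DataFrame({"g": g})
        sig = fit_cox_signature(f, t, np.ones(n, bool))
        se = 2.0 / np.sqrt(n)  # approximate SE of log HR with all events
        assert abs(sig.coefficients["g"] - np.log(2.0)) < 2 * se + 0.05
        assert sig.ci_lower["g"] < sig.hazard_ratios["g"] < sig.ci_upper["g"]

    def test_risk_score_refit_is_self_consistent(self, rng):
        df = gen_cohort(CohortSpec(
            n_subjects=300, cox_coefficients_ttp={"SZLGE": 0.7, "Busyness": -0.4},
            seed=8,
        ))
        sig = fit_cox_signature(df[["SZLGE", "Busyness"]], df["ttp_days"], df["ttp_event"])
        score = sig.risk_score(df)
        refit = fit_cox_signature(
            pd.DataFrame({"score": score}), df["ttp_days"], df["ttp_event"]
        )
        assert refit.coefficients["score"] == pytest.approx(1.0, abs=0.2)

    def test_overall_tests_agree_on_strong_signal(self, rng):
        df = gen_cohort(CohortSpec(
            n_subjects=200, cox_coefficients_ttp={"SZLGE": 1.0}, seed=9,
        ))
        sig = fit_cox_signature(df[["SZLGE"]], df["ttp_days"], df["ttp_event"])
        assert sig.p_likelihood_ratio < 1e-4
        assert sig.p_wald < 1e-4
        assert sig.p_score < 1e-4

    def test_null_likelihood_ratio_p_roughly_uniform(self, rng):
        ps = []
        for s in range(60):
            df = gen_cohort(CohortSpec(
                n_subjects=60, cox_coefficients_ttp={}, seed=500 + s,
            ))
            sig = fit_cox_signature(df[["SZLGE"]], df["ttp_days"], df["ttp_event"])
            ps.append(sig.p_likelihood_ratio)
        ps = np.asarray(ps)
        # uniform[0,1]: mean 0.5 +- 3/sqrt(12 n)
        assert abs(ps.mean() - 0.5) < 3.0 / np.sqrt(12 * len(ps))

    def test_score_test_matches_logrank_for_binary_covariate(self, rng):
        t = rng.exponential(50, 40)
        e = rng.uniform(size=40) < 0.8
        g = (rng.uniform(size=40) < 0.5)
        _, p_lr = logrank_test(t, e, g)
        p_score = cox_score_test(g.astype(float)[:, None], t, e)
        assert p_score == pytest.approx(p_lr, rel=1e-9)

    def test_events_per_covariate_warning(self, rng):
        df = gen_cohort(CohortSpec(n_subjects=12, seed=10))
        with pytest.warns(UserWarning, match="comfort margin"):
            fit_cox_signature(
                df[["SZLGE", "Busyness", "QVariance_CM"]],
                df["ttp_days"], df["ttp_event"],
            )


class TestRLModel:
    def test_perfect_separation_gives_auc_one(self, rng):
        x = np.concatenate([rng.uniform(0, 1, 16), rng.uniform(2, 3, 16)])
        y = np.repeat([0, 1], 16)
        rl = fit_rl_model(pd.DataFrame({"x": x}), y, n_boot=50, seed=0)
        assert rl.auc == pytest.approx(1.0, abs=1e-9)
        assert rl.coefficients["x"] > 0

    def test_null_predictor_auc_near_half(self, rng):
        aucs = []
        for s in range(8):
            x = rng.normal(size=32)
            y = (rng.uniform(size=32) < 0.5).astype(int)
            if np.unique(y).size < 2:
                continue
            rl = fit_rl_model(pd.DataFrame({"x": x}), y, n_boot=200, seed=s)
            aucs.append(rl.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.06

    def test_imbalance_adjustment_matches_plain_on_balanced_classes(self, rng):
        x = np.concatenate([rng.normal(0, 1, 40), rng.normal(1.2, 1, 40)])
        y = np.repeat([0, 1], 40)
        rl = fit_rl_model(pd.DataFrame({"x": x}), y, n_boot=300, seed=1)
        # balanced classes: adjusted bootstrap estimate stays near apparent AUC
        assert abs(rl.auc - rl.auc_apparent) < 0.08
        assert 0.0 <= rl.sensitivity <= 1.0

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            fit_rl_model(np.arange(12.0), np.zeros(12), n_boot=10)

    def test_nan_labels_dropped(self, rng):
        x = rng.normal(size=40)
        y = (x > 0).astype(float)
        y[:5] = np.nan
        rl = fit_rl_model(pd.DataFrame({"x": x}), y, n_boot=50, seed=2)
        assert rl.auc > 0.9

    def test_determinism_under_seed(self, rng):
        x = rng.normal(size=32)
        y = (x + rng.normal(0, 1, 32) > 0).astype(int)
        a = fit_rl_model(pd.DataFrame({"x": x}), y, n_boot=100, seed=5)
        b = fit_rl_model(pd.DataFrame({"x": x}), y, n_boot=100, seed=5)
        assert a == b


class TestRecurrenceLocationLabel:
    def test_majority_overlap_rule(self):
        v_pet = np.zeros((6, 6, 6), bool)
        v_pet[:3] = True
        rec = np.zeros((6, 6, 6), bool)
        rec[2:4, 0, 0] = True  # 1 of 2 voxels inside: not > 50%
        assert recurrence_location_label(rec, v_pet) == 0
        rec[2, 1, 0] = True    # 2 of 3 inside
        assert recurrence_location_label(rec, v_pet) == 1


class TestFullPipeline:
    def test_driving_feature_selected_and_significant(self):
        df = gen_cohort(CohortSpec(
            n_subjects=200, cox_coefficients_ttp={"SZLGE": 1.0}, seed=42,
        ))
        cols = [c for c in df.columns if c not in (
            "subject_id", "ttp_days", "ttp_event", "os_days", "os_event", "rl_label")]
        res = run_full_pipeline(df[cols], df, n_boot=100, seed=0)
        assert "SZLGE" in res.significant_features
        assert res.signature_ttp is not None
        assert "SZLGE" in res.signature_ttp.features
        assert res.best_feature_ttp == "SZLGE"
        assert res.rl_signature is not None

    def test_rerun_is_deterministic(self):
        df = gen_cohort(CohortSpec(n_subjects=64, seed=3))
        cols = [c for c in df.columns if c not in (
            "subject_id", "ttp_days", "ttp_event", "os_days", "os_event", "rl_label")]
        a = run_full_pipeline(df[cols], df, n_boot=60, seed=4)
        b = run_full_pipeline(df[cols], df, n_boot=60, seed=4)
        pd.testing.assert_frame_equal(a.km_table, b.km_table)
        assert a.signature_ttp == b.signature_ttp
        assert a.rl_signature == b.rl_signature

    def test_robust_restriction_limits_family(self):
        df = gen_cohort(CohortSpec(n_subjects=64, seed=5))
        cols = [c for c in df.columns if c not in (
            "subject_id", "ttp_days", "ttp_event", "os_days", "os_event", "rl_label")]
        res = run_full_pipeline(df[cols], df, robust_features=["SZLGE", "SUV_min"],
                                n_boot=40, seed=6)
        assert set(res.km_table.index) == {"SZLGE", "SUV_min"}
        assert res.bonferroni_k == 2
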