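"""Exclusions, phenotype classification, and the statistical battery."""

import numpy as np
import pandas as pd
import pytest

from cogeffort import CohortConfig
from cogeffort.cohort import Cohort
from cogeffort.exceptions import FitError, InsufficientDataError
from cogeffort.stats import (
    anova_mixed_2x2,
    apply_exclusions,
    classify_all,
    classify_effort_group,
    correlation_matrix,
    fit_group_logistic,
    fit_multilevel,
    fit_proportion_linear,
    lagged_performance_regression,
    mixed_anova_2x2_core,
    pairwise_t_tests,
    summarize_by_group,
    welch_t_test,
)


def make_cohort(participants, choice_trials):
    empty = pd.DataFrame({"participant_id": []})
    return Cohort(
        participants=participants,
        detection_trials=empty,
        choice_trials=choice_trials,
        mid_ratings=empty,
        config=CohortConfig(),
    )


def choice_rows(pid, n_hr, n_lr, accuracy=1.0, latency=1.0):
    rows = []
    for i in range(n_hr + n_lr):
        rows.append(
            {
                "participant_id": pid,
                "trial_index": i + 1,
                "choice": "HR" if i < n_hr else "LR",
                "choice_latency": latency,
                "performed_correct": (i % 10) < accuracy * 10,
                "performed_set_size": 6 if i < n_hr else 2,
            }
        )
    return rows


class TestExclusions:
    def _participants(self, n, **overrides):
        df = pd.DataFrame(
            {
                "participant_id": np.arange(1, n + 1),
                "completed_survey": True,
                "completed_mid": True,
                "repeated_task": False,
            }
        )
        for col, vals in overrides.items():
            df[col] = vals
        return df

    def test_rules_reasons_and_conservation(self):
        parts = self._participants(
            5,
            completed_survey=[False, True, True, True, True],
            repeated_task=[False, True, False, False, False],
        )
        trials = (
            choice_rows(1, 15, 15)
            + choice_rows(2, 15, 15)
            + choice_rows(3, 15, 15, latency=31.0)  # > 30 s: excluded
            + choice_rows(4, 15, 15, accuracy=0.5)  # exactly chance: excluded
            + choice_rows(5, 15, 15)
        )
        cohort = make_cohort(parts, pd.DataFrame(trials))
        kept, log = apply_exclusions(cohort)
        assert len(kept.participants) + len(log) == 5
        reasons = dict(zip(log["participant_id"], log["reason"]))
        assert reasons == {
            1: "incomplete_survey",
            2: "repeated_task",
            3: "slow_choice_gt30s",
            4: "chance_choice_accuracy",
        }
        assert list(kept.participants["participant_id"]) == [5]

    def test_boundary_latency_exactly_30s_kept(self):
        parts = self._participants(1)
        cohort = make_cohort(parts, pd.DataFrame(choice_rows(1, 15, 15, latency=30.0)))
        kept, log = apply_exclusions(cohort)
        assert len(log) == 0 and len(kept.participants) == 1

    def test_first_failure_recorded_once(self):
        # a participant failing several rules gets exactly one reason: the first
        parts = self._participants(1, completed_survey=[False], repeated_task=[True])
        cohort = make_cohort(parts, pd.DataFrame(choice_rows(1, 15, 15, accuracy=0.3)))
        _, log = apply_exclusions(cohort)
        assert log["reason"].tolist() == ["incomplete_survey"]


class TestClassification:
    @pytest.mark.parametrize(
        "n_hr,expected",
        [(21, "low_effort"), (22, "high_effort"), (30, "high_effort"), (0, "low_effort")],
    )
    def test_threshold(self, n_hr, expected):
        df = pd.DataFrame(choice_rows(1, n_hr, 30 - n_hr))
        asg = classify_effort_group(df)
        assert asg.group == expected
        assert asg.proportion_hr == pytest.approx(n_hr / 30)

    def test_permutation_invariance(self, rng):
        df = pd.DataFrame(choice_rows(1, 22, 8))
        base = classify_effort_group(df)
        for _ in range(20):
            shuffled = df.sample(frac=1.0, random_state=rng.integers(1 << 31))
            assert classify_effort_group(shuffled) == base

    def test_zero_trials_rejected(self):
        with pytest.raises(InsufficientDataError):
            classify_effort_group(pd.DataFrame({"participant_id": [], "choice": []}))


class TestSummaries:
    def test_perfect_accuracy_cells(self):
        trials = pd.DataFrame(choice_rows(1, 25, 5) + choice_rows(2, 5, 25))
        asg = classify_all(trials)
        table = summarize_by_group(trials, asg)
        assert np.allclose(table["mean_accuracy"], 1.0)
        assert np.allclose(table["sd_accuracy"].dropna(), 0.0)

    def test_single_participant_cells_have_nan_sd(self):
        trials = pd.DataFrame(choice_rows(1, 25, 5))
        table = summarize_by_group(trials, classify_all(trials))
        assert table["sd_accuracy"].isna().all()


class TestWelch:
    def test_identical_groups(self):
        r = welch_t_test(np.arange(10.0), np.arange(10.0), family_size=4)
        assert r.t == 0 and r.cohens_d == 0 and r.p_adjusted == 1.0

    def test_bonferroni_arithmetic(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.2, 1, 40)
        r = welch_t_test(x, y, family_size=4)
        assert r.p_adjusted == pytest.approx(min(1.0, 4 * r.p_raw))

    def test_sex_difference_power_at_study_sizes(self):
        # a planted d = 0.45 shift at the study's group sizes is detected
        # after Bonferroni correction in nearly every replicate
        rng = np.random.default_rng(99)
        hits = 0
        reps = 60
        for _ in range(reps):
            f = rng.normal(0.27, 0.17, 332)
            m = rng.normal(0.27 - 0.45 * 0.17, 0.17, 92)
            hits += welch_t_test(f, m, family_size=4).p_adjusted < 0.05
        assert hits / reps >= 0.90


class TestCorrelations:
    def test_self_correlation_and_independence(self, rng):
        n = 10_000
        df = pd.DataFrame(
            {
                "bdi_prop": rng.normal(size=n),
                "pss": rng.normal(size=n),
                "anticipation": rng.normal(size=n),
                "k": rng.normal(size=n),
            }
        )
        tab = correlation_matrix(df)
        assert tab.query("var1 == var2")["r"].eq(1.0).all()
        off = tab.query("var1 != var2")["r"]
        assert (off.abs() < 0.05).all()

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({"bdi_prop": [1, 1, 1], "pss": [1, 2, 3],
                           "anticipation": [2, 3, 4], "k": [1, 2, 3]})
        tab = correlation_matrix(df)
        assert tab.query("var1 == 'bdi_prop' and var2 == 'pss'")["r"].isna().all()


def _participant_table(rng, n=300, k_effect=0.0):
    k = rng.normal(3, 1, n)
    logits = -0.4 + k_effect * (k - 3) + rng.normal(0, 0.5, n)
    prop = 1 / (1 + np.exp(-logits))
    prop_hr = rng.binomial(30, prop) / 30
    return pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "sex": rng.choice(["female", "male"], size=n),
            "k": k,
            "bdi_prop": rng.normal(0.27, 0.17, n),
            "pss": rng.normal(20, 6, n),
            "anticipation": rng.normal(4, 1.8, n),
            "proportion_hr": prop_hr,
            "group": np.where(prop_hr > 0.7, "high_effort", "low_effort"),
        }
    )


class TestRegressions:
    def test_logistic_odds_ratio_identity_and_effect(self, rng):
        tab = _participant_table(rng, n=400, k_effect=0.8)
        res = fit_group_logistic(tab)
        for t in res.terms:
            assert res.odds_ratios[t] == pytest.approx(np.exp(res.coef[t]))
        assert res.coef["k"] > 0 and res.pvalues["k"] < 0.05

    def test_logistic_null_effect_nominal_coverage(self, rng):
        # with zero capacity coupling the 95% CI for e^beta_k should cover 1
        # at roughly the nominal rate
        covered = 0
        reps = 30
        for _ in range(reps):
            tab = _participant_table(rng, n=400, k_effect=0.0)
            res = fit_group_logistic(tab)
            lo = np.exp(res.coef["k"] - 1.96 * res.se["k"])
            hi = np.exp(res.coef["k"] + 1.96 * res.se["k"])
            covered += lo < 1.0 < hi
        assert covered / reps >= 0.85

    def test_linear_constant_outcome(self, rng):
        tab = _participant_table(rng, n=100)
        tab["proportion_hr"] = 0.5
        res = fit_proportion_linear(tab)
        for t in res.terms:
            if t != "const":
                assert res.coef[t] == pytest.approx(0.0, abs=1e-10)
        assert res.fit_stats["r2"] == pytest.approx(0.0, abs=1e-10)

    def test_linear_planted_slope_recovered(self, rng):
        tab = _participant_table(rng, n=429)
        tab["proportion_hr"] = 0.5 + 0.02 * tab["k"] + rng.normal(0, 0.05, len(tab))
        res = fit_proportion_linear(tab)
        assert res.coef["k"] == pytest.approx(0.02, abs=2 * res.se["k"])

    def test_collinear_design_rejected(self, rng):
        tab = _participant_table(rng, n=100)
        tab["bdi_prop"] = 2 * tab["pss"]
        with pytest.raises(FitError, match="collinear"):
            fit_proportion_linear(tab)

    def test_sex_difference_t_tests_run_per_measure(self, rng):
        tab = _participant_table(rng, n=200)
        tab["dars"] = rng.normal(36, 10, 200)
        res = pairwise_t_tests(tab)
        assert set(res) == {"bdi_prop", "pss", "dars", "anticipation"}
        assert all(r.family_size == 4 for r in res.values())


def naive_mixed_anova(y1, y2, group1_mask):
    """Loop-based Type III sums-of-squares oracle for the 2x2 design."""
    y1 = list(map(float, y1))
    y2 = list(map(float, y2))
    g = list(map(bool, group1_mask))
    N = len(y1)
    idx1 = [i for i in range(N) if g[i]]
    idx2 = [i for i in range(N) if not g[i]]
    n1, n2 = len(idx1), len(idx2)
    m = [(a + b) / 2 for a, b in zip(y1, y2)]
    d = [a - b for a, b in zip(y1, y2)]
    mean = lambda xs: sum(xs) / len(xs)
    m1, m2 = mean([m[i] for i in idx1]), mean([m[i] for i in idx2])
    d1, d2 = mean([d[i] for i in idx1]), mean([d[i] for i in idx2])
    ss_group = 2 * n1 * n2 / N * (m1 - m2) ** 2
    ss_subj = 2 * (
        sum((m[i] - m1) ** 2 for i in idx1) + sum((m[i] - m2) ** 2 for i in idx2)
    )
    ssw_d = sum((d[i] - d1) ** 2 for i in idx1) + sum((d[i] - d2) ** 2 for i in idx2)
    beta = (n1 * d1 - n2 * d2) / N
    sse0 = sum(x * x for x in d) - N * beta * beta
    ss_trial = (sse0 - ssw_d) / 2
    ss_inter = (n1 * n2 / N) * (d1 - d2) ** 2 / 2
    ss_err = ssw_d / 2
    dfe = N - 2
    return {
        "F_group": ss_group / (ss_subj / dfe),
        "F_trial_type": ss_trial / (ss_err / dfe),
        "F_interaction": ss_inter / (ss_err / dfe),
    }


class TestMixedAnova:
    def _long(self, rng, n1=30, n2=20, tt_effect=0.0, g_effect=0.0, int_effect=0.0):
        rows = []
        for i in range(n1 + n2):
            grp = "high" if i < n1 else "low"
            base = rng.normal(g_effect if grp == "high" else 0.0, 0.3)
            for lvl, sign in (("HR", -0.5), ("LR", 0.5)):
                val = base + sign * tt_effect + rng.normal(0, 0.2)
                if grp == "high":
                    val += sign * int_effect
                rows.append({"participant_id": i, "group": grp, "choice": lvl, "y": val})
        return pd.DataFrame(rows)

    def test_gg_correction_is_identity_for_two_levels(self, rng):
        res = anova_mixed_2x2(self._long(rng, tt_effect=0.5), "y")
        assert res.gg_epsilon == 1.0
        for e in res.effects:
            assert e["p_gg"] == e["p"]

    def test_agrees_with_naive_oracle(self, rng):
        for _ in range(5):
            df = self._long(rng, tt_effect=0.3, g_effect=0.2, int_effect=0.1)
            res = anova_mixed_2x2(df, "y")
            wide = df.pivot_table(index=["participant_id", "group"], columns="choice", values="y")
            gmask = wide.index.get_level_values("group") == "high"
            oracle = naive_mixed_anova(wide["HR"], wide["LR"], gmask)
            assert res.effect("group")["F"] == pytest.approx(oracle["F_group"], abs=1e-8)
            assert res.effect("trial_type")["F"] == pytest.approx(oracle["F_trial_type"], abs=1e-8)
            assert res.effect("interaction")["F"] == pytest.approx(oracle["F_interaction"], abs=1e-8)

    def test_agrees_with_pingouin_on_balanced_data(self, rng):
        import pingouin as pg

        df = self._long(rng, n1=25, n2=25, tt_effect=0.4, g_effect=0.3)
        res = anova_mixed_2x2(df, "y")
        ref = pg.mixed_anova(
            data=df, dv="y", within="choice", between="group", subject="participant_id"
        ).set_index("Source")
        assert res.effect("group")["F"] == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert res.effect("trial_type")["F"] == pytest.approx(ref.loc["choice", "F"], rel=1e-9)
        assert res.effect("interaction")["F"] == pytest.approx(ref.loc["Interaction", "F"], rel=1e-9)

    def test_planted_trial_type_effect_only(self, rng):
        df = self._long(rng, n1=60, n2=40, tt_effect=0.6)
        res = anova_mixed_2x2(df, "y")
        assert res.effect("trial_type")["p"] < 1e-6
        assert res.effect("group")["p"] > 0.01
        assert res.effect("interaction")["p"] > 0.01

    def test_ges_in_unit_interval(self, rng):
        res = anova_mixed_2x2(self._long(rng, tt_effect=0.5, g_effect=0.4), "y")
        for e in res.effects:
            assert 0.0 <= e["ges"] <= 1.0

    def test_vectorised_core_matches_scalar(self, rng):
        y1 = rng.normal(size=(7, 40))
        y2 = rng.normal(size=(7, 40))
        g = np.arange(40) < 22
        batch = mixed_anova_2x2_core(y1, y2, g)
        for r in range(7):
            single = mixed_anova_2x2_core(y1[r], y2[r], g)
            for key in ("F_group", "F_trial_type", "F_interaction"):
                assert batch[key][r] == pytest.approx(single[key], rel=1e-12)


class TestMultilevel:
    def _long(self, rng, n=60, obs=30, re_sd=0.2, effort_effect=1.0):
        rows = []
        for i in range(n):
            icpt = rng.normal(0, re_sd)
            k = rng.normal(3, 1)
            sex = "male" if rng.random() < 0.3 else "female"
            for t in range(obs):
                lr = rng.random() < 0.4
                y = 1.0 + icpt + effort_effect * lr + rng.normal(0, 0.5)
                rows.append(
                    {
                        "participant_id": i, "sex": sex, "k": k,
                        "bdi_prop": rng.normal(0.27, 0.17), "pss": rng.normal(20, 6),
                        "anticipation": rng.normal(4, 1.8),
                        "choice": "LR" if lr else "HR", "y": y,
                    }
                )
        return pd.DataFrame(rows)

    def test_planted_effort_effect_recovered(self, rng):
        df = self._long(rng, effort_effect=1.0)
        res = fit_multilevel(df, outcome="y")
        assert res.coef["effort_level"] == pytest.approx(
            1.0, abs=2.5 * res.se["effort_level"]
        )
        assert res.pvalues["effort_level"] < 1e-6
        assert 0 <= res.fit_stats["r2_marginal"] <= res.fit_stats["r2_conditional"] <= 1

    def test_random_intercept_sd_recovered(self, rng):
        df = self._long(rng, n=200, obs=30, re_sd=0.2)
        res = fit_multilevel(df, outcome="y")
        assert res.fit_stats["sd_intercept"] == pytest.approx(0.2, rel=0.2)

    def test_zero_between_variance_matches_ols(self, rng):
        import statsmodels.api as sm

        df = self._long(rng, n=40, obs=20, re_sd=0.0)
        res = fit_multilevel(df, outcome="y")
        df2 = df.copy()
        df2["effort_level"] = (df2["choice"] == "LR").astype(float)
        df2["sex_male"] = (df2["sex"] == "male").astype(float)
        X = sm.add_constant(
            df2[["sex_male", "k", "bdi_prop", "pss", "anticipation", "effort_level"]]
        )
        ols = sm.OLS(df2["y"], X).fit()
        assert res.coef["effort_level"] == pytest.approx(
            ols.params["effort_level"], abs=0.01
        )


class TestLaggedRegression:
    def _trials(self, rng, n=80, markov=0.0):
        rows = []
        for i in range(n):
            prev = True
            for t in range(30):
                p = 0.7 + markov * (0.1 if prev else -0.1) / 0.1 * 0.05
                cur = rng.random() < (0.7 + (0.1 if prev else -0.1) * markov)
                rows.append(
                    {
                        "participant_id": i, "trial_index": t + 1,
                        "choice": "HR" if rng.random() < 0.6 else "LR",
                        "performed_correct": cur, "choice_latency": 1.0,
                    }
                )
                prev = cur
        return pd.DataFrame(rows)

    def test_iid_lag_coefficient_covers_zero(self, rng):
        df = self._trials(rng, markov=0.0)
        res = lagged_performance_regression(df, classify_all(df))
        assert abs(res.coef["prev_correct"]) < 2.5 * res.se["prev_correct"]

    def test_planted_markov_dependence_detected(self, rng):
        df = self._trials(rng, n=150, markov=1.0)
        res = lagged_performance_regression(df, classify_all(df))
        assert res.coef["prev_correct"] > 0
        assert res.pvalues["prev_correct"] < 0.001

    def test_single_trial_participants_excluded_and_logged(self, rng):
        df = self._trials(rng, n=10)
        solo = pd.DataFrame(
            [{"participant_id": 999, "trial_index": 1, "choice": "HR",
              "performed_correct": True, "choice_latency": 1.0}]
        )
        both = pd.concat([df, solo], ignore_index=True)
        res = lagged_performance_regression(both, classify_all(both))
        assert any("1 single-trial" in n for n in res.notes)
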