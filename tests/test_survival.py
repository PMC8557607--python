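"""Survival engine tests against hand-computed and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from stromascore.survival import (
    bootstrap_c_compare,
    cohort_baseline_tests,
    cox_fit,
    cox_linear_predictor,
    harrell_c,
    km_estimate,
    logrank_test,
    pearson_correlation,
)
from stromascore.synthetic import SyntheticCohortSpec, generate_cohort


def harrell_oracle(time, event, risk):
    """Exhaustive double-loop pair enumeration (independent of the
    vectorized implementation)."""
    usable = concordant = tied = 0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (time[i] < time[j] and event[i] == 1) or (
                time[i] == time[j] and event[i] == 1 and event[j] == 0
            ):
                usable += 1
                if risk[i] > risk[j]:
                    concordant += 1
                elif risk[i] == risk[j]:
                    tied += 1
    return (concordant + 0.5 * tied) / usable


def km_oracle(time, event):
    """Hand product-limit computation returning a dict t -> S(t)."""
    s = 1.0
    out = {}
    for t in sorted(set(time)):
        at_risk = sum(1 for x in time if x >= t)
        deaths = sum(1 for x, e in zip(time, event) if x == t and e == 1)
        s *= 1 - deaths / at_risk
        out[t] = s
    return out


class TestKaplanMeier:
    def test_hand_product_limit_example(self):
        df = pd.DataFrame(
            {"time_months": [10, 15, 20, 25], "event": [1, 0, 1, 0], "g": "a"}
        )
        curve = km_estimate(df, "g")["a"]
        assert curve.rate_at(20) == pytest.approx((3 / 4) * (1 / 2))
        assert curve.rate_at(12) == pytest.approx(3 / 4)

    def test_matches_oracle_on_random_small_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 11))
            time = rng.integers(1, 8, size=n).astype(float)
            event = rng.integers(0, 2, size=n)
            if event.sum() == 0:
                event[0] = 1
            df = pd.DataFrame({"time_months": time, "event": event, "g": "x"})
            curve = km_estimate(df, "g")["x"]
            for t, s in km_oracle(time, event).items():
                assert curve.rate_at(t) == pytest.approx(s), (time, event)

    def test_all_censored_curve_stays_at_one(self):
        df = pd.DataFrame({"time_months": [5, 10, 15], "event": [0, 0, 0], "g": "a"})
        curve = km_estimate(df, "g")["a"]
        assert curve.rate_at(100) == 1.0

    def test_rate_carries_forward_beyond_last_event(self):
        df = pd.DataFrame({"time_months": [10, 40], "event": [1, 1], "g": "a"})
        curve = km_estimate(df, "g")["a"]
        assert curve.rate_at(60) == curve.rate_at(40)


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        base = pd.DataFrame({"time_months": [5, 8, 12, 20], "event": [1, 0, 1, 1]})
        df = pd.concat(
            [base.assign(g="a"), base.assign(g="b")], ignore_index=True
        )
        stat, dof, p = logrank_test(df, "g")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_three_groups_give_two_degrees_of_freedom(self):
        df = generate_cohort(SyntheticCohortSpec(n_patients=60, rng_seed=1))
        df["g"] = np.repeat(["a", "b", "c"], 20)
        _, dof, _ = logrank_test(df, "g")
        assert dof == 2

    def test_single_group_rejected(self):
        df = pd.DataFrame({"time_months": [1, 2], "event": [1, 1], "g": "a"})
        with pytest.raises(ValueError):
            logrank_test(df, "g")

    def test_no_events_rejected(self):
        df = pd.DataFrame(
            {"time_months": [1, 2, 3, 4], "event": 0, "g": ["a", "a", "b", "b"]}
        )
        with pytest.raises(ValueError):
            logrank_test(df, "g")


class TestCox:
    def _toy(self):
        return pd.DataFrame(
            {
                "time_months": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 1, 0, 1, 1, 0],
                "x1": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
                "x2": [0.3, -0.2, 0.1, 0.5, -0.4, 0.0],
            }
        )

    def test_matches_brute_force_partial_likelihood(self):
        df = self._toy()
        X = df[["x1", "x2"]].to_numpy()
        time = df["time_months"].to_numpy()
        event = df["event"].to_numpy()

        def neg_log_pl(beta):
            lp = X @ beta
            ll = 0.0
            for i in np.where(event == 1)[0]:
                risk_set = time >= time[i]
                ll += lp[i] - np.log(np.sum(np.exp(lp[risk_set])))
            return -ll

        oracle = minimize(
            neg_log_pl, [0.0, 0.0], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12},
        ).x
        fit = cox_fit(df, ["x1", "x2"])
        assert fit.terms["x1"].log_hr == pytest.approx(oracle[0], abs=1e-6)
        assert fit.terms["x2"].log_hr == pytest.approx(oracle[1], abs=1e-6)

    def test_efron_equals_breslow_without_ties(self):
        df = self._toy()
        fe = cox_fit(df, ["x1", "x2"], ties="efron")
        fb = cox_fit(df, ["x1", "x2"], ties="breslow")
        assert fe.terms["x1"].log_hr == pytest.approx(fb.terms["x1"].log_hr, abs=1e-8)

    def test_hazard_ratio_consistency(self):
        fit = cox_fit(self._toy(), ["x1"])
        t = fit.terms["x1"]
        assert t.hr == pytest.approx(np.exp(t.log_hr))
        assert t.ci_low < t.hr < t.ci_high

    def test_constant_covariate_rejected(self):
        df = self._toy().assign(c=1.0)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["c"])

    def test_all_censored_rejected(self):
        df = self._toy().assign(event=0)
        with pytest.raises(ValueError, match="event"):
            cox_fit(df, ["x1"])

    def test_categorical_covariates_are_dummy_coded(self):
        df = generate_cohort(
            SyntheticCohortSpec(
                n_patients=300, censor_rate=0.2, rng_seed=5,
                covariate_effects={"stage": 0.8},
            )
        )
        fit = cox_fit(df, ["stage", "age"])
        assert "stage=III" in fit.terms
        assert fit.terms["stage=III"].hr > 1.0

    def test_stratified_fit_runs(self):
        df = generate_cohort(SyntheticCohortSpec(n_patients=200, rng_seed=6))
        fit = cox_fit(df, ["score"], strata="sex")
        assert fit.strata == "sex"


class TestHarrellC:
    def test_perfect_reverse_ordering_gives_one(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        assert harrell_c(t, np.ones(5), np.array([1.0, 2.0, 3.0, 4.0, 5.0])) == 1.0

    def test_constant_risk_gives_half(self):
        t = np.array([1.0, 2.0, 3.0])
        assert harrell_c(t, np.ones(3), np.zeros(3)) == 0.5

    def test_mixed_censoring_fixture_matches_enumeration(self):
        time = np.array([3.0, 5.0, 5.0, 8.0, 10.0])
        event = np.array([1, 1, 0, 0, 1])
        risk = np.array([2.0, 1.5, 1.5, 0.5, 0.1])
        assert harrell_c(time, event, risk) == pytest.approx(
            harrell_oracle(time, event, risk)
        )

    def test_random_fixtures_match_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(3, 15))
            time = rng.integers(1, 10, n).astype(float)
            event = rng.integers(0, 2, n)
            risk = rng.choice([0.0, 0.5, 1.0, 2.0], n)
            if not ((event == 1).any()):
                event[0] = 1
            assert harrell_c(time, event, risk) == pytest.approx(
                harrell_oracle(time, event, risk)
            )

    def test_agrees_with_lifelines_on_tie_free_data(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(12)
        time = rng.exponential(10, 50) + rng.random(50) * 1e-6
        event = rng.integers(0, 2, 50)
        event[0] = 1
        risk = rng.normal(size=50)
        ours = harrell_c(time, event, risk)
        theirs = concordance_index(time, -risk, event)
        assert ours == pytest.approx(theirs)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        time = rng.exponential(10, 40)
        event = rng.integers(0, 2, 40)
        event[:5] = 1
        risk = rng.normal(size=40)
        assert harrell_c(time, event, risk) == pytest.approx(
            harrell_c(time, event, np.exp(3 * risk))
        )

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            harrell_c(np.array([1.0, 2.0]), np.array([0, 0]), np.array([1.0, 2.0]))


class TestBootstrapComparison:
    def _cohort(self, n=120, seed=2):
        df = generate_cohort(
            SyntheticCohortSpec(
                n_patients=n, true_log_hr_per_score_sd=np.log(0.5),
                censor_rate=0.2, rng_seed=seed,
            )
        )
        df["stage_iii"] = (df["stage"] == "III").astype(float)
        return df

    def test_identical_specs_show_no_difference(self):
        df = self._cohort()
        comp = bootstrap_c_compare(
            df, {"a": ["score"], "b": ["score"]}, B=100, seed=3
        )
        key = ("a", "b")
        assert comp.p_adjusted[key] == pytest.approx(1.0)
        assert comp.means["a"] == pytest.approx(comp.means["b"])

    def test_too_small_bootstrap_rejected(self):
        with pytest.raises(ValueError, match="≥ 100"):
            bootstrap_c_compare(self._cohort(), {"a": ["score"], "b": ["age"]}, B=1)

    def test_single_spec_rejected(self):
        with pytest.raises(ValueError, match="2 model specs"):
            bootstrap_c_compare(self._cohort(), {"a": ["score"]}, B=100)

    def test_seeded_runs_are_bit_reproducible(self):
        df = self._cohort()
        specs = {"stage": ["stage_iii"], "both": ["stage_iii", "score"]}
        a = bootstrap_c_compare(df, specs, B=100, seed=9)
        b = bootstrap_c_compare(df, specs, B=100, seed=9)
        assert np.array_equal(a.samples["both"], b.samples["both"])
        assert a.p_values == b.p_values


class TestAssociations:
    def test_pearson_identity_and_sign(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_chi_square_matches_textbook_formula(self):
        """2×2 table (10,20 / 30,40) against the closed-form statistic."""
        table = np.array([[10.0, 20.0], [30.0, 40.0]])
        n = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / n
        oracle = ((table - expected) ** 2 / expected).sum()

        g1 = pd.DataFrame({"v": ["x"] * 10 + ["y"] * 20})
        g2 = pd.DataFrame({"v": ["x"] * 30 + ["y"] * 40})
        report = cohort_baseline_tests({"a": g1, "b": g2}, variables=["v"])
        assert report.loc[0, "statistic"] == pytest.approx(oracle)

    def test_identical_groups_are_not_flagged(self):
        g = generate_cohort(SyntheticCohortSpec(n_patients=80, rng_seed=4))
        report = cohort_baseline_tests({"a": g, "b": g.copy()}, variables=["age", "sex"])
        assert (report["p"] > 0.9).all()

    def test_kruskal_used_for_numeric_chi2_for_categorical(self):
        g1 = generate_cohort(SyntheticCohortSpec(n_patients=60, rng_seed=7))
        g2 = generate_cohort(SyntheticCohortSpec(n_patients=60, rng_seed=8))
        report = cohort_baseline_tests({"a": g1, "b": g2}, variables=["age", "sex"])
        tests = dict(zip(report["variable"], report["test"]))
        assert tests == {"age": "kruskal-wallis", "sex": "chi-square"}

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            cohort_baseline_tests({"a": pd.DataFrame({"v": [1]})})
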