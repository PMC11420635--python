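"""KM, log-rank, maximally selected cutpoints, Cox fits, elimination, GVIF."""

import warnings

import numpy as np
import pandas as pd
import pytest

from dceauc import (
    CohortSpec,
    Covariate,
    CovariateSpec,
    SurvivalCutpoint,
    backward_eliminate,
    bonferroni_adjust,
    cox_fit,
    generate_survival_cohort,
    gvif,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
)
from dceauc.survival import standardized_logrank


class TestKaplanMeier:
    def test_all_censored_survival_stays_at_one(self):
        km = km_estimate([5, 10, 20, 40], [False] * 4)
        assert np.allclose(km.survival, 1.0)
        assert km.survival_at(60.0) == 1.0

    def test_four_events_step_by_quarters(self):
        km = km_estimate([1, 2, 3, 4], [True] * 4)
        for t, s in [(1, 0.75), (2, 0.5), (3, 0.25), (4, 0.0)]:
            assert km.survival_at(t) == pytest.approx(s)

    def test_matches_product_limit_enumeration(self, rng):
        n = 20
        time = rng.exponential(20, n).round(1) + 0.1
        event = rng.random(n) < 0.7
        km = km_estimate(time, event)
        # brute-force product over risk sets at each distinct event time
        for t_query in np.sort(time[event]):
            s = 1.0
            for t in np.sort(np.unique(time[event])):
                if t > t_query:
                    break
                n_risk = np.sum(time >= t)
                d = np.sum(event & (time == t))
                s *= 1 - d / n_risk
            assert km.survival_at(t_query) == pytest.approx(s)

    def test_survival_is_monotone_from_one(self, rng):
        time = rng.exponential(30, 50) + 0.1
        event = rng.random(50) < 0.6
        km = km_estimate(time, event)
        assert km.survival[0] <= 1.0 and km.survival_at(0) == 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_risk_table_counts_subjects_under_observation(self):
        km = km_estimate([5, 13, 25, 40, 59], [True, False, True, False, True])
        expected = {0: 5, 12: 4, 24: 3, 36: 2, 48: 1, 60: 0}
        got = dict(zip(km.risk_table["time_months"], km.risk_table["n_at_risk"]))
        assert got == expected

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [True, True])


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        time = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        event = [True] * 10
        group = [0] * 5 + [1] * 5
        chi2, p = logrank_test(time, event, group)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_fully_separated_groups_highly_significant(self):
        time = list(range(1, 16)) + list(range(100, 115))
        event = [True] * 30
        group = [0] * 15 + [1] * 15
        _, p = logrank_test(time, event, group)
        assert p < 0.001

    def test_invariant_under_monotone_time_transform(self, rng):
        time = rng.exponential(20, 40) + 0.5
        event = rng.random(40) < 0.7
        group = rng.random(40) < 0.5
        chi2_a, _ = logrank_test(time, event, group)
        chi2_b, _ = logrank_test(np.exp(time / 30.0), event, group)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [True, True], [0, 0])

    def test_handrolled_z_matches_lifelines_chi2(self, rng):
        time = rng.exponential(20, 60).round(1) + 0.1
        event = rng.random(60) < 0.7
        group = rng.random(60) < 0.4
        z = standardized_logrank(time, event, group)
        chi2, _ = logrank_test(time, event, group)
        assert z * z == pytest.approx(chi2, rel=1e-9)


class TestCutpoint:
    def test_perfect_separation_cuts_between_ranges(self, rng):
        # short survivors all have marker below 10, long survivors above 20;
        # within each group times are unrelated to the marker
        marker = np.r_[np.linspace(1, 9, 10), np.linspace(21, 30, 10)]
        time = np.r_[rng.permutation(np.linspace(1, 5, 10)),
                     rng.permutation(np.linspace(50, 60, 10))]
        event = np.ones(20, dtype=bool)
        res = optimal_cutpoint(marker, time, event)
        assert 9 < res.cutoff < 21

    def test_matches_exhaustive_lifelines_scan(self, rng):
        """Oracle: per-split log-rank via lifelines at every admissible midpoint."""
        n = 40
        marker = rng.normal(30, 8, n)
        time = rng.exponential(30, n) * np.exp(-0.03 * (marker - 30)) + 0.1
        event = rng.random(n) < 0.8
        res = optimal_cutpoint(marker, time, event, min_prop=0.10)
        uniq = np.sort(np.unique(marker))
        best, best_cut = -np.inf, None
        for lo, hi in zip(uniq[:-1], uniq[1:]):
            cut = 0.5 * (lo + hi)
            n_low = np.sum(marker <= cut)
            if n_low < 4 or n - n_low < 4:
                continue
            chi2, _ = logrank_test(time, event, marker > cut)
            if chi2 > best + 1e-12:
                best, best_cut = chi2, cut
        assert res.cutoff == pytest.approx(best_cut)
        assert res.std_statistic**2 == pytest.approx(best, rel=1e-9)

    def test_cutoff_lies_strictly_between_marker_values(self, rng):
        marker = rng.normal(0, 1, 30)
        time = rng.exponential(20, 30) + 0.1
        event = np.ones(30, dtype=bool)
        res = optimal_cutpoint(marker, time, event)
        assert np.all(res.cutoff != marker)
        below = marker[marker < res.cutoff]
        above = marker[marker > res.cutoff]
        assert len(below) >= 3 and len(above) >= 3

    def test_increasing_min_prop_never_increases_maximum(self, rng):
        marker = rng.normal(0, 1, 60)
        time = rng.exponential(20, 60) + 0.1
        event = rng.random(60) < 0.8
        stats_by_prop = [
            optimal_cutpoint(marker, time, event, min_prop=p).std_statistic
            for p in (0.05, 0.10, 0.20, 0.40)
        ]
        assert np.all(np.diff(stats_by_prop) <= 1e-12)

    def test_no_admissible_split_rejected(self):
        marker = np.r_[np.zeros(19), [1.0]]  # any cut strands a single subject
        time = np.arange(1, 21, dtype=float)
        event = np.ones(20, dtype=bool)
        with pytest.raises(ValueError, match="admissible"):
            optimal_cutpoint(marker, time, event, min_prop=0.10)

    def test_transform_dichotomizes_at_fitted_cutoff(self, rng):
        marker = rng.normal(0, 1, 40)
        time = rng.exponential(20, 40) + 0.1
        cut = SurvivalCutpoint().fit(marker, time, np.ones(40, dtype=bool))
        high = cut.transform(marker)
        np.testing.assert_array_equal(high, marker > cut.cutoff_)

    def test_naive_selected_p_is_anticonservative(self):
        """Post-dichotomisation log-rank at the learned cutpoint rejects far
        more than 5% under the null; a pre-specified median split does not.
        This inflation is what the Bonferroni layer guards against."""
        n_reps, n = 150, 60
        naive_rej, fixed_rej = 0, 0
        for rep in range(n_reps):
            df = generate_survival_cohort(
                CohortSpec(n_patients=n, log_hr=0.0, censor_rate=0.004,
                           baseline_hazard=0.02, seed=70_000 + rep)
            )
            t, e, m = df["time_months"], df["event"], df["biomarker"]
            res = optimal_cutpoint(m, t, e)
            _, p_naive = logrank_test(t, e, m > res.cutoff)
            naive_rej += p_naive < 0.05
            _, p_fixed = logrank_test(t, e, m > np.median(m))
            fixed_rej += p_fixed < 0.05
        assert naive_rej / n_reps > 0.15
        assert fixed_rej / n_reps < 0.12


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, n, thr, display",
        [(0.05, 14, 0.05 / 14, ".004"), (0.05, 1, 0.05, ".050"), (0.05, 5, 0.01, ".010")],
    )
    def test_threshold_and_display(self, alpha, n, thr, display):
        got_thr, got_disp = bonferroni_adjust(alpha, n)
        assert got_thr == pytest.approx(thr)
        assert got_disp == display

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(0.05, 0)


def _nocensor_two_group_fixture(rng, n=30):
    x = (rng.random(n) < 0.5).astype(float)
    # continuous times, no ties
    time = rng.exponential(20, n) * np.exp(-0.8 * x)
    return pd.DataFrame({"time_months": time + 1e-3, "event": True, "x": x})


class TestCox:
    def test_null_covariate_small_beta_ci_covers_zero(self):
        df = generate_survival_cohort(
            CohortSpec(n_patients=1000, log_hr=0.0, censor_rate=0.004, seed=5)
        )
        df["x"] = np.random.default_rng(6).normal(size=1000)
        fit = cox_fit(df, [Covariate("x")])
        beta = fit.summary.loc["x", "coef"]
        assert abs(beta) < 0.1
        assert fit.summary.loc["x", "hr_lower95"] <= 1.0 <= fit.summary.loc["x", "hr_upper95"]

    def test_score_test_at_zero_equals_logrank(self, rng):
        """On a no-tie two-group sample the Cox score test at beta=0 is the
        log-rank statistic. Score U(0) and information I(0) are computed by
        numerical differentiation of a hand-written Breslow partial
        log-likelihood (exact without ties)."""
        df = _nocensor_two_group_fixture(rng)
        t = df["time_months"].to_numpy()
        x = df["x"].to_numpy()

        def pll(beta):
            order = np.argsort(t)
            ts, xs = t[order], x[order]
            ll = 0.0
            for i in range(len(ts)):
                risk = xs[i:]  # all with time >= ts[i]
                ll += beta * xs[i] - np.log(np.sum(np.exp(beta * risk)))
            return ll

        h = 1e-5
        u0 = (pll(h) - pll(-h)) / (2 * h)
        i0 = -(pll(h) - 2 * pll(0.0) + pll(-h)) / h**2
        score_chi2 = u0**2 / i0
        chi2, _ = logrank_test(df["time_months"], df["event"], x > 0.5)
        assert score_chi2 == pytest.approx(chi2, rel=1e-4)

    def test_recovers_known_log_hazard_ratio(self):
        df = generate_survival_cohort(
            CohortSpec(n_patients=800, log_hr=0.7, true_cutpoint=31.7,
                       baseline_hazard=0.015, censor_rate=0.002, seed=21)
        )
        df["high"] = df["biomarker_high"].astype(float)
        fit = cox_fit(df, [Covariate("high")])
        assert fit.summary.loc["high", "coef"] == pytest.approx(0.7, abs=0.25)

    def test_categorical_expansion_against_reference(self):
        rng = np.random.default_rng(3)
        n = 300
        stage = rng.choice(["T1", "T2", "T3"], n, p=[0.3, 0.4, 0.3])
        beta = {"T1": 0.0, "T2": 0.4, "T3": 1.0}
        h = 0.02 * np.exp([beta[s] for s in stage])
        df = pd.DataFrame({
            "time_months": np.maximum(rng.exponential(1 / h), 1e-3),
            "event": True,
            "stage": stage,
        })
        fit = cox_fit(df, [Covariate("stage", "categorical", reference="T1")])
        assert list(fit.summary.index) == ["stage[T2]", "stage[T3]"]
        assert fit.summary.loc["stage[T3]", "coef"] > fit.summary.loc["stage[T2]", "coef"]
        assert fit.summary.loc["stage[T3]", "coef"] == pytest.approx(1.0, abs=0.35)

    def test_too_few_events_rejected_and_low_events_warned(self):
        df = pd.DataFrame({
            "time_months": [1.0, 2.0, 3.0, 4.0],
            "event": [True, False, False, False],
            "a": [1.0, 0.0, 1.0, 0.0],
            "b": [0.5, 1.5, 2.5, 3.5],
        })
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, [Covariate("a"), Covariate("b")])
        df["event"] = [True, True, True, False]
        with pytest.warns(UserWarning, match="events per coefficient"):
            cox_fit(df, [Covariate("a")])

    def test_hr_ci_contains_hr(self, rng):
        df = _nocensor_two_group_fixture(rng, n=60)
        fit = cox_fit(df, [Covariate("x")])
        row = fit.summary.loc["x"]
        assert row["hr_lower95"] <= row["hr"] <= row["hr_upper95"]
        assert row["hr"] > 0


class TestBackwardElimination:
    def _cohort(self, seed, n=500):
        return generate_survival_cohort(
            CohortSpec(
                n_patients=n, log_hr=0.8, true_cutpoint=31.7,
                baseline_hazard=0.015, censor_rate=0.002,
                covariates=(
                    CovariateSpec("age_high", "binary", (0.5,), 0.7),
                    CovariateSpec("noise", "normal", (0.0, 1.0), 0.0),
                ),
                seed=seed,
            )
        ).assign(high=lambda d: d["biomarker_high"].astype(float))

    def test_strong_covariates_all_kept(self):
        df = self._cohort(1)
        covs = [Covariate("high"), Covariate("age_high")]
        fit, trace = backward_eliminate(df, covs, threshold=0.05)
        assert trace == []
        assert set(fit.blocks) == {"high", "age_high"}

    def test_threshold_one_eliminates_nothing(self):
        df = self._cohort(2)
        covs = [Covariate("high"), Covariate("age_high"), Covariate("noise")]
        fit, trace = backward_eliminate(df, covs, threshold=1.0)
        assert trace == []
        assert set(fit.blocks) == {"high", "age_high", "noise"}

    def test_noise_covariate_eliminated_first_in_most_replicates(self):
        wins = 0
        n_reps = 60
        for rep in range(n_reps):
            df = self._cohort(3000 + rep, n=400)
            covs = [Covariate("high"), Covariate("age_high"), Covariate("noise")]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, trace = backward_eliminate(df, covs, threshold=0.05)
            if trace and trace[0]["dropped"] == "noise":
                wins += 1
            elif not trace:
                # nothing eliminated: noise survived, not a win
                pass
        assert wins / n_reps >= 0.90

    def test_all_covariates_eliminated_returns_empty_model_with_trace(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({
            "time_months": rng.exponential(20, 200) + 0.1,
            "event": rng.random(200) < 0.7,
            "noise1": rng.normal(size=200),
            "noise2": rng.normal(size=200),
        })
        fit, trace = backward_eliminate(
            df, [Covariate("noise1"), Covariate("noise2")], threshold=1e-6
        )
        assert fit is None
        assert {t["dropped"] for t in trace} == {"noise1", "noise2"}


class TestGVIF:
    def test_orthogonal_covariates_have_unit_gvif(self):
        n = 64
        a = np.tile([0.0, 1.0], n // 2)
        b = np.repeat([0.0, 1.0], n // 2)
        df = pd.DataFrame({"a": a, "b": b})
        rep = gvif(df, [Covariate("a"), Covariate("b")])
        assert rep.table.loc["a", "gvif"] == pytest.approx(1.0, abs=1e-10)
        assert rep.table.loc["b", "gvif"] == pytest.approx(1.0, abs=1e-10)
        assert rep.flagged == []

    def test_continuous_gvif_equals_vif_identity(self, rng):
        """GVIF of a single continuous covariate equals 1/(1-R^2) of the
        auxiliary regression of that covariate on the others."""
        n = 200
        z1, z2 = rng.normal(size=(2, n))
        x = 0.8 * z1 + 0.4 * z2 + 0.3 * rng.normal(size=n)
        df = pd.DataFrame({"x": x, "z1": z1, "z2": z2})
        rep = gvif(df, [Covariate("x"), Covariate("z1"), Covariate("z2")])
        design = np.column_stack([np.ones(n), z1, z2])
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        resid = x - design @ beta
        r2 = 1 - resid.var() / x.var()
        assert rep.table.loc["x", "gvif"] == pytest.approx(1 / (1 - r2), rel=1e-6)

    def test_near_duplicate_covariates_both_flagged(self, rng):
        n = 300
        u = rng.normal(size=n)
        df = pd.DataFrame({
            "a": u,
            "b": u + 0.05 * rng.normal(size=n),  # corr ~0.999
            "c": rng.normal(size=n),
        })
        rep = gvif(df, [Covariate("a"), Covariate("b"), Covariate("c")])
        assert set(rep.flagged) >= {"a", "b"}

    def test_rank_deficient_design_names_aliased_columns(self):
        n = 50
        u = np.linspace(0, 1, n)
        df = pd.DataFrame({"a": u, "b": 2 * u})
        with pytest.raises(ValueError, match="aliased"):
            gvif(df, [Covariate("a"), Covariate("b")])

    def test_categorical_block_df_adjustment(self, rng):
        n = 240
        cat = rng.choice(["x", "y", "z"], n)
        other = rng.normal(size=n)
        df = pd.DataFrame({"cat": cat, "other": other})
        rep = gvif(df, [Covariate("cat", "categorical", reference="x"),
                        Covariate("other")])
        assert rep.table.loc["cat", "df"] == 2
        assert rep.table.loc["cat", "gvif"] >= 1.0 - 1e-9
        assert rep.table.loc["cat", "gvif_adj"] == pytest.approx(
            rep.table.loc["cat", "gvif"] ** 0.25
        )
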