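"""Outcome definitions and logistic risk modelling tests.

Closed-form 2x2 odds ratios and an exhaustive pair-counting AUC serve as
independent oracles for the statsmodels-backed fits.
"""

import warnings

import numpy as np
import pytest
from scipy.special import expit

from bscore.outcomes import (ClinicalRecord, OutcomeSpec, added_value,
                             adjusted_fit, assign_quartiles, auc,
                             current_outcome, fit_logistic, future_outcome,
                             interval_width_ratio, klg_design, outcome_vector,
                             p_stars, quartile_or_table, risk_curve,
                             select_function_knee)


def record(knee_id="k1", person_id="p1", nrs=None, womacF=None, **kw):
    return ClinicalRecord(knee_id=knee_id, person_id=person_id,
                          nrs_pain=nrs or [], womac_function=womacF or [], **kw)


class TestOutcomeDefinitions:
    @pytest.mark.parametrize("baseline,severity,expected", [
        (4, "moderate", True),   # at the threshold counts
        (3, "moderate", False),
        (8, "severe", True),
    ])
    def test_current_pain_thresholds(self, baseline, severity, expected):
        rec = record(nrs=[baseline, 0, 0])
        spec = OutcomeSpec(scale="nrs_pain", severity=severity)
        assert current_outcome(rec, spec) is expected

    def test_current_severe_function_at_35(self):
        rec = record(womacF=[35])
        spec = OutcomeSpec(scale="womac_function", severity="severe")
        assert current_outcome(rec, spec) is True

    def test_threshold_override_for_sensitivity_analysis(self):
        rec = record(womacF=[35])
        spec = OutcomeSpec(scale="womac_function", severity="severe",
                           threshold=36)
        assert current_outcome(rec, spec) is False

    def test_missing_baseline_raises(self):
        spec = OutcomeSpec()
        with pytest.raises(ValueError, match="baseline"):
            current_outcome(record(nrs=[None, 5]), spec)

    @pytest.mark.parametrize("follow,expected", [
        ([2, 4, 6], True),        # median 4
        ([3, 5], True),           # even count -> mean of middle two = 4.0
        ([0, 0, 0, 9], False),    # single spike does not flip the median
    ])
    def test_future_median_convention(self, follow, expected):
        rec = record(nrs=[0, *follow])
        spec = OutcomeSpec(scale="nrs_pain", severity="moderate",
                           timing="future")
        assert future_outcome(rec, spec) is expected

    def test_future_requires_followup(self):
        spec = OutcomeSpec(timing="future")
        with pytest.raises(ValueError, match="follow-up"):
            future_outcome(record(nrs=[5, None, None]), spec)

    def test_outcome_vector_skips_missing(self):
        recs = [record("k1", nrs=[5]), record("k2", nrs=[None]),
                record("k3", nrs=[2])]
        with pytest.warns(UserWarning, match="skipped"):
            idx, y = outcome_vector(recs, OutcomeSpec())
        assert idx.tolist() == [0, 2]
        assert y.tolist() == [True, False]

    def test_tkr_is_the_flag(self):
        assert current_outcome(record(tkr=True), OutcomeSpec(scale="tkr"))

    def test_score_range_validation(self):
        with pytest.raises(ValueError, match="nrs_pain"):
            record(nrs=[11])


class TestSelectFunctionKnee:
    def test_highest_bscore_wins(self):
        recs = [record("a_L", side="left"), record("a_R", side="right")]
        assert select_function_knee(recs, {"a_L": 1.2, "a_R": 3.4}) == "a_R"
        assert select_function_knee(recs, {"a_L": 3.4, "a_R": 1.2}) == "a_L"

    def test_tie_prefers_right_then_lexicographic(self):
        recs = [record("a_L", side="left"), record("a_R", side="right")]
        assert select_function_knee(recs, {"a_L": 2.0, "a_R": 2.0}) == "a_R"
        both_left = [record("b", side="left"), record("a", side="left")]
        assert select_function_knee(both_left, {"a": 2.0, "b": 2.0}) == "a"

    def test_unscored_error(self):
        with pytest.raises(ValueError, match="B-score"):
            select_function_knee([record("a")], {})


class TestFitLogistic:
    def test_null_data_near_zero_coefficients(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        y = np.tile([0, 1], 1000)
        fit = fit_logistic(y, x.reshape(-1, 1), names=["x"])
        assert abs(fit.coef("x")) < 3 * fit.se("x")
        assert abs(fit.coef("const")) < 3 * fit.se("const")

    def test_two_by_two_log_odds_oracle(self):
        """On a binary predictor the slope is exactly log(ad/bc)."""
        a, b, c, d = 10, 90, 30, 70  # exposed/unexposed x outcome counts
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        x = np.array([1.0] * (a + b) + [0.0] * (c + d))
        fit = fit_logistic(y, x.reshape(-1, 1), names=["x"])
        assert fit.coef("x") == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)
        assert fit.odds_ratio("x")[0] == pytest.approx(0.259, abs=5e-4)

    def test_parameter_recovery_consistency(self):
        """At large n the MLE sits within a few standard errors (and close
        in absolute terms) of the generating (intercept, slope)."""
        rng = np.random.default_rng(2024)
        x = rng.normal(1.0, 2.0, size=50_000)
        y = rng.uniform(size=50_000) < expit(-2.0 + 0.5 * x)
        fit = fit_logistic(y, x.reshape(-1, 1), names=["x"])
        for name, true in [("const", -2.0), ("x", 0.5)]:
            assert abs(fit.coef(name) - true) < 4 * fit.se(name)
            assert fit.coef(name) == pytest.approx(true, abs=0.1)

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.ones(20), np.arange(20.0).reshape(-1, 1))

    def test_collinear_design_error(self):
        x = np.arange(20.0)
        y = np.tile([0, 1], 10)
        with pytest.raises(ValueError, match="collinear"):
            fit_logistic(y, np.column_stack([x, 2 * x]), names=["a", "b"])

    def test_complete_separation_error(self):
        x = np.concatenate([np.arange(10.0), np.arange(10.0) + 20])
        y = np.array([0] * 10 + [1] * 10)
        with pytest.raises(ValueError, match="separation"):
            fit_logistic(y, x.reshape(-1, 1), names=["x"])


def constant_risk_fit(intercept, slope=0.0, n=100):
    """A hand-built LogisticFit for closed-form risk-curve checks."""
    from bscore.outcomes import LogisticFit
    return LogisticFit(params=np.array([intercept, slope]),
                       names=["const", "x"], cov=np.eye(2) * 1e-4, n=n,
                       llf=0.0, converged=True,
                       fitted_probabilities=np.full(n, expit(intercept)))


class TestRiskCurve:
    def test_flat_ten_percent(self):
        fit = constant_risk_fit(np.log(1 / 9))
        curve = risk_curve(fit, np.linspace(-3, 7, 11))
        assert np.allclose(curve["risk"], 10.0, atol=1e-10)

    def test_fifty_percent_at_zero(self):
        fit = constant_risk_fit(0.0, slope=1.0)
        curve = risk_curve(fit, np.array([0.0]))
        assert curve["risk"].iloc[0] == pytest.approx(50.0, abs=1e-10)

    def test_ci_bracket_and_bounds_on_random_fits(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            fit = constant_risk_fit(rng.normal(scale=3), rng.normal(scale=2))
            fit.cov = np.diag(rng.uniform(0.01, 4.0, size=2))
            curve = risk_curve(fit, rng.normal(scale=5, size=9))
            assert ((0 <= curve["ci_lo"]) & (curve["ci_lo"] <= curve["risk"])
                    & (curve["risk"] <= curve["ci_hi"])
                    & (curve["ci_hi"] <= 100)).all()

    def test_positive_slope_strictly_increasing(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=500)
        y = rng.uniform(size=500) < expit(-0.5 + 1.2 * x)
        fit = fit_logistic(y, x.reshape(-1, 1), names=["x"])
        curve = risk_curve(fit, np.linspace(-3, 3, 25))
        assert (np.diff(curve["risk"]) > 0).all()

    def test_saturated_binary_predictor_matches_proportions(self):
        rng = np.random.default_rng(9)
        x = np.repeat([0.0, 1.0], 200)
        y = np.concatenate([rng.uniform(size=200) < 0.2,
                            rng.uniform(size=200) < 0.6])
        fit = fit_logistic(y, x.reshape(-1, 1), names=["x"])
        curve = risk_curve(fit, np.array([0.0, 1.0]))
        assert curve["risk"].iloc[0] == pytest.approx(100 * y[:200].mean(), abs=1e-8)
        assert curve["risk"].iloc[1] == pytest.approx(100 * y[200:].mean(), abs=1e-8)

    def test_extreme_grid_clamped_with_warning(self):
        fit = constant_risk_fit(0.0, slope=10.0)
        with pytest.warns(UserWarning, match="clamped"):
            curve = risk_curve(fit, np.array([100.0]))
        assert curve["risk"].iloc[0] <= 100


class TestAUC:
    def test_perfect_separation_is_one(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        assert auc(np.array([1, 2, 3, 4, 5, 6.0]), y) == 1.0

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, size=20_000)
        assert auc(rng.normal(size=20_000), y) == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_brute_force_pair_counting(self, seed):
        """Mann-Whitney concordance equals exhaustive pair enumeration
        (ties worth 1/2) on small inputs."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        pos, neg = scores[y == 1], scores[y == 0]
        pairs = [(0.5 if p == q else float(p > q)) for p in pos for q in neg]
        assert auc(scores, y) == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="single"):
            auc(np.arange(5.0), np.ones(5))


class TestQuartiles:
    @pytest.mark.parametrize("n", [16, 17, 18, 19])
    def test_partition_sizes_differ_by_at_most_one(self, n):
        rng = np.random.default_rng(n)
        q, _ = assign_quartiles(rng.normal(size=n))
        counts = np.bincount(q, minlength=4)
        assert counts.max() - counts.min() <= 1

    def test_boundary_values_go_to_lower_quartile(self):
        values = np.arange(8.0)  # quantiles 1.75, 3.5, 5.25
        q, bounds = assign_quartiles(values)
        assert q[values <= bounds[0]].max() == 0

    def _stratum_records(self, rng, n, klg, slope):
        recs, scores = [], {}
        for i in range(n):
            b = rng.normal(2.0, 1.5)
            pain = int(rng.uniform() < expit(-1.5 + slope * b)) * 5
            recs.append(record(f"k{klg}_{i}", f"p{klg}_{i}", klg=klg,
                               nrs=[pain]))
            scores[f"k{klg}_{i}"] = b
        return recs, scores

    def test_null_calibration_covers_one(self):
        """With outcome independent of B-score, the Q4-vs-Q1 CI covers
        OR=1 in at least 90% of seeded null replicates."""
        covered = 0
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            recs, scores = self._stratum_records(rng, 240, klg=2, slope=0.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = quartile_or_table(recs, scores, OutcomeSpec())
            row = table[(table.klg == 2) & (table.quartile == 4)].iloc[0]
            covered += row.ci_lo <= 1.0 <= row.ci_hi
        assert covered / n_rep >= 0.90

    def test_monotone_generator_orders_odds_ratios(self):
        """Risk rising in B-score puts the mean log-OR in Q2 < Q3 < Q4."""
        logs = np.zeros(3)
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(2000 + seed)
            recs, scores = self._stratum_records(rng, 320, klg=3, slope=0.8)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = quartile_or_table(recs, scores, OutcomeSpec())
            sub = table[table.klg == 3].sort_values("quartile")
            logs += np.log(sub["or"].to_numpy())
        assert logs[0] < logs[1] < logs[2]

    def test_small_stratum_skipped_with_warning(self):
        rng = np.random.default_rng(5)
        recs, scores = self._stratum_records(rng, 5, klg=4, slope=0.0)
        with pytest.warns(UserWarning, match="KLG 4"):
            table = quartile_or_table(recs, scores, OutcomeSpec())
        assert table.empty


class TestAddedValue:
    def _cohort(self, rng, n=600, informative=True):
        recs, scores = [], {}
        for i in range(n):
            s = rng.normal(2.0, 2.0)
            klg = int(np.clip(np.digitize(s, [-0.5, 1.0, 2.5, 4.0]), 0, 4))
            b = s + rng.normal(scale=0.2) if informative else rng.normal(size=1)[0]
            pain = int(rng.uniform() < expit(-1.6 + 0.45 * s)) * 6
            recs.append(record(f"k{i}", f"p{i}", klg=klg, nrs=[pain]))
            scores[f"k{i}"] = float(b)
        return recs, scores

    def test_continuous_severity_beats_coarse_grade(self):
        """When outcomes follow continuous severity and KLG merely
        discretises it, adding B-score raises the AUC in >= 95% of runs."""
        wins = 0
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(3000 + seed)
            recs, scores = self._cohort(rng)
            res = added_value(recs, scores, OutcomeSpec())
            wins += res["auc_klg_plus_b"] > res["auc_klg"]
        assert wins / n_rep >= 0.95

    def test_null_bscore_p_uniform(self):
        """With B-score pure noise given KLG, the Wald p-value is uniform
        (KS test over seeded replicates at alpha = 0.01)."""
        from scipy.stats import kstest
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(4000 + seed)
            recs, scores = self._cohort(rng, n=1000, informative=False)
            pvals.append(added_value(recs, scores, OutcomeSpec())["p_bscore"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_duplicate_klg_column_rejected(self):
        rng = np.random.default_rng(6)
        recs, _ = self._cohort(rng, n=200)
        duplicated = {r.knee_id: float(r.klg) for r in recs}
        with pytest.raises(ValueError, match="collinear|separation"):
            added_value(recs, duplicated, OutcomeSpec())


class TestAdjustedFit:
    def _cohort(self, rng, n=800, confounded=False):
        recs, scores = [], {}
        for i in range(n):
            age = rng.normal(60, 10)
            b = rng.normal(2.0, 2.0) + (0.08 * (age - 60) if confounded else 0)
            lp = -1.5 + 0.4 * b + (0.06 * (age - 60) if confounded else 0)
            pain = int(rng.uniform() < expit(lp)) * 6
            recs.append(record(f"k{i}", f"p{i}", nrs=[pain], covariates={
                "age": age, "bmi": rng.normal(30, 5),
                "smoking": rng.choice(["never", "former", "current"])}))
            scores[f"k{i}"] = float(b)
        return recs, scores

    COVARS = ("age", "bmi", "smoking")

    def test_independent_covariates_leave_or_unchanged(self):
        """Covariates unrelated to outcome and score: adjusted log-OR stays
        within one SE of the unadjusted one (averaged over replicates)."""
        close = 0
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(5000 + seed)
            recs, scores = self._cohort(rng)
            res = adjusted_fit(recs, scores, OutcomeSpec(), covariates=self.COVARS)
            diff = abs(np.log(res["or_adjusted"][0])
                       - np.log(res["or_unadjusted"][0]))
            close += diff <= res["fit"].se("bscore")
        assert close / n_rep >= 0.8

    def test_confounder_adjustment_attenuates_toward_truth(self):
        """Age driving both score and outcome biases the crude OR upward;
        adjustment pulls the log-OR back toward the generating 0.4."""
        crude_err = adj_err = 0.0
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(6000 + seed)
            recs, scores = self._cohort(rng, confounded=True)
            res = adjusted_fit(recs, scores, OutcomeSpec(), covariates=self.COVARS)
            crude_err += abs(np.log(res["or_unadjusted"][0]) - 0.4)
            adj_err += abs(np.log(res["or_adjusted"][0]) - 0.4)
        assert adj_err < crude_err

    def test_zero_variance_covariate_dropped(self):
        rng = np.random.default_rng(11)
        recs, scores = self._cohort(rng, n=200)
        for r in recs:
            r.covariates["nsaid"] = 0
        with pytest.warns(UserWarning, match="zero variance"):
            res = adjusted_fit(recs, scores, OutcomeSpec(),
                               covariates=("age", "nsaid"))
        assert "nsaid" not in res["fit"].names

    def test_missing_covariates_complete_case(self):
        rng = np.random.default_rng(12)
        recs, scores = self._cohort(rng, n=200)
        for r in recs[:30]:
            del r.covariates["age"]
        with pytest.warns(UserWarning, match="30 records excluded"):
            res = adjusted_fit(recs, scores, OutcomeSpec(), covariates=("age",))
        assert res["n_excluded"] == 30
        assert res["n_complete"] == 170


class TestHelpers:
    def test_interval_width_ratio(self):
        assert interval_width_ratio((4.5, 45.5), (13.3, 17.3)) \
            == pytest.approx(10.25)
        with pytest.raises(ValueError):
            interval_width_ratio((0, 1), (2, 2))

    def test_klg_design_reference_zero(self):
        X, names = klg_design([0, 1, 2, 3, 4])
        assert names == ["klg1", "klg2", "klg3", "klg4"]
        assert np.array_equal(X[0], [0, 0, 0, 0])
        assert np.array_equal(np.diag(X[1:]), [1, 1, 1, 1])

    @pytest.mark.parametrize("p,stars", [
        (0.2, ""), (0.04, "*"), (0.009, "**"), (0.0005, "***")])
    def test_p_stars(self, p, stars):
        assert p_stars(p) == stars
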