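import numpy as np
import pandas as pd
import pytest
from scipy import stats

import irgpsig as ir
from irgpsig.model import RiskProfile

from conftest import random_survival


def _profile(scores, ids=None):
    ids = ids or [f"S{i}" for i in range(len(scores))]
    return RiskProfile(ids, np.asarray(scores, dtype=float))


def _clin(time, event, ids=None):
    ids = ids or [f"S{i}" for i in range(len(time))]
    return pd.DataFrame({"time": time, "event": event},
                        index=pd.Index(ids, name="sample_id"))


class TestTimedepROC:
    def test_perfect_separation_no_censoring(self):
        scores = [3.0, 2.5, 2.0, 0.5, 0.4, 0.1]
        clin = _clin([0.2, 0.5, 0.9, 2.0, 3.0, 4.0], [1, 1, 1, 1, 1, 1])
        roc = ir.timedep_roc(_profile(scores), clin, horizon=1.0)
        assert roc.auc == pytest.approx(1.0)
        # ties break toward the lower threshold: top of the low cluster
        assert 0.5 <= roc.optimal_cutoff < 2.0

    def test_null_scores_give_half_auc(self):
        rng = np.random.default_rng(7)
        n = 2000
        scores = rng.normal(size=n)
        t = rng.exponential(1.2, n)
        clin = _clin(t, np.ones(n, dtype=int))
        roc = ir.timedep_roc(_profile(scores), clin, horizon=1.0)
        assert roc.auc == pytest.approx(0.5, abs=0.03)

    def test_censored_fixture_matches_weighted_mann_whitney(self):
        # 12 subjects with censoring before and after the horizon
        time = np.array([0.3, 0.5, 0.6, 0.8, 0.9, 1.2, 1.5, 2.0, 0.4, 0.7, 3.0, 1.1])
        event = np.array([1, 1, 0, 1, 1, 0, 1, 1, 0, 1, 0, 1])
        rng = np.random.default_rng(3)
        scores = rng.normal(size=12)
        clin = _clin(time, event)
        roc = ir.timedep_roc(_profile(scores), clin, horizon=1.0)

        # brute-force IPCW Mann-Whitney oracle with its own censoring KM
        def g_surv(t):
            s, at_risk = 1.0, len(time)
            for tau in np.sort(np.unique(time[event == 0])):
                if tau > t:
                    break
                n_at = (time >= tau).sum()
                d_c = ((time == tau) & (event == 0)).sum()
                s *= 1 - d_c / n_at
            return s

        cases = np.flatnonzero((event == 1) & (time <= 1.0))
        controls = np.flatnonzero(time > 1.0)
        wc = np.array([1 / g_surv(time[i] - 1e-9) for i in cases])
        wk = np.array([1 / g_surv(1.0) for _ in controls])
        num = 0.0
        for i, wi in zip(cases, wc):
            for j, wj in zip(controls, wk):
                cmp_ = 1.0 if scores[i] > scores[j] else \
                    0.5 if scores[i] == scores[j] else 0.0
                num += wi * wj * cmp_
        expected = num / (wc.sum() * wk.sum())
        assert roc.auc == pytest.approx(expected, rel=1e-10)

    def test_auc_invariant_under_monotone_score_transform(self, rng):
        surv = random_survival(rng, 80)
        scores = rng.normal(size=80)
        r1 = ir.timedep_roc(_profile(scores), surv, horizon=1.0)
        r2 = ir.timedep_roc(_profile(np.exp(2 * scores)), surv, horizon=1.0)
        assert r1.auc == pytest.approx(r2.auc, rel=1e-12)

    def test_no_cases_errors(self):
        clin = _clin([2.0, 3.0], [1, 1])
        with pytest.raises(ValueError, match="events"):
            ir.timedep_roc(_profile([1.0, 2.0]), clin, horizon=1.0)

    def test_no_controls_errors(self):
        clin = _clin([0.2, 0.3], [1, 1])
        with pytest.raises(ValueError, match="past"):
            ir.timedep_roc(_profile([1.0, 2.0]), clin, horizon=1.0)


class TestOptimalCutoff:
    def test_equals_exhaustive_scan(self, rng):
        for _ in range(10):
            n = 40
            scores = rng.normal(size=n).round(1)  # force score ties
            surv = random_survival(rng, n, censor_frac=0.0)
            roc = ir.timedep_roc(_profile(scores), surv, horizon=1.0)
            best, best_y = None, -np.inf
            cases = (surv["event"].to_numpy() == 1) & (surv["time"].to_numpy() <= 1.0)
            controls = surv["time"].to_numpy() > 1.0
            for c in np.unique(scores):
                sens = (scores[cases] > c).mean()
                spec = (scores[controls] <= c).mean()
                y = sens + spec - 1
                if y > best_y + 1e-12:
                    best, best_y = c, y
            assert roc.optimal_cutoff == pytest.approx(best)

    def test_degenerate_equal_scores(self):
        clin = _clin([0.5, 0.6, 2.0, 3.0], [1, 1, 1, 1])
        roc = ir.timedep_roc(_profile([1.5] * 4), clin, horizon=1.0)
        assert roc.optimal_cutoff == 1.5
        assert roc.auc == pytest.approx(0.5)


class TestAssignGroups:
    def test_strict_boundary(self):
        prof = ir.assign_groups(_profile([1.20, 1.057, 0.50]), cutoff=1.057)
        assert prof.group.tolist() == ["high", "low", "low"]

    def test_partition(self, rng):
        prof = ir.assign_groups(_profile(rng.normal(size=25)), cutoff=0.1)
        assert ((prof.group == "high") | (prof.group == "low")).all()

    def test_nonfinite_cutoff_rejected(self):
        with pytest.raises(ValueError):
            ir.assign_groups(_profile([1.0]), cutoff=np.nan)


class TestCompareSurvival:
    def _grouped(self, rng, n=120, hr=1.0):
        hi = rng.random(n) < 0.5
        t = rng.exponential(1.0, n) * np.exp(-np.log(hr) * hi)
        clin = _clin(np.maximum(t, 1e-9), np.ones(n, dtype=int))
        prof = RiskProfile(list(clin.index), hi.astype(float),
                           np.where(hi, "high", "low"), 0.5)
        return prof, clin

    def test_label_swap_symmetry(self, rng):
        prof, clin = self._grouped(rng, hr=2.0)
        _, _, p1 = ir.compare_survival(prof, clin)
        flipped = RiskProfile(list(prof.sample_ids), prof.scores,
                              np.where(prof.group == "high", "low", "high"), 0.5)
        _, _, p2 = ir.compare_survival(flipped, clin)
        assert p1 == pytest.approx(p2)

    def test_strong_effect_detected(self, rng):
        hits = 0
        for _ in range(20):
            prof, clin = self._grouped(rng, n=300, hr=3.0)
            _, _, p = ir.compare_survival(prof, clin)
            hits += p < 0.01
        assert hits >= 19

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(200):
            prof, clin = self._grouped(rng, n=60, hr=1.0)
            ps.append(ir.compare_survival(prof, clin)[2])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_group_rejected(self, rng):
        prof, clin = self._grouped(rng)
        bad = RiskProfile(list(prof.sample_ids), prof.scores,
                          np.full(len(prof.sample_ids), "low"), 0.5)
        with pytest.raises(ValueError):
            ir.compare_survival(bad, clin)


class TestCoxFit:
    def test_binary_effect_recovery(self):
        rng = np.random.default_rng(0)
        n = 500
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1.0, n) * np.exp(-x)
        clin = _clin(np.maximum(t, 1e-9), np.ones(n, dtype=int))
        cov = pd.DataFrame({"x": x}, index=clin.index)
        fit = ir.cox_fit(cov, clin, "univariate")
        assert fit.loc["x", "coef"] == pytest.approx(1.0, abs=0.2)
        assert fit.loc["x", "hazard_ratio"] == pytest.approx(
            np.exp(fit.loc["x", "coef"]))
        assert fit.loc["x", "ci95_low"] < fit.loc["x", "hazard_ratio"] \
            < fit.loc["x", "ci95_high"]

    def test_negated_covariate_flips_everything(self, rng):
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(1.0, n) * np.exp(-0.5 * x)
        clin = _clin(np.maximum(t, 1e-9), np.ones(n, dtype=int))
        f1 = ir.cox_fit(pd.DataFrame({"x": x}, index=clin.index), clin)
        f2 = ir.cox_fit(pd.DataFrame({"x": -x}, index=clin.index), clin)
        assert f1.loc["x", "coef"] == pytest.approx(-f2.loc["x", "coef"], rel=1e-6)
        assert f1.loc["x", "hazard_ratio"] == pytest.approx(
            1 / f2.loc["x", "hazard_ratio"], rel=1e-6)

    def test_efron_and_breslow_differ_on_ties(self, rng):
        # heavy event-time ties: the two corrections must disagree
        from scipy.optimize import minimize
        from irgpsig.model import breslow_loglik
        n = 60
        x = (rng.random(n) < 0.5).astype(float)
        t = np.ceil(rng.exponential(1.0, n) * np.exp(-0.8 * x) * 4) / 4  # gridded
        clin = _clin(np.maximum(t, 0.25), np.ones(n, dtype=int))
        cov = pd.DataFrame({"x": x}, index=clin.index)
        efron = ir.cox_fit(cov, clin).loc["x", "coef"]
        res = minimize(lambda b: -breslow_loglik(b, x[:, None],
                                                 clin["time"].to_numpy(),
                                                 clin["event"].to_numpy()),
                       x0=[0.0], method="BFGS")
        breslow = res.x[0]
        assert abs(efron - breslow) > 1e-4       # ties make them differ
        assert efron == pytest.approx(breslow, abs=0.4)  # but not wildly

    def test_multivariate_mode_joint_fit(self, rng):
        n = 300
        x1 = rng.normal(size=n)
        x2 = x1 * 0.8 + rng.normal(size=n) * 0.6  # correlated
        t = rng.exponential(1.0, n) * np.exp(-0.8 * x1)
        clin = _clin(np.maximum(t, 1e-9), np.ones(n, dtype=int))
        cov = pd.DataFrame({"x1": x1, "x2": x2}, index=clin.index)
        uni = ir.cox_fit(cov, clin, "univariate")
        multi = ir.cox_fit(cov, clin, "multivariate")
        # x2 only matters through x1: the joint fit should shrink it
        assert abs(multi.loc["x2", "coef"]) < abs(uni.loc["x2", "coef"])


class TestEncodeCovariates:
    def test_standard_encoding(self):
        clin = pd.DataFrame({
            "time": [1.0, 2.0], "event": [1, 0],
            "age": [70.0, 55.0], "gender": ["Male", "Female"],
            "grade": ["Grade 3", "Grade 1"], "stage": ["Stage II", "Stage IV"],
        }, index=["A", "B"])
        enc = ir.encode_covariates(clin, ["age", "gender", "grade", "stage"])
        assert enc.loc["A"].tolist() == [70.0, 1.0, 3.0, 2.0]
        assert enc.loc["B"].tolist() == [55.0, 0.0, 1.0, 4.0]

    def test_unknown_category_rejected(self):
        clin = pd.DataFrame({"grade": ["Grade 9"]}, index=["A"])
        with pytest.raises(ValueError):
            ir.encode_covariates(clin, ["grade"])


class TestSummarizeCohort:
    def test_rounding_half_up(self):
        clin = pd.DataFrame({"status": ["a"] * 1 + ["b"] * 7}, index=range(8))
        s = ir.summarize_cohort(clin, ["status"])["status"]
        assert s.loc["a", "percent"] == 12.5

    def test_percentages_sum_to_100(self, rng):
        clin = pd.DataFrame({"v": rng.choice(list("abcd"), 97)})
        s = ir.summarize_cohort(clin, ["v"])["v"]
        assert s["percent"].sum() == pytest.approx(100.0, abs=0.101)

    def test_single_category(self):
        clin = pd.DataFrame({"v": ["only"] * 5})
        assert ir.summarize_cohort(clin, ["v"])["v"].loc["only", "percent"] == 100.0

    def test_unknown_variable(self):
        with pytest.raises(KeyError):
            ir.summarize_cohort(pd.DataFrame({"v": [1]}), ["nope"])


class TestCompareFeatureByGroup:
    def _prof(self, n_hi, n_lo):
        ids = [f"S{i}" for i in range(n_hi + n_lo)]
        return RiskProfile(ids, np.zeros(n_hi + n_lo),
                           np.array(["high"] * n_hi + ["low"] * n_lo), 0.0)

    def test_shifted_feature_detected_with_direction(self, rng):
        prof = self._prof(80, 80)
        up = np.concatenate([rng.normal(1.0, 1.0, 80), rng.normal(0.0, 1.0, 80)])
        down = np.concatenate([rng.normal(-1.0, 1.0, 80), rng.normal(0.0, 1.0, 80)])
        feats = pd.DataFrame({"up": up, "down": down}, index=prof.sample_ids)
        out = ir.compare_feature_by_group(feats, prof)
        assert out.loc["up", "direction"] == "higher in high-risk"
        assert out.loc["down", "direction"] == "lower in high-risk"
        assert out.loc["up", "p_value"] < 0.05

    def test_constant_feature(self):
        prof = self._prof(5, 5)
        feats = pd.DataFrame({"flat": np.ones(10)}, index=prof.sample_ids)
        out = ir.compare_feature_by_group(feats, prof)
        assert out.loc["flat", "p_value"] == 1.0
        assert out.loc["flat", "direction"] == "n.s."

    def test_significance_stars_follow_thresholds(self, rng):
        prof = self._prof(60, 60)
        feats = pd.DataFrame(
            {f"f{i}": rng.normal(size=120) + prof.scores for i in range(12)},
            index=prof.sample_ids)
        feats += np.where(np.array(prof.group) == "high", 0.4, 0.0)[:, None]
        out = ir.compare_feature_by_group(feats, prof)
        for _, row in out.iterrows():
            p = row["p_value"]
            expected = "***" if p < 0.001 else "**" if p < 0.01 else \
                "*" if p < 0.05 else ""
            assert row["stars"] == expected
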