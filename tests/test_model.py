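import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import irgpsig as ir
from irgpsig.model import LassoCoxConfig, breslow_loglik, fit_lasso_cox

from conftest import monotone_warp, random_survival


def _features(rng, n, specs):
    """Binary feature matrix and survival driven by given log-hazard effects."""
    cols = {}
    lp = np.zeros(n)
    for name, effect in specs:
        x = (rng.random(n) < 0.5).astype(float)
        cols[name] = x
        lp += effect * x
    t = rng.exponential(1.0, n) * np.exp(-lp)
    clin = pd.DataFrame({"time": np.maximum(t, 1e-9), "event": 1},
                        index=[f"S{i}" for i in range(n)])
    return pd.DataFrame(cols, index=clin.index), clin


class TestFitLassoCox:
    def test_path_maximum_shrinks_everything(self, rng):
        x, clin = _features(rng, 120, [("a", 1.0), ("b", 0.0), ("c", -0.5)])
        path = fit_lasso_cox(x, clin, LassoCoxConfig(cv_folds=3, repeats=1))
        assert np.all(path.coefs[:, 0] == 0.0)  # largest penalty: empty model

    def test_small_penalty_approaches_unpenalized_fit(self, rng):
        x, clin = _features(rng, 400, [("strong", 1.2), ("noise", 0.0)])
        cfg = LassoCoxConfig(cv_folds=3, alpha_min_ratio=1e-4)
        path = fit_lasso_cox(x, clin, cfg)
        df = x.copy()
        df["time"], df["event"] = clin["time"], clin["event"]
        ref = CoxPHFitter().fit(df, "time", "event").params_["strong"]
        assert path.coefs[0, -1] == pytest.approx(ref, rel=0.05)

    def test_cv_curve_is_deterministic_given_seed(self, rng):
        x, clin = _features(rng, 100, [("a", 1.0), ("b", 0.0), ("c", 0.3)])
        cfg = LassoCoxConfig(cv_folds=4, seed=42)
        p1 = fit_lasso_cox(x, clin, cfg)
        p2 = fit_lasso_cox(x, clin, cfg)
        assert np.array_equal(p1.cv_deviance, p2.cv_deviance)
        assert p1.best_index == p2.best_index

    def test_zero_events_rejected(self, rng):
        x, clin = _features(rng, 50, [("a", 0.5), ("b", 0.0)])
        clin["event"] = 0
        with pytest.raises(ValueError, match="event"):
            fit_lasso_cox(x, clin, LassoCoxConfig(cv_folds=3))

    def test_constant_feature_dropped_with_warning(self, rng):
        x, clin = _features(rng, 100, [("a", 1.0), ("b", 0.0)])
        x["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            path = fit_lasso_cox(x, clin, LassoCoxConfig(cv_folds=3))
        assert "flat" not in path.feature_names


class TestBreslowLoglik:
    def test_matches_direct_enumeration(self, rng):
        # 4 subjects, no ties: partial likelihood has a closed form
        x = rng.normal(size=(4, 2))
        beta = np.array([0.3, -0.7])
        time = np.array([4.0, 3.0, 2.0, 1.0])
        event = np.array([1, 0, 1, 1])
        eta = x @ beta
        expected = 0.0
        for i in np.flatnonzero(event):
            risk = eta[time >= time[i]]
            expected += eta[i] - np.log(np.exp(risk).sum())
        assert breslow_loglik(beta, x, time, event) == pytest.approx(expected)


class TestStabilitySelect:
    def test_recovers_planted_features(self, rng):
        specs = [("sig1", 1.3), ("sig2", 1.3), ("sig3", -1.3)] + \
            [(f"noise{i}", 0.0) for i in range(27)]
        x, clin = _features(rng, 300, specs)
        sig = ir.stability_select(x, clin, LassoCoxConfig(repeats=20, seed=5))
        names = {a for a, _, _ in sig.entries}
        assert {"sig1", "sig2", "sig3"} <= names

    def test_single_repeat_reduces_to_one_fit(self, rng):
        x, clin = _features(rng, 200, [("a", 1.5), ("b", 0.0), ("c", 0.0)])
        cfg = LassoCoxConfig(repeats=1, seed=9)
        sig = ir.stability_select(x, clin, cfg)
        path = fit_lasso_cox(x, clin, cfg)
        assert {a for a, _, _ in sig.entries} == path.support

    def test_pure_noise_raises_empty_support(self):
        rng = np.random.default_rng(0)
        specs = [(f"noise{i}", 0.0) for i in range(10)]
        x, clin = _features(rng, 120, specs)
        with pytest.raises(ValueError, match="empty"):
            ir.stability_select(x, clin, LassoCoxConfig(repeats=5, seed=1))

    def test_effect_signs_point_the_right_way(self, rng):
        x, clin = _features(rng, 300, [("up", 1.5), ("down", -1.5), ("z", 0.0)])
        sig = ir.stability_select(x, clin, LassoCoxConfig(repeats=5, seed=1))
        coefs = {a: c for a, _, c in sig.entries}
        assert coefs["up"] > 0 > coefs["down"]


class TestRiskScore:
    def test_published_signature_patterns(self):
        sig = ir.load_pancreatic_signature()
        assert len(sig) == 18
        none_on = ir.exemplar_expression(sig, active=[])
        one_on = ir.exemplar_expression(sig, active=[("ERAP2", "SSTR1")])
        all_on = ir.exemplar_expression(sig, active=sig.pairs)
        assert ir.risk_score(sig, none_on).scores[0] == pytest.approx(0.0)
        assert ir.risk_score(sig, one_on).scores[0] == pytest.approx(0.739)
        assert ir.risk_score(sig, all_on).scores[0] == pytest.approx(1.093)

    def test_missing_gene_is_named(self):
        sig = ir.Signature([("A", "B", 0.5)])
        m = pd.DataFrame({"S1": [1.0]}, index=["A"])
        with pytest.raises(KeyError, match="B"):
            ir.risk_score(sig, m)

    def test_rank_invariance_of_scores(self, rng):
        sig = ir.Signature([("G0", "G1", 0.7), ("G2", "G3", -0.4)])
        m = pd.DataFrame(np.exp(rng.normal(size=(4, 10))),
                         index=["G0", "G1", "G2", "G3"],
                         columns=[f"S{i}" for i in range(10)])
        warped = m.copy()
        for col in warped.columns:
            warped[col] = monotone_warp(rng, warped[col].to_numpy())
        a = ir.risk_score(sig, m).scores
        b = ir.risk_score(sig, warped).scores
        np.testing.assert_array_equal(a, b)

    def test_serialization_round_trip_preserves_scores(self, tmp_path, rng):
        sig = ir.Signature([("G0", "G1", 0.7231), ("G2", "G3", -0.4189)],
                           {"seed": 1, "repeats": 10})
        m = pd.DataFrame(np.exp(rng.normal(size=(4, 6))),
                         index=["G0", "G1", "G2", "G3"],
                         columns=[f"S{i}" for i in range(6)])
        sig.write(tmp_path / "sig.tsv")
        back = ir.Signature.read(tmp_path / "sig.tsv")
        assert back.entries == sig.entries
        assert back.provenance["repeats"] == 10
        np.testing.assert_array_equal(ir.risk_score(sig, m).scores,
                                      ir.risk_score(back, m).scores)

    def test_signature_validation(self):
        with pytest.raises(ValueError):
            ir.Signature([("A", "B", 0.0)])
        with pytest.raises(ValueError):
            ir.Signature([("A", "B", 0.5), ("A", "B", 0.2)])
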