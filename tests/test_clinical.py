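"""Survival screening, dichotomization, multivariable models, classifiers."""

import numpy as np
import pandas as pd
import pytest

import morphoctx as m


def _surv_frame(time, event, **cov):
    return pd.DataFrame({"time": time, "event": event, **cov})


def _two_group_exponential(n, hr, censor=0.0, seed=0, rate=0.1):
    labels = np.repeat([1, 2], n // 2)
    t, e = m.simulate_survival(labels, {1: 0.0, 2: float(np.log(hr))}, rate, censor, seed)
    return labels, _surv_frame(t, e)


class TestCoxUnivariate:
    def test_null_feature(self):
        rng = np.random.default_rng(0)
        t, e = m.simulate_survival([1] * 2000, {1: 0.0}, 0.1, 0.2, seed=1)
        res = m.cox_univariate(rng.normal(size=2000), _surv_frame(t, e))
        assert 0.9 <= res.hr <= 1.1
        assert res.ci_low <= res.hr <= res.ci_high

    def test_recovers_planted_hazard_ratio(self):
        """Mean estimated HR across seeds within 5% of the planted HR 2."""
        hrs = []
        for seed in range(20):
            labels, surv = _two_group_exponential(2000, 2.0, censor=0.2, seed=seed)
            hrs.append(m.cox_univariate((labels == 2).astype(float), surv).hr)
        assert np.mean(hrs) == pytest.approx(2.0, rel=0.05)

    def test_degenerate_inputs_rejected(self):
        surv = _surv_frame([1.0, 2.0, 3.0], [0, 0, 0])
        with pytest.raises(ValueError):
            m.cox_univariate(np.array([1.0, 2.0, 3.0]), surv)
        surv = _surv_frame([1.0, 2.0, 3.0], [1, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            m.cox_univariate(np.ones(3), surv)


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert m.fdr_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_evaluated_step_up(self):
        q = m.fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_saturate(self):
        assert (m.fdr_adjust(np.ones(5)) == 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            m.fdr_adjust(np.array([0.1, 1.5]))

    def test_matches_brute_force_definition(self):
        """q_i = min over j with p_j >= p_i of m * p_j / rank_j, capped at 1."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            mlen = rng.integers(1, 21)
            p = rng.uniform(size=mlen)
            order = np.argsort(p)
            ranked = p[order]
            raw = mlen * ranked / np.arange(1, mlen + 1)
            stepped = np.minimum.accumulate(raw[::-1])[::-1]
            expect = np.empty(mlen)
            expect[order] = np.minimum(stepped, 1.0)
            assert np.allclose(m.fdr_adjust(p), expect)


class TestDichotomize:
    def test_median_split(self):
        x = np.arange(1.0, 101.0)
        t, e = m.simulate_survival([1] * 100, {1: 0.0}, 0.1, 0.0, seed=0)
        labels, cut = m.dichotomize(x, _surv_frame(t, e), method="median")
        assert (labels == "low").sum() == 50 and (labels == "high").sum() == 50

    def test_maxrank_recovers_planted_threshold(self):
        rng = np.random.default_rng(1)
        n = 500
        x = rng.uniform(size=n)
        thresh = np.quantile(x, 0.6)
        lp = np.where(x > thresh, np.log(2), 0.0)
        t, e = m.simulate_survival_from_loghazard(lp, 0.1, 0.0, seed=2)
        _, cut = m.dichotomize(x, _surv_frame(t, e), method="maxrank")
        cut_pctile = (x <= cut).mean()
        assert abs(cut_pctile - 0.6) <= 0.05

    def test_group_size_constraint(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        t, e = m.simulate_survival([1] * 100, {1: 0.0}, 0.1, 0.0, seed=3)
        labels, _ = m.dichotomize(x, _surv_frame(t, e), min_group=0.1)
        assert (labels == "high").sum() >= 10 and (labels == "low").sum() >= 10

    def test_constant_feature_rejected(self):
        t, e = m.simulate_survival([1] * 20, {1: 0.0}, 0.1, 0.0, seed=0)
        with pytest.raises(ValueError):
            m.dichotomize(np.ones(20), _surv_frame(t, e))


class TestKmLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        e = np.array([1, 1, 0, 1] * 2)
        groups = np.repeat(["a", "b"], 4)
        _, stat, p = m.km_logrank(groups, _surv_frame(t, e))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_large_effect_power(self):
        labels, surv = _two_group_exponential(400, 4.0, seed=5)
        _, _, p = m.km_logrank(labels, surv)
        assert p < 1e-6

    def test_product_limit_reaches_zero(self):
        t = np.array([1.0, 2.0, 5.0, 9.0])
        curves, _, _ = m.km_logrank(
            np.array(["a", "a", "a", "b"]), _surv_frame(t, np.ones(4, int))
        )
        assert curves["a"]["survival"].iloc[-1] == pytest.approx(0.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            m.km_logrank(np.array(["a", "a"]), _surv_frame([1.0, 2.0], [1, 1]))


class TestCoxMultivariable:
    def test_bypass_equals_simultaneous_fit(self):
        rng = np.random.default_rng(6)
        n = 300
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        t, e = m.simulate_survival_from_loghazard(0.5 * x1, 0.1, 0.2, seed=7)
        surv = _surv_frame(t, e, x1=x1, x2=x2)
        model, results = m.cox_multivariable(surv, ["x1", "x2"], selection="none")
        from lifelines import CoxPHFitter

        direct = CoxPHFitter().fit(surv, "time", "event")
        for r in results:
            assert r.hr == pytest.approx(float(np.exp(direct.params_[r.name])), rel=1e-6)

    def test_collinear_pair_named(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=100)
        t, e = m.simulate_survival([1] * 100, {1: 0.0}, 0.1, 0.0, seed=8)
        surv = _surv_frame(t, e, a=x, b=2 * x, c=rng.normal(size=100))
        with pytest.raises(ValueError, match="'a'|'b'"):
            m.cox_multivariable(surv, ["a", "b", "c"])

    def test_stepwise_keeps_signal_drops_noise(self):
        kept_true, kept_noise = 0, 0
        n_runs = 10
        for seed in range(n_runs):
            rng = np.random.default_rng(100 + seed)
            n = 600
            x = rng.normal(size=n)
            noise = {f"z{i}": rng.normal(size=n) for i in range(5)}
            t, e = m.simulate_survival_from_loghazard(np.log(2) * x, 0.1, 0.2, seed=seed)
            surv = _surv_frame(t, e, x=x, **noise)
            try:
                _, results = m.cox_multivariable(
                    surv, ["x", *noise], selection="stepwise_aic"
                )
            except ValueError:
                continue
            names = {r.name for r in results}
            kept_true += "x" in names
            kept_noise += len(names - {"x"})
        assert kept_true >= 0.9 * n_runs
        assert kept_noise / n_runs <= 1.0

    def test_adjusted_subtype_effect_recovered(self):
        rng = np.random.default_rng(9)
        n = 800
        subtype = rng.integers(0, 2, n).astype(float)
        # stage correlated with subtype
        stage = np.clip(subtype + rng.integers(0, 3, n), 0, 3).astype(float)
        lp = np.log(2.5) * subtype + 0.2 * stage
        t, e = m.simulate_survival_from_loghazard(lp, 0.1, 0.3, seed=10)
        surv = _surv_frame(t, e, subtype=subtype, stage=stage)
        _, results = m.cox_multivariable(surv, ["subtype", "stage"], selection="none")
        sub = next(r for r in results if r.name == "subtype")
        assert sub.q < 0.05
        assert sub.hr == pytest.approx(2.5, rel=0.25)


class TestBootstrapClassifierEval:
    def test_chance_level_on_independent_labels(self):
        rng = np.random.default_rng(10)
        ev = m.bootstrap_classifier_eval(
            rng.normal(size=(200, 2)), rng.integers(0, 2, 200), n_boot=100, seed=3
        )
        assert 0.45 <= ev.auc <= 0.55

    def test_binormal_auc_closed_form(self):
        """Classes shifted by 2 with unit SD: AUC = Phi(2/sqrt(2)) = 0.921."""
        rng = np.random.default_rng(11)
        n = 400
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(0, 1, n) + 2.0 * y
        ev = m.bootstrap_classifier_eval(x, y, n_boot=100, seed=4)
        assert ev.auc == pytest.approx(0.9214, abs=0.03)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(12)
        X, y = rng.normal(size=(100, 3)), rng.integers(0, 2, 100)
        e1 = m.bootstrap_classifier_eval(X, y, n_boot=20, seed=5)
        e2 = m.bootstrap_classifier_eval(X, y, n_boot=20, seed=5)
        assert e1.auc == e2.auc and e1.auc_ci == e2.auc_ci
        assert e1.sensitivity == e2.sensitivity and e1.specificity == e2.specificity

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            m.bootstrap_classifier_eval(np.zeros((10, 1)), np.zeros(10))


class TestSurvivalAucCompare:
    def test_identical_models_zero_delta(self):
        rng = np.random.default_rng(13)
        n = 200
        x = rng.normal(size=n)
        t, e = m.simulate_survival_from_loghazard(0.5 * x, 0.1, 0.2, seed=14)
        surv = _surv_frame(t, e, x=x)
        out = m.survival_auc_compare(surv, ["x"], ["x"], [5.0, 10.0], n_boot=20, seed=0)
        assert np.allclose(out["delta"], 0.0)
        assert (out["p"] == 1.0).all()

    def test_planted_signal_detected(self):
        rng = np.random.default_rng(14)
        n = 1000
        subtype = rng.integers(0, 2, n).astype(float)
        z = rng.normal(size=n)
        t, e = m.simulate_survival_from_loghazard(np.log(2) * subtype, 0.1, 0.2, seed=15)
        surv = _surv_frame(t, e, subtype=subtype, z=z)
        horizon = float(np.median(t))
        out = m.survival_auc_compare(
            surv, ["subtype", "z"], ["z"], [horizon], n_boot=100, seed=1
        )
        assert out["p"].iloc[0] < 0.05
        assert out["delta"].iloc[0] > 0

    def test_noise_model_chance_auc(self):
        rng = np.random.default_rng(100)
        n = 1000
        z = rng.normal(size=n)
        t, e = m.simulate_survival_from_loghazard(np.zeros(n), 0.1, 0.2, seed=200)
        surv = _surv_frame(t, e, z=z, w=rng.normal(size=n))
        horizons = [float(np.quantile(t, 0.4)), float(np.quantile(t, 0.6))]
        out = m.survival_auc_compare(surv, ["z", "w"], ["z"], horizons, n_boot=40, seed=2)
        assert ((out["auc_full"] > 0.45) & (out["auc_full"] < 0.55)).all()

    def test_horizon_beyond_followup_rejected(self):
        surv = _surv_frame([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], x=[0.0, 1.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="horizon"):
            m.survival_auc_compare(surv, ["x"], ["x"], [10.0], n_boot=5)


class TestScreenBiomarkers:
    def test_constant_column_reported_nan(self):
        rng = np.random.default_rng(16)
        n = 150
        ctx = pd.DataFrame({"CMB_1": rng.normal(size=n), "CMB_2": np.ones(n)})
        t, e = m.simulate_survival_from_loghazard(np.zeros(n), 0.1, 0.2, seed=17)
        out = m.screen_biomarkers(ctx, _surv_frame(t, e))
        assert np.isnan(out.loc[out["biomarker"] == "CMB_2", "hr"]).all()
        assert out.loc[out["biomarker"] == "CMB_1", "q"].notna().all()

    def test_type_i_error_controlled(self):
        """Null biomarkers yield few FDR discoveries."""
        rng = np.random.default_rng(17)
        n = 200
        ctx = pd.DataFrame(rng.normal(size=(n, 40)),
                           columns=[f"CMB_{j}" for j in range(1, 41)])
        t, e = m.simulate_survival_from_loghazard(np.zeros(n), 0.1, 0.2, seed=18)
        out = m.screen_biomarkers(ctx, _surv_frame(t, e))
        assert (out["q"] < 0.05).mean() <= 0.05
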