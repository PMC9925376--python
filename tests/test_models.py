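"""Inference layer: GEE, cluster-robust Cox, Wald tests, KM medians, power."""
import numpy as np
import pandas as pd
import pytest

from pgxreg import models as mo


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _binary_records(n, rng, beta=0.8):
    score = rng.integers(1, 7, n)
    x = (score >= 5).astype(float)
    y = rng.random(n) < _sigmoid(-1.0 + beta * x)
    return pd.DataFrame({
        "person_id": np.arange(n),
        "event": y.astype(int),
        "activity_score": score,
        "sex": np.where(rng.random(n) < 0.5, "female", "male"),
        "wave": rng.integers(1, 4, n),
        "age_at_start": rng.uniform(20, 70, n),
    })


def _survival_records(n, rng, log_hr=0.0, base=0.01, cap=200.0, score=None):
    if score is None:
        score = rng.integers(1, 7, n)
    t = rng.exponential(1.0 / (base * np.exp(log_hr * (score - 3))))
    return pd.DataFrame({
        "person_id": np.arange(n),
        "event": (t <= cap).astype(int),
        "time_days": np.minimum(t, cap),
        "activity_score": score,
        "sex": np.where(rng.random(n) < 0.5, "female", "male"),
        "wave": rng.integers(1, 4, n),
        "age_at_start": rng.uniform(20, 70, n),
    })


SPEC_TREND_BARE = mo.ModelSpec(coding="activity_score", covariates=())


class TestGEE:
    def test_singleton_clusters_equal_plain_logistic(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(1)
        recs = _binary_records(800, rng)
        spec = mo.ModelSpec(outcome="nonpersistence", coding="activity_score",
                            covariates=("age_at_start",))
        res = mo.fit_gee_logistic(recs, spec)
        X = sm.add_constant(recs[["activity_score", "age_at_start"]].astype(float))
        glm = sm.GLM(recs["event"], X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            res.params[["activity_score", "age_at_start"]],
            glm.params[["activity_score", "age_at_start"]], rtol=1e-5)

    def test_requires_both_outcome_classes(self):
        rng = np.random.default_rng(2)
        recs = _binary_records(50, rng)
        recs["event"] = 1
        with pytest.raises(ValueError, match="event"):
            mo.fit_gee_logistic(recs, mo.ModelSpec(outcome="nonpersistence",
                                                   coding="activity_score",
                                                   covariates=()))

    def test_separation_is_an_error(self):
        rng = np.random.default_rng(3)
        recs = _binary_records(200, rng)
        recs["event"] = (recs["activity_score"] >= 4).astype(int)
        with pytest.raises(ValueError, match="separation"):
            mo.fit_gee_logistic(recs, mo.ModelSpec(outcome="nonpersistence",
                                                   coding="activity_score",
                                                   covariates=()))


class TestCox:
    def test_two_group_hazard_ratio_recovered(self):
        rng = np.random.default_rng(4)
        score = rng.integers(3, 5, 5000)  # two groups, one score step apart
        recs = _survival_records(5000, rng, log_hr=np.log(2.0), score=score)
        res = mo.fit_cox_clustered(recs, SPEC_TREND_BARE)
        hr = float(np.exp(res.params["activity_score"]))
        assert 1.85 <= hr <= 2.15

    def test_no_events_is_an_error(self):
        rng = np.random.default_rng(5)
        recs = _survival_records(50, rng)
        recs["event"] = 0
        with pytest.raises(ValueError, match="events"):
            mo.fit_cox_clustered(recs, SPEC_TREND_BARE)

    def test_constant_exposure_is_an_error(self):
        rng = np.random.default_rng(6)
        recs = _survival_records(100, rng, score=np.full(100, 3))
        with pytest.raises(ValueError, match="variation"):
            mo.trend_cox(recs, SPEC_TREND_BARE)

    def test_score_inversion_inverts_hazard_ratio(self):
        rng = np.random.default_rng(7)
        recs = _survival_records(2000, rng, log_hr=np.log(1.4))
        hr = np.exp(mo.trend_cox(recs, SPEC_TREND_BARE).params["activity_score"])
        flipped = recs.assign(activity_score=7 - recs["activity_score"])
        hr_inv = np.exp(mo.trend_cox(flipped, SPEC_TREND_BARE).params["activity_score"])
        np.testing.assert_allclose(hr_inv, 1.0 / hr, rtol=1e-6)

    def test_robust_se_close_to_model_se_for_singletons(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(8)
        recs = _survival_records(2000, rng, log_hr=np.log(1.3))
        res = mo.fit_cox_clustered(recs, SPEC_TREND_BARE)
        plain = CoxPHFitter().fit(
            recs[["time_days", "event", "activity_score"]],
            duration_col="time_days", event_col="event")
        ratio = (res.summary.loc["activity_score", "se"]
                 / plain.summary.loc["activity_score", "se(coef)"])
        assert 0.9 <= ratio <= 1.1

    def test_wave_dropped_when_a_wave_has_no_events(self):
        rng = np.random.default_rng(9)
        recs = _survival_records(300, rng)
        recs.loc[recs["wave"] == 2, "event"] = 0
        spec = mo.ModelSpec(coding="activity_score")
        with pytest.warns(UserWarning, match="wave"):
            res = mo.fit_cox_clustered(recs, spec)
        assert not any(t.startswith("wave") for t in res.params.index)

    def test_categorical_coding_requires_reference_level(self):
        rng = np.random.default_rng(10)
        recs = _survival_records(100, rng)
        recs["phenotype"] = "PM"
        with pytest.raises(ValueError, match="reference"):
            mo.fit_cox_clustered(recs, mo.ModelSpec(coding="categorical6",
                                                    covariates=()))


class TestWaldInteraction:
    def _fit_pair(self, rng, beta_int):
        n = 3000
        score = rng.integers(1, 7, n)
        mono = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.01 * np.exp(
            0.1 * (score - 3) + beta_int * mono * (score - 3))))
        recs = pd.DataFrame({
            "person_id": np.arange(n), "event": (t <= 200).astype(int),
            "time_days": np.minimum(t, 200.0),
            "activity_score": score, "monotherapy_flag": mono,
        })
        full = mo.fit_cox_clustered(recs, mo.ModelSpec(
            coding="activity_score", covariates=(), interaction_monotherapy=True))
        reduced = mo.fit_cox_clustered(recs, SPEC_TREND_BARE)
        return full, reduced

    def test_identical_models_give_p_one(self):
        rng = np.random.default_rng(11)
        recs = _survival_records(200, rng)
        res = mo.fit_cox_clustered(recs, SPEC_TREND_BARE)
        assert mo.wald_interaction_test(res, res) == 1.0

    def test_non_nested_models_error(self):
        rng = np.random.default_rng(12)
        recs = _survival_records(200, rng)
        a = mo.fit_cox_clustered(recs, SPEC_TREND_BARE)
        b = mo.fit_cox_clustered(recs, mo.ModelSpec(coding="activity_score",
                                                    covariates=("age_at_start",)))
        with pytest.raises(ValueError, match="nested"):
            mo.wald_interaction_test(a, b)

    def test_strong_interaction_detected(self):
        full, reduced = self._fit_pair(np.random.default_rng(13), beta_int=0.5)
        assert mo.wald_interaction_test(full, reduced) < 0.01


class TestKMMedian:
    def test_exponential_median_closed_form(self):
        rng = np.random.default_rng(14)
        lam = 0.01
        t = rng.exponential(1 / lam, 20000)
        assert abs(mo.km_median(t) - np.log(2) / lam) < 2.0

    def test_all_censored_is_absent(self):
        assert mo.km_median([5.0, 8.0], events=[0, 0]) is None

    def test_single_event(self):
        assert mo.km_median([10.0], events=[1]) == 10.0


class TestSampleSize:
    def test_schoenfeld_events_derived_example(self):
        # (z_0.975 + z_0.8)^2 / (0.25 * ln(2)^2) ≈ 65.3 events
        assert mo.cox_sample_size(2.0, 0.5, 1.0) == 66

    def test_monotonicity_and_symmetry(self):
        n = mo.cox_sample_size
        assert n(1.2, 0.036, 0.5) > n(1.5, 0.036, 0.5) > n(2.0, 0.036, 0.5)
        assert n(1.2, 0.036, 0.5) > n(1.2, 0.036, 0.9)
        assert n(1.2, 0.036, 0.5, power=0.9) > n(1.2, 0.036, 0.5, power=0.8)
        assert n(1.3, 0.2, 0.5) == n(1.3, 0.8, 0.5)

    @pytest.mark.parametrize("kwargs", [
        dict(hazard_ratio=1.0, exposed_proportion=0.1, event_rate=0.5),
        dict(hazard_ratio=-2.0, exposed_proportion=0.1, event_rate=0.5),
        dict(hazard_ratio=1.2, exposed_proportion=0.0, event_rate=0.5),
        dict(hazard_ratio=1.2, exposed_proportion=0.1, event_rate=0.0),
    ])
    def test_invalid_specifications(self, kwargs):
        with pytest.raises(ValueError):
            mo.cox_sample_size(**kwargs)
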