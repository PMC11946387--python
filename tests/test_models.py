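"""Logistic pCR models: fitting, AUC, cross-validated predictor selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from ftvresponse.models import (
    candidate_predictor_sets,
    complete_records,
    compute_auc,
    fit_logistic,
    model_from_json,
    model_to_json,
    select_model,
)
from ftvresponse.synthetic import PatientRecord, Subtype

from conftest import brute_force_auc


def make_records(x2, y, x1=None, x0=None):
    """Records with dftv_t2 = x2 (and optional dftv_t1 / ftv_t0 columns)."""
    n = len(x2)
    x1 = np.zeros(n) if x1 is None else x1
    x0 = np.full(n, 10.0) if x0 is None else x0
    return [
        PatientRecord(
            patient_id=f"r{i}",
            subtype=Subtype.TRIPLE_NEG,
            pcr=bool(y[i]),
            ftv_t0=float(x0[i]),
            dftv_t1=float(np.clip(x1[i], -100, None)),
            dftv_t2=float(np.clip(x2[i], -100, None)),
        )
        for i in range(n)
    ]


class TestComputeAuc:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_small_example_all_pairs(self):
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        labels = [1, 1, 1, 0, 0, 0]
        assert compute_auc(scores, labels) == pytest.approx(8 / 9)

    def test_null_scores_near_half(self, rng):
        scores = rng.random(10_000)
        labels = rng.random(10_000) < 0.4
        assert compute_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([0.1, 0.9], [1, 1])

    @given(
        st.lists(
            st.tuples(st.integers(0, 20), st.booleans()),
            min_size=2,
            max_size=200,
        ).filter(lambda v: len({b for _, b in v}) == 2)
    )
    def test_matches_all_pairs_count_with_ties(self, pairs):
        scores = [s / 20 for s, _ in pairs]
        labels = [b for _, b in pairs]
        assert compute_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_agrees_with_sklearn(self, rng):
        scores = rng.choice(np.linspace(0, 1, 17), size=500)
        labels = rng.random(500) < 0.3
        assert compute_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.5
        a = compute_auc(scores, labels)
        assert compute_auc(np.exp(scores), labels) == pytest.approx(a, abs=1e-12)
        assert compute_auc(3 * scores - 7, labels) == pytest.approx(a, abs=1e-12)


class TestFitLogistic:
    def test_null_predictor_coefficient_near_zero(self, rng):
        n = 5000
        x = rng.normal(-50, 20, n)
        y = rng.random(n) < 0.4  # independent of x
        model = fit_logistic(make_records(x, y), ("dftv_t2",))
        # SE of the slope in a null logistic ~ 1/(sd(x) * sqrt(n p(1-p)))
        se = 1 / (x.std() * np.sqrt(n * 0.4 * 0.6))
        assert abs(model.coefficients["dftv_t2"]) < 3 * se

    def test_parameter_recovery(self, rng):
        n = 20_000
        x = rng.normal(-50, 30, n)
        y = rng.random(n) < expit(-1 + 0.05 * x)
        model = fit_logistic(make_records(x, y), ("dftv_t2",))
        assert model.intercept == pytest.approx(-1.0, rel=0.10)
        assert model.coefficients["dftv_t2"] == pytest.approx(0.05, rel=0.10)

    def test_intercept_only_predicts_prevalence(self, rng):
        y = np.zeros(100, dtype=bool)
        y[:36] = True
        model = fit_logistic(make_records(rng.normal(size=100), y), ())
        probs = model.predict_proba(make_records(rng.normal(size=5), [0] * 5))
        np.testing.assert_allclose(probs, 0.36, atol=1e-6)

    def test_complete_separation_flagged_but_usable(self):
        x = np.array([-90.0] * 10 + [-10.0] * 10)
        y = np.array([1] * 10 + [0] * 10)
        model = fit_logistic(make_records(x, y), ("dftv_t2",))
        assert model.separation_flag
        probs = model.predict_proba(make_records(x, y))
        assert np.all(np.isfinite(probs))
        assert probs[:10].mean() > 0.9 and probs[10:].mean() < 0.1

    def test_single_class_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            fit_logistic(make_records(x, np.ones(10)), ("dftv_t2",))

    def test_undefined_percent_change_records_excluded(self, rng):
        recs = make_records(rng.normal(-50, 20, 50), rng.random(50) < 0.5)
        nan_rec = PatientRecord("x", Subtype.TRIPLE_NEG, True, 10.0,
                                float("nan"), float("nan"))
        assert len(complete_records(recs + [nan_rec])) == len(recs)

    def test_binormal_auc_matches_closed_form(self, rng):
        """Single binormal predictor: AUC converges to Phi(delta/(sigma*sqrt2))."""
        n = 50_000
        mu1, mu0, sd = -80.0, -50.0, 25.0
        y = rng.random(n) < 0.4
        x = np.where(y, rng.normal(mu1, sd, n), rng.normal(mu0, sd, n))
        # higher score = more likely pCR; the model direction is -x
        auc = compute_auc(-x, y)
        expected = norm.cdf(abs(mu1 - mu0) / (sd * np.sqrt(2)))
        assert auc == pytest.approx(expected, abs=0.02)


class TestSelectModel:
    def test_candidate_enumeration(self):
        cands = candidate_predictor_sets()
        assert len(cands) == 7
        assert cands[0] == ("dftv_t1",)
        assert cands[-1] == ("dftv_t1", "dftv_t2", "ftv_t0")

    def test_single_candidate_returned_unchanged(self, rng):
        x = rng.normal(-50, 20, 200)
        y = rng.random(200) < expit(-(x + 50) / 10)
        model = select_model(make_records(x, y), candidates=[("dftv_t2",)],
                             k_folds=5, seed=0)
        assert model.predictors == ("dftv_t2",)

    def test_pure_noise_cv_auc_near_half(self, rng):
        n = 600
        recs = make_records(
            rng.normal(size=n), rng.random(n) < 0.4,
            x1=rng.normal(size=n), x0=rng.lognormal(3, 1, n),
        )
        model = select_model(recs, k_folds=5, seed=1)
        assert model.cv_auc[model.predictors] == pytest.approx(0.5, abs=0.05)

    def test_signal_predictor_selected(self, rng):
        """When only the T2 change carries outcome signal, selection should
        almost always return exactly {dftv_t2}."""
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            n = 400
            x2 = r.normal(-60, 30, n)
            y = r.random(n) < expit(-3.5 - 0.05 * x2)
            if y.sum() < 5 or y.sum() > n - 5:
                continue
            recs = make_records(x2, y, x1=r.normal(-30, 30, n),
                                x0=r.lognormal(3, 1, n))
            model = select_model(recs, k_folds=5, seed=rep)
            hits += model.predictors == ("dftv_t2",)
        assert hits / n_rep > 0.9

    def test_in_sample_selection_mode(self, rng):
        n = 300
        x = rng.normal(-50, 25, n)
        y = rng.random(n) < expit(-(x + 50) / 15)
        recs = make_records(x, y, x1=rng.normal(size=n))
        model = select_model(recs, k_folds=5, seed=3, cv=False)
        # in-sample AUC of the winner is at least the single-predictor's
        assert model.cv_auc[model.predictors] >= 0.5
        assert model.predictors in model.cv_auc

    def test_order_invariance(self, rng):
        n = 300
        x = rng.normal(-50, 25, n)
        y = rng.random(n) < expit(-(x + 50) / 15)
        recs = make_records(x, y, x1=rng.normal(size=n))
        m1 = select_model(recs, k_folds=5, seed=4)
        perm = rng.permutation(n)
        m2 = select_model([recs[i] for i in perm], k_folds=5, seed=4)
        assert m1.predictors == m2.predictors
        for p in m1.predictors:
            assert m1.coefficients[p] == pytest.approx(m2.coefficients[p], rel=1e-6)

    def test_too_few_minority_records_rejected(self, rng):
        x = rng.normal(size=20)
        y = np.zeros(20, dtype=bool)
        y[:3] = True
        with pytest.raises(ValueError, match="minority"):
            select_model(make_records(x, y), k_folds=5, seed=0)


def test_model_json_roundtrip(tmp_path, rng):
    x = rng.normal(-50, 25, 200)
    y = rng.random(200) < expit(-(x + 50) / 15)
    model = select_model(make_records(x, y), k_folds=3, seed=2, scope="TN")
    path = tmp_path / "model.json"
    model_to_json(model, path)
    back = model_from_json(path)
    assert back.scope == "TN"
    assert back.predictors == model.predictors
    assert back.intercept == pytest.approx(model.intercept)
    assert back.cv_auc == pytest.approx(model.cv_auc)
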