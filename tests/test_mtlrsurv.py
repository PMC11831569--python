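"""MTLR survival model: grid, DE selection, likelihood reductions,
prediction invariants, concordance."""

import numpy as np
import pandas as pd
import pytest
from lifelines.utils import concordance_index
from sklearn.linear_model import LogisticRegression

from fibrosen.mtlrsurv import (
    TimeGrid,
    concordance,
    fit_mtlr,
    make_time_grid,
    predict_survival,
    select_de_features,
)
from oracles import brute_harrell_c


def _surv_data(n=80, d=3, beta=None, seed=0, censor_scale=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.zeros(d) if beta is None else np.asarray(beta)
    hazard = 0.01 * np.exp(X @ beta)
    death = rng.exponential(1.0 / hazard)
    if censor_scale:
        censor = rng.exponential(censor_scale, n)
        times = np.minimum(death, censor)
        events = (death <= censor).astype(int)
    else:
        times, events = death, np.ones(n, dtype=int)
    return X, times, events


class TestTimeGrid:
    def test_sqrt_events_rule(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, 100)
        grid = make_time_grid(times, np.ones(100, dtype=int))
        assert grid.m == 10

    def test_boundaries_increasing_subset(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        grid = make_time_grid(times, np.ones(4, dtype=int))
        b = np.asarray(grid.boundaries)
        assert np.all(np.diff(b) > 0)
        assert b.min() >= 1.0 and b.max() <= 4.0

    def test_single_event_rejected(self):
        with pytest.raises(ValueError):
            make_time_grid(np.array([5.0, 3.0]), np.array([1, 0]))

    def test_invalid_boundaries_rejected(self):
        with pytest.raises(ValueError):
            TimeGrid(boundaries=(2.0, 1.0))
        with pytest.raises(ValueError):
            TimeGrid(boundaries=(0.0, 1.0))


class TestSelectDeFeatures:
    def test_returns_requested_count(self):
        X, times, events = _surv_data(n=60, d=12, beta=[2, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        expr = pd.DataFrame(X, columns=[f"G{i:02d}" for i in range(12)])
        feats = select_de_features(expr, times, events, n_features=10)
        assert len(feats) == 10

    def test_flat_gene_never_beats_differential_gene(self):
        rng = np.random.default_rng(1)
        n = 60
        times = np.sort(rng.exponential(50, n))
        events = np.ones(n, dtype=int)
        expr = pd.DataFrame(
            {
                "flat": np.zeros(n) + 1e-9 * rng.normal(size=n),
                "prognostic": -np.log(times) + 0.1 * rng.normal(size=n),
            }
        )
        feats = select_de_features(expr, times, events, n_features=1)
        assert feats == ["prognostic"]

    def test_planted_prognostic_genes_dominate(self):
        from fibrosen.icimodel import batch_standardize
        from fibrosen.synthdata import SimConfig, generate_bulk_cohorts

        bulk, truth = generate_bulk_cohorts(SimConfig(seed=2))
        std = batch_standardize(bulk.expression, bulk.clinical["cohort"])
        feats = select_de_features(
            std, bulk.clinical["os_time"], bulk.clinical["os_event"], n_features=10
        )
        planted = set(truth.fss_genes)
        assert sum(f in planted for f in feats) >= 8


class TestMtlrFit:
    def test_m1_reduces_to_ridge_logistic(self):
        for seed in range(20):
            X, times, events = _surv_data(n=100, d=2, beta=[1.0, -0.5], seed=seed)
            t1 = float(np.median(times))
            grid = TimeGrid(boundaries=(t1,))
            params = fit_mtlr(X, times, events, grid, c1=1.0, c2=0.0, tol=1e-7)
            y = (times <= t1).astype(int)
            ref = LogisticRegression(C=1.0, tol=1e-12, max_iter=10000)
            ref.fit(X, y)
            np.testing.assert_allclose(params.theta[0], ref.coef_[0], atol=1e-4)
            np.testing.assert_allclose(params.bias[0], ref.intercept_[0], atol=1e-4)

    def test_all_zero_features_give_identical_curves(self):
        X, times, events = _surv_data(n=50, d=2, seed=3)
        grid = make_time_grid(times, events)
        params = fit_mtlr(np.zeros_like(X), times, events, grid)
        pred = predict_survival(params, np.zeros_like(X))
        assert np.allclose(pred.survival, pred.survival[0])

    def test_no_events_rejected(self):
        X, times, _ = _surv_data(n=30, d=2, seed=4)
        grid = TimeGrid(boundaries=(float(np.median(times)),))
        with pytest.raises(ValueError, match="no events"):
            fit_mtlr(X, times, np.zeros(30, dtype=int), grid)

    def test_ridge_strength_shrinks_weights(self):
        X, times, events = _surv_data(n=100, d=3, beta=[1, 1, 1], seed=5)
        grid = make_time_grid(times, events)
        norms = []
        for c1 in (0.1, 1.0, 10.0):
            params = fit_mtlr(X, times, events, grid, c1=c1)
            norms.append(np.linalg.norm(params.theta))
        assert norms[0] > norms[1] > norms[2]

    def test_censored_fit_converges(self):
        X, times, events = _surv_data(n=120, d=3, beta=[1, 0, -1], seed=6, censor_scale=80)
        assert 0 < events.mean() < 1
        grid = make_time_grid(times, events)
        params = fit_mtlr(X, times, events, grid)
        assert params.converged or params.grad_norm < 1e-4


class TestPredictSurvival:
    def test_probability_simplex_and_monotonicity(self):
        X, times, events = _surv_data(n=60, d=3, beta=[1, 0, -1], seed=7)
        grid = make_time_grid(times, events)
        params = fit_mtlr(X, times, events, grid)
        pred = predict_survival(params, X)
        np.testing.assert_allclose(pred.sequence_probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diff(pred.survival, axis=1) <= 1e-12)
        assert np.all(pred.survival >= -1e-12) and np.all(pred.survival <= 1 + 1e-12)

    def test_m1_risk_equals_logistic_probability(self):
        X, times, events = _surv_data(n=100, d=2, beta=[1.0, 0.5], seed=8)
        t1 = float(np.median(times))
        grid = TimeGrid(boundaries=(t1,))
        params = fit_mtlr(X, times, events, grid, c1=1.0, c2=0.0, tol=1e-7)
        pred = predict_survival(params, X)
        ref = LogisticRegression(C=1.0, tol=1e-12, max_iter=10000)
        ref.fit(X, (times <= t1).astype(int))
        np.testing.assert_allclose(pred.risk, ref.predict_proba(X)[:, 1], atol=1e-4)

    def test_feature_mismatch_rejected(self):
        X, times, events = _surv_data(n=40, d=3, seed=9)
        grid = make_time_grid(times, events)
        params = fit_mtlr(X, times, events, grid)
        with pytest.raises(ValueError, match="feature mismatch"):
            predict_survival(params, X[:, :2])


class TestConcordance:
    def test_perfect_risk_ordering(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.ones(4, dtype=int)
        assert concordance(times, events, -times) == 1.0

    def test_random_risks_near_half(self):
        rng = np.random.default_rng(10)
        cs = []
        for _ in range(10):
            times = rng.exponential(10, 200)
            events = rng.integers(0, 2, 200)
            events[0] = 1
            cs.append(concordance(times, events, rng.normal(size=200)))
        assert np.mean(cs) == pytest.approx(0.5, abs=0.05)

    def test_matches_enumeration_and_lifelines(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = 20
            times = rng.exponential(10, n)
            events = rng.integers(0, 2, n)
            events[0] = 1
            risks = rng.normal(size=n)
            ours = concordance(times, events, risks)
            assert ours == pytest.approx(brute_harrell_c(times, events, risks), abs=1e-12)
            assert ours == pytest.approx(
                concordance_index(times, -risks, events), abs=1e-12
            )

    def test_uno_weighted_variant_runs(self):
        rng = np.random.default_rng(12)
        times = rng.exponential(10, 100)
        censor = rng.exponential(10, 100)
        obs = np.minimum(times, censor)
        events = (times <= censor).astype(int)
        c = concordance(obs, events, -times, method="uno")
        assert 0.5 < c <= 1.0

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance(np.array([1.0, 1.0]), np.array([0, 0]), np.array([1.0, 2.0]))
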