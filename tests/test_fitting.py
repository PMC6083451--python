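import numpy as np
import pandas as pd
import pytest

from ecwm.fitting import (
    GridSpec,
    ResponseMatrix,
    aic,
    assign_response_bin,
    assign_stimulus_bin,
    bin_loglik,
    build_response_matrix,
    compare,
    fit_grid,
    prediction_curves,
    response_edges,
    stimulus_centers,
    trial_cell_counts,
)
from ecwm.neural import PopulationConfig
from ecwm.spa import SPAParams
from ecwm.synthetic import gen_observer


def make_trials(targets, responses, N):
    return pd.DataFrame({
        "subject": "s", "condition": "none", "block": 0,
        "set_size": N, "target": targets,
        "nontargets": [np.zeros(N - 1)] * len(targets),
        "response": responses,
    })


class TestBinning:
    def test_centers_evenly_spaced(self):
        c = stimulus_centers()
        assert len(c) == 25
        assert np.allclose(np.diff(c), 2 * np.pi / 25)

    def test_nearest_center_assignment(self):
        c = stimulus_centers()
        idx = assign_stimulus_bin(c + 0.01)
        assert np.array_equal(idx, np.arange(25))

    def test_wrap_assignment(self):
        # just below -pi side of the first bin edge wraps to last bin center
        idx = assign_stimulus_bin([-np.pi + 0.001])
        assert idx[0] in (0, 24)

    def test_response_bins_partition(self):
        q = assign_response_bin(np.linspace(-np.pi, np.pi - 1e-9, 1000))
        assert q.min() == 0
        assert q.max() == 24


class TestResponseMatrix:
    def test_rows_sum_to_one(self, uniform_config):
        m = build_response_matrix(uniform_config, 1, reps=300, seed=0)
        assert np.allclose(m.probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(m.probs > 0)

    def test_uniform_prior_circulant(self, uniform_config):
        m = build_response_matrix(uniform_config, 1, reps=3000, seed=1)
        # row j approximately equals row 0 shifted by j
        err = max(
            np.abs(np.roll(m.probs[0], j) - m.probs[j]).max()
            for j in range(0, 25, 6)
        )
        assert err < 0.06  # Monte-Carlo bound at 3000 reps

    def test_pure_guessing_spa_rows_uniform(self):
        p = SPAParams(K=1, kappa1=5.0)
        m = build_response_matrix(p, 1000, method="analytic")
        assert np.allclose(m.probs, 1 / 25, atol=1e-3)

    def test_analytic_requires_spa(self, uniform_config):
        with pytest.raises(ValueError):
            build_response_matrix(uniform_config, 1, method="analytic")

    def test_validation(self):
        with pytest.raises(ValueError):
            ResponseMatrix(probs=np.full((25, 25), 1.0), N=1)
        with pytest.raises(ValueError):
            ResponseMatrix(probs=np.ones((3, 3)) / 3, N=1)

    def test_spa_sim_matches_analytic(self):
        p = SPAParams(K=2, kappa1=6.0, eta=0.1, lam=0.3)
        sim = build_response_matrix(p, 4, reps=20000, seed=2, method="simulate")
        ana = build_response_matrix(p, 4, method="analytic")
        assert np.abs(sim.probs - ana.probs).max() < 0.01


class TestBinLoglik:
    def test_uniform_matrix_closed_form(self, rng):
        m = ResponseMatrix(probs=np.full((25, 25), 1 / 25), N=2)
        targets = rng.uniform(-np.pi, np.pi, 100)
        responses = rng.uniform(-np.pi, np.pi, 100)
        trials = make_trials(targets, responses, 2)
        assert bin_loglik({2: m}, trials) == pytest.approx(100 * np.log(1 / 25),
                                                           rel=1e-12)

    def test_empty_table(self):
        assert bin_loglik({}, pd.DataFrame(columns=["set_size", "target",
                                                    "response"])) == 0.0

    def test_doubling_additivity(self, rng):
        m = build_response_matrix(SPAParams(K=3, kappa1=5.0), 2,
                                  method="analytic")
        targets = rng.uniform(-np.pi, np.pi, 50)
        responses = rng.uniform(-np.pi, np.pi, 50)
        t1 = make_trials(targets, responses, 2)
        t2 = pd.concat([t1, t1], ignore_index=True)
        assert bin_loglik({2: m}, t2) == pytest.approx(
            2 * bin_loglik({2: m}, t1), rel=1e-12)

    def test_missing_set_size_errors(self, rng):
        m = build_response_matrix(SPAParams(K=3, kappa1=5.0), 2,
                                  method="analytic")
        trials = make_trials([0.1], [0.2], 4)
        with pytest.raises(KeyError):
            bin_loglik({2: m}, trials)

    def test_brute_force_loop_oracle(self, rng):
        """bin_loglik equals a per-trial lookup loop to 1e-12."""
        m = build_response_matrix(SPAParams(K=3, kappa1=5.0, eta=0.2), 4,
                                  method="analytic")
        targets = rng.uniform(-np.pi, np.pi, 200)
        responses = rng.uniform(-np.pi, np.pi, 200)
        trials = make_trials(targets, responses, 4)
        total = 0.0
        for t, r in zip(targets, responses):
            j = assign_stimulus_bin([t])[0]
            q = assign_response_bin([r])[0]
            total += np.log(m.probs[j, q])
        assert bin_loglik({4: m}, trials) == pytest.approx(total, abs=1e-12)


class TestAic:
    def test_arithmetic_exact(self):
        assert aic(-100.0, 2) == 204.0
        assert aic(-100.0, 4) == 208.0

    def test_identical_loglik_penalty_difference(self):
        assert aic(-50.0, 2) - aic(-50.0, 4) == -4.0


class TestCompare:
    def _fit(self, model_id, ll, p):
        from ecwm.fitting import FitResult
        return FitResult(model_id, {}, ll, aic(ll, p), {})

    def test_delta_sign_convention(self):
        fits = {"a": {"neural": self._fit("neural", -50, 2),
                      "spa": self._fit("spa", -50, 4)}}
        out = compare(fits)
        assert out["per_observer"][0]["delta_aic"] == pytest.approx(-4.0)
        assert out["summed_delta_aic"] == pytest.approx(-4.0)
        assert out["n_prefer_neural"] == 1

    def test_single_observer_sum(self):
        fits = {"a": {"neural": self._fit("neural", -60, 2),
                      "spa": self._fit("spa", -50, 4)}}
        out = compare(fits)
        assert out["summed_delta_aic"] == pytest.approx(
            out["per_observer"][0]["delta_aic"])

    def test_permutation_invariance(self):
        f1 = {"a": {"neural": self._fit("neural", -50, 2),
                    "spa": self._fit("spa", -55, 4)},
              "b": {"neural": self._fit("neural", -70, 2),
                    "spa": self._fit("spa", -60, 4)}}
        f2 = dict(reversed(list(f1.items())))
        assert compare(f1)["summed_delta_aic"] == pytest.approx(
            compare(f2)["summed_delta_aic"])

    def test_requires_both_fits(self):
        with pytest.raises(ValueError):
            compare({"a": {"neural": self._fit("neural", -50, 2)}})


class TestFitGrid:
    def test_spa_recovery_small(self):
        truth = SPAParams(K=2, kappa1=4.0, eta=0.0, lam=0.0)
        trials = gen_observer(truth, [1, 4], 400, seed=7)
        grid = GridSpec(
            neural_kappa=np.array([2.0]), neural_gamma=np.array([50.0]),
            spa_K=np.array([1, 2, 3]), spa_kappa1=np.array([2.0, 4.0, 8.0]),
            spa_eta=np.array([0.0]), spa_lam=np.array([0.0]))
        fit = fit_grid("spa", trials, grid, seed=0)
        assert fit.params["K"] == 2
        assert fit.params["kappa1"] == pytest.approx(4.0)
        assert fit.aic == pytest.approx(aic(fit.loglik, 4))
        assert set(fit.loglik_by_set_size) == {1, 4}

    def test_neural_crn_reproducible(self, default_config):
        trials = gen_observer(default_config, [2], 100, seed=3)
        grid = GridSpec(
            neural_kappa=np.array([1.0, 2.0]),
            neural_gamma=np.array([30.0, 50.0]),
            spa_K=np.array([1]), spa_kappa1=np.array([1.0]),
            spa_eta=np.array([0.0]), spa_lam=np.array([0.0]))
        f1 = fit_grid("neural", trials, grid, seed=9, reps=150)
        f2 = fit_grid("neural", trials, grid, seed=9, reps=150)
        assert f1.params == f2.params
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-12)

    def test_neural_prefers_truth_neighborhood(self, default_config):
        """logL at truth beats a far-away grid point."""
        trials = gen_observer(default_config, [1, 4], 400, seed=5)
        grid = GridSpec(
            neural_kappa=np.array([0.5, 2.0, 8.0]),
            neural_gamma=np.array([10.0, 50.0, 100.0]),
            spa_K=np.array([1]), spa_kappa1=np.array([1.0]),
            spa_eta=np.array([0.0]), spa_lam=np.array([0.0]))
        fit = fit_grid("neural", trials, grid, seed=1, reps=400)
        assert fit.params["kappa"] == pytest.approx(2.0)
        assert fit.params["gamma"] == pytest.approx(50.0)

    def test_model_selection_sanity(self):
        """Strong-guessing SPA data favors SPA over the neural model."""
        truth = SPAParams(K=1, kappa1=8.0)
        wins = 0
        n_obs = 5
        grid = GridSpec(
            neural_kappa=np.array([1.0, 2.0, 4.0]),
            neural_gamma=np.array([20.0, 50.0, 80.0]),
            spa_K=np.array([1, 2]), spa_kappa1=np.array([4.0, 8.0, 12.0]),
            spa_eta=np.array([0.0]), spa_lam=np.array([0.0]))
        for seed in range(n_obs):
            trials = gen_observer(truth, [4], 300, seed=seed)
            f_spa = fit_grid("spa", trials, grid, seed=0)
            f_neu = fit_grid("neural", trials, grid, seed=0, reps=200)
            if f_spa.aic < f_neu.aic:
                wins += 1
        assert wins >= 4

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            fit_grid("spa", pd.DataFrame(columns=["set_size", "target",
                                                  "response"]))

    def test_unknown_family(self, rng):
        trials = make_trials([0.0], [0.0], 1)
        with pytest.raises(ValueError):
            fit_grid("vp", trials)


class TestPredictionCurves:
    def test_uniform_prior_flat_bias(self, uniform_config):
        out = prediction_curves(uniform_config, 1, samples_per_target=50,
                                n_points=16, reps=500, resamples=20, seed=0)
        assert np.abs(out["bias"]).max() < 0.05

    def test_resampling_reduces_variance(self):
        p = SPAParams(K=2, kappa1=4.0)
        many, few = [], []
        for seed in range(6):
            o1 = prediction_curves(p, 2, samples_per_target=30, n_points=4,
                                   reps=2000, resamples=1, seed=seed)
            o2 = prediction_curves(p, 2, samples_per_target=30, n_points=4,
                                   reps=2000, resamples=100, seed=seed)
            few.append(o1["precision"])
            many.append(o2["precision"])
        assert np.var(np.array(many), axis=0).mean() < np.var(
            np.array(few), axis=0).mean()

    def test_full_subsample_equals_no_resampling(self):
        p = SPAParams(K=4, kappa1=6.0)
        o_many = prediction_curves(p, 1, samples_per_target=400, n_points=4,
                                   reps=400, resamples=5, seed=1)
        o_one = prediction_curves(p, 1, samples_per_target=400, n_points=4,
                                  reps=400, resamples=1, seed=1)
        assert np.allclose(o_many["bias"], o_one["bias"], atol=1e-12)
        assert np.allclose(o_many["precision"], o_one["precision"], atol=1e-12)

    def test_rejects_tiny_subsample(self, uniform_config):
        with pytest.raises(ValueError):
            prediction_curves(uniform_config, 1, samples_per_target=1)


class TestGridSpec:
    def test_full_grid_dimensions(self):
        g = GridSpec.full()
        assert len(g.neural_kappa) == 100
        assert len(g.neural_gamma) == 100
        assert g.neural_kappa[0] == pytest.approx(0.1)
        assert g.neural_kappa[-1] == pytest.approx(10.0)
        assert g.neural_gamma[0] == 1.0
        assert g.neural_gamma[-1] == 100.0
        assert len(g.spa_K) == 10
        assert len(g.spa_kappa1) == 100
        assert len(g.spa_eta) == 21
        assert len(g.spa_lam) == 11
        assert g.is_full

    def test_coarse_flagged(self):
        assert not GridSpec.coarse().is_full
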