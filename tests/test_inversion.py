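"""ELM least-squares optimality and the particle-swarm optimiser."""

import numpy as np
import pytest

from canopychl import (
    ConfigurationError,
    PsoConfig,
    elm_fit,
    elm_predict,
    pso_elm_fit,
    pso_minimize,
)
from canopychl.inversion import _hidden_matrix, inertia_at, load_model, save_model
from canopychl.metrics import rmse


def normal_equations_oracle(H, y):
    """Independent least-squares solution via the normal equations."""
    return np.linalg.solve(H.T @ H, H.T @ y)


class TestElm:
    def test_zero_targets_give_zero_weights_and_predictions(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        model = elm_fit(X, np.zeros(10), hidden_count=5, seed=1)
        assert model.output_weights == pytest.approx(np.zeros(5), abs=1e-12)
        assert elm_predict(model, X) == pytest.approx(np.zeros(10), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_output_weights_match_normal_equations(self, seed):
        """On well-conditioned tiny instances the pseudoinverse solution equals
        the normal-equations solution."""
        rng = np.random.default_rng(seed)
        n, d, hidden = 12, 2, 4
        X = rng.normal(size=(n, d))
        y = rng.normal(size=n)
        model = elm_fit(X, y, hidden_count=hidden, seed=seed)
        H = _hidden_matrix(model, X)
        assert model.output_weights == pytest.approx(
            normal_equations_oracle(H, y), abs=1e-8
        )

    def test_residual_is_least_squares_optimal(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        model = elm_fit(X, y, hidden_count=4, seed=3)
        H = _hidden_matrix(model, X)
        base = np.linalg.norm(y - H @ model.output_weights)
        for _ in range(30):
            perturbed = model.output_weights + rng.normal(0, 0.01, size=4)
            assert np.linalg.norm(y - H @ perturbed) >= base - 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_interpolation_when_hidden_at_least_n(self, seed):
        rng = np.random.default_rng(seed + 50)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        model = elm_fit(X, y, hidden_count=10, seed=seed)
        assert rmse(y, elm_predict(model, X)) < 1e-6

    def test_training_row_prediction_matches_fit(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        model = elm_fit(X, y, hidden_count=6, seed=2)
        full = elm_predict(model, X)
        assert elm_predict(model, X[3:4])[0] == pytest.approx(full[3])

    def test_nonfinite_inputs_rejected(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ConfigurationError):
            elm_fit(X, np.zeros(2), 2)

    def test_dimension_mismatch_rejected(self):
        model = elm_fit(np.zeros((4, 3)), np.zeros(4), 2, seed=0)
        with pytest.raises(ConfigurationError):
            elm_predict(model, np.zeros((2, 5)))

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        model = elm_fit(X, y, hidden_count=3, seed=8)
        save_model(model, tmp_path / "elm.json")
        back = load_model(tmp_path / "elm.json")
        assert elm_predict(back, X) == pytest.approx(elm_predict(model, X))


class TestPso:
    def test_swarm_at_optimum_stays_there(self):
        cfg = PsoConfig(pop=4, iterations=10, seed=0, bounds=(-2, 2))
        trace = pso_minimize(
            lambda x: float(np.sum(x**2)), 3, cfg, init_positions=np.zeros((4, 3))
        )
        assert np.all(trace.gbest_fitness == 0.0)

    def test_inertia_schedule_endpoints_and_midpoint(self):
        cfg = PsoConfig(w_schedule=(0.9, 0.3), iterations=100)
        assert inertia_at(cfg, 0) == pytest.approx(0.9)
        assert inertia_at(cfg, 99) == pytest.approx(0.3)
        assert inertia_at(cfg, 49.5) == pytest.approx(0.6)

    def test_constant_schedule(self):
        cfg = PsoConfig(w_schedule=0.7, iterations=10)
        assert inertia_at(cfg, 0) == inertia_at(cfg, 9) == 0.7

    def test_sphere_converges(self):
        cfg = PsoConfig(pop=20, iterations=100, seed=3, bounds=(-5, 5))
        trace = pso_minimize(lambda x: float(np.sum(x**2)), 2, cfg)
        assert trace.best_fitness < 1e-3

    @pytest.mark.parametrize("seed", range(5))
    def test_gbest_never_increases(self, seed):
        cfg = PsoConfig(pop=8, iterations=30, seed=seed, bounds=(-3, 3))
        trace = pso_minimize(
            lambda x: float(np.sum((x - 1.0) ** 2) + 0.5), 4, cfg
        )
        assert np.all(np.diff(trace.gbest_fitness) <= 0)

    def test_nonfinite_fitness_names_particle(self):
        cfg = PsoConfig(pop=3, iterations=2, seed=0)
        with pytest.raises(ConfigurationError, match="particle"):
            pso_minimize(lambda x: float("nan"), 2, cfg)


@pytest.fixture(scope="module")
def regression_problem():
    rng = np.random.default_rng(60)
    X = rng.normal(size=(80, 3))
    y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2 + X[:, 2]
    return (X[:60], y[:60], X[60:], y[60:])


class TestPsoElm:
    def test_degenerate_swarm_returns_the_seeded_elm(self, regression_problem):
        X, y, Xv, yv = regression_problem
        plain = elm_fit(X, y, hidden_count=4, seed=5)
        position = np.concatenate(
            [plain.input_weights.ravel(), plain.hidden_biases]
        )
        cfg = PsoConfig(pop=1, iterations=1, seed=5)
        model, _ = pso_elm_fit(X, y, Xv, yv, 4, cfg, init_positions=position)
        assert model.input_weights == pytest.approx(plain.input_weights)
        assert model.output_weights == pytest.approx(plain.output_weights)

    def test_bit_identical_on_rerun(self, regression_problem):
        X, y, Xv, yv = regression_problem
        cfg = PsoConfig(pop=6, iterations=5, seed=9)
        m1, t1 = pso_elm_fit(X, y, Xv, yv, 5, cfg)
        m2, t2 = pso_elm_fit(X, y, Xv, yv, 5, cfg)
        assert np.array_equal(m1.input_weights, m2.input_weights)
        assert np.array_equal(t1.gbest_fitness, t2.gbest_fitness)

    def test_returned_model_fitness_equals_final_gbest(self, regression_problem):
        X, y, Xv, yv = regression_problem
        cfg = PsoConfig(pop=6, iterations=8, seed=2)
        model, trace = pso_elm_fit(X, y, Xv, yv, 5, cfg)
        val_rmse = rmse(yv, elm_predict(model, Xv))
        assert val_rmse == pytest.approx(trace.best_fitness, abs=1e-10)

    def test_empty_validation_rejected(self, regression_problem):
        X, y, _, _ = regression_problem
        with pytest.raises(ConfigurationError):
            pso_elm_fit(X, y, X[:0], y[:0], 4, PsoConfig(pop=2, iterations=1))
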