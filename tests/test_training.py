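"""Hybrid trainer: encode/decode, fitness semantics, isolation, gains."""

import numpy as np
import pytest

from teacelm import diagnostics
from teacelm.datasets import Dataset, GeneratorConfig, generate_dataset
from teacelm.elm import ELMModel, hidden_matrix, init_hidden, predict, \
    solve_output_weights
from teacelm.preprocessing import fit_normalizer, normalize, split
from teacelm.pso import PSOConfig
from teacelm.training import (TrainerConfig, decode, elm_fitness, encode,
                              train)


def test_encode_length_and_round_trip():
    W, c = init_hidden(3, 2, seed=0)
    pos = encode(W, c)
    assert pos.shape == (2 * 3 + 2,)
    W2, c2 = decode(pos, 2, 3)
    np.testing.assert_array_equal(W2, W)
    np.testing.assert_array_equal(c2, c)


def test_encode_ordering_is_row_major_weights_then_biases():
    W = np.array([[11.0, 12.0], [21.0, 22.0]])
    c = np.array([1.0, 2.0])
    np.testing.assert_array_equal(encode(W, c), [11, 12, 21, 22, 1, 2])


def test_decode_rejects_wrong_length():
    with pytest.raises(ValueError, match="length"):
        decode(np.zeros(7), 2, 3)


def test_fitness_is_zero_for_realizable_linear_target(rng):
    X = rng.uniform(-1, 1, size=(30, 3))
    y = X @ np.array([0.5, -0.2, 0.1]) + 0.3
    cfg = TrainerConfig(n_hidden=4, activation="linear", ridge=0.0)
    pos = encode(*init_hidden(3, 4, seed=1))
    assert elm_fitness(pos, X, y, cfg) <= 1e-6


def test_fitness_zero_for_constant_target_even_with_zero_weights():
    X = np.zeros((10, 2))
    y = np.full(10, 0.7)
    cfg = TrainerConfig(n_hidden=3, ridge=0.0)
    assert elm_fitness(np.zeros(3 * 3), X, y, cfg) <= 1e-12


def test_fitness_agrees_with_external_rmse(rng):
    """The optimizer's fitness must equal diagnostics.fit_metrics recomputed
    on the same decoded model."""
    X = rng.uniform(-1, 1, size=(25, 4))
    y = rng.uniform(-1, 1, size=25)
    cfg = TrainerConfig(n_hidden=5, ridge=1e-8)
    pos = encode(*init_hidden(4, 5, seed=2))
    W, c = decode(pos, 5, 4)
    model = ELMModel(W, c, activation=cfg.activation)
    A = hidden_matrix(X, model)
    model.output_weights = solve_output_weights(A, y, ridge=cfg.ridge)
    external = diagnostics.fit_metrics(y + 2.0, predict(model, X) + 2.0).rmse
    assert elm_fitness(pos, X, y, cfg) == pytest.approx(external, abs=1e-12)


def small_setup(seed=7, n=48):
    data = generate_dataset(GeneratorConfig(n_samples=max(n, 10), seed=seed))
    sp = split(data.n_samples, seed=seed)
    params = fit_normalizer(data)
    return data, sp, params


def test_test_partition_never_touches_training(fast_trainer):
    """Corrupting every test row leaves the trained model bit-identical."""
    data, sp, params = small_setup()
    corrupted = data.features.copy()
    corrupted[sp.test_indices] += 1e6
    target = data.target.copy()
    target[sp.test_indices] = -1e6
    evil = Dataset(corrupted, target, feature_names=data.feature_names)

    model_a, _ = train(data, sp, params, fast_trainer)
    model_b, _ = train(evil, sp, params, fast_trainer)
    assert np.array_equal(model_a.input_weights, model_b.input_weights)
    assert np.array_equal(model_a.output_weights, model_b.output_weights)


def test_training_is_reproducible(fast_trainer):
    data, sp, params = small_setup()
    model_a, rep_a = train(data, sp, params, fast_trainer)
    model_b, rep_b = train(data, sp, params, fast_trainer)
    assert np.array_equal(model_a.input_weights, model_b.input_weights)
    assert np.array_equal(model_a.output_weights, model_b.output_weights)
    assert np.array_equal(rep_a.fitness_history, rep_b.fitness_history)


def test_final_fitness_not_worse_than_any_initial_particle(fast_trainer):
    data, sp, params = small_setup()
    _, report = train(data, sp, params, fast_trainer)
    assert report.best_fitness <= report.fitness_history[0]
    assert np.all(np.diff(report.fitness_history) <= 0)


def test_swarm_tuning_beats_untuned_random_hidden_layer():
    """Median training RMSE over 5 seeds: tuned < single random draw at
    equal hidden size."""
    tuned, untuned = [], []
    for seed in range(5):
        data, sp, params = small_setup(seed=seed + 100)
        cfg = TrainerConfig(seed=seed,
                            pso=PSOConfig(n_particles=10, max_iterations=30))
        _, report = train(data, sp, params, cfg)
        tuned.append(report.best_fitness)

        norm = normalize(data, params)
        Xtr = norm.features[sp.train_indices]
        ytr = norm.target[sp.train_indices]
        W, c = init_hidden(data.n_features, cfg.n_hidden, seed=seed)
        model = ELMModel(W, c, activation=cfg.activation)
        A = hidden_matrix(Xtr, model)
        model.output_weights = solve_output_weights(A, ytr, ridge=cfg.ridge)
        err = predict(model, Xtr) - ytr
        untuned.append(float(np.sqrt(np.mean(err**2))))
    assert np.median(tuned) < np.median(untuned)


def test_noiseless_linear_generator_is_recovered():
    """max_r2 = 1 leaves the target an exact linear function of the latent
    factor; the tuned model should be essentially perfect."""
    for seed in (0, 1, 2):
        cfg = GeneratorConfig(n_samples=120, max_r2=1.0, seed=seed)
        data = generate_dataset(cfg)
        sp = split(data.n_samples, seed=seed)
        params = fit_normalizer(data)
        model, _ = train(data, sp, params, TrainerConfig(
            seed=seed, pso=PSOConfig(n_particles=15, max_iterations=60)))
        norm = normalize(data, params)
        from teacelm.preprocessing import denormalize_target
        pred = denormalize_target(predict(model, norm.features), params)
        assert diagnostics.fit_metrics(data.target, pred).r2 >= 0.999


def test_cv_fitness_mode_runs_and_differs_from_plain(rng):
    X = rng.uniform(-1, 1, size=(40, 3))
    y = rng.uniform(-1, 1, size=40)
    pos = encode(*init_hidden(3, 6, seed=3))
    plain = elm_fitness(pos, X, y, TrainerConfig(n_hidden=6))
    cv = elm_fitness(pos, X, y, TrainerConfig(n_hidden=6, cv_folds=5))
    assert np.isfinite(cv) and cv > plain  # held-out error exceeds train error


def test_empty_training_partition_is_an_error(fast_trainer):
    data, sp, params = small_setup()
    from teacelm.preprocessing import SplitIndices
    empty = SplitIndices(np.array([], dtype=int), np.arange(data.n_samples), 0)
    with pytest.raises(ValueError, match="empty"):
        train(data, empty, params, fast_trainer)


def test_trainer_config_validation():
    with pytest.raises(ValueError):
        TrainerConfig(n_hidden=0)
    with pytest.raises(ValueError):
        TrainerConfig(fitness_metric="mae")
    with pytest.raises(ValueError):
        TrainerConfig(cv_folds=1)
    assert TrainerConfig(n_hidden=2).pso_for(3).n_dimensions == 8
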