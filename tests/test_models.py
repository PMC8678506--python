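"""Sequence models (RNN / LSTM / RNN-Decay / ODE-RNN) and tabular baselines."""

import numpy as np
import pytest

from coagcast.encoding import EncodingConfig
from coagcast.evaluation import auroc
from coagcast.models import (SequenceModel, SequenceModelConfig, TabularModel,
                             pack_windows, rk4_solve, train_tabular_baselines)

from conftest import make_toy_window, toy_dataset

TOY_ENC = EncodingConfig(variables=("V0", "V1"), horizons_h=(8.0,))
HEADS = [("SIC", 8.0), ("DIC", 8.0)]


def _model(cell, seed=0, **kw):
    cfg = SequenceModelConfig(cell=cell, hidden_dim=8, seed=seed, **kw)
    return SequenceModel(cfg, n_variables=2, heads=HEADS)


def _packed(windows):
    return pack_windows(windows, TOY_ENC, ("SIC", "DIC"), (8.0,))


@pytest.fixture()
def toy_pair():
    """Twin windows: identical observations, one inter-observation gap moved
    within the same discretization cell."""
    rng = np.random.default_rng(1)
    a = make_toy_window(rng, "A", lambda x: 0, timestamps=[2.0, 10.0, 18.0])
    b = make_toy_window(rng, "B", lambda x: 0, timestamps=[2.0, 12.0, 18.0])
    b.x, b.m = a.x.copy(), a.m.copy()
    return a, b


def test_plain_rnn_zero_weights_ignore_input():
    m = _model("rnn")
    for k in ("Wx", "Wh"):
        m.params[k].data[:] = 0.0
    m.params["b"].data[:] = 0.3
    packed = _packed(toy_dataset(4, 0, lambda x: 0))
    h = m.forward_hidden(packed, np.arange(4)).data
    assert np.allclose(h, np.tanh(0.3))


def test_plain_rnn_variable_permutation_symmetry():
    m = _model("rnn")
    windows = toy_dataset(6, 3, lambda x: 0)
    packed = _packed(windows)
    h = m.forward_hidden(packed, np.arange(6)).data

    perm = [1, 0]  # swap the two variables in the grid view (x block, m block)
    packed2 = _packed(windows)
    G = packed2.GRID
    D = 2
    packed2.GRID = np.concatenate([G[:, :, perm], G[:, :, [D + p for p in perm]]],
                                  axis=2)
    m2 = _model("rnn")
    Wx = m2.params["Wx"].data
    m2.params["Wx"].data = np.concatenate([Wx[perm], Wx[[D + p for p in perm]]])
    h2 = m2.forward_hidden(packed2, np.arange(6)).data
    np.testing.assert_allclose(h, h2, atol=1e-12)


def test_single_cell_window_is_one_recurrent_step():
    enc = EncodingConfig(sampling_window_h=8.0, slide_step_h=8.0,
                         discretization_grid_h=8.0, variables=("V0", "V1"),
                         horizons_h=(8.0,))
    rng = np.random.default_rng(2)
    w = make_toy_window(rng, "A", lambda x: 0, T=2, timestamps=[1.0, 5.0])
    packed = pack_windows([w], enc, ("SIC",), (8.0,))
    m = SequenceModel(SequenceModelConfig(cell="rnn", hidden_dim=8, seed=0), 2,
                      [("SIC", 8.0)])
    h = m.forward_hidden(packed, np.array([0])).data
    u = packed.GRID[0, 0, :]
    expected = np.tanh(u @ m.params["Wx"].data + m.params["b"].data)
    np.testing.assert_allclose(h, expected, atol=1e-12)


def test_decay_gamma_is_identity_at_zero_gap():
    m = _model("decay")
    w = make_toy_window(np.random.default_rng(3), "A", lambda x: 0, T=1,
                        timestamps=[0.0])  # first step measured from start: gap 0
    packed = _packed([w])
    h = m.forward_hidden(packed, np.array([0])).data
    u = np.concatenate([w.x[0], w.m[0], w.delta[0] / TOY_ENC.delta_scale_h])
    expected = np.tanh(u @ m.params["Wx"].data + m.params["b"].data)
    np.testing.assert_allclose(h, expected, atol=1e-12)


def test_decay_shrinks_monotonically_with_gap():
    m = _model("decay")
    w_g = m.params["w_gamma"].data
    w_g[:] = np.abs(w_g) + 0.05  # strictly positive rates
    h = np.tanh(np.random.default_rng(4).normal(size=(1, 8)))

    def decayed(gap):
        gamma = np.exp(-np.maximum(0.0, w_g * gap + m.params["b_gamma"].data))
        return np.abs(h * gamma)

    small, large = decayed(2.0), decayed(4.0)
    assert np.all(large < small)
    assert np.allclose(decayed(0.0), np.abs(h))          # gamma = 1 at zero gap
    assert np.all(decayed(1e6) < 1e-6)                   # gamma -> 0 for huge gaps


def test_ode_with_zero_dynamics_equals_recurrent_cell_chain():
    m = _model("ode")
    m.params["F2"].data[:] = 0.0
    m.params["f2"].data[:] = 0.0
    windows = toy_dataset(5, 5, lambda x: 0)
    packed = _packed(windows)
    h = m.forward_hidden(packed, np.arange(5)).data

    for i, w in enumerate(windows):
        ref = np.zeros((1, 8))
        for t in range(len(w.timestamps)):
            u = np.concatenate([w.x[t], w.m[t], w.delta[t] / TOY_ENC.delta_scale_h])
            ref = np.tanh(u @ m.params["Wx"].data + ref @ m.params["Wh"].data
                          + m.params["b"].data)
        np.testing.assert_allclose(h[i], ref[0], atol=1e-10)


def test_rk4_recovers_exponential_decay():
    y = rk4_solve(lambda v: -v, np.array([1.0]), 0.0, 1.0, max_step=0.05)
    assert y[0] == pytest.approx(np.exp(-1.0), abs=1e-6)


def test_ode_query_smoke(toy_pair):
    m = _model("ode")
    h_mid = m.ode_query(toy_pair[0], TOY_ENC, t=15.0)
    h_end = m.ode_query(toy_pair[0], TOY_ENC, t=20.0)
    assert np.all(np.isfinite(h_mid)) and np.all(np.isfinite(h_end))
    assert not np.allclose(h_mid, h_end)


def test_head_risks_zero_weights_give_half():
    m = _model("rnn")
    m.params["Wo"].data[:] = 0.0
    m.params["bo"].data[:] = 0.0
    risks = m.head_risks(np.random.default_rng(0).normal(size=(3, 8)))
    assert np.allclose(risks, 0.5)


def test_head_risks_monotone_and_independent():
    m = _model("rnn")
    h = np.zeros((1, 8))
    base = m.head_risks(h)
    m.params["bo"].data[0, 0] += 1.0
    bumped = m.head_risks(h)
    assert bumped[0, 0] > base[0, 0]
    assert bumped[0, 1] == pytest.approx(base[0, 1])


def test_gap_perturbation_sensed_only_by_continuous_time_models(toy_pair):
    a, b = toy_pair
    pa, pb = _packed([a]), _packed([b])
    idx = np.array([0])
    h_rnn_a = _model("rnn").forward_hidden(pa, idx).data
    h_rnn_b = _model("rnn").forward_hidden(pb, idx).data
    np.testing.assert_allclose(h_rnn_a, h_rnn_b)         # grid view is blind to gaps
    for cell in ("decay", "ode"):
        ha = _model(cell).forward_hidden(pa, idx).data
        hb = _model(cell).forward_hidden(pb, idx).data
        assert not np.allclose(ha, hb)


@pytest.mark.parametrize("cell", ["rnn", "lstm", "decay", "ode"])
def test_sequence_models_learn_separable_toy(cell, toy_separable):
    train, test = toy_separable[:220], toy_separable[220:]
    lr = 0.05 if cell == "ode" else 0.02
    cfg = SequenceModelConfig(cell=cell, hidden_dim=8, epochs=30, seed=1,
                              learning_rate=lr, ode_substeps=2)
    ptr, pte = _packed(train), _packed(test)
    m = SequenceModel(cfg, 2, ptr.heads)
    m.fit(ptr, None)
    k = ptr.heads.index(("SIC", 8.0))
    risks = m.predict_risks(pte)
    assert auroc(risks[:, k], pte.Y[:, k]) > 0.95


def test_shuffled_labels_give_chance_validation_auroc():
    rng = np.random.default_rng(6)
    windows = toy_dataset(500, 66, lambda x: rng.integers(0, 2))
    cfg = SequenceModelConfig(cell="rnn", hidden_dim=8, epochs=10, seed=2)
    ptr = _packed(windows[:300])
    pva = _packed(windows[300:])
    m = SequenceModel(cfg, 2, ptr.heads)
    log = m.fit(ptr, pva)
    assert 0.4 <= log[-1]["valid_auroc"] <= 0.6


def test_training_is_deterministic_given_seed(toy_separable):
    cfg = SequenceModelConfig(cell="decay", hidden_dim=8, epochs=3, seed=9)
    ptr = _packed(toy_separable[:100])
    runs = []
    for _ in range(2):
        m = SequenceModel(cfg, 2, ptr.heads)
        m.fit(ptr, None)
        runs.append({k: p.data.copy() for k, p in m.params.items()})
    for k in runs[0]:
        np.testing.assert_array_equal(runs[0][k], runs[1][k])


def test_training_aborts_on_single_class_targets(toy_separable):
    windows = toy_separable[:50]
    for w in windows:
        w.targets = {8.0: (1, 1)}
    ptr = _packed(windows)
    m = _model("rnn")
    with pytest.raises(ValueError, match="one-class"):
        m.fit(ptr)


def test_negative_step_rejected(toy_separable):
    packed = _packed(toy_separable[:2])
    packed.STEP[0, 1] = -1.0
    with pytest.raises(ValueError, match="sorted"):
        _model("decay").forward_hidden(packed, np.array([0, 1]))


def test_logistic_regression_learns_separable_toy(toy_separable):
    train, test = toy_separable[:220], toy_separable[220:]
    m = train_tabular_baselines(train, TOY_ENC, ("V0", "V1"), "logreg",
                                diseases=("SIC",), seed=0)
    rows = m.predict(test).rows("SIC", 8.0)
    assert auroc(rows["risk"], rows["label"]) > 0.95
    assert rows["risk"].between(0, 1).all()


def test_boosted_trees_beat_logistic_on_nonlinear_toy(toy_nonlinear):
    train, test = toy_nonlinear[:380], toy_nonlinear[380:]
    scores = {}
    for name in ("logreg", "xgboost"):
        m = train_tabular_baselines(train, TOY_ENC, ("V0", "V1"), name,
                                    diseases=("SIC",), seed=0)
        rows = m.predict(test).rows("SIC", 8.0)
        scores[name] = auroc(rows["risk"], rows["label"])
    assert scores["xgboost"] >= scores["logreg"]
    assert scores["xgboost"] > 0.8


def test_tabular_single_class_head_skipped(toy_separable):
    windows = toy_separable[:40]
    for w in windows:
        w.targets = {8.0: (0, 0)}
    m = train_tabular_baselines(windows, TOY_ENC, ("V0", "V1"), "logreg")
    assert m.estimators == {}
    assert ("SIC", 8.0) in m.fit_skipped


def test_unknown_models_rejected():
    with pytest.raises(ValueError):
        TabularModel("forest")
    with pytest.raises(ValueError):
        SequenceModelConfig(cell="gru")
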