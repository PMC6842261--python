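import dataclasses
import math

import numpy as np
import pytest

from visitcd import (
    BiLSTMModel,
    CodeVocabulary,
    CohortSplit,
    LSTMParams,
    OutputParams,
    PlantedSignal,
    CohortConfig,
    TrainConfig,
    build_vocabulary,
    class_probabilities,
    encode_patient,
    evaluate_auc_ci,
    format_auc_ci,
    generate_cohort,
    load_model,
    lstm_step,
    pad_batch,
    predict_case_probability,
    save_model,
    sequence_forward,
    stratified_split,
    train,
)
from visitcd.model import _batch_features, _batch_loss_grads, _init_params

from conftest import random_lstm_params, random_model, random_sequence


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def test_lstm_step_zero_weights_closed_form(rng):
    h = 4
    params = LSTMParams.zeros(h, 6)
    x = rng.random(6)
    c_prev = rng.normal(size=h)
    s = lstm_step(x, rng.normal(size=h), c_prev, params)
    np.testing.assert_allclose(s.i, 0.5)
    np.testing.assert_allclose(s.f, 0.5)
    np.testing.assert_allclose(s.o, 0.5)
    np.testing.assert_allclose(s.g, 0.0)
    np.testing.assert_allclose(s.c, 0.5 * c_prev)
    np.testing.assert_allclose(s.h, 0.5 * np.tanh(0.5 * c_prev))


def test_lstm_step_bias_only_gates(rng):
    params = LSTMParams.zeros(3, 5)
    params.b_i[:] = [0.3, -0.2, 1.0]
    s = lstm_step(np.zeros(5), np.zeros(3), np.zeros(3), params)
    np.testing.assert_allclose(s.i, [sigmoid(0.3), sigmoid(-0.2), sigmoid(1.0)])


def test_lstm_step_matches_scalar_loop_oracle(rng):
    """The vector step equals an elementwise scalar re-computation of the
    gate and state update equations."""
    h, d = 4, 6
    params = random_lstm_params(rng, h, d)
    x = (rng.random(d) < 0.4).astype(float)
    h_prev = rng.normal(size=h)
    c_prev = rng.normal(size=h)
    s = lstm_step(x, h_prev, c_prev, params)
    for k in range(h):
        pre = {
            g: sum(getattr(params, f"W_{g}")[k, j] * x[j] for j in range(d))
            + sum(getattr(params, f"U_{g}")[k, j] * h_prev[j] for j in range(h))
            + getattr(params, f"b_{g}")[k]
            for g in "ifog"
        }
        i_k, f_k, o_k = (sigmoid(pre[g]) for g in "ifo")
        g_k = math.tanh(pre["g"])
        c_k = f_k * c_prev[k] + i_k * g_k
        assert abs(s.c[k] - c_k) < 1e-10
        assert abs(s.h[k] - o_k * math.tanh(c_k)) < 1e-10


def test_sequence_forward_single_visit(rng):
    model = random_model(rng, hidden=3, inputs=5)
    seq = random_sequence(rng, 1, 5)
    feature, states = sequence_forward(model, seq)
    assert len(states["forward"]) == len(states["backward"]) == 1
    np.testing.assert_array_equal(states["forward"][0].i.shape, (3,))
    np.testing.assert_allclose(
        feature, np.concatenate([states["forward"][0].h, states["backward"][0].h])
    )


def test_sequence_forward_zero_backward_weights(rng):
    """With backward weights and biases all zero the backward feature half is a
    constant independent of the input: h = 0.5*tanh(c) with c following
    c_t = 0.5*c_{t-1} (g=0 makes every increment zero, so c stays 0)."""
    model = random_model(rng, hidden=3, inputs=5)
    model.backward_params = LSTMParams.zeros(3, 5)
    seq = random_sequence(rng, 4, 5)
    feature, _ = sequence_forward(model, seq)
    fwd_only = BiLSTMModel(
        direction="lstm", forward_params=model.forward_params,
        output=OutputParams(weights=np.zeros((2, 3)), bias=np.zeros(2)),
        vocab=model.vocab,
    )
    fwd_feature, _ = sequence_forward(fwd_only, seq)
    np.testing.assert_allclose(feature[:3], fwd_feature)
    np.testing.assert_allclose(feature[3:], 0.0, atol=1e-15)


def test_sequence_forward_reversal_symmetry(rng):
    """With identical forward/backward weights, reversing the input swaps the
    roles of the two directions' states."""
    model = random_model(rng, hidden=4, inputs=6)
    model.backward_params = model.forward_params
    seq = random_sequence(rng, 3, 6)
    rev = dataclasses.replace(seq, matrix=seq.matrix[::-1].copy())
    f1, _ = sequence_forward(model, seq)
    f2, _ = sequence_forward(model, rev)
    np.testing.assert_allclose(f1[:4], f2[4:], atol=1e-12)
    np.testing.assert_allclose(f1[4:], f2[:4], atol=1e-12)


def test_class_probabilities():
    out = OutputParams(weights=np.zeros((2, 3)), bias=np.zeros(2))
    np.testing.assert_allclose(class_probabilities(np.ones(3), out), [0.5, 0.5])
    out2 = OutputParams(weights=np.array([[1.0, 0.0], [0.0, 0.0]]), bias=np.zeros(2))
    p = class_probabilities(np.array([1.0, 0.0]), out2)
    e = math.e
    np.testing.assert_allclose(p, [e / (e + 1), 1 / (e + 1)], atol=1e-12)
    assert abs(p.sum() - 1.0) < 1e-12


def test_batched_forward_matches_unpadded_reference(rng):
    """Padding inertness: the vectorized masked batch forward equals the
    per-patient reference pass over the true visits only."""
    h, d = 4, 6
    model = random_model(rng, hidden=h, inputs=d)
    seqs = [random_sequence(rng, t, d) for t in (2, 5, 3)]
    batch, lengths = pad_batch(seqs)
    params = {}
    params["wx_f"], params["wh_f"], params["b_f"] = model.forward_params.pack()
    params["wx_b"], params["wh_b"], params["b_b"] = model.backward_params.pack()
    feat, _ = _batch_features(batch, lengths, params, True)
    for n, seq in enumerate(seqs):
        ref, _ = sequence_forward(model, seq)
        np.testing.assert_allclose(feat[n], ref, atol=1e-12)


def test_gradients_match_finite_differences(rng):
    d = 5
    params = _init_params(rng, 3, d, True)
    x = (rng.random((4, 6, d)) < 0.3).astype(float)
    lengths = np.array([6, 3, 4, 1])
    y = np.array([1, 0, 1, 0])
    _, _, grads = _batch_loss_grads(x, lengths, y, params, True)
    eps = 1e-6
    for key in params:
        flat = params[key].reshape(-1)
        for idx in rng.choice(flat.size, size=min(10, flat.size), replace=False):
            flat[idx] += eps
            lp, _, _ = _batch_loss_grads(x, lengths, y, params, True, want_grads=False)
            flat[idx] -= 2 * eps
            lm, _, _ = _batch_loss_grads(x, lengths, y, params, True, want_grads=False)
            flat[idx] += eps
            num = (lp - lm) / (2 * eps)
            assert abs(num - grads[key].reshape(-1)[idx]) < 1e-7


def _tiny_split(seed, penetrance=(1.0, 0.0), n=300, shuffle_labels=False):
    cfg = CohortConfig(
        n_patients=n, vocab_size=20, visit_count_range=(3, 6),
        codes_per_visit_range=(1, 2),
        signal=PlantedSignal(signal_codes=(18, 19), penetrance_case=penetrance[0],
                             penetrance_control=penetrance[1]),
        seed=seed,
    )
    cohort = generate_cohort(cfg)
    if shuffle_labels:
        labels = [r.label for r in cohort]
        rng = np.random.default_rng(seed + 1)
        rng.shuffle(labels)
        cohort = [dataclasses.replace(r, label=l) for r, l in zip(cohort, labels)]
    vocab = build_vocabulary(cohort)
    return stratified_split(cohort, seed=seed), vocab


@pytest.mark.parametrize("direction", ["lstm", "bilstm"])
def test_training_separable_signal_reaches_high_auc(direction):
    split, vocab = _tiny_split(0)
    cfg = TrainConfig(hidden_size=16, max_epochs=80, patience=8, batch_size=8, seed=0)
    model = train(split, vocab, cfg, direction=direction)
    from sklearn.metrics import roc_auc_score

    y = [1 if r.label == "case" else 0 for r in split.test]
    auc = roc_auc_score(y, predict_case_probability(model, split.test))
    assert auc > 0.99


def test_training_shuffled_labels_near_chance():
    split, vocab = _tiny_split(1, n=400, shuffle_labels=True)
    cfg = TrainConfig(hidden_size=8, max_epochs=6, patience=2, batch_size=32, seed=1)
    model = train(split, vocab, cfg, direction="lstm")
    from sklearn.metrics import roc_auc_score

    y = [1 if r.label == "case" else 0 for r in split.test]
    auc = roc_auc_score(y, predict_case_probability(model, split.test))
    assert 0.35 < auc < 0.65


def test_training_deterministic():
    split, vocab = _tiny_split(2, n=120)
    cfg = TrainConfig(hidden_size=6, max_epochs=3, patience=1, batch_size=16, seed=5)
    m1 = train(split, vocab, cfg, direction="bilstm")
    m2 = train(split, vocab, cfg, direction="bilstm")
    np.testing.assert_array_equal(m1.forward_params.W_i, m2.forward_params.W_i)
    np.testing.assert_array_equal(m1.output.weights, m2.output.weights)


def test_patience_zero_stops_at_first_non_improvement():
    split, vocab = _tiny_split(3, n=120, shuffle_labels=True)
    cfg = TrainConfig(hidden_size=6, max_epochs=40, patience=0, batch_size=16, seed=9)
    model = train(split, vocab, cfg, direction="lstm")
    losses = model.train_history["val_losses"]
    if len(losses) < cfg.max_epochs:  # early stop actually triggered
        best_before_last = min(losses[:-1])
        assert losses[-1] >= best_before_last - 1e-9  # final epoch did not improve
        for k in range(1, len(losses) - 1):  # and it is the first such epoch
            assert losses[k] < min(losses[:k]) - 1e-9


def test_model_round_trip_exact(tmp_path, rng):
    model = random_model(rng, hidden=3, inputs=4)
    path = tmp_path / "m.json"
    save_model(model, str(path))
    back = load_model(str(path))
    assert back.direction == model.direction
    np.testing.assert_array_equal(back.forward_params.W_g, model.forward_params.W_g)
    np.testing.assert_array_equal(back.backward_params.U_f, model.backward_params.U_f)
    np.testing.assert_array_equal(back.output.weights, model.output.weights)
    assert back.vocab.codes == model.vocab.codes


def test_metrics_report_csv(tmp_path):
    import pandas as pd

    from visitcd import write_metrics_report

    path = tmp_path / "metrics.csv"
    write_metrics_report({0: 0.8, 1: 0.9}, str(path))
    df = pd.read_csv(path)
    assert list(df.run_seed) == ["0", "1", "summary"]
    summary = df.iloc[-1]
    assert summary.auc == pytest.approx(0.85)
    assert summary.ci_low < 0.85 < summary.ci_high


class _ScoreModel:
    """Stub exposing the prediction surface evaluate_auc_ci touches."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)


def test_auc_ci(monkeypatch, rng):
    from visitcd import model as model_mod
    from visitcd.ehr import PatientRecord, Visit

    records = [
        PatientRecord(
            patient_id=f"p{i}",
            visits=[Visit(ordinal=1, age_years=1.0, codes=frozenset({"A"}))],
            label="case" if i < 3 else "control",
        )
        for i in range(6)
    ]
    monkeypatch.setattr(
        model_mod, "predict_case_probability", lambda m, recs: m.scores
    )
    y = [1, 1, 1, 0, 0, 0]
    perfect = _ScoreModel([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
    mean, lo, hi, aucs = model_mod.evaluate_auc_ci([perfect, perfect], records)
    assert mean == 1.0 and lo == hi == 1.0
    constant = _ScoreModel([0.5] * 6)
    mean, lo, hi, _ = model_mod.evaluate_auc_ci([constant, constant], records)
    assert mean == 0.5  # ties count one half
    assert format_auc_ci(0.831, 0.824, 0.838) == "0.831 (0.824-0.838)"
    with pytest.raises(ValueError):
        model_mod.evaluate_auc_ci([perfect], records)
    single = [r for r in records if r.label == "case"]
    with pytest.raises(ValueError):
        model_mod.evaluate_auc_ci([perfect, perfect], single)
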