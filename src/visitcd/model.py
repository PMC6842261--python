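"""LSTM / BiLSTM sequence classifiers over multi-hot visit sequences.

The recurrence is the standard LSTM cell

    i_t = sigmoid(W_i x_t + U_i h_{t-1} + b_i)      (input gate)
    f_t = sigmoid(W_f x_t + U_f h_{t-1} + b_f)      (forget gate)
    o_t = sigmoid(W_o x_t + U_o h_{t-1} + b_o)      (output gate)
    g_t = tanh   (W_g x_t + U_g h_{t-1} + b_g)      (cell candidate)
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

with a softmax classification head over C = 2 classes reading the learned
feature vector: h at the true final visit for a forward-only model, and the
concatenation [h_fwd at the last visit, h_bwd at the first visit] for a
bidirectional model. Variable-length sequences are post-padded with zero
rows; padded steps copy the state through unchanged, so padding can never
influence predictions or gradients.

Training (cross-entropy, Adam, early stopping on validation loss) is
implemented directly in NumPy with backpropagation through time; trained
weights are exported into the plain parameter containers that the contextual
decomposition module consumes, so interpretation never depends on the
trainer.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .ehr import (
    CodeVocabulary,
    CohortSplit,
    EncodedSequence,
    PatientRecord,
    encode_patient,
    pad_batch,
)

__all__ = [
    "LSTMParams",
    "OutputParams",
    "BiLSTMModel",
    "TrainConfig",
    "StepState",
    "lstm_step",
    "sequence_forward",
    "class_probabilities",
    "train",
    "predict_case_probability",
    "evaluate_auc_ci",
    "format_auc_ci",
    "save_model",
    "load_model",
]

GATES = ("i", "f", "o", "g")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class LSTMParams:
    """One direction's weights: input (W), recurrent (U) and bias (b) per gate."""

    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    W_g: np.ndarray
    U_i: np.ndarray
    U_f: np.ndarray
    U_o: np.ndarray
    U_g: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_g: np.ndarray

    def __post_init__(self) -> None:
        h, d = self.W_i.shape
        for g in GATES:
            if getattr(self, f"W_{g}").shape != (h, d):
                raise ValueError("inconsistent input-weight shapes")
            if getattr(self, f"U_{g}").shape != (h, h):
                raise ValueError("inconsistent recurrent-weight shapes")
            if getattr(self, f"b_{g}").shape != (h,):
                raise ValueError("inconsistent bias shapes")
            for name in (f"W_{g}", f"U_{g}", f"b_{g}"):
                if not np.all(np.isfinite(getattr(self, name))):
                    raise ValueError(f"non-finite entries in {name}")

    @property
    def hidden_size(self) -> int:
        return self.W_i.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_i.shape[1]

    @classmethod
    def zeros(cls, hidden: int, inputs: int) -> "LSTMParams":
        return cls(
            **{f"W_{g}": np.zeros((hidden, inputs)) for g in GATES},
            **{f"U_{g}": np.zeros((hidden, hidden)) for g in GATES},
            **{f"b_{g}": np.zeros(hidden) for g in GATES},
        )

    # packed layout [i, f, o, g] used by the vectorized trainer
    def pack(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        wx = np.concatenate([getattr(self, f"W_{g}") for g in GATES], axis=0)
        wh = np.concatenate([getattr(self, f"U_{g}") for g in GATES], axis=0)
        b = np.concatenate([getattr(self, f"b_{g}") for g in GATES])
        return wx, wh, b

    @classmethod
    def unpack(cls, wx: np.ndarray, wh: np.ndarray, b: np.ndarray) -> "LSTMParams":
        h = wh.shape[1]
        parts = {}
        for k, g in enumerate(GATES):
            parts[f"W_{g}"] = wx[k * h : (k + 1) * h].copy()
            parts[f"U_{g}"] = wh[k * h : (k + 1) * h].copy()
            parts[f"b_{g}"] = b[k * h : (k + 1) * h].copy()
        return cls(**parts)


@dataclass
class OutputParams:
    """Softmax head: row j of ``weights`` scores class j's logit W_j . h + b_j."""

    weights: np.ndarray  # C x H (H = hidden, or 2*hidden for BiLSTM)
    bias: np.ndarray  # C

    def __post_init__(self) -> None:
        if self.weights.ndim != 2 or self.bias.shape != (self.weights.shape[0],):
            raise ValueError("output layer shape mismatch")


@dataclass
class BiLSTMModel:
    direction: str  # "lstm" (forward-only) or "bilstm"
    forward_params: LSTMParams
    output: OutputParams
    vocab: CodeVocabulary
    backward_params: LSTMParams | None = None
    hidden_size: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("lstm", "bilstm"):
            raise ValueError(f"direction must be 'lstm' or 'bilstm', got {self.direction!r}")
        if (self.backward_params is not None) != (self.direction == "bilstm"):
            raise ValueError("backward_params present iff bidirectional")
        self.hidden_size = self.forward_params.hidden_size
        expected = self.hidden_size * (2 if self.direction == "bilstm" else 1)
        if self.output.weights.shape[1] != expected:
            raise ValueError("output layer width does not match feature size")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.0005
    max_epochs: int = 50
    patience: int = 5
    batch_size: int = 32
    hidden_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.max_epochs, self.batch_size,
               self.hidden_size) <= 0 or self.patience < 0:
            raise ValueError("training hyperparameters must be positive (patience >= 0)")


@dataclass
class StepState:
    """Gate activations and states for a single recurrence step."""

    i: np.ndarray
    f: np.ndarray
    o: np.ndarray
    g: np.ndarray
    c: np.ndarray
    h: np.ndarray


# ---------------------------------------------------------------------------
# forward computation (reference path, used by decomposition and tests)

def lstm_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, params: LSTMParams
) -> StepState:
    """One LSTM recurrence step on a single input vector."""
    i = _sigmoid(params.W_i @ x_t + params.U_i @ h_prev + params.b_i)
    f = _sigmoid(params.W_f @ x_t + params.U_f @ h_prev + params.b_f)
    o = _sigmoid(params.W_o @ x_t + params.U_o @ h_prev + params.b_o)
    g = np.tanh(params.W_g @ x_t + params.U_g @ h_prev + params.b_g)
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(h))):
        raise FloatingPointError("non-finite LSTM state")
    return StepState(i=i, f=f, o=o, g=g, c=c, h=h)


def _run_direction(params: LSTMParams, xs: np.ndarray) -> list[StepState]:
    h = np.zeros(params.hidden_size)
    c = np.zeros(params.hidden_size)
    states = []
    for x in xs:
        s = lstm_step(x, h, c, params)
        states.append(s)
        h, c = s.h, s.c
    return states


def sequence_forward(
    model: BiLSTMModel, seq: EncodedSequence
) -> tuple[np.ndarray, dict[str, list[StepState]]]:
    """Run the recurrence over the true (unpadded) visits.

    Returns the classifier feature vector — h_fwd at the final visit,
    concatenated with h_bwd at the first visit for a bidirectional model —
    and the per-step states of each direction (backward states listed in
    reversed-sequence order).
    """
    if seq.true_length < 1:
        raise ValueError("empty sequence")
    xs = seq.matrix[: seq.true_length]
    fwd = _run_direction(model.forward_params, xs)
    states = {"forward": fwd}
    feature = fwd[-1].h
    if model.direction == "bilstm":
        bwd = _run_direction(model.backward_params, xs[::-1])
        states["backward"] = bwd
        feature = np.concatenate([fwd[-1].h, bwd[-1].h])
    return feature, states


def class_probabilities(h: np.ndarray, out: OutputParams) -> np.ndarray:
    """Softmax of W h + b; strictly positive components summing to one."""
    z = out.weights @ h + out.bias
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# vectorized training path

def _reverse_within_length(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    n, t, _ = x.shape
    pos = np.arange(t)[None, :]
    rev = np.where(pos < lengths[:, None], lengths[:, None] - 1 - pos, pos)
    return x[np.arange(n)[:, None], rev]


def _forward_batch(x, lengths, wx, wh, b):
    n, t, _ = x.shape
    h4 = wh.shape[1]
    h = np.zeros((n, h4))
    c = np.zeros((n, h4))
    xproj = x.reshape(n * t, -1) @ wx.T
    xproj = xproj.reshape(n, t, -1)
    cache = []
    for step in range(t):
        pre = xproj[:, step] + h @ wh.T + b
        i = _sigmoid(pre[:, :h4])
        f = _sigmoid(pre[:, h4 : 2 * h4])
        o = _sigmoid(pre[:, 2 * h4 : 3 * h4])
        g = np.tanh(pre[:, 3 * h4 :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        m = (step < lengths).astype(np.float64)[:, None]
        cache.append((h, c, i, f, o, g, tc, m))
        h = m * (o * tc) + (1.0 - m) * h
        c = m * c_new + (1.0 - m) * c
    return h, cache


def _backward_batch(x, cache, dh_final, wh):
    n, t, d = x.shape
    h4 = wh.shape[1]
    dwx = np.zeros((4 * h4, d))
    dwh = np.zeros((4 * h4, h4))
    db = np.zeros(4 * h4)
    dh = dh_final
    dc = np.zeros_like(dh_final)
    for step in range(t - 1, -1, -1):
        h_prev, c_prev, i, f, o, g, tc, m = cache[step]
        dh_new = m * dh
        dh_carry = (1.0 - m) * dh
        dc_new = m * dc + dh_new * o * (1.0 - tc * tc)
        dc_carry = (1.0 - m) * dc
        do = dh_new * tc
        df = dc_new * c_prev
        di = dc_new * g
        dg = dc_new * i
        dpre = np.concatenate(
            [di * i * (1.0 - i), df * f * (1.0 - f), do * o * (1.0 - o),
             dg * (1.0 - g * g)],
            axis=1,
        )
        dwx += dpre.T @ x[:, step]
        dwh += dpre.T @ h_prev
        db += dpre.sum(axis=0)
        dh = dpre @ wh + dh_carry
        dc = dc_new * f + dc_carry
    return dwx, dwh, db


def _batch_features(x, lengths, params: dict, bidirectional: bool):
    h_f, cache_f = _forward_batch(x, lengths, params["wx_f"], params["wh_f"], params["b_f"])
    if not bidirectional:
        return h_f, (cache_f, None, None)
    x_rev = _reverse_within_length(x, lengths)
    h_b, cache_b = _forward_batch(x_rev, lengths, params["wx_b"], params["wh_b"], params["b_b"])
    return np.concatenate([h_f, h_b], axis=1), (cache_f, cache_b, x_rev)


def _batch_loss_grads(x, lengths, y, params, bidirectional, want_grads=True):
    feat, (cache_f, cache_b, x_rev) = _batch_features(x, lengths, params, bidirectional)
    logits = feat @ params["wout"].T + params["bout"]
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    p = e / e.sum(axis=1, keepdims=True)
    n = x.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    if not want_grads:
        return loss, p, None
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n
    grads = {
        "wout": dlogits.T @ feat,
        "bout": dlogits.sum(axis=0),
    }
    dfeat = dlogits @ params["wout"]
    h = params["wh_f"].shape[1]
    dwx, dwh, db = _backward_batch(x, cache_f, dfeat[:, :h], params["wh_f"])
    grads.update(wx_f=dwx, wh_f=dwh, b_f=db)
    if bidirectional:
        dwx, dwh, db = _backward_batch(x_rev, cache_b, dfeat[:, h:], params["wh_b"])
        grads.update(wx_b=dwx, wh_b=dwh, b_b=db)
    return loss, p, grads


def _init_params(rng, hidden, d, bidirectional):
    scale = 1.0 / np.sqrt(hidden)

    def u(*shape):
        return rng.uniform(-scale, scale, size=shape)

    params = {
        "wx_f": u(4 * hidden, d),
        "wh_f": u(4 * hidden, hidden),
        "b_f": u(4 * hidden),
        "wout": u(2, 2 * hidden if bidirectional else hidden),
        "bout": u(2),
    }
    if bidirectional:
        params.update(wx_b=u(4 * hidden, d), wh_b=u(4 * hidden, hidden),
                      b_b=u(4 * hidden))
    return params


def _encode_all(records: Sequence[PatientRecord], vocab: CodeVocabulary):
    seqs = [encode_patient(r, vocab) for r in records]
    x, lengths = pad_batch(seqs)
    y = np.array([1 if r.label == "case" else 0 for r in records], dtype=np.int64)
    return x, lengths, y


def train(
    split: CohortSplit,
    vocab: CodeVocabulary,
    cfg: TrainConfig = TrainConfig(),
    direction: str = "bilstm",
) -> BiLSTMModel:
    """Fit by Adam on cross-entropy with early stopping on validation loss.

    Stops when the validation loss has not improved for ``cfg.patience``
    consecutive epochs and returns the weights of the best validation epoch.
    Deterministic given ``cfg.seed``.
    """
    bidirectional = direction == "bilstm"
    x_tr, len_tr, y_tr = _encode_all(split.train, vocab)
    x_va, len_va, y_va = _encode_all(split.validation, vocab)
    rng = np.random.default_rng(cfg.seed)
    params = _init_params(rng, cfg.hidden_size, len(vocab), bidirectional)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(val) for k, val in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_loss = np.inf
    best_params = {k: val.copy() for k, val in params.items()}
    stale = 0
    val_losses: list[float] = []
    n = x_tr.shape[0]
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, _, grads = _batch_loss_grads(
                x_tr[idx], len_tr[idx], y_tr[idx], params, bidirectional
            )
            if not np.isfinite(loss):
                raise FloatingPointError("training diverged: non-finite loss")
            step += 1
            bc1 = 1.0 - beta1**step
            bc2 = 1.0 - beta2**step
            for k, g in grads.items():
                m[k] = beta1 * m[k] + (1.0 - beta1) * g
                v[k] = beta2 * v[k] + (1.0 - beta2) * g * g
                params[k] -= cfg.learning_rate * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + eps)
        val_loss, _, _ = _batch_loss_grads(
            x_va, len_va, y_va, params, bidirectional, want_grads=False
        )
        val_losses.append(float(val_loss))
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_params = {k: val.copy() for k, val in params.items()}
            stale = 0
        else:
            stale += 1
            if stale > cfg.patience:
                break
    fwd = LSTMParams.unpack(best_params["wx_f"], best_params["wh_f"], best_params["b_f"])
    bwd = None
    if bidirectional:
        bwd = LSTMParams.unpack(best_params["wx_b"], best_params["wh_b"], best_params["b_b"])
    out = OutputParams(weights=best_params["wout"].copy(), bias=best_params["bout"].copy())
    model = BiLSTMModel(
        direction=direction, forward_params=fwd, backward_params=bwd,
        output=out, vocab=vocab,
    )
    # diagnostic record of the early-stopping trajectory
    model.train_history = {
        "val_losses": val_losses,
        "epochs_run": len(val_losses),
        "best_val_loss": float(best_loss),
    }
    return model


def predict_case_probability(
    model: BiLSTMModel, records: Sequence[PatientRecord]
) -> np.ndarray:
    """Probability of class 1 (case) for each record, via the batched forward pass."""
    x, lengths, _ = _encode_all(records, model.vocab)
    params: dict[str, np.ndarray] = {}
    params["wx_f"], params["wh_f"], params["b_f"] = model.forward_params.pack()
    if model.backward_params is not None:
        params["wx_b"], params["wh_b"], params["b_b"] = model.backward_params.pack()
    feat, _ = _batch_features(x, lengths, params, model.direction == "bilstm")
    logits = feat @ model.output.weights.T + model.output.bias
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e[:, 1] / e.sum(axis=1)


# ---------------------------------------------------------------------------
# evaluation

def evaluate_auc_ci(
    models: Sequence[BiLSTMModel], test: Sequence[PatientRecord]
) -> tuple[float, float, float, list[float]]:
    """Mean test AUC over seeded runs with a normal-approximation 95% CI
    (mean +/- 1.96 * sd / sqrt(runs)); ties in scores count one half."""
    if len(models) < 2:
        raise ValueError("need at least 2 runs for a confidence interval")
    y = np.array([1 if r.label == "case" else 0 for r in test])
    if len(np.unique(y)) < 2:
        raise ValueError("test set contains a single class; AUC undefined")
    aucs = [float(roc_auc_score(y, predict_case_probability(m, test))) for m in models]
    mean = float(np.mean(aucs))
    sd = float(np.std(aucs, ddof=1))
    half = 1.96 * sd / np.sqrt(len(aucs))
    return mean, mean - half, mean + half, aucs


def format_auc_ci(mean: float, lo: float, hi: float) -> str:
    return f"{mean:.3f} ({lo:.3f}-{hi:.3f})"


def write_metrics_report(aucs_by_seed: dict[int, float], path: str) -> None:
    """CSV report: one (run_seed, auc) row per run plus a summary row with the
    mean and its 95% CI bounds."""
    import pandas as pd

    aucs = list(aucs_by_seed.values())
    mean = float(np.mean(aucs))
    sd = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0
    half = 1.96 * sd / np.sqrt(len(aucs))
    rows = [{"run_seed": s, "auc": a} for s, a in aucs_by_seed.items()]
    rows.append({"run_seed": "summary", "auc": mean,
                 "ci_low": mean - half, "ci_high": mean + half})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# serialization (exact round-trip via repr-precision floats)

def _array_to_obj(a: np.ndarray) -> dict:
    return {"shape": list(a.shape), "data": a.ravel().tolist()}


def _array_from_obj(obj: dict) -> np.ndarray:
    return np.array(obj["data"], dtype=np.float64).reshape(obj["shape"])


def _lstm_to_obj(p: LSTMParams) -> dict:
    return {name: _array_to_obj(getattr(p, name))
            for g in GATES for name in (f"W_{g}", f"U_{g}", f"b_{g}")}


def _lstm_from_obj(obj: dict) -> LSTMParams:
    return LSTMParams(**{k: _array_from_obj(v) for k, v in obj.items()})


def save_model(model: BiLSTMModel, path: str) -> None:
    obj = {
        "direction": model.direction,
        "vocab": list(model.vocab.codes),
        "vocab_level": int(model.vocab.level),
        "forward": _lstm_to_obj(model.forward_params),
        "backward": _lstm_to_obj(model.backward_params)
        if model.backward_params is not None
        else None,
        "output": {"weights": _array_to_obj(model.output.weights),
                   "bias": _array_to_obj(model.output.bias)},
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def load_model(path: str) -> BiLSTMModel:
    with open(path) as fh:
        obj = json.load(fh)
    from .ehr import CodeLevel

    vocab = CodeVocabulary(codes=tuple(obj["vocab"]), level=CodeLevel(obj["vocab_level"]))
    return BiLSTMModel(
        direction=obj["direction"],
        forward_params=_lstm_from_obj(obj["forward"]),
        backward_params=_lstm_from_obj(obj["backward"]) if obj["backward"] else None,
        output=OutputParams(
            weights=_array_from_obj(obj["output"]["weights"]),
            bias=_array_from_obj(obj["output"]["bias"]),
        ),
        vocab=vocab,
    )
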