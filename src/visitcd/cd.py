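"""Contextual decomposition (CD) of LSTM and BiLSTM classifiers.

CD splits every hidden and cell state of the recurrence into a *relevant*
part beta, driven solely by a chosen subset S of visits, and an *irrelevant*
remainder gamma, so that beta + gamma equals the exact forward state at every
step. The contribution of S to class j is the pre-softmax score W_j . beta
(W_j . [beta_fwd, beta_bwd] for a BiLSTM), and by construction

    score_relevant + score_irrelevant + b_j  ==  logit of the full model.

Nonlinearities are handled by Shapley linearization: the gate pre-activation
is written as a sum of a relevant, an irrelevant and a bias summand, and each
summand's contribution to sigma(sum) / tanh(sum) is its average marginal
effect over all orderings of the summands. Conventions fixed here: the
activation-at-zero offset is assigned to the bias summand (to the irrelevant
one when no bias summand participates); the bias-times-bias interaction term
of the cell update counts as relevant only at steps t in S; the output gate
is left undecomposed.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .ehr import EncodedSequence
from .model import BiLSTMModel, LSTMParams, OutputParams, _sigmoid

__all__ = [
    "VisitSubset",
    "CDState",
    "CDResult",
    "shapley_linearize",
    "cd_lstm",
    "cd_bilstm",
    "decompose",
    "visit_attributions",
]

_ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sigmoid": _sigmoid,
    "tanh": np.tanh,
}


@dataclass(frozen=True)
class VisitSubset:
    """A set of 1-based visit ordinals; the empty set is the null probe."""

    indices: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", frozenset(int(i) for i in self.indices))

    @classmethod
    def of(cls, indices: Iterable[int]) -> "VisitSubset":
        return cls(indices=frozenset(indices))

    def __contains__(self, t: int) -> bool:
        return t in self.indices


@dataclass
class CDState:
    """Decomposed hidden and cell state after one direction's recursion."""

    beta_h: np.ndarray
    gamma_h: np.ndarray
    beta_c: np.ndarray
    gamma_c: np.ndarray


@dataclass
class CDResult:
    subset: VisitSubset
    class_index: int
    score_relevant: float
    score_irrelevant: float
    logit: float
    beta: np.ndarray
    gamma: np.ndarray


def shapley_linearize(
    summands: Sequence[np.ndarray],
    activation: str,
    bias_index: int | None = None,
) -> list[np.ndarray]:
    """Split ``activation(sum(summands))`` into per-summand contributions.

    The contribution of summand k is its marginal effect on the activation,
    averaged elementwise over all permutations of the summands; the
    contributions then telescope to ``act(total) - act(0)``, and the ``act(0)``
    offset is added to the bias summand (``bias_index``) when one is present,
    otherwise to the last summand, which callers place as the irrelevant one.
    At most three summands (relevant, irrelevant, bias) are supported.
    """
    k = len(summands)
    if not 1 <= k <= 3:
        raise ValueError(f"need 1-3 summands, got {k}")
    act = _ACTIVATIONS[activation]
    summands = [np.asarray(s, dtype=np.float64) for s in summands]
    contribs = [np.zeros_like(s) for s in summands]
    perms = list(itertools.permutations(range(k)))
    for perm in perms:
        running = np.zeros_like(summands[0])
        prev = act(running)
        for idx in perm:
            running = running + summands[idx]
            cur = act(running)
            contribs[idx] = contribs[idx] + (cur - prev)
            prev = cur
    inv = 1.0 / len(perms)
    contribs = [c * inv for c in contribs]
    offset = float(act(np.zeros(1))[0])
    target = bias_index if bias_index is not None else k - 1
    contribs[target] = contribs[target] + offset
    return contribs


def _cd_direction(
    params: LSTMParams, xs: np.ndarray, in_subset: Sequence[bool]
) -> CDState:
    """CD recursion over one direction; ``xs`` holds the true visits in the
    direction's own time order and ``in_subset[t]`` marks membership of S."""
    hidden = params.hidden_size
    beta_h = np.zeros(hidden)
    gamma_h = np.zeros(hidden)
    beta_c = np.zeros(hidden)
    h = np.zeros(hidden)
    c = np.zeros(hidden)
    for x, rel_step in zip(xs, in_subset):
        lin: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for gate, activation in (("i", "sigmoid"), ("f", "sigmoid"), ("g", "tanh")):
            w = getattr(params, f"W_{gate}")
            u = getattr(params, f"U_{gate}")
            b = getattr(params, f"b_{gate}")
            wx = w @ x
            rel = u @ beta_h + (wx if rel_step else 0.0)
            irr = u @ gamma_h + (0.0 if rel_step else wx)
            lin[gate] = tuple(shapley_linearize([rel, irr, b], activation, bias_index=2))
        # exact forward states alongside the decomposition
        i = _sigmoid(params.W_i @ x + params.U_i @ h + params.b_i)
        f = _sigmoid(params.W_f @ x + params.U_f @ h + params.b_f)
        o = _sigmoid(params.W_o @ x + params.U_o @ h + params.b_o)
        g = np.tanh(params.W_g @ x + params.U_g @ h + params.b_g)
        c_new = f * c + i * g
        i_r, _, i_b = lin["i"]
        f_r, _, f_b = lin["f"]
        g_r, _, g_b = lin["g"]
        beta_c_new = (f_r + f_b) * beta_c + (i_r + i_b) * g_r + i_r * g_b
        if rel_step:
            beta_c_new = beta_c_new + i_b * g_b
        gamma_c_new = c_new - beta_c_new
        tanh_beta, _ = shapley_linearize([beta_c_new, gamma_c_new], "tanh")
        h_new = o * np.tanh(c_new)
        beta_h = o * tanh_beta
        gamma_h = h_new - beta_h
        beta_c, c, h = beta_c_new, c_new, h_new
    return CDState(beta_h=beta_h, gamma_h=gamma_h, beta_c=beta_c, gamma_c=c - beta_c)


def _check_subset(subset: VisitSubset, true_length: int) -> None:
    bad = [t for t in subset.indices if not 1 <= t <= true_length]
    if bad:
        raise ValueError(
            f"subset ordinals {sorted(bad)} outside the true sequence 1..{true_length}"
        )


def _projection(out: OutputParams, class_index: int, contrast: bool):
    if contrast:
        # convenience mode: score the class-1-minus-class-0 logit difference
        return out.weights[1] - out.weights[0], float(out.bias[1] - out.bias[0])
    return out.weights[class_index], float(out.bias[class_index])


def cd_lstm(
    params: LSTMParams,
    out: OutputParams,
    seq: EncodedSequence,
    subset: VisitSubset,
    class_index: int = 1,
    contrast: bool = False,
) -> CDResult:
    """Decompose a forward-only LSTM's class logit over the visit subset."""
    _check_subset(subset, seq.true_length)
    xs = seq.matrix[: seq.true_length]
    flags = [t + 1 in subset for t in range(seq.true_length)]
    state = _cd_direction(params, xs, flags)
    w_j, b_j = _projection(out, class_index, contrast)
    rel = float(w_j @ state.beta_h)
    irr = float(w_j @ state.gamma_h)
    return CDResult(
        subset=subset,
        class_index=class_index,
        score_relevant=rel,
        score_irrelevant=irr,
        logit=rel + irr + b_j,
        beta=state.beta_h,
        gamma=state.gamma_h,
    )


def cd_bilstm(
    model: BiLSTMModel,
    seq: EncodedSequence,
    subset: VisitSubset,
    class_index: int = 1,
    contrast: bool = False,
) -> CDResult:
    """Decompose a BiLSTM's class logit: the forward recursion runs on the
    sequence as-is and the backward recursion on the reversed sequence with S
    mapped through the reversal; beta/gamma concatenate as [fwd, bwd] to match
    the classifier's feature layout."""
    if model.direction != "bilstm":
        raise ValueError("model is forward-only; use cd_lstm")
    _check_subset(subset, seq.true_length)
    t_len = seq.true_length
    xs = seq.matrix[:t_len]
    flags_fwd = [t + 1 in subset for t in range(t_len)]
    fwd = _cd_direction(model.forward_params, xs, flags_fwd)
    bwd = _cd_direction(model.backward_params, xs[::-1], flags_fwd[::-1])
    beta = np.concatenate([fwd.beta_h, bwd.beta_h])
    gamma = np.concatenate([fwd.gamma_h, bwd.gamma_h])
    w_j, b_j = _projection(model.output, class_index, contrast)
    rel = float(w_j @ beta)
    irr = float(w_j @ gamma)
    return CDResult(
        subset=subset,
        class_index=class_index,
        score_relevant=rel,
        score_irrelevant=irr,
        logit=rel + irr + b_j,
        beta=beta,
        gamma=gamma,
    )


def decompose(
    model: BiLSTMModel,
    seq: EncodedSequence,
    subset: VisitSubset,
    class_index: int = 1,
    contrast: bool = False,
) -> CDResult:
    """Dispatch to :func:`cd_lstm` or :func:`cd_bilstm` by model direction."""
    if model.direction == "bilstm":
        return cd_bilstm(model, seq, subset, class_index, contrast)
    return cd_lstm(model.forward_params, model.output, seq, subset, class_index, contrast)


def visit_attributions(
    model: BiLSTMModel,
    seq: EncodedSequence,
    class_index: int = 1,
    contrast: bool = False,
) -> list[float]:
    """Per-visit CD scores: score_t = relevant score of the singleton S={t}."""
    return [
        decompose(model, seq, VisitSubset.of({t}), class_index, contrast).score_relevant
        for t in range(1, seq.true_length + 1)
    ]
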