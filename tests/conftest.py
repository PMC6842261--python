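import numpy as np
import pytest

from visitcd import (
    BiLSTMModel,
    CodeVocabulary,
    EncodedSequence,
    LSTMParams,
    OutputParams,
)


def random_lstm_params(rng, hidden, inputs, scale=0.5) -> LSTMParams:
    return LSTMParams(
        **{f"W_{g}": rng.normal(0, scale, (hidden, inputs)) for g in "ifog"},
        **{f"U_{g}": rng.normal(0, scale, (hidden, hidden)) for g in "ifog"},
        **{f"b_{g}": rng.normal(0, scale, hidden) for g in "ifog"},
    )


def random_model(rng, hidden=5, inputs=7, direction="bilstm") -> BiLSTMModel:
    width = 2 * hidden if direction == "bilstm" else hidden
    return BiLSTMModel(
        direction=direction,
        forward_params=random_lstm_params(rng, hidden, inputs),
        backward_params=random_lstm_params(rng, hidden, inputs)
        if direction == "bilstm"
        else None,
        output=OutputParams(
            weights=rng.normal(0, 0.5, (2, width)), bias=rng.normal(0, 0.5, 2)
        ),
        vocab=CodeVocabulary(tuple(f"{i:03d}" for i in range(inputs))),
    )


def random_sequence(rng, t, inputs, density=0.3) -> EncodedSequence:
    matrix = (rng.random((t, inputs)) < density).astype(float)
    # every visit carries at least one code
    empty = matrix.sum(axis=1) == 0
    matrix[empty, rng.integers(0, inputs, size=int(empty.sum()))] = 1.0
    return EncodedSequence(matrix=matrix, true_length=t, patient_id="R")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
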