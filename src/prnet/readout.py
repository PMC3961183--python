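"""Optimal linear readouts and lag-resolved classification performance.

Following the reservoir-computing probe, one multi-output linear
classifier is trained per time lag on recorded network states.  The
state matrix ``X`` (rows = time steps) is regressed onto one-hot
targets ``Y`` of the lagged input class by ordinary least squares via
the Moore-Penrose pseudoinverse,

    W_out = pinv(X) @ Y,

and decoding applies winner-take-all over the class scores of each
row.  Performance is the fraction of correctly classified rows;
chance level is ``1/n_classes``.  Negative lags probe memory of past
inputs, positive lags prediction of future ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkConfig, NetworkParams, kwta_step
from .tasks import Task, drive_matrix

__all__ = [
    "ReadoutModel",
    "fit_readout",
    "evaluate_performance",
    "record_trajectory",
    "lag_sweep",
]

#: relative singular-value cutoff for the pseudoinverse; binary k-sparse
#: state matrices are routinely rank-deficient.
PINV_RCOND = 1e-10


@dataclass
class ReadoutModel:
    """Per-lag linear readout: an ``N x n_classes`` weight matrix, no bias."""

    W_out: np.ndarray
    lag: int
    n_classes: int

    def scores(self, states: np.ndarray) -> np.ndarray:
        return states @ self.W_out

    def predict(self, states: np.ndarray) -> np.ndarray:
        """Winner-take-all class per row; score ties go to the lowest class."""
        return np.argmax(self.scores(states), axis=1)


def _lagged_rows(
    n_rows: int, labels: np.ndarray, lag: int
) -> tuple[np.ndarray, np.ndarray]:
    """Row indices whose lagged target exists, plus those targets.

    The label of row ``t`` at lag ``l`` is ``labels[t + l]``; rows whose
    target index falls outside the sequence, or whose target is the
    undefined sentinel -1, are dropped.
    """
    t = np.arange(n_rows)
    tgt = t + lag
    ok = (tgt >= 0) & (tgt < len(labels))
    ok[ok] &= labels[tgt[ok]] >= 0
    return t[ok], labels[tgt[ok]]


def fit_readout(
    states: np.ndarray, labels: np.ndarray, lag: int, n_classes: int
) -> ReadoutModel:
    """Least-squares fit of one-hot lagged targets from network states."""
    rows, y = _lagged_rows(states.shape[0], np.asarray(labels), lag)
    if rows.size == 0:
        raise ValueError("no training rows remain after lag trimming")
    X = states[rows].astype(float)
    Y = np.eye(n_classes)[y]
    W_out = np.linalg.pinv(X, rcond=PINV_RCOND) @ Y
    return ReadoutModel(W_out=W_out, lag=lag, n_classes=n_classes)


def evaluate_performance(
    model: ReadoutModel, states: np.ndarray, labels: np.ndarray
) -> float:
    """Fraction of rows whose winner-take-all class equals the lagged target."""
    if states.shape[1] != model.W_out.shape[0]:
        raise ValueError("state dimension does not match the readout")
    rows, y = _lagged_rows(states.shape[0], np.asarray(labels), model.lag)
    if rows.size == 0:
        raise ValueError("no rows to evaluate")
    pred = model.predict(states[rows].astype(float))
    return float(np.mean(pred == y))


def record_trajectory(
    config: NetworkConfig,
    params: NetworkParams,
    state: np.ndarray,
    task: Task,
    length: int,
    rng: np.random.Generator,
    nu: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the frozen network and record states and the driving symbols.

    Returns ``(states, seq, final_state)``; ``states[t]`` is the state
    emitted under input ``seq[t]``.  With ``nu > 0`` each emitted state
    is corrupted by flip noise before being recorded and fed back.
    """
    from .network import apply_flip_noise

    drives = drive_matrix(task.rf_map, config.drive_amplitude)
    seq = task.sequence(length, rng)
    states = np.empty((length, config.N), dtype=bool)
    x = state.astype(bool).copy()
    for t in range(length):
        x = kwta_step(x, params, drives[seq[t]], config.k, rng)
        if nu > 0.0:
            x = apply_flip_noise(x, nu, rng)
        states[t] = x
    return states, seq, x


def lag_sweep(
    config: NetworkConfig,
    params: NetworkParams,
    init_state: np.ndarray,
    task: Task,
    lags: range | list[int],
    train_len: int,
    test_len: int,
    rng: np.random.Generator,
    nu_train: float = 0.0,
    nu_test: float = 0.0,
) -> dict[int, float]:
    """Train and evaluate one readout per lag on a contiguous run.

    The testing trajectory continues from the training trajectory's
    final state (one uninterrupted run of the frozen network); one
    classifier is fitted per lag and scored on the held-out segment.
    """
    train_states, train_seq, x = record_trajectory(
        config, params, init_state, task, train_len, rng, nu=nu_train
    )
    test_states, test_seq, _ = record_trajectory(
        config, params, x, task, test_len, rng, nu=nu_test
    )
    y_train = task.targets(train_seq)
    y_test = task.targets(test_seq)
    out: dict[int, float] = {}
    for lag in lags:
        model = fit_readout(train_states, y_train, lag, task.n_classes)
        out[lag] = evaluate_performance(model, test_states, y_test)
    return out
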