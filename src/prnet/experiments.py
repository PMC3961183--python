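"""Experiment orchestration: seeded, reproducible sweeps over
plasticity conditions, perturbations and noise levels.

Every experiment is a pure function of its spec and seed list.  Results
are returned as tidy pandas DataFrames (one row per seed/condition/lag
or sweep point) ready to be written as delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import NetworkConfig, perturb_state
from .plasticity import CONDITIONS, train_condition
from .readout import lag_sweep, record_trajectory
from .information import (
    distinct_states,
    plugin_entropy,
    state_input_information,
)
from .tasks import make_task

__all__ = [
    "ExperimentSpec",
    "run_condition_experiment",
    "perturbation_sweep",
    "noise_sweep",
    "info_timecourse",
    "aggregate_performance",
]


@dataclass(frozen=True)
class ExperimentSpec:
    """Settings shared by the experiment drivers.

    ``seeds`` identifies the networks: one independent network per
    seed.  Defaults mirror the simulation conditions used throughout:
    a 50,000-step plasticity phase, 5,000-step training and testing
    phases, and readout lags -8..+8.
    """

    task: str = "rand4"
    condition: str = "SIP"
    seeds: tuple[int, ...] = tuple(range(10))
    plasticity_steps: int = 50_000
    train_len: int = 5_000
    test_len: int = 5_000
    lags: tuple[int, ...] = tuple(range(-8, 9))
    epsilons: tuple[int, ...] = (0, 2, 6, 12)
    noise_levels: tuple[float, ...] = (0.01, 0.02, 0.05, 0.1, 0.2)
    checkpoints: tuple[int, ...] = (0, 5_000, 10_000, 20_000, 50_000)
    config: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self) -> None:
        if len(set(self.seeds)) != len(self.seeds) or not self.seeds:
            raise ValueError("seeds must be nonempty and distinct")
        if any(c > self.plasticity_steps for c in self.checkpoints):
            raise ValueError("checkpoints must not exceed the plasticity phase")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


def _train_and_sweep(
    spec: ExperimentSpec,
    condition: str,
    seed: int,
    epsilon: int | None = None,
    nu_plast: float = 0.0,
    nu_train: float = 0.0,
    nu_test: float = 0.0,
) -> dict[int, float]:
    """One network: plasticity, optional perturbation/reset, lag sweep.

    ``epsilon=None`` resets to a uniformly random state (the default
    protocol); an integer epsilon perturbs the end-of-plasticity state
    to that exact Hamming distance.
    """
    task = make_task(spec.task, spec.config.N)
    rng = np.random.default_rng(seed)
    trained = train_condition(
        spec.config, condition, task, spec.plasticity_steps, rng, nu=nu_plast
    )
    if epsilon is None:
        from .network import random_state

        init = random_state(spec.config.N, spec.config.k, rng)
    else:
        init = perturb_state(trained.state, epsilon, rng)
    return lag_sweep(
        spec.config, trained.params, init, task, list(spec.lags),
        spec.train_len, spec.test_len, rng,
        nu_train=nu_train, nu_test=nu_test,
    )


def run_condition_experiment(
    spec: ExperimentSpec, conditions: tuple[str, ...] = ("SIP", "IP", "SP", "NONPLASTIC")
) -> pd.DataFrame:
    """Per-lag readout performance for each condition and seed.

    Networks are reset to a random state between the plasticity and
    training phases.  Returns rows (condition, task, lag, seed,
    performance).
    """
    rows = []
    for cond in conditions:
        for seed in spec.seeds:
            perf = _train_and_sweep(spec, cond, seed)
            for lag, p in perf.items():
                rows.append(
                    dict(condition=cond, task=spec.task, lag=lag, seed=seed, performance=p)
                )
    return pd.DataFrame(rows)


def aggregate_performance(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error over networks, per condition and lag."""
    g = table.groupby(["condition", "task", "lag"])["performance"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")


def perturbation_sweep(spec: ExperimentSpec) -> pd.DataFrame:
    """Performance and neural-code metrics after perturbing the
    end-of-plasticity state by each epsilon.

    Returns rows (condition, epsilon, seed, performance, entropy_bits,
    mi_bits); performance is the mean over the requested lags.
    """
    task_name = spec.task
    rows = []
    for eps in spec.epsilons:
        if eps % 2:
            raise ValueError("epsilons must be even")
        for seed in spec.seeds:
            perf = _train_and_sweep(spec, spec.condition, seed, epsilon=eps)
            # recompute the trajectory for the code metrics
            task = make_task(task_name, spec.config.N)
            rng = np.random.default_rng(seed)
            trained = train_condition(
                spec.config, spec.condition, task, spec.plasticity_steps, rng
            )
            init = perturb_state(trained.state, eps, rng)
            states, seq, _ = record_trajectory(
                spec.config, trained.params, init, task, spec.train_len, rng
            )
            rows.append(
                dict(
                    condition=spec.condition,
                    epsilon=eps,
                    seed=seed,
                    performance=float(np.mean(list(perf.values()))),
                    entropy_bits=plugin_entropy(states[100:]),
                    mi_bits=state_input_information(states, seq, rng=rng),
                )
            )
    return pd.DataFrame(rows)


def paired_noise_trajectories(
    config: NetworkConfig,
    params,
    init: np.ndarray,
    task,
    length: int,
    seq_rng: np.random.Generator,
    noise_rng: np.random.Generator,
    nu: float,
    clean_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """A noiseless and a noisy trajectory of the same network under the
    same input sequence.

    The noisy copy applies feedback flip noise at level ``nu`` to every
    emitted state.  Returns (clean_states, noisy_states, seq,
    measured_ratio) where the ratio is the mean fraction of spikes at
    which the two runs differ — the network may amplify the injected
    noise well beyond ``nu`` as the trajectories separate.
    """
    from .network import apply_flip_noise, hamming_distance
    from .readout import record_trajectory
    from .tasks import drive_matrix

    drives = drive_matrix(task.rf_map, config.drive_amplitude)
    seq = task.sequence(length, seq_rng)
    xc = (init if clean_init is None else clean_init).astype(bool).copy()
    xn = init.astype(bool).copy()
    clean = np.empty((length, config.N), dtype=bool)
    noisy = np.empty_like(clean)
    diff = 0
    for t in range(length):
        from .network import kwta_step

        xc = kwta_step(xc, params, drives[seq[t]], config.k)
        xn = kwta_step(xn, params, drives[seq[t]], config.k)
        xn = apply_flip_noise(xn, nu, noise_rng)
        clean[t], noisy[t] = xc, xn
        diff += hamming_distance(xc, xn)
    ratio = diff / (2 * config.k * length)
    return clean, noisy, seq, float(ratio)


def noise_sweep(spec: ExperimentSpec, mode: str = "robustness") -> pd.DataFrame:
    """Noise experiments.

    ``robustness`` mode: networks are trained (plasticity) without
    noise and the state is then perturbed by epsilon = 2k; feedback
    flip noise at each level acts during the readout training and
    testing phases.  Readouts are fitted separately on the noiseless
    and the noisy trajectory of the same network under the same input,
    and rows report the relative performance change together with the
    measured noisy-spike ratio between the paired runs (the band the
    change is compared against).

    ``constructive`` mode: the same noise level is applied in the
    plasticity, training and testing phases, with no perturbation
    (epsilon = 0); rows report absolute performance and code metrics.
    """
    from .readout import evaluate_performance, fit_readout

    rows = []
    two_k = 2 * spec.config.k
    for seed in spec.seeds:
        if mode == "robustness":
            task = make_task(spec.task, spec.config.N)
            rng = np.random.default_rng(seed)
            trained = train_condition(
                spec.config, spec.condition, task, spec.plasticity_steps, rng
            )
            init = perturb_state(trained.state, two_k, rng)
            for nu in spec.noise_levels:
                seq_rng = np.random.default_rng((seed, 1))
                noise_rng = np.random.default_rng((seed, 2))
                ctr, ntr, seq_tr, r1 = paired_noise_trajectories(
                    spec.config, trained.params, init, task,
                    spec.train_len, seq_rng, noise_rng, nu,
                )
                cte, nte, seq_te, r2 = paired_noise_trajectories(
                    spec.config, trained.params, ntr[-1], task,
                    spec.test_len, seq_rng, noise_rng, nu,
                    clean_init=ctr[-1],
                )
                perfs = {}
                for label, (Xtr, Xte) in {
                    "clean": (ctr, cte), "noisy": (ntr, nte)
                }.items():
                    y_tr, y_te = task.targets(seq_tr), task.targets(seq_te)
                    vals = [
                        evaluate_performance(
                            fit_readout(Xtr, y_tr, lag, task.n_classes), Xte, y_te
                        )
                        for lag in spec.lags
                    ]
                    perfs[label] = float(np.mean(vals))
                rows.append(
                    dict(
                        condition=spec.condition, seed=seed, nu=nu,
                        performance=perfs["noisy"], baseline=perfs["clean"],
                        relative_change=(perfs["noisy"] - perfs["clean"])
                        / perfs["clean"],
                        noisy_spike_ratio=(r1 + r2) / 2,
                    )
                )
        elif mode == "constructive":
            for nu in [0.0, *spec.noise_levels]:
                perf = _train_and_sweep(
                    spec, spec.condition, seed, epsilon=0,
                    nu_plast=nu, nu_train=nu, nu_test=nu,
                )
                task = make_task(spec.task, spec.config.N)
                rng = np.random.default_rng(seed)
                trained = train_condition(
                    spec.config, spec.condition, task, spec.plasticity_steps, rng, nu=nu
                )
                states, seq, _ = record_trajectory(
                    spec.config, trained.params, trained.state, task,
                    spec.train_len, rng, nu=nu,
                )
                rows.append(
                    dict(
                        condition=spec.condition, seed=seed, nu=nu,
                        performance=float(np.mean(list(perf.values()))),
                        entropy_bits=plugin_entropy(states[100:]),
                        mi_bits=state_input_information(states, seq, rng=rng),
                    )
                )
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows)


def info_timecourse(
    spec: ExperimentSpec, conditions: tuple[str, ...] = ("SIP", "IP", "SP"),
    sample_len: int = 5_000,
) -> pd.DataFrame:
    """Entropy and 3-step-window MI at checkpoints of the plasticity phase.

    At each checkpoint the parameters are frozen, the network is
    reinitialized to a random state, driven for ``sample_len`` steps,
    and the trajectory (after a 100-step transient) is passed to the
    estimators.
    """
    from .network import random_state

    rows = []
    for cond in conditions:
        for seed in spec.seeds:
            task = make_task(spec.task, spec.config.N)
            rng = np.random.default_rng(seed)
            trained = train_condition(
                spec.config, cond, task, spec.plasticity_steps, rng,
                checkpoints=spec.checkpoints,
            )
            for step, params in sorted(trained.checkpoints.items()):
                init = random_state(spec.config.N, spec.config.k, rng)
                states, seq, _ = record_trajectory(
                    spec.config, params, init, task, sample_len, rng
                )
                rows.append(
                    dict(
                        condition=cond, seed=seed, step=step,
                        entropy_bits=plugin_entropy(states[100:]),
                        n_states=distinct_states(states[100:]),
                        mi_bits=state_input_information(states, seq, rng=rng),
                    )
                )
    return pd.DataFrame(rows)
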