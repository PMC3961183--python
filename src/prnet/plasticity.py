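"""Plasticity rules and training protocols.

Two local rules shape the network during a plasticity phase:

* **STDP** (spike-timing-dependent plasticity): a synapse ``j -> i`` is
  potentiated by ``eta`` when the presynaptic neuron fires one step
  before the postsynaptic neuron and depressed by ``eta`` in the
  reverse order,

      dW_ij = eta * (x_i(t) x_j(t-1) - x_i(t-1) x_j(t)),

  with hard bounds keeping every weight in ``[0, 1]``.  When both
  neurons fire at t-1 and at t the two terms cancel exactly.

* **IP** (intrinsic plasticity): each threshold moves toward the state
  that equalizes firing rates at the population rate ``k/N``,

      dT_i = eta_ip * (x_i(t) - k/N).

  The rule is subtractive and conserves the threshold sum exactly.

Four training conditions are supported: ``SIP`` (both rules), ``SP``
(STDP only), ``IP`` (a pre-phase with both rules, then a weight
shuffle that destroys the learned structure while keeping the weight
distribution, then an IP-only phase), and ``NONPLASTIC`` (STDP
training followed by a weight shuffle, then frozen).  The variant
``SP+IPTHRESH`` combines the weights of an SP run with the thresholds
of an IP run post hoc, removing any interaction between the two rules
during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    NetworkConfig,
    NetworkParams,
    apply_flip_noise,
    initialize_network,
    kwta_step,
)
from .tasks import Task, drive_matrix

__all__ = [
    "CONDITIONS",
    "stdp_update",
    "ip_update",
    "shuffle_weights",
    "run_plasticity_phase",
    "train_condition",
    "TrainedNetwork",
]

CONDITIONS = ("SIP", "SP", "IP", "NONPLASTIC", "SP+IPTHRESH")


def stdp_update(
    params: NetworkParams,
    x_prev: np.ndarray,
    x_curr: np.ndarray,
    eta: float,
    respect_mask: bool = False,
) -> None:
    """Apply one antisymmetric STDP step in place.

    Only the entries at (currently active) x (previously active) index
    pairs can change, so the update touches at most ``2 k^2`` weights.
    """
    W = params.W
    ci = np.flatnonzero(x_curr)
    pi = np.flatnonzero(x_prev)
    pot = np.ix_(ci, pi)
    dep = np.ix_(pi, ci)
    if respect_mask:
        W[pot] += eta * params.mask[pot]
        W[dep] -= eta * params.mask[dep]
    else:
        W[pot] += eta
        W[dep] -= eta
        np.fill_diagonal(W, 0.0)
    W[pot] = np.clip(W[pot], 0.0, 1.0)
    W[dep] = np.clip(W[dep], 0.0, 1.0)
    if not respect_mask:
        # potentiation may recruit new synapses and depression may
        # prune them; keep the mask synchronized with the support of W
        params.mask[pot] = W[pot] > 0
        params.mask[dep] = W[dep] > 0
        np.fill_diagonal(params.mask, False)


def ip_update(
    params: NetworkParams, x_curr: np.ndarray, eta_ip: float, target_rate: float
) -> None:
    """Homeostatic threshold step in place: ``dT = eta_ip (x - target)``.

    With ``target_rate = k/N`` the total threshold mass is conserved at
    every step since the state carries exactly ``k`` ones.
    """
    params.T += eta_ip * (x_curr - target_rate)


def shuffle_weights(params: NetworkParams, rng: np.random.Generator) -> NetworkParams:
    """Destroy the weight structure, keeping the weight distribution.

    The multiset of nonzero efficacies is permuted onto uniformly
    random off-diagonal positions; the mask follows the new positions
    and the diagonal stays zero.
    """
    N = params.W.shape[0]
    offdiag = ~np.eye(N, dtype=bool)
    W = np.zeros_like(params.W)
    W[offdiag] = rng.permutation(params.W[offdiag])
    out = NetworkParams(W=W, mask=W > 0, T=params.T.copy())
    out.validate()
    return out


@dataclass
class TrainedNetwork:
    """Result of a training run: parameters, final state, bookkeeping."""

    config: NetworkConfig
    condition: str
    task_name: str
    params: NetworkParams
    state: np.ndarray
    checkpoints: dict[int, NetworkParams] = field(default_factory=dict)


def run_plasticity_phase(
    config: NetworkConfig,
    params: NetworkParams,
    state: np.ndarray,
    task: Task,
    steps: int,
    rng: np.random.Generator,
    stdp_on: bool = True,
    ip_on: bool = True,
    nu: float = 0.0,
    checkpoints: tuple[int, ...] = (),
) -> dict[int, NetworkParams]:
    """Drive the network for ``steps`` steps, updating enabled rules in place.

    Per step: draw the input symbol, apply the drive, take one kWTA
    step, optionally corrupt the emitted state with flip noise, then
    apply the enabled plasticity rules.  Plasticity always sees the
    state the network actually emits (the post-noise state when noise
    is on).  Returns parameter snapshots at the requested step indices
    (a snapshot at step ``s`` reflects ``s`` completed updates).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    drives = drive_matrix(task.rf_map, config.drive_amplitude)
    seq = task.sequence(steps, rng)
    target_rate = config.k / config.N
    snaps: dict[int, NetworkParams] = {}
    checkpoint_set = set(checkpoints)
    if 0 in checkpoint_set:
        snaps[0] = params.copy()
    for t in range(steps):
        new = kwta_step(state, params, drives[seq[t]], config.k, rng)
        if nu > 0.0:
            new = apply_flip_noise(new, nu, rng)
        if stdp_on and config.eta_stdp > 0:
            stdp_update(
                params, state, new, config.eta_stdp,
                respect_mask=config.stdp_respect_mask,
            )
        if ip_on and config.eta_ip > 0:
            ip_update(params, new, config.eta_ip, target_rate)
        state[:] = new
        if (t + 1) in checkpoint_set:
            snaps[t + 1] = params.copy()
    return snaps


def train_condition(
    config: NetworkConfig,
    condition: str,
    task: Task,
    steps: int,
    rng: np.random.Generator,
    nu: float = 0.0,
    checkpoints: tuple[int, ...] = (),
) -> TrainedNetwork:
    """Initialize a network and train it under one of the named conditions.

    ``IP`` runs a pre-phase of the same length with both rules active,
    shuffles the weights, and only then runs the IP-only phase, so that
    its weight distribution matches the STDP-shaped conditions while
    carrying no structure.  ``NONPLASTIC`` is an SP run whose weights
    are shuffled and then frozen.  ``SP+IPTHRESH`` grafts the
    thresholds of an independent IP run onto the weights of an SP run.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    params, state = initialize_network(config, rng)
    out = TrainedNetwork(
        config=config, condition=condition, task_name=task.name,
        params=params, state=state,
    )
    if condition == "SIP":
        out.checkpoints = run_plasticity_phase(
            config, params, state, task, steps, rng,
            stdp_on=True, ip_on=True, nu=nu, checkpoints=checkpoints,
        )
    elif condition == "SP":
        out.checkpoints = run_plasticity_phase(
            config, params, state, task, steps, rng,
            stdp_on=True, ip_on=False, nu=nu, checkpoints=checkpoints,
        )
    elif condition == "IP":
        run_plasticity_phase(
            config, params, state, task, steps, rng,
            stdp_on=True, ip_on=True, nu=nu,
        )
        out.params = shuffle_weights(params, rng)
        out.checkpoints = run_plasticity_phase(
            config, out.params, state, task, steps, rng,
            stdp_on=False, ip_on=True, nu=nu, checkpoints=checkpoints,
        )
    elif condition == "NONPLASTIC":
        run_plasticity_phase(
            config, params, state, task, steps, rng,
            stdp_on=True, ip_on=False, nu=nu,
        )
        out.params = shuffle_weights(params, rng)
    elif condition == "SP+IPTHRESH":
        run_plasticity_phase(
            config, params, state, task, steps, rng,
            stdp_on=True, ip_on=False, nu=nu,
        )
        donor = train_condition(config, "IP", task, steps, rng, nu=nu)
        out.params.T = donor.params.T.copy()
    return out
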