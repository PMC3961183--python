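"""Core k-winner-take-all (kWTA) binary recurrent network.

The network consists of ``N`` memoryless binary neurons of which exactly
``k`` fire at every discrete time step.  The update is

    a_i(t+1) = sum_j W_ij x_j(t) + u_i(t+1) - T_i
    x(t+1)   = kWTA_k(a(t+1))

where ``W`` is the (sparse, bounded, zero-diagonal) recurrent efficacy
matrix, ``T`` the vector of firing thresholds and ``u`` the external
drive.  The kWTA nonlinearity sets the ``k`` units with the highest
membrane potential to 1 and all others to 0, which clamps the population
firing rate at ``k/N`` without an explicit inhibitory population.

States live in the Hamming metric space of binary vectors; because every
valid state has Hamming length exactly ``k``, pairwise distances between
valid states are even and bounded by ``2k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkConfig",
    "NetworkParams",
    "initialize_network",
    "kwta_step",
    "hamming_distance",
    "apply_flip_noise",
    "perturb_state",
    "random_state",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Structural and plasticity parameters of a kWTA network.

    Parameters
    ----------
    N : int
        Number of neurons.
    k : int
        Number of winners per time step (``k < N``).
    eta_stdp, eta_ip : float
        Learning rates of the synaptic (STDP) and intrinsic (threshold)
        plasticity rules.
    connectivity : float
        Bernoulli probability of an off-diagonal synapse existing.
    w_init_max : float
        Initial weights are drawn uniformly on ``[0, w_init_max]``.
    thr_sd : float
        Initial thresholds are Gaussian with zero mean and this s.d.
    drive_amplitude : float
        External drive delivered to each neuron of the active receptive
        field.  Its scale relative to the threshold spread and to the
        saturated recurrent input decides whether the input or the
        recurrence dominates the winner selection.
    stdp_respect_mask : bool
        When True, STDP only modifies synapses present in the initial
        connectivity mask; by default potentiation may recruit any
        off-diagonal pair (the initial 10% sparsity constrains the
        starting weights, not the plasticity rule).
    """

    N: int = 100
    k: int = 12
    eta_stdp: float = 0.001
    eta_ip: float = 0.001
    connectivity: float = 0.10
    w_init_max: float = 0.1
    thr_sd: float = 0.1
    drive_amplitude: float = 0.2
    stdp_respect_mask: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.k < self.N):
            raise ValueError(f"need 0 < k < N, got k={self.k}, N={self.N}")
        if not (0.0 < self.connectivity <= 1.0):
            raise ValueError("connectivity must lie in (0, 1]")
        if self.eta_stdp < 0 or self.eta_ip < 0:
            raise ValueError("learning rates must be nonnegative")


@dataclass
class NetworkParams:
    """Recurrent weight matrix, connectivity mask and thresholds.

    Invariants (checked by :meth:`validate`): the diagonal of ``W`` is
    zero, all weights lie in ``[0, 1]`` and ``W`` is nonzero only where
    ``mask`` is True.
    """

    W: np.ndarray
    mask: np.ndarray
    T: np.ndarray

    def validate(self) -> None:
        N = self.W.shape[0]
        if self.W.shape != (N, N) or self.mask.shape != (N, N) or self.T.shape != (N,):
            raise ValueError("inconsistent parameter shapes")
        if np.any(np.diag(self.W) != 0) or np.any(np.diag(self.mask)):
            raise ValueError("self-coupling is not allowed (diagonal must be zero)")
        if self.W.min() < 0 or self.W.max() > 1:
            raise ValueError("weights must lie in [0, 1]")
        if np.any(self.W[~self.mask] != 0):
            raise ValueError("weights outside the connectivity mask must be zero")

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.W.copy(), self.mask.copy(), self.T.copy())


def random_state(N: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """A uniformly random valid state: exactly ``k`` of ``N`` ones."""
    x = np.zeros(N, dtype=bool)
    x[rng.choice(N, size=k, replace=False)] = True
    return x


def initialize_network(
    config: NetworkConfig, rng: np.random.Generator
) -> tuple[NetworkParams, np.ndarray]:
    """Draw initial parameters and a random initial state.

    Off-diagonal synapses exist with probability ``config.connectivity``
    and carry uniform ``[0, w_init_max]`` efficacies; thresholds are
    Gaussian ``(0, thr_sd)``.
    """
    N = config.N
    mask = rng.random((N, N)) < config.connectivity
    np.fill_diagonal(mask, False)
    W = np.where(mask, rng.uniform(0.0, config.w_init_max, (N, N)), 0.0)
    T = rng.normal(0.0, config.thr_sd, N)
    state = random_state(N, config.k, rng)
    params = NetworkParams(W=W, mask=mask, T=T)
    params.validate()
    return params, state


def _top_k(a: np.ndarray, k: int, rng: np.random.Generator | None) -> np.ndarray:
    """Indices of the k largest entries of ``a``.

    Ties at the k-th value are broken by lowest index when ``rng`` is
    None (deterministic mode), otherwise uniformly at random from the
    run's stream.  After training, weights are effectively continuous
    and exact ties have measure zero; the rule only matters for
    hand-built degenerate inputs.
    """
    if k >= a.size:
        return np.arange(a.size)
    thr = np.partition(a, a.size - k)[a.size - k]
    sure = np.flatnonzero(a > thr)
    tied = np.flatnonzero(a == thr)
    need = k - sure.size
    if need == tied.size:
        chosen = tied
    elif rng is None:
        chosen = tied[:need]
    else:
        chosen = rng.choice(tied, size=need, replace=False)
    return np.concatenate([sure, chosen])


def kwta_step(
    state: np.ndarray,
    params: NetworkParams,
    drive: np.ndarray,
    k: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One deterministic network update.

    Membrane potentials are ``a = W @ x + drive - T``; exactly the ``k``
    highest-potential units fire in the returned state.
    """
    if drive.shape != state.shape:
        raise ValueError("drive must have length N")
    a = params.W @ state + drive - params.T
    out = np.zeros_like(state, dtype=bool)
    out[_top_k(a, k, rng)] = True
    return out


def hamming_distance(x: np.ndarray, y: np.ndarray) -> int:
    """Number of positions at which the two binary vectors differ."""
    if x.shape != y.shape:
        raise ValueError("states must have equal length")
    return int(np.count_nonzero(x.astype(bool) ^ y.astype(bool)))


def apply_flip_noise(
    state: np.ndarray, nu: float, rng: np.random.Generator
) -> np.ndarray:
    """Spike-flip noise that preserves the kWTA constraint.

    Each active neuron falls silent independently with probability
    ``nu``; for every silenced neuron one uniformly chosen neuron that
    is silent (after the silencing step) fires instead, so the output
    still has exactly ``k`` ones.
    """
    if not (0.0 <= nu <= 1.0):
        raise ValueError("nu must lie in [0, 1]")
    out = state.astype(bool).copy()
    active = np.flatnonzero(out)
    flips = active[rng.random(active.size) < nu]
    if flips.size == 0:
        return out
    out[flips] = False
    silent = np.flatnonzero(~out)
    out[rng.choice(silent, size=flips.size, replace=False)] = True
    return out


def perturb_state(
    state: np.ndarray, epsilon: int, rng: np.random.Generator
) -> np.ndarray:
    """Move the state to exact Hamming distance ``epsilon``.

    ``epsilon/2`` randomly chosen active neurons are silenced and
    ``epsilon/2`` randomly chosen silent neurons fire instead; the
    result is a valid state at distance exactly ``epsilon``.
    """
    if epsilon % 2 != 0 or epsilon < 0:
        raise ValueError("epsilon must be an even nonnegative integer")
    half = epsilon // 2
    out = state.astype(bool).copy()
    active = np.flatnonzero(out)
    silent = np.flatnonzero(~out)
    if half > active.size or half > silent.size:
        raise ValueError("epsilon too large for this state")
    if half == 0:
        return out
    out[rng.choice(active, size=half, replace=False)] = False
    out[rng.choice(silent, size=half, replace=False)] = True
    return out
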