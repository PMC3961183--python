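"""Input-sequence generators, receptive fields and task targets.

Three benchmark tasks drive the network:

* ``RAND x 4`` — four symbols drawn i.i.d. uniformly; probes how much
  of the past is retained in the network state.
* ``Markov-85`` — four symbols from a Markov chain that follows the
  cycle A -> B -> C -> D -> A with probability 0.85 and takes any other
  transition with probability 0.05; probes whether temporal structure
  in the input is learned and can be predicted.
* ``Parity-3`` — two symbols drawn i.i.d. uniformly; the target is the
  parity (XOR) of three successive inputs, a nonlinear function of the
  input history.

Each symbol has a disjoint receptive field: a block of neurons that
receives a constant positive drive while the symbol is presented
(field size 15 for the four-symbol tasks, 40 for the binary task).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MarkovChainSpec",
    "UniformSpec",
    "markov85_spec",
    "generate_sequence",
    "ReceptiveFieldMap",
    "make_receptive_fields",
    "drive_vector",
    "parity3_target",
    "parity3_targets",
    "make_task",
    "Task",
]


@dataclass(frozen=True)
class UniformSpec:
    """I.i.d. uniform draws over ``n_symbols`` symbols."""

    n_symbols: int

    def __post_init__(self) -> None:
        if self.n_symbols < 1:
            raise ValueError("need at least one symbol")


@dataclass(frozen=True)
class MarkovChainSpec:
    """First-order Markov chain over ``transition.shape[0]`` symbols."""

    transition: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.transition, dtype=float)
        pi = np.asarray(self.initial, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1] or pi.shape != (P.shape[0],):
            raise ValueError("transition must be square and match initial")
        if P.min() < 0 or pi.min() < 0:
            raise ValueError("probabilities must be nonnegative")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(pi.sum(), 1.0, atol=1e-12):
            raise ValueError("initial distribution must sum to 1")
        object.__setattr__(self, "transition", P)
        object.__setattr__(self, "initial", pi)

    @property
    def n_symbols(self) -> int:
        return self.transition.shape[0]


def markov85_spec() -> MarkovChainSpec:
    """The 4-symbol chain cycling 0->1->2->3->0 at 0.85, else 0.05.

    The matrix is doubly stochastic, so the stationary distribution is
    uniform; the initial symbol is drawn from it.
    """
    P = np.full((4, 4), 0.05)
    for s in range(4):
        P[s, (s + 1) % 4] = 0.85
    return MarkovChainSpec(transition=P, initial=np.full(4, 0.25))


def generate_sequence(
    spec: UniformSpec | MarkovChainSpec, length: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw a symbol sequence (integer array) from the given spec."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if isinstance(spec, UniformSpec):
        return rng.integers(0, spec.n_symbols, size=length)
    if isinstance(spec, MarkovChainSpec):
        seq = np.empty(length, dtype=np.int64)
        cumulative = spec.transition.cumsum(axis=1)
        u = rng.random(length)
        seq[0] = np.searchsorted(spec.initial.cumsum(), u[0], side="right")
        for t in range(1, length):
            seq[t] = np.searchsorted(cumulative[seq[t - 1]], u[t], side="right")
        return seq
    raise TypeError(f"unknown sequence spec: {spec!r}")


@dataclass(frozen=True)
class ReceptiveFieldMap:
    """Disjoint symbol -> neuron-index-set mapping."""

    fields: tuple[np.ndarray, ...]
    N: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for f in self.fields:
            idx = set(int(i) for i in f)
            if idx & seen:
                raise ValueError("receptive fields must be pairwise disjoint")
            if f.min() < 0 or f.max() >= self.N:
                raise ValueError("receptive field index out of range")
            seen |= idx

    @property
    def n_symbols(self) -> int:
        return len(self.fields)


def make_receptive_fields(
    n_symbols: int,
    field_size: int,
    N: int,
    rng: np.random.Generator | None = None,
) -> ReceptiveFieldMap:
    """Assign disjoint receptive fields.

    By default fields are contiguous index blocks (symbol ``s`` owns
    neurons ``[s*field_size, (s+1)*field_size)``), which is convenient
    for inspection; pass an ``rng`` for a randomized disjoint
    assignment instead.
    """
    if n_symbols * field_size > N:
        raise ValueError("receptive fields do not fit into the network")
    if rng is None:
        pool = np.arange(n_symbols * field_size)
    else:
        pool = rng.choice(N, size=n_symbols * field_size, replace=False)
    fields = tuple(
        np.sort(pool[s * field_size : (s + 1) * field_size]) for s in range(n_symbols)
    )
    return ReceptiveFieldMap(fields=fields, N=N)


def drive_vector(
    symbol: int, rf_map: ReceptiveFieldMap, amplitude: float, N: int
) -> np.ndarray:
    """External-drive vector: ``amplitude`` on the symbol's field, else 0."""
    if not (0 <= symbol < rf_map.n_symbols):
        raise KeyError(f"unknown symbol {symbol!r}")
    if N != rf_map.N:
        raise ValueError("N does not match the receptive-field map")
    u = np.zeros(N)
    u[rf_map.fields[symbol]] = amplitude
    return u


def drive_matrix(rf_map: ReceptiveFieldMap, amplitude: float) -> np.ndarray:
    """All per-symbol drive vectors stacked as rows (n_symbols x N)."""
    return np.stack(
        [drive_vector(s, rf_map, amplitude, rf_map.N) for s in range(rf_map.n_symbols)]
    )


def parity3_target(seq: np.ndarray, t: int, lag: int) -> int | None:
    """Parity (XOR) of the three successive binary inputs ending at ``t + lag``.

    Returns ``None`` when the three-step window falls outside the
    sequence; such rows are excluded from readout training.
    """
    end = t + lag
    if end - 2 < 0 or end >= len(seq):
        return None
    window = seq[end - 2 : end + 1]
    return int(window[0] ^ window[1] ^ window[2])


def parity3_targets(seq: np.ndarray) -> np.ndarray:
    """Vectorized parity labels: entry ``t`` is the XOR of inputs t-2..t.

    The first two entries, where the window is incomplete, are -1.
    """
    seq = np.asarray(seq)
    out = np.full(len(seq), -1, dtype=np.int64)
    if len(seq) >= 3:
        out[2:] = seq[2:] ^ seq[1:-1] ^ seq[:-2]
    return out


@dataclass(frozen=True)
class Task:
    """A task bundles a sequence spec, receptive fields and targets."""

    name: str
    spec: UniformSpec | MarkovChainSpec
    rf_map: ReceptiveFieldMap
    n_classes: int

    def sequence(self, length: int, rng: np.random.Generator) -> np.ndarray:
        return generate_sequence(self.spec, length, rng)

    def targets(self, seq: np.ndarray) -> np.ndarray:
        """Per-time-step class labels (-1 marks undefined rows)."""
        if self.name == "parity3":
            return parity3_targets(seq)
        return np.asarray(seq, dtype=np.int64)


_FIELD_SIZES = {"rand4": 15, "markov85": 15, "parity3": 40}


def make_task(
    name: str,
    N: int = 100,
    rng: np.random.Generator | None = None,
    field_size: int | None = None,
) -> Task:
    """Construct one of the three named benchmark tasks.

    ``field_size`` overrides the task's default receptive-field size
    (15 for the four-symbol tasks, 40 for the binary one), e.g. for
    reduced networks.
    """
    if name == "rand4":
        spec: UniformSpec | MarkovChainSpec = UniformSpec(4)
        n_classes = 4
    elif name == "markov85":
        spec = markov85_spec()
        n_classes = 4
    elif name == "parity3":
        spec = UniformSpec(2)
        n_classes = 2
    else:
        raise ValueError(f"unknown task {name!r}")
    n_symbols = 4 if n_classes == 4 else 2
    size = _FIELD_SIZES[name] if field_size is None else field_size
    rf_map = make_receptive_fields(n_symbols, size, N, rng)
    return Task(name=name, spec=spec, rf_map=rf_map, n_classes=n_classes)
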