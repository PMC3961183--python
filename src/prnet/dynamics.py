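"""Nonautonomous-dynamics toolkit: limit cycles, volumes of
representation, inclusion checks, ellipsoid summaries and
attractor-distance features.

Clamping one input symbol turns the driven network into a
deterministic autonomous map on the finite set of valid states, so a
trajectory must revisit a state and from there on follows a limit
cycle.  The *volume of representation* of an input sequence is the
set of states observed immediately after that sequence was applied;
its *order* is the sequence length.  On a single sampled trajectory
the volumes obey an exact nesting (inclusion) property: every
order-(n+1) volume is a subset of the order-n volume sharing its most
recent inputs, and the order-n volume is the union of its
refinements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkConfig, NetworkParams, kwta_step
from .tasks import Task, drive_matrix

__all__ = [
    "LimitCycle",
    "find_limit_cycle",
    "sample_volumes",
    "volume_inclusion_check",
    "EllipsoidSummary",
    "ellipsoid_summary",
    "attractor_distance_features",
]


@dataclass
class LimitCycle:
    """An ordered state cycle of the clamped-input map."""

    vertexes: np.ndarray  # (period, N) boolean
    clamped_symbol: int

    @property
    def period(self) -> int:
        return self.vertexes.shape[0]

    def verify(self, config: NetworkConfig, params: NetworkParams, drive: np.ndarray) -> bool:
        """Re-simulate one period from every vertex; must reproduce the cycle."""
        for i in range(self.period):
            nxt = kwta_step(self.vertexes[i], params, drive, config.k)
            if not np.array_equal(nxt, self.vertexes[(i + 1) % self.period]):
                return False
        return True


def find_limit_cycle(
    config: NetworkConfig,
    params: NetworkParams,
    task: Task,
    clamped_symbol: int,
    init: np.ndarray,
    max_iters: int = 10_000,
    transient: int = 1_000,
) -> LimitCycle:
    """Iterate the deterministic clamped-input map until a state revisit.

    The map is run for ``transient`` steps first to leave the
    transient, then every visited state is indexed until the first
    revisit closes the cycle.  The deterministic tie rule (lowest
    index) is used so the map is a function of the state alone.
    """
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    drive = drive_matrix(task.rf_map, config.drive_amplitude)[clamped_symbol]
    x = init.astype(bool).copy()
    for _ in range(transient):
        x = kwta_step(x, params, drive, config.k)
    seen: dict[bytes, int] = {}
    trail: list[np.ndarray] = []
    for i in range(max_iters):
        key = x.tobytes()
        if key in seen:
            return LimitCycle(
                vertexes=np.array(trail[seen[key] :]), clamped_symbol=clamped_symbol
            )
        seen[key] = i
        trail.append(x)
        x = kwta_step(x, params, drive, config.k)
    raise RuntimeError(f"no state revisit within {max_iters} iterations")


def sample_volumes(
    config: NetworkConfig,
    params: NetworkParams,
    init: np.ndarray,
    task: Task,
    run_length: int,
    max_order: int,
    rng: np.random.Generator,
    transient: int = 100,
) -> dict[tuple[int, ...], set[bytes]]:
    """Volumes of representation from one driven trajectory.

    Each visited state (after the transient) is binned under the keys
    of its most recent 1..max_order inputs; the value sets hold the
    packed state bytes.  Keys are symbol tuples ordered oldest-first,
    so ``(a, b)`` means input ``a`` then ``b``, with ``b`` most recent.
    """
    drives = drive_matrix(task.rf_map, config.drive_amplitude)
    seq = task.sequence(run_length, rng)
    x = init.astype(bool).copy()
    volumes: dict[tuple[int, ...], set[bytes]] = {}
    for t in range(run_length):
        x = kwta_step(x, params, drives[seq[t]], config.k)
        if t < transient:
            continue
        key_bytes = x.tobytes()
        for order in range(1, max_order + 1):
            if t - order + 1 < 0:
                break
            key = tuple(int(s) for s in seq[t - order + 1 : t + 1])
            volumes.setdefault(key, set()).add(key_bytes)
    return volumes


def volume_inclusion_check(
    volumes: dict[tuple[int, ...], set[bytes]]
) -> tuple[bool, list[str]]:
    """Verify subset and union relations between volume orders.

    Every order-(n+1) volume must be a subset of the order-n volume
    sharing its most recent n inputs, and each order-n volume must
    equal the union of its observed order-(n+1) refinements.  Returns
    (ok, list of named violations); on volumes sampled from a single
    trajectory any violation indicates an implementation bug.
    """
    violations: list[str] = []
    max_order = max((len(k) for k in volumes), default=0)
    for key, states in volumes.items():
        if len(key) < 2:
            continue
        parent = key[1:]
        if parent not in volumes:
            violations.append(f"missing parent {parent} of {key}")
        elif not states <= volumes[parent]:
            violations.append(f"{key} not a subset of {parent}")
    for key, states in volumes.items():
        if len(key) >= max_order:
            continue
        children = [v for ck, v in volumes.items() if len(ck) == len(key) + 1 and ck[1:] == key]
        if children:
            union: set[bytes] = set().union(*children)
            # the earliest steps of a run have no order-(n+1) history;
            # beyond that the union must reconstitute the parent
            if not union <= states:
                violations.append(f"union of refinements of {key} exceeds it")
            if states - union:
                violations.append(f"union of refinements of {key} misses states")
    return (not violations), violations


@dataclass
class EllipsoidSummary:
    """Axis-aligned ellipsoid summarizing a state set in PCA coordinates."""

    center: np.ndarray
    semi_axes: np.ndarray
    mode: str

    def overlaps(self, other: "EllipsoidSummary") -> bool:
        """Conservative overlap test along each axis (bounding boxes)."""
        lo1, hi1 = self.center - self.semi_axes, self.center + self.semi_axes
        lo2, hi2 = other.center - other.semi_axes, other.center + other.semi_axes
        return bool(np.all((lo1 <= hi2) & (lo2 <= hi1)))


def ellipsoid_summary(
    states: np.ndarray,
    basis_mean: np.ndarray,
    basis_components: np.ndarray,
    mode: str = "mean-sd",
    percentiles: tuple[float, float] = (5.0, 95.0),
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
) -> EllipsoidSummary:
    """Summarize a state set as an ellipsoid in a fixed PCA basis.

    ``mean-sd`` mode: center = coordinate means, semi-axes = coordinate
    standard deviations.  ``percentile`` mode: the axes extend to the
    given percentiles of bootstrap-resampled coordinate means.
    """
    states = np.asarray(states, dtype=float)
    if states.ndim != 2 or states.shape[0] < 1:
        raise ValueError("need a (n_states, N) array")
    coords = (states - basis_mean) @ basis_components.T
    if states.shape[0] == 1:
        import warnings

        warnings.warn("singleton state set: zero semi-axes")
        return EllipsoidSummary(coords[0], np.zeros(coords.shape[1]), mode)
    if mode == "mean-sd":
        return EllipsoidSummary(coords.mean(axis=0), coords.std(axis=0), mode)
    if mode == "percentile":
        rng = np.random.default_rng(0) if rng is None else rng
        idx = rng.integers(0, coords.shape[0], size=(n_boot, coords.shape[0]))
        boot_means = coords[idx].mean(axis=1)
        lo = np.percentile(boot_means, percentiles[0], axis=0)
        hi = np.percentile(boot_means, percentiles[1], axis=0)
        center = coords.mean(axis=0)
        return EllipsoidSummary(center, np.maximum(hi - center, center - lo), mode)
    raise ValueError(f"unknown mode {mode!r}")


def attractor_distance_features(
    trajectory: np.ndarray, cycles: list[LimitCycle]
) -> np.ndarray:
    """Hamming distances from each state to every vertex of every cycle.

    Row ``t`` concatenates, over all cycles and their vertexes, the
    Hamming distance of ``trajectory[t]`` to that vertex.  These
    features compress the geometric relation of the driven trajectory
    (the meta-transient) to the clamped-input attractors and can be
    fed to linear readouts in place of the raw states.
    """
    if not cycles:
        raise ValueError("need at least one cycle")
    traj = np.asarray(trajectory, dtype=bool)
    verts = np.concatenate([c.vertexes for c in cycles], axis=0).astype(bool)
    # d(x, v) = |x| + |v| - 2 x.v with |x| = |v| = k
    dots = traj.astype(np.int64) @ verts.T.astype(np.int64)
    kx = traj.sum(axis=1, keepdims=True)
    kv = verts.sum(axis=1, keepdims=True).T
    return kx + kv - 2 * dots
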