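"""Information-theoretic quantification of the neural code.

Two estimators are provided:

* a plug-in (empirical-frequency) entropy for discrete network states,
  exact for the small state sets that STDP-only networks collapse to;
* a Kraskov-style k-nearest-neighbor mutual-information estimator for
  the general case, where states are first reduced by PCA to the
  components carrying 95% of the variance and input windows are
  embedded through a 3-bit symbol code with equal pairwise Hamming
  distances between the four symbols.

Entropy and mutual information are reported in bits.
"""

from __future__ import annotations

import numpy as np

from scipy.special import digamma
from sklearn.decomposition import PCA

__all__ = [
    "plugin_entropy",
    "distinct_states",
    "plugin_mutual_information",
    "pca_reduce",
    "knn_mutual_information",
    "SYMBOL_CODE",
    "encode_windows",
    "state_input_information",
]

#: even-weight 3-bit codewords for the four input symbols; any two
#: codewords are at Hamming distance exactly 2.
SYMBOL_CODE = np.array(
    [[0, 0, 0], [0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float
)

#: jitter amplitude used to break distance ties before neighbor search;
#: the k-NN estimator assumes continuous densities and binary states
#: produce massive ties without it.
_JITTER = 1e-10


def _row_ids(samples: np.ndarray) -> np.ndarray:
    """Integer id per distinct row."""
    arr = np.ascontiguousarray(np.asarray(samples))
    _, ids = np.unique(arr, axis=0, return_inverse=True)
    return ids


def plugin_entropy(samples: np.ndarray) -> float:
    """Empirical (plug-in) entropy of the sample rows, in bits."""
    samples = np.asarray(samples)
    if samples.size == 0:
        raise ValueError("need at least one sample")
    counts = np.bincount(_row_ids(samples))
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def distinct_states(samples: np.ndarray) -> int:
    """Number of distinct rows in the sample."""
    return int(_row_ids(np.asarray(samples)).max()) + 1


def plugin_mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Exact plug-in MI between two discrete row-samples, in bits.

    Serves as the independent cross-check of the k-NN estimator on
    fully enumerable joints.
    """
    xi, yi = _row_ids(x), _row_ids(y)
    joint = np.stack([xi, yi], axis=1)
    return plugin_entropy(xi[:, None]) + plugin_entropy(yi[:, None]) - plugin_entropy(joint)


def pca_reduce(
    samples: np.ndarray, variance_fraction: float = 0.95
) -> tuple[np.ndarray, int]:
    """Project onto the minimal leading principal subspace covering
    ``variance_fraction`` of the variance.

    Returns the projected coordinates and the component count.  A
    zero-variance input yields zero components.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] < 2:
        raise ValueError("need at least two samples")
    centered = samples - samples.mean(axis=0)
    if not np.any(centered):
        import warnings

        warnings.warn("zero-variance input: returning 0 components")
        return np.empty((samples.shape[0], 0)), 0
    pca = PCA(svd_solver="full")
    coords = pca.fit_transform(samples)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    n_comp = min(n_comp, coords.shape[1])
    return coords[:, :n_comp], n_comp


def _chebyshev_block(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Chebyshev (max-norm) distances between row blocks."""
    from scipy.spatial.distance import cdist

    return cdist(a, b, metric="chebyshev")


def knn_mutual_information(
    x_samples: np.ndarray,
    y_samples: np.ndarray,
    k_neighbors: int = 3,
    rng: np.random.Generator | None = None,
) -> float:
    """Kraskov k-NN estimate of I(X; Y), in bits.

    Uses the first Kraskov estimator: with ``eps_i`` the Chebyshev
    distance to the k-th joint neighbor, ``n_x`` and ``n_y`` count
    marginal neighbors strictly within ``eps_i`` and

        I = psi(k) + psi(n) - < psi(n_x + 1) + psi(n_y + 1) >.

    A tiny isotropic jitter is added to both samples first to break
    the distance ties that exact repeats of discrete data produce.
    """
    x = np.asarray(x_samples, dtype=float)
    y = np.asarray(y_samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have the same number of rows")
    n = x.shape[0]
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if n <= k_neighbors:
        raise ValueError("need more samples than k_neighbors")
    rng = np.random.default_rng(0) if rng is None else rng
    x = x + rng.uniform(-_JITTER, _JITTER, x.shape)
    y = y + rng.uniform(-_JITTER, _JITTER, y.shape)
    # brute-force Chebyshev distances in row chunks: KD-trees degrade in
    # the high-dimensional joint space while n stays modest here
    nx = np.empty(n, dtype=np.int64)
    ny = np.empty(n, dtype=np.int64)
    chunk = max(1, int(2**22 // max(n, 1)))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        dx = _chebyshev_block(x[lo:hi], x)
        dy = _chebyshev_block(y[lo:hi], y)
        dz = np.maximum(dx, dy)
        rows = np.arange(hi - lo)
        dz[rows, np.arange(lo, hi)] = np.inf  # exclude self
        eps = np.partition(dz, k_neighbors - 1, axis=1)[:, k_neighbors - 1]
        r = eps[:, None] * (1 - 1e-12)
        nx[lo:hi] = (dx < r).sum(axis=1) - 1
        ny[lo:hi] = (dy < r).sum(axis=1) - 1
    est = digamma(k_neighbors) + digamma(n) - np.mean(
        digamma(nx + 1) + digamma(ny + 1)
    )
    return float(est / np.log(2))


def encode_windows(seq: np.ndarray, window: int = 3) -> np.ndarray:
    """Embed the most recent ``window`` symbols of each time step.

    Row ``t`` is the concatenation of the 3-bit codewords of symbols
    ``t - window + 1 .. t``; the first ``window - 1`` rows, whose
    window is incomplete, are dropped by the caller via the returned
    offset convention (rows start at index ``window - 1``).
    """
    seq = np.asarray(seq)
    if len(seq) < window:
        raise ValueError("sequence shorter than the window")
    cols = [SYMBOL_CODE[seq[i : len(seq) - window + 1 + i]] for i in range(window)]
    return np.hstack(cols)


def state_input_information(
    states: np.ndarray,
    seq: np.ndarray,
    window: int = 3,
    k_neighbors: int = 3,
    variance_fraction: float = 0.95,
    rng: np.random.Generator | None = None,
) -> float:
    """MI (bits) between network states and the last ``window`` inputs.

    States are PCA-reduced at the given variance fraction; the input
    windows are embedded with the 3-bit symbol code.  ``states[t]``
    is paired with inputs ``seq[t-window+1..t]``.
    """
    states = np.asarray(states)
    if states.shape[0] != len(seq):
        raise ValueError("states and seq must be aligned")
    coords, _ = pca_reduce(states, variance_fraction)
    xw = encode_windows(seq, window)
    return knn_mutual_information(
        coords[window - 1 :], xw, k_neighbors=k_neighbors, rng=rng
    )
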