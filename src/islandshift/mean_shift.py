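"""From-scratch mean-shift clustering of window composition vectors.

The density of the n feature vectors x_i in R^d is estimated with a
radially symmetric kernel K(x) = c_{k,d} k(||x||^2):

    f_h(x) = 1/(n h^d) * sum_i K((x - x_i)/h)

Differentiating and writing g = -k' yields the mean-shift vector

    m_h(x) = sum_i x_i g(||(x - x_i)/h||^2) / sum_i g(...) - x,

which points toward the maximum increase of the estimated density.  Each
point is iterated x <- x + m_h(x) until the displacement falls below a
threshold; points converging to the same stationary point (mode) form one
cluster.  The number of clusters is therefore a consequence of the
bandwidth h, not an input.

Only the mode-merging step leans on scipy (single-linkage grouping of the
converged modes); the mean-shift procedure itself is implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist


class IsolatedPointError(ValueError):
    """All shadow weights vanished: the point sees no data at this bandwidth."""


@dataclass(frozen=True)
class KernelSpec:
    """A radially symmetric kernel: profile k, shadow g = -k', normalization.

    ``profile`` and ``shadow`` act on the *squared* scaled distance
    ||(x - x_i)/h||^2 and must be vectorized (accept ndarray).
    """

    name: str
    profile: Callable[[np.ndarray], np.ndarray]
    shadow: Callable[[np.ndarray], np.ndarray]
    c_kd: float
    d: int = 4


def get_kernel(name: str, d: int = 4) -> KernelSpec:
    """Return the gaussian or flat (uniform-ball) kernel in dimension *d*."""
    if name == "gaussian":
        # k(x) = exp(-x/2), g = -k' = k/2; c_kd = (2 pi)^(-d/2)
        return KernelSpec(
            name="gaussian",
            profile=lambda x: np.exp(-0.5 * x),
            shadow=lambda x: 0.5 * np.exp(-0.5 * x),
            c_kd=(2.0 * math.pi) ** (-d / 2.0),
            d=d,
        )
    if name == "flat":
        # k = indicator [0,1]; g likewise; c_kd = 1/volume(unit d-ball)
        return KernelSpec(
            name="flat",
            profile=lambda x: (x <= 1.0).astype(float),
            shadow=lambda x: (x <= 1.0).astype(float),
            c_kd=math.gamma(d / 2.0 + 1.0) / math.pi ** (d / 2.0),
            d=d,
        )
    raise ValueError(f"unknown kernel {name!r} (expected 'gaussian' or 'flat')")


@dataclass
class MeanShiftConfig:
    """Bandwidth and convergence controls for the mode-seeking iteration."""

    bandwidth: float
    epsilon: float = 1e-3
    max_iterations: int = 500
    mode_merge_radius: float | None = None  # default: bandwidth / 10

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.mode_merge_radius is not None and self.mode_merge_radius <= 0:
            raise ValueError("mode_merge_radius must be positive")

    @property
    def merge_radius(self) -> float:
        if self.mode_merge_radius is not None:
            return self.mode_merge_radius
        return self.bandwidth / 10.0


@dataclass(frozen=True)
class ModeResult:
    """Endpoint of the mean-shift trajectory started at ``start_point``."""

    start_point: np.ndarray
    mode: np.ndarray
    iterations: int
    converged: bool


@dataclass
class Clustering:
    """A partition of the input points by shared density mode."""

    labels: np.ndarray          # per-point cluster id, 0-based
    modes: list[np.ndarray]     # one representative mode per cluster
    cluster_mass: np.ndarray | None = None  # per-cluster total bp, if known

    @property
    def n_clusters(self) -> int:
        return len(self.modes)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster_id)[0]

    def to_tsv(self) -> str:
        lines = ["window\tcluster"]
        lines += [f"{i}\t{int(c)}" for i, c in enumerate(self.labels)]
        return "\n".join(lines) + "\n"


def _as_array(data: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("data must be a list of equal-length vectors")
    return arr


def density_estimate(
    x: np.ndarray,
    data: Sequence[np.ndarray] | np.ndarray,
    kernel: KernelSpec,
    h: float,
) -> float:
    """Kernel density estimate f_h(x) = 1/(n h^d) sum_i K((x - x_i)/h)."""
    arr = _as_array(data)
    if arr.shape[0] == 0:
        raise ValueError("data must be non-empty")
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    sq = np.sum(((np.asarray(x, float) - arr) / h) ** 2, axis=1)
    n, d = arr.shape
    return float(kernel.c_kd * kernel.profile(sq).sum() / (n * h**d))


def mean_shift_vector(
    x: np.ndarray,
    data: Sequence[np.ndarray] | np.ndarray,
    kernel: KernelSpec,
    h: float,
) -> np.ndarray:
    """The shift m_h(x): g-weighted mean of the data minus x.

    Raises :class:`IsolatedPointError` when every shadow weight is zero
    (flat kernel with an empty window, or gaussian weights underflowing);
    callers treat such a point as its own mode.
    """
    arr = _as_array(data)
    x = np.asarray(x, dtype=float)
    sq = np.sum(((x - arr) / h) ** 2, axis=1)
    w = kernel.shadow(sq)
    total = w.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise IsolatedPointError(
            "all kernel weights vanished; point is isolated at this bandwidth"
        )
    return (w @ arr) / total - x


def shift_to_mode(
    x0: np.ndarray,
    data: Sequence[np.ndarray] | np.ndarray,
    kernel: KernelSpec,
    config: MeanShiftConfig,
) -> ModeResult:
    """Iterate x <- x + m_h(x) from *x0* until ||x^{t+1} - x^t|| < epsilon.

    Non-convergence within ``max_iterations`` is flagged, not raised: the
    trajectory endpoint is still a usable mode estimate.
    """
    x0 = np.asarray(x0, dtype=float)
    x = x0.copy()
    for it in range(1, config.max_iterations + 1):
        try:
            shift = mean_shift_vector(x, data, kernel, config.bandwidth)
        except IsolatedPointError:
            # nothing within reach: x is its own stationary point
            return ModeResult(start_point=x0, mode=x, iterations=it,
                              converged=True)
        x_next = x + shift
        if float(np.linalg.norm(shift)) < config.epsilon:
            return ModeResult(start_point=x0, mode=x_next, iterations=it,
                              converged=True)
        x = x_next
    return ModeResult(start_point=x0, mode=x,
                      iterations=config.max_iterations, converged=False)


def cluster_modes(
    mode_results: Sequence[ModeResult],
    merge_radius: float,
) -> Clustering:
    """Group converged modes by single linkage at *merge_radius*.

    Modes whose single-linkage (transitive nearest-neighbour) distance is
    below the radius are identified as one mode; points sharing a mode form
    one cluster.  Cluster ids are ordered by first-occurring point index.
    """
    modes = np.array([r.mode for r in mode_results], dtype=float)
    n = modes.shape[0]
    if n == 0:
        raise ValueError("no mode results")
    if n == 1:
        raw = np.zeros(1, dtype=int)
    else:
        Z = linkage(modes, method="single")
        raw = fcluster(Z, t=merge_radius, criterion="distance") - 1
    # relabel so cluster ids follow first occurrence order
    labels = np.empty(n, dtype=int)
    remap: dict[int, int] = {}
    for i, r in enumerate(raw):
        if r not in remap:
            remap[int(r)] = len(remap)
        labels[i] = remap[int(r)]
    k = len(remap)
    reps = [modes[labels == c].mean(axis=0) for c in range(k)]
    return Clustering(labels=labels, modes=reps)


def run_mean_shift(
    data: Sequence[np.ndarray] | np.ndarray,
    kernel: KernelSpec,
    config: MeanShiftConfig,
    masses: Sequence[int] | None = None,
) -> Clustering:
    """Cluster all points: mode seeking per point, then mode merging.

    *masses* optionally carries a per-point bp length (window length); the
    per-cluster totals are then filled into ``cluster_mass``.
    """
    arr = _as_array(data)
    if arr.shape[0] == 0:
        raise ValueError("data must be non-empty")
    results = [shift_to_mode(x, arr, kernel, config) for x in arr]
    clustering = cluster_modes(results, config.merge_radius)
    if masses is not None:
        m = np.asarray(masses, dtype=np.int64)
        clustering.cluster_mass = np.array(
            [int(m[clustering.labels == c].sum())
             for c in range(clustering.n_clusters)],
            dtype=np.int64,
        )
    return clustering


def max_pairwise_distance(data: Sequence[np.ndarray] | np.ndarray) -> float:
    """Largest euclidean distance between any two points (data diameter)."""
    arr = _as_array(data)
    if arr.shape[0] < 2:
        return 0.0
    return float(pdist(arr).max())
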