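"""Hyperparameter tuning with the scheme's bespoke cost functions.

Two costs, one per clustering family:

* partition/hierarchical/graph methods are scored from the labeled
  clustering's macro-averaged sensitivity and precision,
  ``C = (1 - S_rec) + 0.1 * |S_rec - S_pre|``
  — minimized by perfect, balanced class performance;
* DBSCAN, whose cluster count cannot be fixed in advance, is scored by
  ``C = N_out + (1 - beta) * (alpha * |N_in - K|) + beta * sigma``
  with ``N_out`` the noise count, ``N_in`` the number of recovered clusters,
  ``K`` the expected count (4 categories), ``alpha = 100`` the deviation
  penalty, ``beta = 0.01`` the variance weight and ``sigma`` the mean squared
  deviation of per-cluster sizes from the expected 180 frames per class.

The search driver minimizes either cost over a parameter space by Bayesian
optimization (Gaussian-process surrogate with expected improvement) or by
seeded random search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

from .clustering import ClusterResult

DEFAULT_ALPHA = 100.0
DEFAULT_BETA = 0.01
DEFAULT_K = 4
DEFAULT_N_TARGET = 180


def cost_partition(S_rec: float, S_pre: float) -> float:
    """Cost for methods with a fixed cluster count.

    ``(1 - S_rec) + 0.1 * |S_rec - S_pre|`` with both scores macro-averaged
    over categories; zero iff recall and precision are both perfect.
    """
    if not (0.0 <= S_rec <= 1.0 and 0.0 <= S_pre <= 1.0):
        raise ValueError("scores must lie in [0, 1]")
    return (1.0 - S_rec) + 0.1 * abs(S_rec - S_pre)


def cost_dbscan(labels, K: int = DEFAULT_K, alpha: float = DEFAULT_ALPHA,
                beta: float = DEFAULT_BETA, n_target: int = DEFAULT_N_TARGET) -> float:
    """Cost steering DBSCAN toward K clean clusters of the expected size.

    ``sigma`` is the mean squared deviation of each non-noise cluster's size
    from ``n_target`` — zero exactly when every cluster holds the expected
    per-class frame count.
    """
    arr = labels.labels if isinstance(labels, ClusterResult) else np.asarray(labels, dtype=int)
    if arr.size == 0:
        raise ValueError("empty labels")
    n_out = int((arr == -1).sum())
    kept = arr[arr >= 0]
    if kept.size == 0:
        raise ValueError("no non-noise points")
    sizes = np.bincount(kept)
    sizes = sizes[sizes > 0]
    n_in = len(sizes)
    sigma = float(((sizes - n_target) ** 2).mean())
    return n_out + (1.0 - beta) * (alpha * abs(n_in - K)) + beta * sigma


@dataclass
class SearchSpace:
    """Named parameter space with an evaluation budget.

    ``dims`` maps a parameter name to ``("int", lo, hi)``, ``("log", lo, hi)``
    (log-uniform continuous), ``("uniform", lo, hi)`` or
    ``("choice", options)``.
    """

    method: str
    dims: dict[str, tuple]
    budget: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if not self.dims:
            raise ValueError("empty search space")
        for name, spec in self.dims.items():
            kind = spec[0]
            if kind in ("int", "log", "uniform"):
                lo, hi = spec[1], spec[2]
                if not lo <= hi:
                    raise ValueError(f"bounds for {name} are not well-ordered")
                if kind == "log" and lo <= 0:
                    raise ValueError(f"log bounds for {name} must be positive")
            elif kind == "choice":
                if not spec[1]:
                    raise ValueError(f"no options for {name}")
            else:
                raise ValueError(f"unknown dimension kind {kind!r}")


@dataclass
class SearchResult:
    best_params: dict[str, Any]
    best_cost: float
    trace: list[tuple[dict, float]] = field(default_factory=list)


def _sample(space: SearchSpace, rng: np.random.Generator) -> dict[str, Any]:
    point = {}
    for name, spec in space.dims.items():
        kind = spec[0]
        if kind == "int":
            point[name] = int(rng.integers(spec[1], spec[2] + 1))
        elif kind == "uniform":
            point[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "log":
            point[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        else:
            point[name] = spec[1][int(rng.integers(len(spec[1])))]
    return point


def _encode(space: SearchSpace, point: dict) -> np.ndarray:
    """Map a params point to a unit-scaled numeric vector for the surrogate."""
    x = []
    for name, spec in space.dims.items():
        kind = spec[0]
        v = point[name]
        if kind == "int" or kind == "uniform":
            lo, hi = spec[1], spec[2]
            x.append((v - lo) / (hi - lo) if hi > lo else 0.0)
        elif kind == "log":
            lo, hi = np.log(spec[1]), np.log(spec[2])
            x.append((np.log(v) - lo) / (hi - lo) if hi > lo else 0.0)
        else:
            opts = spec[1]
            x.append(opts.index(v) / max(1, len(opts) - 1))
    return np.asarray(x)


def search(space: SearchSpace, evaluator: Callable[[dict], float],
           strategy: str = "bo") -> SearchResult:
    """Minimize ``evaluator`` over ``space``; reproducible given ``space.seed``.

    ``strategy="random"`` draws uniform points.  ``strategy="bo"`` seeds with
    random points (a third of the budget, at most 10) and then proposes the
    expected-improvement argmax over a random candidate pool under a
    Gaussian-process surrogate.
    """
    if strategy not in ("bo", "random"):
        raise ValueError("strategy must be 'bo' or 'random'")
    rng = np.random.default_rng(space.seed)
    trace: list[tuple[dict, float]] = []

    def record(point) -> float:
        cost = float(evaluator(point))
        trace.append((point, cost))
        return cost

    if strategy == "random":
        for _ in range(space.budget):
            record(_sample(space, rng))
    else:
        from scipy.stats import norm
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import Matern, WhiteKernel

        n_init = min(10, max(2, space.budget // 3))
        for _ in range(min(n_init, space.budget)):
            record(_sample(space, rng))
        while len(trace) < space.budget:
            X = np.array([_encode(space, p) for p, _ in trace])
            y = np.array([c for _, c in trace])
            y_mean, y_sd = y.mean(), max(y.std(), 1e-12)
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5) + WhiteKernel(1e-6, noise_level_bounds=(1e-12, 1e2)),
                normalize_y=False, random_state=int(rng.integers(2**31 - 1)))
            import warnings
            from sklearn.exceptions import ConvergenceWarning

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(X, (y - y_mean) / y_sd)
            pool = [_sample(space, rng) for _ in range(256)]
            Xp = np.array([_encode(space, p) for p in pool])
            mu, sd = gp.predict(Xp, return_std=True)
            best = (y.min() - y_mean) / y_sd
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (best - mu) / sd
                ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
            ei[sd < 1e-12] = 0.0
            record(pool[int(np.argmax(ei))])

    best_params, best_cost = min(trace, key=lambda pc: pc[1])
    return SearchResult(best_params, best_cost, trace)
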