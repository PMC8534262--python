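"""Sequential model-based (Bayesian) hyperparameter search.

A Gaussian-process surrogate (Matern kernel) is fitted to the evaluated
(configuration, score) pairs and the next configuration is chosen from a
finite seeded candidate pool by expected improvement.  Dimensions are
declared as categorical choices, integer ranges, or (optionally
log-scaled) float ranges; all are encoded into [0, 1]^d for the
surrogate.  The search is deterministic given the seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def sample(self, rng) -> object:
        return self.choices[rng.integers(len(self.choices))]

    def encode(self, value) -> float:
        return self.choices.index(value) / max(len(self.choices) - 1, 1)


@dataclass(frozen=True)
class Integer:
    lo: int
    hi: int  # inclusive

    def sample(self, rng) -> int:
        return int(rng.integers(self.lo, self.hi + 1))

    def encode(self, value) -> float:
        return (value - self.lo) / max(self.hi - self.lo, 1)


@dataclass(frozen=True)
class Real:
    lo: float
    hi: float
    log: bool = False

    def sample(self, rng) -> float:
        if self.log:
            return float(np.exp(rng.uniform(math.log(self.lo), math.log(self.hi))))
        return float(rng.uniform(self.lo, self.hi))

    def encode(self, value) -> float:
        if self.log:
            return (math.log(value) - math.log(self.lo)) / (
                math.log(self.hi) - math.log(self.lo)
            )
        return (value - self.lo) / (self.hi - self.lo)


def _encode(space: dict, params: dict) -> list[float]:
    return [space[k].encode(params[k]) for k in space]


def bayes_search(
    objective,
    space: dict,
    n_iter: int = 32,
    n_init: int = 8,
    pool_size: int = 256,
    seed: int = 0,
):
    """Maximize ``objective(params)`` over the space; returns (best_params,
    best_score, trace).

    trace is the list of (params, score) in evaluation order.
    """
    rng = np.random.default_rng(seed)
    pool: list[dict] = []
    seen = set()
    for _ in range(pool_size * 4):
        cand = {k: dim.sample(rng) for k, dim in space.items()}
        key = tuple(sorted((k, repr(v)) for k, v in cand.items()))
        if key not in seen:
            seen.add(key)
            pool.append(cand)
        if len(pool) >= pool_size:
            break
    n_iter = min(n_iter, len(pool))
    n_init = min(n_init, n_iter)

    trace: list[tuple[dict, float]] = []
    evaluated = np.zeros(len(pool), dtype=bool)
    for i in range(n_init):
        evaluated[i] = True
        trace.append((pool[i], float(objective(pool[i]))))

    X_pool = np.array([_encode(space, p) for p in pool])
    while len(trace) < n_iter:
        X = np.array([_encode(space, p) for p, _ in trace])
        y = np.array([s for _, s in trace])
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=0.3 * np.ones(X.shape[1])),
            alpha=1e-4,
            normalize_y=True,
            random_state=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(X, y)
            mu, sigma = gp.predict(X_pool, return_std=True)
        best = y.max()
        sigma = np.maximum(sigma, 1e-12)
        z = (mu - best) / sigma
        ei = (mu - best) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)
        ei[evaluated] = -np.inf
        pick = int(np.argmax(ei))
        evaluated[pick] = True
        trace.append((pool[pick], float(objective(pool[pick]))))

    best_params, best_score = max(trace, key=lambda t: t[1])
    return best_params, best_score, trace
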