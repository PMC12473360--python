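"""Sequential model-based hyperparameter search (tree-structured Parzen estimator).

A compact TPE in the style of sequential model-based optimisation: after a
random startup phase, observed trials are split at the gamma-quantile of the
objective into "good" and "bad" sets; per dimension, each set is modelled by
a Parzen mixture (truncated normals for numeric dimensions, add-one-smoothed
categoricals for choices).  Candidates are drawn from the good-set mixture
and the one maximising the density ratio l(x)/g(x) is proposed.  The search
is fully deterministic under a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Dict, List, Tuple

import numpy as np

__all__ = [
    "IntUniform",
    "FloatUniform",
    "Categorical",
    "TPESampler",
    "optimize",
]


@dataclass(frozen=True)
class IntUniform:
    low: int
    high: int  # inclusive

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.low, self.high + 1))

    @property
    def span(self) -> float:
        return float(self.high - self.low)

    def clip(self, x: float) -> int:
        return int(np.clip(round(x), self.low, self.high))


@dataclass(frozen=True)
class FloatUniform:
    low: float
    high: float

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.low, self.high))

    @property
    def span(self) -> float:
        return float(self.high - self.low)

    def clip(self, x: float) -> float:
        return float(np.clip(x, self.low, self.high))


@dataclass(frozen=True)
class Categorical:
    choices: Tuple[Any, ...]

    def sample(self, rng: np.random.Generator) -> Any:
        return self.choices[int(rng.integers(len(self.choices)))]


Dimension = Any  # IntUniform | FloatUniform | Categorical


def _normal_logpdf(x: float, mu: np.ndarray, sigma: float) -> np.ndarray:
    z = (x - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - 0.5 * np.log(2 * np.pi)


def _mixture_loglik(x: float, centres: np.ndarray, sigma: float) -> float:
    if centres.size == 0:
        return 0.0
    lp = _normal_logpdf(x, centres, sigma)
    m = lp.max()
    return float(m + np.log(np.exp(lp - m).mean()))


class TPESampler:
    """Proposes parameter dicts for a maximisation objective."""

    def __init__(
        self,
        space: Dict[str, Dimension],
        seed: int,
        n_startup: int = 10,
        gamma: float = 0.25,
        n_candidates: int = 24,
    ):
        if not space:
            raise ValueError("search space is empty")
        self.space = space
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        self.history: List[Tuple[Dict[str, Any], float]] = []

    def _random_params(self) -> Dict[str, Any]:
        return {name: dim.sample(self.rng) for name, dim in self.space.items()}

    def suggest(self) -> Dict[str, Any]:
        if len(self.history) < self.n_startup:
            return self._random_params()
        scores = np.array([s for _, s in self.history])
        n_good = max(1, int(np.ceil(self.gamma * len(scores))))
        order = np.argsort(-scores, kind="stable")
        good_idx = set(order[:n_good].tolist())
        good = [p for i, (p, _) in enumerate(self.history) if i in good_idx]
        bad = [p for i, (p, _) in enumerate(self.history) if i not in good_idx]

        best: Dict[str, Any] | None = None
        best_score = -np.inf
        for _ in range(self.n_candidates):
            cand: Dict[str, Any] = {}
            ratio = 0.0
            for name, dim in self.space.items():
                if isinstance(dim, Categorical):
                    counts_g = np.array(
                        [sum(p[name] == c for p in good) + 1.0 for c in dim.choices]
                    )
                    counts_b = np.array(
                        [sum(p[name] == c for p in bad) + 1.0 for c in dim.choices]
                    )
                    pg = counts_g / counts_g.sum()
                    pb = counts_b / counts_b.sum()
                    j = int(self.rng.choice(len(dim.choices), p=pg))
                    cand[name] = dim.choices[j]
                    ratio += np.log(pg[j]) - np.log(pb[j])
                else:
                    centres_g = np.array([float(p[name]) for p in good])
                    centres_b = np.array([float(p[name]) for p in bad])
                    # Silverman-style bandwidth, floored at 5% of the span
                    sigma = max(
                        0.05 * dim.span,
                        1.06 * max(centres_g.std(), 1e-12) * len(centres_g) ** -0.2,
                    )
                    x = dim.clip(self.rng.normal(centres_g[int(self.rng.integers(len(centres_g)))], sigma))
                    cand[name] = x
                    ratio += _mixture_loglik(float(x), centres_g, sigma)
                    ratio -= _mixture_loglik(float(x), centres_b, sigma)
            if ratio > best_score:
                best_score = ratio
                best = cand
        assert best is not None
        return best

    def tell(self, params: Dict[str, Any], score: float) -> None:
        self.history.append((params, float(score)))

    @property
    def best(self) -> Tuple[Dict[str, Any], float]:
        if not self.history:
            raise RuntimeError("no completed trials")
        i = int(np.argmax([s for _, s in self.history]))
        return self.history[i]


def optimize(
    objective: Callable[[Dict[str, Any]], float],
    space: Dict[str, Dimension],
    n_trials: int,
    seed: int,
    **sampler_kwargs,
) -> Tuple[Dict[str, Any], float, List[Tuple[Dict[str, Any], float]]]:
    """Run the TPE loop; returns (best_params, best_score, history)."""
    sampler = TPESampler(space, seed=seed, **sampler_kwargs)
    for _ in range(n_trials):
        params = sampler.suggest()
        sampler.tell(params, objective(params))
    best_params, best_score = sampler.best
    return best_params, best_score, sampler.history
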