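"""Metropolis-Hastings tuning of reaction rates.

The synthesis stage guarantees only that correct computations *exist*; their
probability under unit rates may be poor.  This module maximizes the averaged
halting-correctness probability over the rate vector with a
Metropolis-Hastings random walk in log10-rate space.

The acceptance rule is rescaled so that a proposal exactly 1% worse than the
current score is accepted with probability 0.25:

    accept = min(1, exp(beta * (proposed - current))),
    beta   = ln(4) / (0.01 * current)

Uphill and equal-score moves are always accepted.  The optimizer reports the
best rate vector visited, not a posterior summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import CRN
from .specs import Specification
from .cme import ScoreEvaluator

__all__ = [
    "OptimizerConfig",
    "OptimizationResult",
    "ChainPoint",
    "acceptance_probability",
    "optimize_rates",
]

_SCORE_FLOOR = 1e-6  # beta fallback when the current score is 0


@dataclass(frozen=True)
class OptimizerConfig:
    """Metropolis-Hastings settings.

    Rates are searched in log10 space within ``log10_rate_bounds`` (default
    [-3, 2], covering slow ~0.01 and fast ~100 reactions with headroom);
    proposals perturb one coordinate per iteration, cyclically, with a
    Gaussian step of ``proposal_sd`` log10 units reflected at the bounds.
    """

    burn_in: int = 200
    samples: int = 200
    log10_rate_bounds: tuple[float, float] = (-3.0, 2.0)
    proposal_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.samples < 0:
            raise ValueError("burn_in and samples must be >= 0")
        lo, hi = self.log10_rate_bounds
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError("log10 rate bounds must be finite and ordered")


@dataclass
class ChainPoint:
    rates: np.ndarray
    score: float
    accepted: bool


@dataclass
class OptimizationResult:
    """Best-visited rate vector, its score, and the full chain."""

    k_opt: np.ndarray
    best_score: float
    chain: list[ChainPoint] = field(default_factory=list)
    config: OptimizerConfig | None = None

    @property
    def scores(self) -> np.ndarray:
        return np.array([p.score for p in self.chain])


def acceptance_probability(current_score: float, proposed_score: float) -> float:
    """Rescaled Metropolis acceptance probability in [0, 1].

    Calibrated so a proposal 1% worse than the current score is accepted with
    probability exactly 0.25; proposals at least as good are always accepted.
    """
    if proposed_score >= current_score:
        return 1.0
    ref = current_score if current_score > 0 else _SCORE_FLOOR
    beta = math.log(4.0) / (0.01 * ref)
    return math.exp(beta * (proposed_score - current_score))


def _reflect(v: float, lo: float, hi: float) -> float:
    width = hi - lo
    v = (v - lo) % (2 * width)
    return lo + (v if v <= width else 2 * width - v)


def optimize_rates(crn: CRN, spec: Specification,
                   config: OptimizerConfig = OptimizerConfig(),
                   evaluator: ScoreEvaluator | None = None) -> OptimizationResult:
    """Maximize the averaged halting-correctness probability over rates.

    The chain has ``burn_in + samples`` iterations, starts at all rates 1,
    and is fully determined by ``config.seed``.  Score evaluations are cached
    per rate vector (the CME solve dominates the cost).
    """
    if evaluator is None:
        evaluator = ScoreEvaluator(crn, spec)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.log10_rate_bounds
    n = len(crn.reactions)

    cache: dict[tuple, float] = {}

    def score_of(log_k: np.ndarray) -> float:
        key = tuple(np.round(log_k, 12))
        if key not in cache:
            cache[key] = evaluator.score(10.0 ** log_k)
        return cache[key]

    log_k = np.zeros(n)  # all rates 1
    cur = score_of(log_k)
    best_k, best = log_k.copy(), cur
    chain = [ChainPoint(10.0 ** log_k, cur, True)]
    total = config.burn_in + config.samples
    for it in range(1, total):
        prop = log_k.copy()
        c = (it - 1) % n  # cyclic coordinate schedule
        prop[c] = _reflect(prop[c] + rng.normal(0.0, config.proposal_sd), lo, hi)
        s = score_of(prop)
        if rng.random() < acceptance_probability(cur, s):
            log_k, cur = prop, s
            accepted = True
        else:
            accepted = False
        if cur > best:
            best, best_k = cur, log_k.copy()
        chain.append(ChainPoint(10.0 ** log_k, cur, accepted))
    return OptimizationResult(k_opt=10.0 ** best_k, best_score=best,
                              chain=chain, config=config)
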