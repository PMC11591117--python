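"""Conventional whale optimization algorithm (WOA).

A population metaheuristic modeled on the bubble-net hunting of humpback
whales.  Each whale holds a position in a box-bounded D-dimensional search
space; per iteration each whale performs one of three moves, chosen by a
switch probability sigma and a coefficient W:

* encircling prey        (sigma < 0.5, |W| < 1): move toward the best
  position found so far,
* search for prey        (sigma < 0.5, |W| >= 1): move relative to a
  random population member (exploration),
* spiral bubble-net attack (sigma >= 0.5): log-spiral approach to the
  best position.

The coefficient W = 2*w*rand - w shrinks with the linearly decayed
w = 2 - 2k/MaxIt, so late iterations favor exploitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ObjectiveFunction
from .exceptions import FitnessEvaluationError


@dataclass
class ControlParams:
    """Per-whale, per-iteration stochastic control coefficients."""

    w: float
    W: float
    C: float
    sigma: float
    l: float


def control_params(k: int, max_it: int, rng: np.random.Generator) -> ControlParams:
    """Draw the control coefficients for iteration ``k`` of ``max_it``.

    ``w`` decays linearly from 2 to 0; ``W`` is uniform on [-w, w]; ``C``
    uniform on [0, 2]; ``sigma`` uniform on [0, 1); ``l`` uniform on
    [-1, 1].
    """
    if not 1 <= k <= max_it:
        raise ValueError(f"iteration k={k} outside [1, {max_it}]")
    w = 2.0 - k * 2.0 / max_it
    W = 2.0 * w * rng.random() - w
    C = 2.0 * rng.random()
    sigma = float(rng.random())
    l = float(rng.uniform(-1.0, 1.0))
    return ControlParams(w=w, W=W, C=C, sigma=sigma, l=l)


def _check_dims(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")


def encircle(yj: np.ndarray, ybest: np.ndarray, W: float, C: float) -> np.ndarray:
    """Encircling-prey move: ``Ybest - W * |C*Ybest - Yj|``."""
    yj = np.asarray(yj, dtype=float)
    ybest = np.asarray(ybest, dtype=float)
    _check_dims(yj, ybest)
    return ybest - W * np.abs(C * ybest - yj)


def search_prey(yj: np.ndarray, yrnd: np.ndarray, W: float, C: float) -> np.ndarray:
    """Search-for-prey move against a random member: ``Yrnd - W * |C*Yrnd - Yj|``."""
    yj = np.asarray(yj, dtype=float)
    yrnd = np.asarray(yrnd, dtype=float)
    _check_dims(yj, yrnd)
    return yrnd - W * np.abs(C * yrnd - yj)


def spiral_attack(
    yj: np.ndarray, ybest: np.ndarray, l: float, spiral_c: float = 1.0
) -> np.ndarray:
    """Logarithmic-spiral move: ``|Ybest - Yj| * e^{c l} * cos(2 pi l) + Ybest``."""
    if not -1.0 <= l <= 1.0:
        raise ValueError(f"spiral parameter l={l} outside [-1, 1]")
    yj = np.asarray(yj, dtype=float)
    ybest = np.asarray(ybest, dtype=float)
    _check_dims(yj, ybest)
    s = np.abs(ybest - yj)
    return s * np.exp(spiral_c * l) * np.cos(2.0 * np.pi * l) + ybest


@dataclass
class WOAResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[float]
    n_evaluations: int
    log: list[dict] = field(default_factory=list)


def _evaluate(objective, position, whale: int, iteration: int) -> float:
    f = float(objective.evaluate(position))
    if not np.isfinite(f):
        raise FitnessEvaluationError(
            f"objective returned non-finite fitness {f} "
            f"for whale {whale} at iteration {iteration}"
        )
    return f


def run_woa(
    objective: ObjectiveFunction,
    n_whales: int = 30,
    max_it: int = 300,
    seed: int = 0,
    spiral_c: float = 1.0,
) -> WOAResult:
    """Minimize a box-bounded objective with the conventional WOA.

    Positions are clipped to the objective's bounds after every move; the
    returned ``history`` holds the best-so-far fitness per iteration and
    is non-increasing by construction.  The same seed reproduces the full
    trajectory.
    """
    if n_whales < 2:
        raise ValueError("population must have at least 2 whales")
    if max_it < 1:
        raise ValueError("max_it must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = objective.lower, objective.upper
    dim = objective.dim

    pos = rng.uniform(lo, hi, size=(n_whales, dim))
    fit = np.array([_evaluate(objective, pos[j], j, 0) for j in range(n_whales)])
    best_idx = int(np.argmin(fit))
    best = pos[best_idx].copy()
    best_fit = float(fit[best_idx])
    n_eval = n_whales

    history: list[float] = []
    log: list[dict] = []
    for k in range(1, max_it + 1):
        for j in range(n_whales):
            p = control_params(k, max_it, rng)
            if p.sigma < 0.5:
                if abs(p.W) < 1.0:
                    new = encircle(pos[j], best, p.W, p.C)
                else:
                    r = int(rng.integers(n_whales))
                    new = search_prey(pos[j], pos[r], p.W, p.C)
            else:
                new = spiral_attack(pos[j], best, p.l, spiral_c)
            new = np.clip(new, lo, hi)
            f = _evaluate(objective, new, j, k)
            n_eval += 1
            pos[j] = new
            fit[j] = f
            if f < best_fit:
                best_fit = f
                best = new.copy()
        history.append(best_fit)
        log.append(
            {"iteration": k, "best_fitness": best_fit, "mean_fitness": float(fit.mean())}
        )
    return WOAResult(
        best_position=best,
        best_fitness=best_fit,
        history=history,
        n_evaluations=n_eval,
        log=log,
    )
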