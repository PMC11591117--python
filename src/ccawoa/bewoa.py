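"""Binary-enhanced whale optimization (bE-WOA) for feature selection.

The enhanced variant augments the conventional WOA with four devices that
fight premature convergence:

* a **pool** of candidate solutions, refreshed each iteration by a
  binary-vector crossover of a perturbed best solution with the current
  worst one;
* a **migrating search** that teleports a random portion of the
  population into the box spanned by the global bounds minus a
  neighborhood of the best solution, re-seeding exploration;
* **preferential selection**, a differential-style move along the
  difference of two random pool members;
* **enriched encircling**, which encircles against a random pool member
  instead of the whale's own position.

For feature selection the continuous positions are the dynamical state;
each evaluation maps a position through a transfer function
U: R -> [0, 1] (S-shaped sigmoid or V-shaped |tanh|) and samples a binary
mask, which a wrapper fitness (e.g. kNN error + feature-ratio penalty)
scores.  A per-whale greedy rule keeps whichever of the old/new
(position, mask, fitness) triples scores lower, so stored fitness never
increases and the global best fitness history is non-increasing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .exceptions import FitnessEvaluationError
from .woa import control_params, encircle, search_prey, spiral_attack

logger = logging.getLogger(__name__)


class Pool:
    """Bounded archive of candidate positions.

    Once ``capacity`` is reached, a new candidate replaces a uniformly
    chosen existing member.
    """

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("pool capacity must be >= 1")
        self.capacity = int(capacity)
        self.members: list[np.ndarray] = []

    def __len__(self) -> int:
        return len(self.members)

    def add(self, candidate: np.ndarray, rng: np.random.Generator) -> None:
        candidate = np.asarray(candidate, dtype=float)
        if not np.all(np.isfinite(candidate)):
            raise ValueError("pool candidates must be finite")
        if len(self.members) < self.capacity:
            self.members.append(candidate)
        else:
            self.members[int(rng.integers(len(self.members)))] = candidate

    def sample(
        self, rng: np.random.Generator, size: int = 1, distinct: bool = True
    ) -> list[np.ndarray]:
        idx = rng.choice(len(self.members), size=size, replace=not distinct)
        return [self.members[int(i)] for i in np.atleast_1d(idx)]


def update_pool(
    pool: Pool,
    ybest: np.ndarray,
    yworst: np.ndarray,
    rng: np.random.Generator,
    lower: np.ndarray,
    upper: np.ndarray,
    perturb_scale: float = 0.1,
    binary_vector: np.ndarray | None = None,
) -> Pool:
    """Append a crossover candidate ``B*Ybrnd + (1-B)*Yworst`` to the pool.

    ``Ybrnd`` is a Gaussian perturbation around the best position with
    scale ``perturb_scale * (upper - lower)``; ``B`` is a random binary
    vector (injectable for testing).
    """
    ybest = np.asarray(ybest, dtype=float)
    yworst = np.asarray(yworst, dtype=float)
    d = ybest.shape[0]
    if binary_vector is None:
        b = rng.integers(0, 2, size=d)
    else:
        b = np.asarray(binary_vector)
    ybrnd = ybest + rng.normal(0.0, perturb_scale * (upper - lower), size=d)
    candidate = b * ybrnd + (1 - b) * yworst
    pool.add(candidate, rng)
    return pool


def migrate(
    lower: np.ndarray,
    upper: np.ndarray,
    best_lower: np.ndarray,
    best_upper: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Migrating-search draw ``Yrnd - Ybrnd``.

    ``Yrnd`` is uniform in the global box [lower, upper]; ``Ybrnd`` is
    uniform in the neighborhood box [best_lower, best_upper] around the
    best position.
    """
    lower, upper = np.broadcast_arrays(
        np.asarray(lower, dtype=float), np.asarray(upper, dtype=float)
    )
    best_lower, best_upper = np.broadcast_arrays(
        np.asarray(best_lower, dtype=float), np.asarray(best_upper, dtype=float)
    )
    if np.any(lower > upper) or np.any(best_lower > best_upper):
        raise ValueError("inverted bounds in migrating search")
    yrnd = rng.random(lower.shape) * (upper - lower) + lower
    ybrnd = rng.random(best_lower.shape) * (best_upper - best_lower) + best_lower
    return yrnd - ybrnd


def preferential_select(
    yj: np.ndarray,
    W: float,
    U: float,
    pool: Pool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Differential move ``Yj + W*U*(Prnd1 - Prnd2)`` with distinct pool members.

    Falls back to a search-for-prey step (against the lone pool member,
    or the whale itself when the pool is empty) when the pool has fewer
    than two members.
    """
    yj = np.asarray(yj, dtype=float)
    if len(pool) >= 2:
        p1, p2 = pool.sample(rng, size=2, distinct=True)
        return yj + W * U * (p1 - p2)
    logger.debug("preferential_select: pool has %d member(s); falling back", len(pool))
    ref = pool.members[0] if len(pool) == 1 else yj
    return search_prey(yj, ref, W, U)


def enriched_encircle(
    ybest: np.ndarray,
    W: float,
    C: float,
    pool: Pool,
    rng: np.random.Generator,
    fallback_yj: np.ndarray | None = None,
) -> np.ndarray:
    """Encircle against a random pool member: ``Ybest - W*|C*Ybest - Prnd3|``.

    Falls back to plain encircling against ``fallback_yj`` (or ``ybest``)
    when the pool is empty.
    """
    ybest = np.asarray(ybest, dtype=float)
    if len(pool) >= 1:
        (p3,) = pool.sample(rng, size=1)
        return ybest - W * np.abs(C * ybest - p3)
    logger.debug("enriched_encircle: empty pool; falling back to encircle")
    yj = ybest if fallback_yj is None else np.asarray(fallback_yj, dtype=float)
    return encircle(yj, ybest, W, C)


def binarize(
    y: np.ndarray, transfer: str = "sigmoid", rng: np.random.Generator | None = None
) -> np.ndarray:
    """Map a continuous position to bits: ``bit_i = 1 iff U(y_i) >= rand``.

    ``sigmoid`` (S-shaped): U(y) = 1/(1+e^{-y}); ``vshape``: U(y) = |tanh(y)|.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("position must be finite")
    if transfer == "sigmoid":
        u = 1.0 / (1.0 + np.exp(-y))
    elif transfer == "vshape":
        u = np.abs(np.tanh(y))
    else:
        raise ValueError("transfer must be 'sigmoid' or 'vshape'")
    if rng is None:
        rng = np.random.default_rng()
    return (u >= rng.random(y.shape)).astype(np.int64)


@dataclass
class SelectionResult:
    """Outcome of a binary feature-selection run."""

    best_mask: np.ndarray
    best_fitness: float
    n_selected: int
    fitness_history: list[float]
    n_evaluations: int
    seed: int
    log: list[dict] = field(default_factory=list)

    def save_mask(self, path, column_ids: list[str] | None = None) -> None:
        """Write the mask as one 0/1 per line (optionally named columns)."""
        if column_ids is None:
            np.savetxt(path, self.best_mask.astype(int), fmt="%d")
        else:
            with open(path, "w") as fh:
                for cid, bit in zip(column_ids, self.best_mask):
                    fh.write(f"{cid},{int(bit)}\n")


def _eval_mask(fitness, bits, whale: int, iteration: int) -> float:
    f = float(fitness(bits))
    if not np.isfinite(f):
        raise FitnessEvaluationError(
            f"fitness returned non-finite value {f} "
            f"for whale {whale} at iteration {iteration}"
        )
    return f


def run_bewoa(
    fitness: Callable[[np.ndarray], float],
    dim: int,
    n_whales: int = 20,
    max_it: int = 60,
    pool_capacity: int | None = None,
    migrate_fraction: float = 0.1,
    transfer: str = "sigmoid",
    seed: int = 0,
    lower: float = -4.0,
    upper: float = 4.0,
    w_switch: float = 0.5,
    spiral_c: float = 1.0,
    best_neighborhood: float = 0.1,
) -> SelectionResult:
    """Minimize a binary-mask fitness with the binary-enhanced WOA.

    Parameters
    ----------
    fitness
        Callable scoring a 0/1 vector of length ``dim``; lower is better.
    pool_capacity
        Pool size; defaults to the population size.
    migrate_fraction
        Fraction of whales re-seeded by migrating search each iteration.
    transfer
        Transfer function mapping continuous coordinates to bit
        probabilities (``sigmoid`` or ``vshape``).
    lower, upper
        Box bounds of the continuous state; the defaults span the
        near-saturated range of the sigmoid transfer.
    w_switch
        Threshold on |W| separating enriched encircling (below) from
        preferential selection (at or above).
    best_neighborhood
        Half-width of the best-solution neighborhood used by migration
        and pool perturbation, as a fraction of the box width.
    """
    if n_whales < 4:
        raise ValueError("population must have at least 4 whales")
    if max_it < 1:
        raise ValueError("max_it must be >= 1")
    if not 0.0 < migrate_fraction < 1.0:
        raise ValueError("migrate_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    lo = np.full(dim, float(lower))
    hi = np.full(dim, float(upper))

    pos = rng.uniform(lo, hi, size=(n_whales, dim))
    bits = (rng.random((n_whales, dim)) >= 0.5).astype(np.int64)
    fit = np.array([_eval_mask(fitness, bits[j], j, 0) for j in range(n_whales)])
    n_eval = n_whales

    best_idx = int(np.argmin(fit))
    best_pos = pos[best_idx].copy()
    best_bits = bits[best_idx].copy()
    best_fit = float(fit[best_idx])

    pool = Pool(pool_capacity if pool_capacity is not None else n_whales)
    n_migrate = max(1, math.ceil(migrate_fraction * n_whales))
    span = hi - lo

    history: list[float] = []
    log: list[dict] = []
    for k in range(1, max_it + 1):
        migrants = set(rng.choice(n_whales, size=n_migrate, replace=False).tolist())
        for j in range(n_whales):
            if j in migrants:
                bl = np.maximum(lo, best_pos - best_neighborhood * span)
                bu = np.minimum(hi, best_pos + best_neighborhood * span)
                new = migrate(lo, hi, bl, bu, rng)
            else:
                p = control_params(k, max_it, rng)
                if p.sigma < 0.5:
                    if abs(p.W) < w_switch:
                        new = enriched_encircle(
                            best_pos, p.W, p.C, pool, rng, fallback_yj=pos[j]
                        )
                    else:
                        new = preferential_select(pos[j], p.W, p.C, pool, rng)
                else:
                    new = spiral_attack(pos[j], best_pos, p.l, spiral_c)
            new = np.clip(new, lo, hi)
            new_bits = binarize(new, transfer, rng)
            f = _eval_mask(fitness, new_bits, j, k)
            n_eval += 1
            # greedy per-whale update: keep the lower-fitness state
            if f <= fit[j]:
                pos[j] = new
                bits[j] = new_bits
                fit[j] = f
            if fit[j] < best_fit:
                best_fit = float(fit[j])
                best_pos = pos[j].copy()
                best_bits = bits[j].copy()
        worst_idx = int(np.argmax(fit))
        update_pool(
            pool, best_pos, pos[worst_idx], rng, lo, hi, perturb_scale=best_neighborhood
        )
        history.append(best_fit)
        log.append(
            {
                "iteration": k,
                "best_fitness": best_fit,
                "n_selected": int(best_bits.sum()),
                "pool_size": len(pool),
            }
        )
    return SelectionResult(
        best_mask=best_bits,
        best_fitness=best_fit,
        n_selected=int(best_bits.sum()),
        fitness_history=history,
        n_evaluations=n_eval,
        seed=int(seed),
        log=log,
    )


def run_binary_woa(
    fitness: Callable[[np.ndarray], float],
    dim: int,
    n_whales: int = 20,
    max_it: int = 60,
    transfer: str = "sigmoid",
    seed: int = 0,
    lower: float = -4.0,
    upper: float = 4.0,
    spiral_c: float = 1.0,
) -> SelectionResult:
    """Binary conventional WOA: same transfer-function binarization, but
    the classic encircle/search/spiral dispatch (|W| < 1 switch),
    unconditional position acceptance and no pool/migration.  Serves as
    the un-enhanced ablation arm for feature selection.
    """
    if n_whales < 2:
        raise ValueError("population must have at least 2 whales")
    rng = np.random.default_rng(seed)
    lo = np.full(dim, float(lower))
    hi = np.full(dim, float(upper))
    pos = rng.uniform(lo, hi, size=(n_whales, dim))
    bits = (rng.random((n_whales, dim)) >= 0.5).astype(np.int64)
    fit = np.array([_eval_mask(fitness, bits[j], j, 0) for j in range(n_whales)])
    n_eval = n_whales
    best_idx = int(np.argmin(fit))
    best_pos = pos[best_idx].copy()
    best_bits = bits[best_idx].copy()
    best_fit = float(fit[best_idx])

    history: list[float] = []
    for k in range(1, max_it + 1):
        for j in range(n_whales):
            p = control_params(k, max_it, rng)
            if p.sigma < 0.5:
                if abs(p.W) < 1.0:
                    new = encircle(pos[j], best_pos, p.W, p.C)
                else:
                    r = int(rng.integers(n_whales))
                    new = search_prey(pos[j], pos[r], p.W, p.C)
            else:
                new = spiral_attack(pos[j], best_pos, p.l, spiral_c)
            new = np.clip(new, lo, hi)
            new_bits = binarize(new, transfer, rng)
            f = _eval_mask(fitness, new_bits, j, k)
            n_eval += 1
            pos[j] = new
            bits[j] = new_bits
            fit[j] = f
            if f < best_fit:
                best_fit = f
                best_pos = new.copy()
                best_bits = new_bits.copy()
        history.append(best_fit)
    return SelectionResult(
        best_mask=best_bits,
        best_fitness=best_fit,
        n_selected=int(best_bits.sum()),
        fitness_history=history,
        n_evaluations=n_eval,
        seed=int(seed),
    )
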