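"""Binary swarm optimizers for subset search: quantum-behaved PSO and a
standard velocity-based PSO baseline.

Both maintain real-valued particle positions that are stochastically
binarized through a sigmoid transfer (bit = 1 when sigmoid(x) beats a
uniform draw); fitness is evaluated on the bit mask. QPSO is velocity-free:
each particle jumps around a per-dimension attractor

    p = phi * pbest + (1 - phi) * gbest,        phi ~ U(0,1),

with spread scaled by its distance to the swarm's mean personal-best
position (mbest) and the contraction–expansion coefficient alpha:

    x' = p ± alpha * |mbest - x| * ln(1/u),     u ~ U(0,1),

the sign drawn with probability 1/2 each way. Personal bests advance only
on strict fitness improvement, so the global-best trace is monotone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

FitnessFunction = Callable[[np.ndarray], float]


@dataclasses.dataclass
class OptimizerConfig:
    """Shared QPSO/PSO settings.

    ``alpha`` follows a linear schedule from ``alpha_start`` to
    ``alpha_end`` over the iterations (set them equal for a constant
    coefficient). The PSO-only fields are the conventional inertia/
    acceleration settings with velocity clipping.
    """
    n_particles: int = 20
    n_iterations: int = 200
    alpha_start: float = 1.0
    alpha_end: float = 0.5
    w_start: float = 0.9
    w_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.n_iterations < 1:
            raise ValueError("need at least 1 iteration")
        if self.alpha_start <= 0 or self.alpha_end <= 0:
            raise ValueError("alpha must be positive")

    def alpha(self, t: int) -> float:
        """Contraction–expansion coefficient at iteration t (0-based)."""
        if self.n_iterations == 1:
            return self.alpha_start
        frac = t / (self.n_iterations - 1)
        return self.alpha_start + (self.alpha_end - self.alpha_start) * frac

    def inertia(self, t: int) -> float:
        if self.n_iterations == 1:
            return self.w_start
        frac = t / (self.n_iterations - 1)
        return self.w_start + (self.w_end - self.w_start) * frac


@dataclasses.dataclass
class SwarmResult:
    """Outcome of one optimizer run."""
    best_mask: np.ndarray
    best_fitness: float
    trace: np.ndarray            # per-iteration global-best fitness
    n_evaluations: int
    search_scope_trace: np.ndarray   # mean per-particle Q = 2*alpha*|mbest-x|, diagnostic

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "best_mask": self.best_mask.astype(int).tolist(),
            "best_fitness": self.best_fitness,
            "trace": self.trace.tolist(),
            "n_evaluations": self.n_evaluations,
        }))


def sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def binarize(position: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sigmoid transfer: bit i is 1 when sigmoid(x_i) exceeds a U(0,1) draw."""
    position = np.asarray(position, dtype=float)
    return (sigmoid(position) > rng.uniform(size=position.shape)).astype(np.int8)


def compute_mbest(pbest_positions: np.ndarray) -> np.ndarray:
    """Mean personal-best position of the swarm, component-wise."""
    return np.asarray(pbest_positions, dtype=float).mean(axis=0)


def attractor(pbest: np.ndarray, gbest: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-dimension convex combination of personal and global best."""
    phi = rng.uniform(size=np.shape(pbest))
    return phi * pbest + (1.0 - phi) * gbest


def qpso_position_update(
    position: np.ndarray,
    mbest: np.ndarray,
    attractor_point: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One quantum jump: x' = p ± alpha*|mbest − x|*ln(1/u), sign ~ fair coin."""
    u = rng.uniform(size=np.shape(position))
    s = rng.uniform(size=np.shape(position))
    step = alpha * np.abs(mbest - position) * np.log(1.0 / u)
    return np.where(s >= 0.5, attractor_point - step, attractor_point + step)


def _check_fitness(value: float, mask: np.ndarray) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"fitness returned non-finite value {value} for mask {mask.tolist()}")
    return value


def _run(
    fitness: FitnessFunction,
    n_dimensions: int,
    config: OptimizerConfig,
    kind: str,
) -> SwarmResult:
    rng = np.random.default_rng(config.seed)
    S, T, d = config.n_particles, config.n_iterations, n_dimensions

    positions = rng.uniform(-1.0, 1.0, size=(S, d))
    velocities = np.zeros((S, d))
    masks = np.stack([binarize(positions[i], rng) for i in range(S)])
    fits = np.array([_check_fitness(fitness(masks[i]), masks[i]) for i in range(S)])
    n_evals = S

    pbest_pos = positions.copy()
    pbest_mask = masks.copy()
    pbest_fit = fits.copy()
    g = int(np.argmax(pbest_fit))
    gbest_pos, gbest_mask, gbest_fit = pbest_pos[g].copy(), pbest_mask[g].copy(), float(pbest_fit[g])

    trace = np.empty(T)
    scope_trace = np.empty(T)

    for t in range(T):
        mbest = compute_mbest(pbest_pos)
        alpha = config.alpha(t)
        scope_trace[t] = float(np.mean(2.0 * alpha * np.abs(mbest - positions)))
        w = config.inertia(t)

        for i in range(S):
            if kind == "qpso":
                p = attractor(pbest_pos[i], gbest_pos, rng)
                positions[i] = qpso_position_update(positions[i], mbest, p, alpha, rng)
            else:
                r1 = rng.uniform(size=d)
                r2 = rng.uniform(size=d)
                velocities[i] = (
                    w * velocities[i]
                    + config.c1 * r1 * (pbest_pos[i] - positions[i])
                    + config.c2 * r2 * (gbest_pos - positions[i])
                )
                np.clip(velocities[i], -config.v_max, config.v_max, out=velocities[i])
                positions[i] = positions[i] + velocities[i]

            masks[i] = binarize(positions[i], rng)
            fit = _check_fitness(fitness(masks[i]), masks[i])
            n_evals += 1
            if fit > pbest_fit[i]:   # strict improvement only
                pbest_fit[i] = fit
                pbest_pos[i] = positions[i].copy()
                pbest_mask[i] = masks[i].copy()
                if fit > gbest_fit:
                    gbest_fit = fit
                    gbest_pos = positions[i].copy()
                    gbest_mask = masks[i].copy()
        trace[t] = gbest_fit

    return SwarmResult(
        best_mask=gbest_mask.astype(np.int8),
        best_fitness=gbest_fit,
        trace=trace,
        n_evaluations=n_evals,
        search_scope_trace=scope_trace,
    )


def run_qpso(fitness: FitnessFunction, n_dimensions: int, config: OptimizerConfig) -> SwarmResult:
    """Quantum-behaved PSO over bit masks; reproducible from ``config.seed``."""
    return _run(fitness, n_dimensions, config, "qpso")


def run_pso(fitness: FitnessFunction, n_dimensions: int, config: OptimizerConfig) -> SwarmResult:
    """Standard binary PSO baseline with the same sigmoid binarization."""
    return _run(fitness, n_dimensions, config, "pso")


def exhaustive_optimum(fitness: FitnessFunction, n_dimensions: int) -> tuple[np.ndarray, float]:
    """Brute-force 2^d enumeration of the fitness surface (d small)."""
    best_mask, best_fit = None, -np.inf
    for code in range(2**n_dimensions):
        mask = np.array([(code >> b) & 1 for b in range(n_dimensions)], dtype=np.int8)
        fit = float(fitness(mask))
        if fit > best_fit:
            best_fit, best_mask = fit, mask
    return best_mask, best_fit


def selected_indices(mask: Sequence[int]) -> np.ndarray:
    """Indices of the set bits of a mask (e.g. 100101 -> [0, 3, 5])."""
    return np.flatnonzero(np.asarray(mask))
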