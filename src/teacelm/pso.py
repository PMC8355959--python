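"""Particle swarm optimization (global-best topology).

Velocities follow the classic update

    v' = w v + c1 r1 (p - x) + c2 r2 (g - x),    x' = x + v'

with independent uniform(0, 1) draws r1, r2 per dimension and term, inertia
weight w and cognitive/social accelerations c1, c2. Positions are clipped to
the configured box and the offending velocity component is zeroed. The
incumbent global best can only improve, so the fitness history is
non-increasing. Lower fitness is better throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PSOConfig:
    """Swarm hyperparameters.

    Defaults w = 0.729, c1 = c2 = 1.49445 are the constriction-equivalent
    values that keep trajectories contracting; N = 30 particles and 200
    iterations are a modest budget for search spaces of a few dozen
    dimensions.
    """

    n_particles: int = 30
    n_dimensions: int = 1
    w: float = 0.729
    c1: float = 1.49445
    c2: float = 1.49445
    max_iterations: int = 200
    position_bounds: tuple[float, float] | np.ndarray = (-1.0, 1.0)
    velocity_clamp: float | None = None  # fraction of each dimension's range
    early_stop: bool = False
    early_stop_tol: float = 1e-10
    early_stop_patience: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.n_dimensions < 1:
            raise ValueError("n_dimensions must be positive")
        if self.w < 0 or self.c1 < 0 or self.c2 < 0:
            raise ValueError("w, c1, c2 must be non-negative")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be non-negative")
        lo, hi = self.bounds_arrays()
        if not np.all(lo < hi):
            raise ValueError("each position bound must satisfy lo < hi")
        if self.velocity_clamp is not None and self.velocity_clamp <= 0:
            raise ValueError("velocity_clamp must be positive when set")

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        b = np.asarray(self.position_bounds, float)
        if b.shape == (2,):
            lo = np.full(self.n_dimensions, b[0])
            hi = np.full(self.n_dimensions, b[1])
        else:
            if b.shape != (self.n_dimensions, 2):
                raise ValueError("position_bounds must be (lo, hi) or D x 2")
            lo, hi = b[:, 0], b[:, 1]
        return lo, hi


@dataclass
class SwarmState:
    """Positions, velocities and best-so-far bookkeeping for one swarm."""

    positions: np.ndarray          # N x D
    velocities: np.ndarray         # N x D
    personal_best: np.ndarray      # N x D
    personal_best_fitness: np.ndarray  # N
    global_best: np.ndarray        # D
    global_best_fitness: float
    iteration: int = 0
    fitness_history: list[float] = field(default_factory=list)


def update_velocity(v: np.ndarray, x: np.ndarray, p: np.ndarray, g: np.ndarray,
                    config: PSOConfig, r1: np.ndarray, r2: np.ndarray
                    ) -> np.ndarray:
    """One velocity update; r1, r2 supply the per-dimension random draws."""
    v_next = config.w * v + config.c1 * r1 * (p - x) + config.c2 * r2 * (g - x)
    if config.velocity_clamp is not None:
        lo, hi = config.bounds_arrays()
        vmax = config.velocity_clamp * (hi - lo)
        v_next = np.clip(v_next, -vmax, vmax)
    return v_next


def update_position(x: np.ndarray, v_next: np.ndarray,
                    bounds: tuple[np.ndarray, np.ndarray]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Move and clip to the box; returns (x_next, out_of_bounds_mask) so the
    caller can zero the offending velocity components."""
    lo, hi = bounds
    x_raw = x + v_next
    x_next = np.clip(x_raw, lo, hi)
    return x_next, x_next != x_raw


def _evaluate(fitness_fn, positions: np.ndarray) -> np.ndarray:
    values = np.empty(positions.shape[0])
    for i, pos in enumerate(positions):
        f = float(fitness_fn(pos))
        if not np.isfinite(f):
            log.warning("non-finite fitness at particle %d; treating as +inf", i)
            f = np.inf
        values[i] = f
    return values


def initialize_swarm(fitness_fn, config: PSOConfig,
                     rng: np.random.Generator) -> SwarmState:
    """Uniform random positions in the box, zero initial velocities."""
    lo, hi = config.bounds_arrays()
    x = rng.uniform(lo, hi, size=(config.n_particles, config.n_dimensions))
    fitness = _evaluate(fitness_fn, x)
    best = int(np.argmin(fitness))
    return SwarmState(
        positions=x, velocities=np.zeros_like(x),
        personal_best=x.copy(), personal_best_fitness=fitness,
        global_best=x[best].copy(), global_best_fitness=float(fitness[best]),
        fitness_history=[float(fitness[best])])


def step(state: SwarmState, fitness_fn, config: PSOConfig,
         rng: np.random.Generator) -> SwarmState:
    """Advance the swarm one iteration in place."""
    shape = state.positions.shape
    r1 = rng.uniform(size=shape)
    r2 = rng.uniform(size=shape)
    v_next = update_velocity(state.velocities, state.positions,
                             state.personal_best, state.global_best,
                             config, r1, r2)
    x_next, clipped = update_position(state.positions, v_next,
                                      config.bounds_arrays())
    v_next = np.where(clipped, 0.0, v_next)

    fitness = _evaluate(fitness_fn, x_next)
    improved = fitness < state.personal_best_fitness
    state.personal_best[improved] = x_next[improved]
    state.personal_best_fitness[improved] = fitness[improved]
    best = int(np.argmin(state.personal_best_fitness))
    if state.personal_best_fitness[best] < state.global_best_fitness:
        state.global_best = state.personal_best[best].copy()
        state.global_best_fitness = float(state.personal_best_fitness[best])

    state.positions, state.velocities = x_next, v_next
    state.iteration += 1
    state.fitness_history.append(state.global_best_fitness)
    return state


def optimize(fitness_fn, config: PSOConfig
             ) -> tuple[np.ndarray, float, np.ndarray]:
    """Run the swarm for its iteration budget; returns the incumbent best
    position, its fitness, and the per-iteration global-best history.

    Fully deterministic given (config, seed, fitness_fn).
    """
    rng = np.random.default_rng(config.seed)
    state = initialize_swarm(fitness_fn, config, rng)
    stalled = 0
    for _ in range(config.max_iterations):
        before = state.global_best_fitness
        step(state, fitness_fn, config, rng)
        if config.early_stop:
            stalled = stalled + 1 if before - state.global_best_fitness \
                < config.early_stop_tol else 0
            if stalled >= config.early_stop_patience:
                log.info("early stop after %d iterations", state.iteration)
                break
    return state.global_best, state.global_best_fitness, \
        np.array(state.fitness_history)
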