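"""Hierarchical particle swarm optimization.

A PSO variant with time-varying acceleration coefficients and no inertia
term: particle velocities are recomputed each step from the cognitive and
social attractions alone.  A velocity component that collapses to exactly
zero (particle sitting on both its personal and the global best) is
re-energized with a random kick — the self-organizing rule that keeps the
swarm searching after convergence of individual dimensions.

Objectives are callables mapping a ``(n, d)`` position matrix to ``n``
objective values; plain scalar objectives (one d-vector in, one float
out) are also accepted and looped over.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HpsoConfig",
    "SwarmState",
    "acceleration_coefficients",
    "hpso_step",
    "init_swarm",
    "objective_sse",
    "optimize",
]


@dataclass(frozen=True)
class HpsoConfig:
    """Swarm size, schedule and box constraints for one optimization run."""

    bounds: tuple[tuple[float, float], ...]
    n_particles: int = 40
    max_iter: int = 1000
    c1i: float = 2.5
    c1f: float = 0.5
    c2i: float = 0.5
    c2f: float = 2.5
    v_max_fraction: float = 0.5
    reinit_velocity_fraction: float = 0.1
    reinit_velocity_fraction_final: float = 0.01
    seed: int | None = None
    tol_rel: float = 1e-8
    patience: int = 50

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        for lo, hi in bounds:
            if lo > hi:
                raise ValueError(f"invalid bound ({lo}, {hi})")
        object.__setattr__(self, "bounds", bounds)

    @property
    def ndim(self) -> int:
        return len(self.bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])


@dataclass
class SwarmState:
    X: np.ndarray
    V: np.ndarray
    P: np.ndarray
    f_P: np.ndarray
    P_g: np.ndarray
    f_g: float
    iter: int
    rng: np.random.Generator = field(repr=False, default=None)


def acceleration_coefficients(iteration: int, cfg: HpsoConfig) -> tuple[float, float]:
    """Linearly scheduled (c1, c2): cognitive ramps c1i→c1f, social c2i→c2f."""
    if not (0 <= iteration <= cfg.max_iter):
        raise ValueError(f"iteration {iteration} outside [0, {cfg.max_iter}]")
    frac = iteration / cfg.max_iter
    c1 = (cfg.c1f - cfg.c1i) * frac + cfg.c1i
    c2 = (cfg.c2f - cfg.c2i) * frac + cfg.c2i
    return c1, c2


def _evaluate(objective: Callable, X: np.ndarray) -> np.ndarray:
    """Evaluate objective on a batch of positions; non-finite values → +inf."""
    try:
        f = np.asarray(objective(X), dtype=float)
        if f.shape != (X.shape[0],):
            raise TypeError
    except (TypeError, ValueError, IndexError):
        f = np.array([float(objective(x)) for x in X])
    bad = ~np.isfinite(f)
    if bad.any():
        logger.warning("objective returned %d non-finite values", int(bad.sum()))
        f = np.where(bad, np.inf, f)
    return f


def init_swarm(objective: Callable, cfg: HpsoConfig, rng: np.random.Generator) -> SwarmState:
    lo, hi = cfg.lower, cfg.upper
    X = lo + (hi - lo) * rng.random((cfg.n_particles, cfg.ndim))
    V = np.zeros_like(X)
    f = _evaluate(objective, X)
    best = int(np.argmin(f))
    return SwarmState(
        X=X, V=V, P=X.copy(), f_P=f.copy(), P_g=X[best].copy(),
        f_g=float(f[best]), iter=0, rng=rng,
    )


def hpso_step(state: SwarmState, objective: Callable, cfg: HpsoConfig) -> SwarmState:
    """Advance the swarm one iteration; the global best never worsens."""
    rng = state.rng
    lo, hi = cfg.lower, cfg.upper
    span = hi - lo
    v_max = cfg.v_max_fraction * span
    c1, c2 = acceleration_coefficients(min(state.iter, cfg.max_iter), cfg)

    r1 = rng.random(state.X.shape)
    r2 = rng.random(state.X.shape)
    V = c1 * r1 * (state.P - state.X) + c2 * r2 * (state.P_g[None, :] - state.X)

    # self-organizing kick: dead velocity components are re-launched at a
    # decaying fraction of v_max with random sign
    frac0, frac1 = cfg.reinit_velocity_fraction, cfg.reinit_velocity_fraction_final
    frac = frac0 + (frac1 - frac0) * min(state.iter, cfg.max_iter) / cfg.max_iter
    dead = (V == 0.0) & (span[None, :] > 0)
    if dead.any():
        signs = np.where(rng.random(int(dead.sum())) < 0.5, -1.0, 1.0)
        V[dead] = signs * frac * np.broadcast_to(v_max, V.shape)[dead]

    V = np.clip(V, -v_max, v_max)
    X = state.X + V
    clipped_lo = X < lo
    clipped_hi = X > hi
    X = np.clip(X, lo, hi)
    V = np.where(clipped_lo | clipped_hi, 0.0, V)

    f = _evaluate(objective, X)
    improved = f < state.f_P
    P = np.where(improved[:, None], X, state.P)
    f_P = np.where(improved, f, state.f_P)
    best = int(np.argmin(f_P))
    if f_P[best] < state.f_g:
        P_g, f_g = P[best].copy(), float(f_P[best])
    else:
        P_g, f_g = state.P_g, state.f_g
    return SwarmState(X=X, V=V, P=P, f_P=f_P, P_g=P_g, f_g=f_g,
                      iter=state.iter + 1, rng=rng)


def optimize(
    objective: Callable, cfg: HpsoConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, float]:
    """Run the swarm to ``max_iter`` or until the best value stalls.

    Returns the best position found (inside the bounds) and its objective
    value.  With ``cfg.seed`` set (or an explicit ``rng``) the run is fully
    deterministic.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    state = init_swarm(objective, cfg, rng)
    tol = cfg.tol_rel * max(abs(state.f_g), 1e-300)
    stall = 0
    for _ in range(cfg.max_iter):
        prev = state.f_g
        state = hpso_step(state, objective, cfg)
        if prev - state.f_g < tol:
            stall += 1
            if stall >= cfg.patience:
                break
        else:
            stall = 0
    return state.P_g.copy(), state.f_g


def objective_sse(
    points: Sequence[tuple[float, float]] | np.ndarray,
    model: Callable[[np.ndarray], np.ndarray],
) -> float:
    """Sum of squared residuals of ``model`` over ``(m, intensity)`` points."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("objective_sse requires at least one point")
    m, y = pts[:, 0], pts[:, 1]
    resid = np.asarray(model(m), dtype=float) - y
    return float(resid @ resid)
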