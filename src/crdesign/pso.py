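"""Particle swarm optimisation with a decaying inertia schedule.

Criterion-agnostic box-constrained minimiser.  Each particle i carries a
position X_i and velocity V_i; at iteration k these are updated as

    V_i(k) = w(k) V_i(k-1) + c1 R1 * (L_i - X_i) + c2 R2 * (G - X_i)
    X_i(k) = X_i(k-1) + V_i(k)

where L_i is the particle's personal best, G the swarm's global best,
and R1, R2 component-wise uniform(0,1) draws.  The inertia w(k) follows
a power-law decay ((Nmax - k)/(Nmax - 1))**relaxation rescaled affinely
onto [inertia_end, inertia_start], so it runs from 0.9 down to 0.4 by
default.

Plumbing not fixed by the update equations: velocities start at zero and
are clipped to a fraction of the box width, positions leaving the box
are clamped with the offending velocity component zeroed, and several
independently seeded swarms are run with the best-ever solution
returned.  Results are bitwise reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = ["PSOConfig", "PSOResult", "inertia_at", "minimize"]


@dataclass(frozen=True)
class PSOConfig:
    """Tuning parameters of the swarm search.

    Defaults are the settings used throughout this package for the
    design problems: 25 particles, 700 iterations, cognitive weight 2.5,
    social weight 0.5, inertia decaying from 0.9 to 0.4 with relaxation
    exponent 1.5, and 5 independent restarts.
    """

    swarm_size: int = 25
    max_iterations: int = 700
    cognitive: float = 2.5
    social: float = 0.5
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    relaxation: float = 1.5
    seed: int = 0
    n_restarts: int = 5
    vmax_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.swarm_size < 1 or self.max_iterations < 1 or self.n_restarts < 1:
            raise ValueError("swarm_size, max_iterations, n_restarts must be >= 1")
        if self.cognitive < 0 or self.social < 0:
            raise ValueError("cognitive and social weights must be >= 0")
        if not (self.inertia_start >= self.inertia_end >= 0):
            raise ValueError("need inertia_start >= inertia_end >= 0")
        if self.relaxation <= 0:
            raise ValueError("relaxation exponent must be > 0")
        if not (0 < self.vmax_fraction <= 1):
            raise ValueError("vmax_fraction must be in (0, 1]")

    def with_seed(self, seed: int) -> "PSOConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class PSOResult:
    """Best solution found, with per-restart convergence traces."""

    position: np.ndarray
    value: float
    #: shape (n_restarts, max_iterations + 1): running global best of each
    #: swarm, starting from the post-initialisation value.
    trace: np.ndarray = field(repr=False)
    restart_values: np.ndarray = field(repr=False)

    def trace_table(self):
        """Best-restart trace as a DataFrame with (iteration, best_value)."""
        import pandas as pd

        best = int(np.argmin(self.restart_values))
        return pd.DataFrame(
            {"iteration": np.arange(self.trace.shape[1]), "best_value": self.trace[best]}
        )


def inertia_at(iteration: int, config: PSOConfig) -> float:
    """Inertia weight at a 1-based iteration.

    ``inertia_end + (inertia_start - inertia_end) *
    ((Nmax - k) / (Nmax - 1)) ** relaxation`` — a power-law decay hitting
    ``inertia_start`` at k=1 and ``inertia_end`` at k=Nmax.
    """
    n = config.max_iterations
    if not 1 <= iteration <= n:
        raise ValueError(f"iteration must be in [1, {n}], got {iteration}")
    if n == 1:
        return config.inertia_end
    frac = (n - iteration) / (n - 1)
    return config.inertia_end + (
        config.inertia_start - config.inertia_end
    ) * frac**config.relaxation


def _as_bounds(bounds) -> tuple[np.ndarray, np.ndarray]:
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or bounds.shape[0] < 1:
        raise ValueError("bounds must be a (D, 2) array of (lower, upper) pairs")
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(bounds)) or np.any(lo >= hi):
        raise ValueError("each bound pair must be finite with lower < upper")
    return lo, hi


def minimize(
    objective: Callable[[np.ndarray], float | np.ndarray],
    bounds: Sequence[tuple[float, float]],
    config: PSOConfig | None = None,
    vectorized: bool = False,
) -> PSOResult:
    """Minimise ``objective`` over a box with multi-restart PSO.

    ``objective`` maps a D-vector to a scalar (finite or +inf).  With
    ``vectorized=True`` it must instead map an (S, D) array to an
    S-vector, which is considerably faster for cheap analytic criteria.
    """
    cfg = config or PSOConfig()
    lo, hi = _as_bounds(bounds)
    dim = lo.size
    width = hi - lo
    vmax = cfg.vmax_fraction * width

    if vectorized:
        evaluate = lambda x: np.asarray(objective(x), dtype=float)
    else:
        evaluate = lambda x: np.array(
            [objective(row) for row in x], dtype=float
        )

    master = np.random.SeedSequence(cfg.seed)
    children = master.spawn(cfg.n_restarts)

    best_pos = None
    best_val = np.inf
    trace = np.empty((cfg.n_restarts, cfg.max_iterations + 1))
    restart_values = np.empty(cfg.n_restarts)

    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        x = lo + rng.uniform(size=(cfg.swarm_size, dim)) * width
        v = np.zeros_like(x)
        fx = evaluate(x)
        pbest = x.copy()
        pbest_val = fx.copy()
        g = int(np.argmin(pbest_val))
        gbest = pbest[g].copy()
        gbest_val = float(pbest_val[g])
        trace[r, 0] = gbest_val

        for k in range(1, cfg.max_iterations + 1):
            w = inertia_at(k, cfg)
            r1 = rng.uniform(size=(cfg.swarm_size, dim))
            r2 = rng.uniform(size=(cfg.swarm_size, dim))
            v = (
                w * v
                + cfg.cognitive * r1 * (pbest - x)
                + cfg.social * r2 * (gbest - x)
            )
            np.clip(v, -vmax, vmax, out=v)
            x = x + v
            low_hit = x < lo
            high_hit = x > hi
            if low_hit.any() or high_hit.any():
                out = low_hit | high_hit
                np.clip(x, lo, hi, out=x)
                v[out] = 0.0

            fx = evaluate(x)
            improved = fx < pbest_val
            pbest[improved] = x[improved]
            pbest_val[improved] = fx[improved]
            g = int(np.argmin(pbest_val))
            if pbest_val[g] < gbest_val:
                gbest_val = float(pbest_val[g])
                gbest = pbest[g].copy()
            trace[r, k] = gbest_val

        restart_values[r] = gbest_val
        if gbest_val < best_val:
            best_val = gbest_val
            best_pos = gbest

    return PSOResult(
        position=np.asarray(best_pos),
        value=float(best_val),
        trace=trace,
        restart_values=restart_values,
    )
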