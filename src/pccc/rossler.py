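"""Benchmark data: unidirectionally coupled Rossler systems.

The master system

    x1' = -omega1*y1 - z1
    y1' =  omega1*x1 + a1*y1
    z1' =  b1 + z1*(x1 - c1)

drives the slave through a diffusive term in its first coordinate only:

    x2' = -omega2*y2 - z2 + eps*(x1 - x2)
    y2' =  omega2*x2 + a2*y2
    z2' =  b2 + z2*(x2 - c2)

Defaults (a=0.15, b=0.2, c=10, omega1=1.015, omega2=0.985, eps=0.09,
sampling interval 0.314, 5000 transient samples discarded) put both systems
in the standard chaotic regime with 17-21 samples per oscillation period;
the slight frequency mismatch keeps the pair out of full synchronization at
the default coupling.  Observational degradations used in the robustness
experiments — additive Gaussian noise scaled to a percentage of the signal
standard deviation, and synchronous/asynchronous random sample deletion —
live here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RosslerConfig",
    "RosslerTrajectories",
    "SparsitySpec",
    "simulate_coupled_rossler",
    "add_noise",
    "sparsify",
    "draw_deletion_indices",
    "samples_per_period",
]


@dataclass(frozen=True)
class RosslerConfig:
    """Parameters of the coupled system, integration and sampling."""

    a1: float = 0.15
    a2: float = 0.15
    b1: float = 0.2
    b2: float = 0.2
    c1: float = 10.0
    c2: float = 10.0
    omega1: float = 1.015
    omega2: float = 0.985
    epsilon: float = 0.09
    dt_sample: float = 0.314
    n_transient: int = 5000
    n_samples: int = 2048
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("coupling epsilon must be >= 0")
        if self.dt_sample <= 0:
            raise ValueError("dt_sample must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_transient < 0:
            raise ValueError("n_transient must be >= 0")


@dataclass(frozen=True)
class RosslerTrajectories:
    """Sampled (n, 3) trajectories of the master and slave systems."""

    master: np.ndarray
    slave: np.ndarray
    dt_sample: float

    @property
    def x1(self) -> np.ndarray:
        return self.master[:, 0]

    @property
    def x2(self) -> np.ndarray:
        return self.slave[:, 0]


@dataclass(frozen=True)
class SparsitySpec:
    """Random sample deletion: fraction ``alpha`` at shared (sync) or
    independent (async) index sets."""

    alpha: float
    mode: str = "sync"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("sparsity fraction alpha must lie in [0, 1)")
        if self.mode not in ("sync", "async"):
            raise ValueError("mode must be 'sync' or 'async'")


def _rhs(t, state, cfg: RosslerConfig):
    x1, y1, z1, x2, y2, z2 = state
    return (
        -cfg.omega1 * y1 - z1,
        cfg.omega1 * x1 + cfg.a1 * y1,
        cfg.b1 + z1 * (x1 - cfg.c1),
        -cfg.omega2 * y2 - z2 + cfg.epsilon * (x1 - x2),
        cfg.omega2 * x2 + cfg.a2 * y2,
        cfg.b2 + z2 * (x2 - cfg.c2),
    )


def random_initial_state(rng: np.random.Generator) -> np.ndarray:
    """Initial condition in the box x,y in [-5,5], z in [0,1] per system."""
    xy = rng.uniform(-5.0, 5.0, size=4)
    z = rng.uniform(0.0, 1.0, size=2)
    return np.array([xy[0], xy[1], z[0], xy[2], xy[3], z[1]])


def simulate_coupled_rossler(
    config: RosslerConfig | None = None,
    initial_state: Sequence[float] | None = None,
) -> RosslerTrajectories:
    """Integrate the coupled system and return the sampled trajectories.

    Uses an adaptive 8th-order Runge-Kutta scheme (DOP853) at tolerance
    1e-9, samples every ``dt_sample`` time units, discards the first
    ``n_transient`` samples and returns the next ``n_samples``.  Initial
    conditions are drawn from ``config.seed`` unless given explicitly.
    """
    cfg = config or RosslerConfig()
    if initial_state is None:
        initial_state = random_initial_state(np.random.default_rng(cfg.seed))
    y0 = np.asarray(initial_state, dtype=float)
    if y0.shape != (6,):
        raise ValueError("initial_state must have 6 components")
    n_total = cfg.n_transient + cfg.n_samples
    t_eval = np.arange(n_total) * cfg.dt_sample
    sol = solve_ivp(
        _rhs,
        (0.0, t_eval[-1]),
        y0,
        t_eval=t_eval,
        method="DOP853",
        rtol=1e-9,
        atol=1e-9,
        args=(cfg,),
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"integration failed: {sol.message}")
    states = sol.y.T[cfg.n_transient :]
    return RosslerTrajectories(
        master=states[:, :3], slave=states[:, 3:], dt_sample=cfg.dt_sample
    )


def add_noise(series: Sequence[float], percent: float, seed=None) -> np.ndarray:
    """Add white Gaussian noise with sd = (percent/100) * sd(series)."""
    if percent < 0:
        raise ValueError("noise percent must be >= 0")
    arr = np.asarray(series, dtype=float)
    if percent == 0:
        return arr.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return arr + rng.normal(0.0, (percent / 100.0) * arr.std(), size=arr.size)


def draw_deletion_indices(
    n: int, spec: SparsitySpec
) -> tuple[np.ndarray, np.ndarray]:
    """Index sets to delete from the two series (identical in sync mode)."""
    n_del = int(round(spec.alpha * n))
    if n_del >= n:
        raise ValueError("cannot delete every sample")
    rng = np.random.default_rng(spec.seed)
    idx_x = np.sort(rng.choice(n, size=n_del, replace=False))
    if spec.mode == "sync":
        return idx_x, idx_x
    idx_y = np.sort(rng.choice(n, size=n_del, replace=False))
    return idx_x, idx_y


def sparsify(
    x: Sequence[float], y: Sequence[float], spec: SparsitySpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Delete a fraction of samples and concatenate the remainder.

    Returns ``(x_sparse, y_sparse, idx_x, idx_y)`` where the index arrays
    are the deleted positions.  Downstream measures receive the shortened
    series with no gap markers.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    idx_x, idx_y = draw_deletion_indices(x.size, spec)
    return np.delete(x, idx_x), np.delete(y, idx_y), idx_x, idx_y


def samples_per_period(x: Sequence[float]) -> np.ndarray:
    """Sample counts between successive strict local maxima of a series.

    A local maximum is a strict 3-point peak (x[i-1] < x[i] > x[i+1]); the
    returned array holds the index differences between consecutive peaks,
    i.e. the per-period sample counts at the configured sampling rate.
    """
    arr = np.asarray(x, dtype=float)
    interior = np.arange(1, arr.size - 1)
    peaks = interior[(arr[1:-1] > arr[:-2]) & (arr[1:-1] > arr[2:])]
    return np.diff(peaks)
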