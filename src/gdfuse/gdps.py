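"""Adaptive parameter selection by classic pattern (compass) search.

The fusion pipeline has two control parameters — the Gaussian window
half-size ``s`` and its spread ``sigma``.  Rather than fixing them, the
GDPS variant tunes ``(s, sigma)`` per input stack by maximizing a
fusion-quality objective (Qabf, Qcb, or negated Qcv) with a
derivative-free compass search: from the incumbent point the four axis
neighbors at the current mesh size are polled in a fixed order; the
first improvement is accepted and the mesh expands (x2), otherwise the
mesh contracts (x0.5).  The search is fully deterministic.

``s`` is searched as a real number and rounded to the nearest integer
(floored at 1) only when the Gaussian window is built; the box
constraints say nothing about integrality and a continuous box keeps
the search space in the form a generic pattern search expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .gd_core import GDConfig, FusedImage, gd_fuse
from .image_io import ImageStack
from .quality_metrics import qabf, qcb, qcv

__all__ = [
    "PSConfig",
    "PSPoint",
    "PSTrace",
    "OptimizationError",
    "fitness",
    "pattern_search",
    "gdps_fuse",
]

Objective = Literal["qabf", "qcb", "qcv"]


class OptimizationError(RuntimeError):
    """The objective was non-finite at every polled point."""

    def __init__(self, message: str, trace: "PSTrace"):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class PSPoint:
    """A candidate (s, sigma) with its objective value."""

    s: float
    sigma: float
    fitness: float


@dataclass
class PSTrace:
    """Iteration log: (iteration, incumbent, mesh size, total evaluations)."""

    records: list[tuple[int, PSPoint, float, int]] = field(default_factory=list)

    def append(self, iteration: int, best: PSPoint, mesh: float, evals: int) -> None:
        self.records.append((iteration, best, mesh, evals))

    @property
    def best_fitness_sequence(self) -> list[float]:
        return [rec[1].fitness for rec in self.records]

    @property
    def n_evaluations(self) -> int:
        return self.records[-1][3] if self.records else 0


@dataclass(frozen=True)
class PSConfig:
    """Compass-search settings.

    The published experimental setup fixes the box [5, 80] x [1, 100],
    start (10, 3.3) and 20 iterations; mesh-management constants are the
    textbook defaults (initial mesh 1, expansion 2, contraction 0.5).
    """

    init: tuple[float, float] = (10.0, 3.3)
    lower: tuple[float, float] = (5.0, 1.0)
    upper: tuple[float, float] = (80.0, 100.0)
    max_iter: int = 20
    objective: Objective = "qabf"
    mesh_init: float = 1.0
    expansion: float = 2.0
    contraction: float = 0.5
    mesh_tol: float = 1e-3

    def __post_init__(self) -> None:
        if not all(lo < hi for lo, hi in zip(self.lower, self.upper)):
            raise ValueError("need lower < upper componentwise")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.objective not in ("qabf", "qcb", "qcv"):
            raise ValueError(f"unknown objective {self.objective!r}")

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


def fitness(
    stack: ImageStack, s: float, sigma: float, objective: Objective = "qabf"
) -> float:
    """Fuse with (round(s), sigma) and score; maximization orientation.

    Qcv is a distortion (lower better) and is returned negated so all
    three objectives are maximized uniformly.
    """
    s_int = max(1, int(round(s)))
    fused = gd_fuse(stack, GDConfig(s=s_int, sigma=float(sigma)))
    if objective == "qabf":
        return qabf(stack[0], stack[1], fused.pixels)
    if objective == "qcb":
        return qcb(stack[0], stack[1], fused.pixels)
    if objective == "qcv":
        return -qcv(stack, fused.pixels)
    raise ValueError(f"unknown objective {objective!r}")


#: Fixed polling order: +s, -s, +sigma, -sigma.
_DIRECTIONS = (
    np.array([1.0, 0.0]),
    np.array([-1.0, 0.0]),
    np.array([0.0, 1.0]),
    np.array([0.0, -1.0]),
)


def pattern_search(
    objective: Callable[[float, float], float], config: PSConfig | None = None
) -> tuple[PSPoint, PSTrace]:
    """Classic compass search maximizing ``objective(s, sigma)``.

    Polls the four axis neighbors at the current mesh size with
    first-improvement acceptance; the mesh expands on success and
    contracts on failure.  Stops after ``max_iter`` polls or when the
    mesh drops below ``mesh_tol``.  Evaluation count is bounded by
    ``1 + 4 * max_iter``.
    """
    cfg = config or PSConfig()
    trace = PSTrace()
    x = cfg.clamp(np.asarray(cfg.init, dtype=float))
    f = float(objective(*x))
    evals = 1
    if not np.isfinite(f):
        trace.append(0, PSPoint(x[0], x[1], f), cfg.mesh_init, evals)
        raise OptimizationError("objective non-finite at the initial point", trace)
    best = PSPoint(x[0], x[1], f)
    mesh = cfg.mesh_init
    trace.append(0, best, mesh, evals)
    any_finite = True
    for it in range(1, cfg.max_iter + 1):
        if mesh < cfg.mesh_tol:
            break
        improved = False
        poll_finite = False
        for direction in _DIRECTIONS:
            cand = cfg.clamp(x + mesh * direction)
            if np.allclose(cand, x):
                continue  # clamped onto the incumbent; nothing new to poll
            fc = float(objective(*cand))
            evals += 1
            if np.isfinite(fc):
                poll_finite = True
            if fc > best.fitness:
                x = cand
                best = PSPoint(cand[0], cand[1], fc)
                improved = True
                break
        any_finite = any_finite or poll_finite
        mesh = mesh * (cfg.expansion if improved else cfg.contraction)
        trace.append(it, best, mesh, evals)
    if not any_finite:
        raise OptimizationError("objective non-finite at every polled point", trace)
    return best, trace


def gdps_fuse(
    stack: ImageStack,
    objective: Objective = "qabf",
    config: PSConfig | None = None,
) -> tuple[FusedImage, tuple[int, float], PSTrace]:
    """Optimize (s, sigma) for a stack and return the tuned fusion.

    Returns the fused image at the best point found, the resolved
    (integer s, sigma) pair, and the search trace.  Because the search
    keeps the incumbent, the final objective value is never worse than
    at the starting point.
    """
    cfg = config or PSConfig()
    if cfg.objective != objective:
        cfg = PSConfig(
            init=cfg.init,
            lower=cfg.lower,
            upper=cfg.upper,
            max_iter=cfg.max_iter,
            objective=objective,
            mesh_init=cfg.mesh_init,
            expansion=cfg.expansion,
            contraction=cfg.contraction,
            mesh_tol=cfg.mesh_tol,
        )
    best, trace = pattern_search(
        lambda s, sigma: fitness(stack, s, sigma, objective), cfg
    )
    s_int = max(1, int(round(best.s)))
    fused = gd_fuse(stack, GDConfig(s=s_int, sigma=best.sigma))
    return fused, (s_int, best.sigma), trace
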