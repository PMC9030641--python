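"""Water Wave Optimization (WWO), the derivative-free trainer used for every
fuzzy-network pretraining/fine-tuning step and for clustering-centroid seeding.

WWO evolves a small population of "waves" (candidate parameter vectors) with
three operators:

* **propagation** — each wave takes a uniform random step scaled by its
  wavelength; good waves get short wavelengths (exploitation), poor waves get
  long ones (exploration);
* **refraction** — a wave that has stagnated for ``h_max`` generations is
  redrawn around the midpoint between itself and the current best;
* **breaking** — a new global best spawns a handful of solitary waves, a
  local search with a breaking coefficient annealed over the run.

The objective is minimised.  All randomness comes from one injected
``numpy.random.Generator``, so runs are reproducible from a single seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["SearchSpace", "OptimizerConfig", "Wave", "OptimizeResult",
           "optimize", "random_search", "propagate", "update_wavelengths",
           "refract", "break_wave"]


@dataclass(frozen=True)
class SearchSpace:
    """A bounded box: per-dimension lower/upper bounds."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lo.shape != hi.shape or np.any(lo >= hi):
            raise ValueError("search space requires lower < upper per dimension")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dim(self) -> int:
        return self.lower.shape[0]

    @property
    def length(self) -> np.ndarray:
        return self.upper - self.lower

    @classmethod
    def unit(cls, dim: int) -> "SearchSpace":
        return cls(np.zeros(dim), np.ones(dim))


@dataclass
class OptimizerConfig:
    """WWO control parameters.

    The wavelength-reduction base ``alpha``, maximum wave height ``h_max``,
    initial wavelength ``lambda_init`` and the linear breaking-coefficient
    schedule follow the original WWO formulation; the evaluation ``budget``
    is the stopping criterion.
    """

    budget: int = 5000
    population: int = 8
    h_max: int = 6
    alpha: float = 1.0026
    beta_hi: float = 0.25
    beta_lo: float = 0.001
    k_max: int | None = None        # default min(12, dim // 2)
    lambda_init: float = 0.5
    eps: float = 1e-31
    seed: int | None = None
    patience: int | None = None     # evaluations without >min_improve progress
    min_improve: float = 1e-6

    def __post_init__(self):
        if self.budget < self.population:
            raise ValueError("budget must be at least the population size")
        if self.population < 2 or self.h_max < 1 or self.alpha <= 0:
            raise ValueError("invalid optimizer configuration")


@dataclass
class Wave:
    position: np.ndarray
    fitness: float
    wavelength: float
    height: int


@dataclass
class OptimizeResult:
    x: np.ndarray
    fun: float
    trace: list = field(default_factory=list)  # (evaluation index, best fitness)
    n_evaluations: int = 0


def propagate(wave: Wave, space: SearchSpace, rng: np.random.Generator) -> np.ndarray:
    """Wavelength-scaled uniform step; out-of-range coordinates are
    reinitialised uniformly inside the box."""
    step = rng.uniform(-1.0, 1.0, space.dim) * wave.wavelength * space.length
    x = wave.position + step
    bad = (x < space.lower) | (x > space.upper)
    if np.any(bad):
        x[bad] = space.lower[bad] + rng.random(int(bad.sum())) * space.length[bad]
    return x


def update_wavelengths(waves: Sequence[Wave], alpha: float, eps: float) -> None:
    """Fitness-ranked multiplicative wavelength update (minimisation): the
    best wave's wavelength shrinks by ~alpha**-1, the worst stays ~unchanged."""
    fs = np.array([w.fitness for w in waves])
    f_min, f_max = fs.min(), fs.max()
    expo = -(f_max - fs + eps) / (f_max - f_min + eps)
    for w, e in zip(waves, expo):
        w.wavelength *= alpha ** e


def refract(wave: Wave, best: Wave, space: SearchSpace,
            rng: np.random.Generator) -> np.ndarray:
    """Stagnation reset: redraw each coordinate from a Gaussian centred at
    the midpoint between the wave and the global best."""
    mid = 0.5 * (best.position + wave.position)
    std = 0.5 * np.abs(best.position - wave.position)
    x = rng.normal(mid, std)
    return np.clip(x, space.lower, space.upper)


def break_wave(best: Wave, space: SearchSpace, rng: np.random.Generator,
               k: int, beta: float) -> np.ndarray:
    """Solitary waves around a new best: ``k`` candidates, each perturbing a
    single random dimension by ``N(0,1) * beta * length``."""
    dims = rng.choice(space.dim, size=min(k, space.dim), replace=False)
    cands = np.repeat(best.position[None, :], len(dims), axis=0)
    for row, d in zip(cands, dims):
        row[d] += rng.normal() * beta * space.length[d]
    return np.clip(cands, space.lower, space.upper)


def _safe(f: float) -> float:
    if not np.isfinite(f):
        warnings.warn("objective returned a non-finite value; treating as +inf",
                      RuntimeWarning, stacklevel=3)
        return np.inf
    return float(f)


def optimize(objective: Callable[[np.ndarray], float], space: SearchSpace,
             config: OptimizerConfig | None = None,
             rng: np.random.Generator | None = None,
             x0: np.ndarray | None = None) -> OptimizeResult:
    """Run WWO, returning the best position, its objective value and the
    best-so-far trace (monotone non-increasing; at most ``budget``
    evaluations).

    ``x0``, if given, seeds one wave of the initial population (the rest are
    uniform in the box) — used to warm-start fine-tuning.
    """
    cfg = config or OptimizerConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    k_max = cfg.k_max if cfg.k_max is not None else max(1, min(12, space.dim // 2))

    n_eval = 0
    trace: list[tuple[int, float]] = []
    best_x, best_f = None, np.inf
    stall_anchor_f, stall_anchor_eval = np.inf, 0
    stop = False

    def evaluate(x: np.ndarray) -> float:
        nonlocal n_eval, best_x, best_f, stall_anchor_f, stall_anchor_eval, stop
        f = _safe(objective(x))
        n_eval += 1
        if f < best_f:
            best_f, best_x = f, x.copy()
        trace.append((n_eval, best_f))
        if cfg.patience is not None:
            if best_f < stall_anchor_f - cfg.min_improve:
                stall_anchor_f, stall_anchor_eval = best_f, n_eval
            elif n_eval - stall_anchor_eval >= cfg.patience:
                stop = True
        if n_eval >= cfg.budget:
            stop = True
        return f

    waves: list[Wave] = []
    for i in range(cfg.population):
        if x0 is not None and i == 0:
            x = np.clip(np.asarray(x0, dtype=float), space.lower, space.upper)
        else:
            x = space.lower + rng.random(space.dim) * space.length
        waves.append(Wave(x, evaluate(x), cfg.lambda_init, cfg.h_max))
        if stop:
            return OptimizeResult(best_x, best_f, trace, n_eval)

    while not stop:
        beta = cfg.beta_hi - (cfg.beta_hi - cfg.beta_lo) * min(1.0, n_eval / cfg.budget)
        for w in waves:
            if stop:
                break
            cand = propagate(w, space, rng)
            f = evaluate(cand)
            if stop and f >= w.fitness:
                break
            if f < w.fitness:
                w.position, w.fitness, w.height = cand, f, cfg.h_max
                if f <= best_f and not stop:
                    # new global best: breaking (elitist — never worsens best)
                    k = int(rng.integers(1, k_max + 1))
                    for bx in break_wave(w, space, rng, k, beta):
                        bf = evaluate(bx)
                        if bf < w.fitness:
                            w.position, w.fitness = bx.copy(), bf
                        if stop:
                            break
            else:
                w.height -= 1
                if w.height <= 0 and not stop:
                    best_w = min(waves, key=lambda v: v.fitness)
                    x = refract(w, best_w, space, rng)
                    fr = evaluate(x)
                    # wavelength rescaled by the cost ratio: an improving
                    # refraction (fr < fitness) shortens the wavelength
                    new_lam = w.wavelength * (
                        (fr + cfg.eps) / (w.fitness + cfg.eps)
                        if fr > 0 and w.fitness > 0 else 1.0)
                    w.position, w.fitness = x, fr
                    w.wavelength = float(np.clip(new_lam, 1e-6, 1.0))
                    w.height = cfg.h_max
        update_wavelengths(waves, cfg.alpha, cfg.eps)

    return OptimizeResult(best_x, best_f, trace, n_eval)


def random_search(objective: Callable[[np.ndarray], float], space: SearchSpace,
                  budget: int, rng: np.random.Generator) -> OptimizeResult:
    """Uniform random search control at the same evaluation budget."""
    best_x, best_f = None, np.inf
    trace = []
    for i in range(budget):
        x = space.lower + rng.random(space.dim) * space.length
        f = _safe(objective(x))
        if f < best_f:
            best_f, best_x = f, x.copy()
        trace.append((i + 1, best_f))
    return OptimizeResult(best_x, best_f, trace, budget)
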