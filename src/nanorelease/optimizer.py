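"""Formulation fitness and the real-coded genetic algorithm.

The design goal is a formulation whose predicted release profile has
maximal loading efficiency (Le), maximal terminal release (RTRmax) at a
maximal release time (TRmax, ideal 240 h) and minimal burst release (BR).
The scalar fitness to minimize is

    F = [ (100 - RTRmax)/100 + BR/100 + |240 - TRmax|/240 + (100 - Le)/100 ] / 5

which is zero exactly at the ideal point (RTRmax=100, BR=0, TRmax=240,
Le=100). The TRmax term is the absolute deviation from the 240-hour ideal
(for TRmax <= 240 this is simply (240 - TRmax)/240); the divisor 5 is kept
as a convention of the original formulation.

The GA is real-coded over the four structural genes with box bounds
(feeding ratio [1, 2], CS% [7, 23], Fe3O4% [1, 7], 5FU% [1, 5]):
rank-based roulette-wheel parent selection (inverted, minimization),
single-elite preservation, blend crossover, annealed Gaussian mutation,
and forward migration of the best individuals around a two-deme ring.
Stopping: generation cap, fitness limit, or a stall of ``stall_generations``
consecutive generations improving less than ``function_tolerance``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .datamodel import FormulationParams, ReleaseParams
from .exceptions import DomainError

#: Chromosome box bounds: feeding ratio, CS%, Fe3O4%, 5FU%.
DEFAULT_BOUNDS = ((1.0, 2.0), (7.0, 23.0), (1.0, 7.0), (1.0, 5.0))

#: Ideal release time, hours.
TRMAX_IDEAL = 240.0


def fitness_terms(rtrmax, br, trmax, le) -> np.ndarray:
    """The four penalty terms, vectorized; stack order (rtrmax, br, trmax, le)."""
    rtrmax, br, trmax, le = (np.asarray(v, dtype=float) for v in (rtrmax, br, trmax, le))
    return np.stack([
        (100.0 - rtrmax) / 100.0,
        br / 100.0,
        np.abs(TRMAX_IDEAL - trmax) / TRMAX_IDEAL,
        (100.0 - le) / 100.0,
    ])


def fitness_value(rtrmax, br, trmax, le):
    """Scalar/vector fitness from raw response values (no invariant checks)."""
    return fitness_terms(rtrmax, br, trmax, le).sum(axis=0) / 5.0


def fitness(response: ReleaseParams) -> float:
    """Fitness of a validated response; 0 iff (RTRmax, BR, TRmax, Le) = (100, 0, 240, 100)."""
    vals = (response.rtrmax, response.br, response.trmax, response.le)
    if not all(np.isfinite(vals)):
        raise DomainError(f"non-finite response {vals}")
    return float(fitness_value(response.rtrmax, response.br, response.trmax, response.le))


def fitness_from_responses(R: np.ndarray) -> np.ndarray:
    """Fitness per row of a response matrix with columns (br, trmax, rtrmax, le)."""
    R = np.atleast_2d(np.asarray(R, dtype=float))
    return fitness_value(R[:, 2], R[:, 0], R[:, 1], R[:, 3])


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 20
    max_generations: int = 100
    elite_count: int = 1
    crossover_fraction: float = 0.8
    mutation_fraction: float = 0.2
    migration_fraction: float = 0.2
    fitness_limit: float = 0.0
    function_tolerance: float = 1e-6
    stall_generations: int = 5
    bounds: tuple = DEFAULT_BOUNDS
    runs: int = 20
    seed: int = 0
    n_demes: int = 2
    mutation_scale: float = 0.1   # initial SD as a fraction of gene span
    anneal_floor: float = 0.05    # fraction of initial SD kept at the last generation

    def __post_init__(self):
        for name in ("crossover_fraction", "mutation_fraction", "migration_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name}={v} outside [0, 1]")
        if self.population_size < 2:
            raise DomainError("population_size must be >= 2")
        if any(lo >= hi for lo, hi in self.bounds):
            raise DomainError("each gene bound must satisfy lower < upper")
        if self.elite_count < 0 or self.elite_count * self.n_demes >= self.population_size:
            raise DomainError("elite_count too large for the population")
        if self.runs < 1 or self.n_demes < 1:
            raise DomainError("runs and n_demes must be >= 1")


@dataclass
class GAResult:
    best_x: np.ndarray
    best_fitness: float
    trace: list
    stopping_reason: str
    seed: int
    generations: int
    runs: Optional[list] = None
    best_formulation: Optional[FormulationParams] = None

    def __post_init__(self):
        assert math.isclose(self.best_fitness, min(self.trace), rel_tol=0, abs_tol=0) or \
            self.best_fitness <= min(self.trace) + 1e-15


def _evaluate(objective, X: np.ndarray) -> np.ndarray:
    f = np.asarray(objective(X), dtype=float)
    bad = ~np.isfinite(f)
    if np.any(bad):
        warnings.warn(f"objective returned {int(bad.sum())} non-finite value(s); "
                      "assigned worst fitness")
        f = np.where(bad, np.inf, f)
    return f


def run_ga(objective: Callable[[np.ndarray], np.ndarray],
           config: Optional[GAConfig] = None,
           seed: Optional[int] = None) -> GAResult:
    """Minimize a vectorized objective over the bounded box with one GA run.

    ``objective`` maps an (n, n_genes) array of candidates to an (n,) array
    of fitness values (lower is better).
    """
    cfg = config if config is not None else GAConfig()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    span = hi - lo
    d = lo.size

    # split the population over demes as evenly as possible
    base, extra = divmod(cfg.population_size, cfg.n_demes)
    deme_sizes = [base + (1 if i < extra else 0) for i in range(cfg.n_demes)]
    demes = [rng.uniform(lo, hi, (m, d)) for m in deme_sizes]
    fits = [_evaluate(objective, P) for P in demes]

    best_f = float(min(f.min() for f in fits))
    best_x = None
    for P, f in zip(demes, fits):
        i = int(np.argmin(f))
        if f[i] == best_f and best_x is None:
            best_x = P[i].copy()

    trace = [best_f]
    stall = 0
    reason = "generations"
    gen = 0
    for gen in range(1, cfg.max_generations + 1):
        anneal = max(1.0 - gen / cfg.max_generations, cfg.anneal_floor)
        sd = cfg.mutation_scale * span * anneal
        new_demes = []
        for P, f in zip(demes, fits):
            m = P.shape[0]
            order = np.argsort(f, kind="stable")
            elites = P[order[:cfg.elite_count]]
            n_off = m - cfg.elite_count
            # rank-based roulette: best rank gets weight m, worst weight 1
            weights = np.empty(m)
            weights[order] = np.arange(m, 0, -1, dtype=float)
            p = weights / weights.sum()

            parents_a = P[rng.choice(m, size=n_off, p=p)]
            parents_b = P[rng.choice(m, size=n_off, p=p)]
            children = parents_a.copy()
            n_cross = int(round(cfg.crossover_fraction * n_off))
            if n_cross > 0:
                u = rng.uniform(-0.25, 1.25, (n_cross, d))  # blend crossover
                children[:n_cross] = (parents_a[:n_cross]
                                      + u * (parents_b[:n_cross] - parents_a[:n_cross]))
            n_mut = int(round(cfg.mutation_fraction * n_off))
            if n_mut > 0:
                idx = rng.choice(n_off, size=n_mut, replace=False)
                children[idx] += rng.normal(0.0, 1.0, (n_mut, d)) * sd
            new_demes.append(np.clip(np.vstack([elites, children]), lo, hi))

        # forward migration around the deme ring: best of deme i replace
        # the worst of deme i+1
        if cfg.n_demes > 1 and cfg.migration_fraction > 0:
            new_fits = [_evaluate(objective, P) for P in new_demes]
            migrated = [P.copy() for P in new_demes]
            for i, (P, f) in enumerate(zip(new_demes, new_fits)):
                n_mig = max(1, int(round(cfg.migration_fraction * P.shape[0])))
                src = P[np.argsort(f, kind="stable")[:n_mig]]
                j = (i + 1) % cfg.n_demes
                worst = np.argsort(new_fits[j], kind="stable")[-n_mig:]
                migrated[j][worst] = src
            demes = migrated
        else:
            demes = new_demes
        fits = [_evaluate(objective, P) for P in demes]

        gen_best = float(min(f.min() for f in fits))
        if gen_best < best_f:
            for P, f in zip(demes, fits):
                i = int(np.argmin(f))
                if f[i] == gen_best:
                    best_x = P[i].copy()
                    break
            improvement = best_f - gen_best
            best_f = gen_best
        else:
            improvement = 0.0
        trace.append(best_f)

        if best_f <= cfg.fitness_limit + 1e-15:
            reason = "fitness_limit"
            break
        stall = stall + 1 if improvement < cfg.function_tolerance else 0
        if stall >= cfg.stall_generations:
            reason = "stall_tolerance"
            break

    return GAResult(best_x=best_x, best_fitness=best_f, trace=trace,
                    stopping_reason=reason, seed=int(seed), generations=gen)


def run_ga_repeated(objective: Callable[[np.ndarray], np.ndarray],
                    config: Optional[GAConfig] = None) -> GAResult:
    """Run the GA ``config.runs`` times from derived seeds; best run reported.

    The returned result carries all individual runs in ``.runs``.
    """
    cfg = config if config is not None else GAConfig()
    seeds = np.random.default_rng(cfg.seed).integers(0, 2**31 - 1, size=cfg.runs)
    results = [run_ga(objective, cfg, seed=int(s)) for s in seeds]
    best = min(results, key=lambda r: r.best_fitness)
    return GAResult(best_x=best.best_x, best_fitness=best.best_fitness,
                    trace=best.trace, stopping_reason=best.stopping_reason,
                    seed=best.seed, generations=best.generations, runs=results)


def optimize_formulation(model, config: Optional[GAConfig] = None) -> GAResult:
    """Search formulation space against a trained surrogate.

    The objective is ``fitness(predict(model, chromosome))``; the best of
    ``config.runs`` GA runs is reported with the chromosome decoded into a
    FormulationParams.
    """
    cfg = config if config is not None else GAConfig()

    def objective(X: np.ndarray) -> np.ndarray:
        return fitness_from_responses(model.predict_array(X))

    result = run_ga_repeated(objective, cfg)
    g = result.best_x
    result.best_formulation = FormulationParams(
        feeding_ratio=float(g[0]), cs_percent=float(g[1]),
        np_percent=float(g[2]), drug_percent=float(g[3]))
    return result
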