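"""Differential Evolution over mate-selection genotypes.

Classic DE/rand/1/bin on the flat real genotype: for each target vector a
mutant ``x_r1 + F (x_r2 − x_r3)`` is built from three distinct others,
binomial crossover with rate ``CR`` (one coordinate forced from the
mutant) forms the trial, and greedy selection keeps the better of trial
and target.  Integer genotype segments stay real-valued here and are
rounded inside the decoder, which keeps the DE arithmetic continuous.

Every vector is decoded into a mating list and scored by a caller-supplied
fitness function; the best-ever solution and a per-generation trajectory
(fitness, components, legality of the incumbent best) are returned.  All
randomness flows from the config seed, so a run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
import pandas as pd

from .grouping import MatingList
from .objective import ObjectiveComponents, components_cached

__all__ = ["DEConfig", "Trajectory", "evolve", "evolve_vectors", "compare_strategies"]


@dataclass(frozen=True)
class DEConfig:
    pop_size: int = 50
    f: float = 0.8
    cr: float = 0.9
    generations: int = 1000
    seed: int = 0
    early_stop_fitness: float | None = None

    def __post_init__(self):
        if self.pop_size < 4:
            raise ValueError("DE/rand/1 needs a population of at least 4")
        if not (0.0 <= self.cr <= 1.0):
            raise ValueError("crossover rate CR must be in [0, 1]")


@dataclass
class Trajectory:
    """Per-generation record of the incumbent best solution."""

    generation: list[int] = field(default_factory=list)
    best_fitness: list[float] = field(default_factory=list)
    mean_index: list[float] = field(default_factory=list)
    coancestry: list[float] = field(default_factory=list)
    mean_inbreeding: list[float] = field(default_factory=list)
    legal: list[bool] = field(default_factory=list)

    def record(self, gen: int, fitness: float, oc: ObjectiveComponents | None, legal: bool):
        self.generation.append(gen)
        self.best_fitness.append(fitness)
        self.mean_index.append(oc.mean_progeny_index if oc else float("nan"))
        self.coancestry.append(oc.parental_coancestry if oc else float("nan"))
        self.mean_inbreeding.append(oc.mean_progeny_inbreeding if oc else float("nan"))
        self.legal.append(legal)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generation,
                "best_fitness": self.best_fitness,
                "mean_index": self.mean_index,
                "coancestry": self.coancestry,
                "mean_inbreeding": self.mean_inbreeding,
                "legal": np.asarray(self.legal, dtype=int),
            }
        )

    @property
    def censored_generations(self) -> int:
        """Generations whose incumbent best breaks a constraint."""
        return int(np.sum(~np.asarray(self.legal, dtype=bool)))

    def final_legal_fitness(self) -> float:
        """Best fitness among generations with a legal incumbent (−inf if none)."""
        legal = np.asarray(self.legal, dtype=bool)
        if not legal.any():
            return float("-inf")
        return float(np.asarray(self.best_fitness)[legal].max())


class VectorProblem(Protocol):
    """Minimal interface for :func:`evolve_vectors` (used by self-tests)."""

    dim: int

    def bounds(self) -> tuple[np.ndarray, np.ndarray]: ...

    def init_population(self, size: int, rng: np.random.Generator) -> np.ndarray: ...

    def evaluate(self, vector: np.ndarray, rng: np.random.Generator) -> float: ...


def evolve_vectors(problem: VectorProblem, cfg: DEConfig):
    """Bare DE loop over a generic real-vector problem (maximisation)."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    lo, hi = problem.bounds()
    pop = problem.init_population(cfg.pop_size, rng)
    fit = np.asarray([problem.evaluate(v, rng) for v in pop])
    best_i = int(np.argmax(fit))
    best_x, best_f = pop[best_i].copy(), float(fit[best_i])
    history = [best_f]
    for _ in range(cfg.generations):
        for i in range(cfg.pop_size):
            r1, r2, r3 = _pick3(cfg.pop_size, i, rng)
            mutant = pop[r1] + cfg.f * (pop[r2] - pop[r3])
            trial = _crossover(pop[i], mutant, cfg.cr, rng)
            np.clip(trial, lo, hi, out=trial)
            tf = problem.evaluate(trial, rng)
            if tf >= fit[i]:
                pop[i], fit[i] = trial, tf
                if tf > best_f:
                    best_x, best_f = trial.copy(), float(tf)
        history.append(best_f)
        if cfg.early_stop_fitness is not None and best_f >= cfg.early_stop_fitness:
            break
    return best_x, best_f, history


def _pick3(n: int, i: int, rng: np.random.Generator) -> tuple[int, int, int]:
    out: list[int] = []
    while len(out) < 3:
        r = int(rng.integers(n))
        if r != i and r not in out:
            out.append(r)
    return out[0], out[1], out[2]


def _crossover(target, mutant, cr, rng):
    d = len(target)
    mask = rng.random(d) < cr
    mask[int(rng.integers(d))] = True
    return np.where(mask, mutant, target)


def evolve(
    problem,
    fitness_fn: Callable[[MatingList, ObjectiveComponents], float],
    cfg: DEConfig,
) -> tuple[MatingList, Trajectory]:
    """Run DE on a :class:`~groupfix.problem.MateSelectionProblem`.

    ``fitness_fn(mating_list, components) -> float`` is maximised.  The
    trajectory's legality flag reports whether the incumbent best solution
    violates the permission matrix, so penalty-mode runs can be censored
    exactly as the comparison experiment requires.  Returns the best-ever
    decoded mating list and the trajectory.
    """
    ss = np.random.SeedSequence(cfg.seed)
    de_ss, decode_ss = ss.spawn(2)
    rng_de = np.random.default_rng(de_ss)
    rng_dec = np.random.default_rng(decode_ss)

    lo, hi = problem.bounds()
    pop = problem.init_population(cfg.pop_size, rng_de)

    def eval_vec(vec):
        ml = problem.decode(vec, rng_dec)
        oc = components_cached(ml, problem)
        return ml, oc, float(fitness_fn(ml, oc))

    evals = [eval_vec(v) for v in pop]
    fit = np.asarray([e[2] for e in evals])
    best_i = int(np.argmax(fit))
    best_ml, best_oc, best_f = evals[best_i]

    traj = Trajectory()
    traj.record(1, best_f, best_oc, best_oc.illegal_pair_count == 0)

    for gen in range(2, cfg.generations + 1):
        for i in range(cfg.pop_size):
            r1, r2, r3 = _pick3(cfg.pop_size, i, rng_de)
            mutant = pop[r1] + cfg.f * (pop[r2] - pop[r3])
            trial = _crossover(pop[i], mutant, cfg.cr, rng_de)
            np.clip(trial, lo, hi, out=trial)
            ml, oc, tf = eval_vec(trial)
            if tf >= fit[i]:
                pop[i], fit[i] = trial, tf
                if tf > best_f:
                    best_ml, best_oc, best_f = ml, oc, tf
        traj.record(gen, best_f, best_oc, best_oc.illegal_pair_count == 0)
        if cfg.early_stop_fitness is not None and best_f >= cfg.early_stop_fitness:
            break
    return best_ml, traj


def compare_strategies(
    groupfix_problem,
    penalty_problem,
    steering,
    penalty_weights,
    cfg: DEConfig,
) -> dict[str, tuple[MatingList, Trajectory]]:
    """Repair vs penalising baselines at a matched budget.

    Runs the repair decoder once and the permission-blind decoder once per
    penalty weight, all with the same DE configuration and seed and the
    same steering anchors, so fitness values are directly comparable.
    Keys are ``"groupfix"`` and ``"penalty_<weight>"``.
    """
    from dataclasses import replace

    from .objective import steered_fitness

    results: dict[str, tuple[MatingList, Trajectory]] = {}
    sc0 = replace(steering, penalty_weight=0.0)
    results["groupfix"] = evolve(groupfix_problem, steered_fitness(sc0), cfg)
    for w in penalty_weights:
        sc = replace(steering, penalty_weight=float(w))
        results[f"penalty_{w:g}"] = evolve(penalty_problem, steered_fitness(sc), cfg)
    return results
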