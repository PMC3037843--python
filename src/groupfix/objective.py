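"""Objective evaluation: component criteria and scalar fitness.

A mating list is summarised by three component criteria:

* **mean progeny index** ``G`` — the average midparent merit over pairs;
* **parental coancestry** ``C = p'Kp`` — the use-weighted mean kinship
  among the parents, where ``p_i = Nm_i / (2 Nt)`` so that ``Σp = 1``;
  this is the quantity whose long-run accumulation optimal-contribution
  theory manages;
* **mean progeny inbreeding** ``F̄`` — the average kinship of the mated
  pairs, i.e. the expected inbreeding of next season's calves.

The balance between gain and diversity is steered by a *target degrees*
setting on the gain/coancestry frontier: 0° means pure index response,
90° means pure minimisation of coancestry.  The scalar used here projects
anchor-normalised components onto that direction,

    fitness = cos(θ) G' − sin(θ) C' + w_F F̄ − penalty × illegal pairs,

where ``G'`` and ``C'`` rescale ``G`` and ``C`` linearly to [0, 1]
between the two frontier endpoints (found by two short single-criterion
optimisations, :func:`calibrate_anchors`).  This projected form is this
package's own construction: it reproduces the documented endpoint
behaviour (0° ranks by index alone, 90° by coancestry alone), supports a
negative or zero inbreeding weighting, and charges penalty-mode solutions
exactly ``weight × number of illegal matings``.  It is isolated here so a
different scalarisation can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .grouping import MatingList
from .problem import MateSelectionProblem

__all__ = [
    "ObjectiveComponents",
    "SteeringConfig",
    "Anchors",
    "components",
    "components_cached",
    "scalar_fitness",
    "steered_fitness",
    "calibrate_anchors",
    "recovery_objective",
]


@dataclass(frozen=True)
class ObjectiveComponents:
    mean_progeny_index: float
    parental_coancestry: float
    mean_progeny_inbreeding: float
    illegal_pair_count: int


@dataclass(frozen=True)
class Anchors:
    """Frontier endpoints used to normalise index and coancestry.

    ``index_0deg``/``coancestry_0deg`` come from the maximum-index
    solution; ``index_90deg``/``coancestry_90deg`` from the
    minimum-coancestry solution.
    """

    index_0deg: float
    coancestry_0deg: float
    index_90deg: float
    coancestry_90deg: float


@dataclass(frozen=True)
class SteeringConfig:
    target_degrees: float = 25.0
    inbreeding_weight: float = -1.0
    penalty_weight: float = 0.0
    anchors: Anchors | None = None

    def __post_init__(self):
        if not (0.0 <= self.target_degrees <= 90.0):
            raise ValueError("target_degrees must lie in [0, 90]")
        if self.inbreeding_weight > 0:
            raise ValueError("inbreeding_weight must be <= 0")
        if self.penalty_weight < 0:
            raise ValueError("penalty_weight must be >= 0")


def components(ml: MatingList, pedigree, candidates) -> ObjectiveComponents:
    """Compute the component criteria directly from their definitions."""
    if len(ml) == 0:
        raise ValueError("cannot evaluate an empty mating list")
    index_of = {str(i): v for i, v in zip(candidates.ids, candidates.index)}
    parents = sorted({a for p in ml.pairs for a in p})
    K = pedigree.kinship_matrix(parents)
    nt = len(ml)
    counts = ml.use_counts()
    p = np.asarray([counts[a] / (2.0 * nt) for a in parents])
    Kv = K.to_numpy()
    coan = float(p @ Kv @ p)
    g = float(np.mean([(index_of[s] + index_of[d]) / 2.0 for s, d in ml.pairs]))
    fbar = float(np.mean([K.loc[s, d] for s, d in ml.pairs]))
    illegal = ml.illegal_pair_count(ml.permission) if ml.permission is not None else 0
    return ObjectiveComponents(g, coan, fbar, illegal)


def components_cached(ml: MatingList, problem: MateSelectionProblem) -> ObjectiveComponents:
    """Fast path using the problem's cached candidate kinship matrix."""
    if len(ml) == 0:
        raise ValueError("cannot evaluate an empty mating list")
    cs = problem.candidates
    nt = len(ml)
    counts = ml.use_counts()
    idx = np.asarray([cs.position(a) for a in counts], dtype=np.int64)
    p = np.asarray([counts[a] for a in counts], dtype=float) / (2.0 * nt)
    K = problem.kinship
    coan = float(p @ K[np.ix_(idx, idx)] @ p)
    si = np.asarray([cs.position(s) for s, _ in ml.pairs], dtype=np.int64)
    di = np.asarray([cs.position(d) for _, d in ml.pairs], dtype=np.int64)
    g = float(np.mean((cs.index[si] + cs.index[di]) / 2.0))
    fbar = float(np.mean(K[si, di]))
    illegal = ml.illegal_pair_count(problem.pm)
    return ObjectiveComponents(g, coan, fbar, illegal)


def scalar_fitness(oc: ObjectiveComponents, sc: SteeringConfig) -> float:
    """Projected, anchor-normalised scalar fitness (see module docstring)."""
    if sc.anchors is None:
        raise ValueError("steering anchors missing; run calibrate_anchors first")
    a = sc.anchors
    g_span = a.index_0deg - a.index_90deg
    c_span = a.coancestry_0deg - a.coancestry_90deg
    g_n = (oc.mean_progeny_index - a.index_90deg) / g_span if abs(g_span) > 1e-12 else 0.0
    c_n = (
        (oc.parental_coancestry - a.coancestry_90deg) / c_span
        if abs(c_span) > 1e-12
        else 0.0
    )
    theta = np.deg2rad(sc.target_degrees)
    return float(
        np.cos(theta) * g_n
        - np.sin(theta) * c_n
        + sc.inbreeding_weight * oc.mean_progeny_inbreeding
        - sc.penalty_weight * oc.illegal_pair_count
    )


def steered_fitness(sc: SteeringConfig) -> Callable[[MatingList, ObjectiveComponents], float]:
    def fitness(ml: MatingList, oc: ObjectiveComponents) -> float:
        return scalar_fitness(oc, sc)

    return fitness


def calibrate_anchors(
    problem: MateSelectionProblem,
    seed: int,
    budget: int = 20_000,
    pop_size: int = 50,
) -> Anchors:
    """Locate the frontier endpoints with two single-criterion runs.

    Runs one short optimisation maximising the mean progeny index and one
    minimising parental coancestry, both under the full decode repair, and
    records the (index, coancestry) pair of each winner.  Anchors only
    steer the normalisation, so approximate endpoints are sufficient.
    """
    from .de import DEConfig, evolve

    generations = max(1, budget // pop_size)
    cfg = DEConfig(pop_size=pop_size, generations=generations, seed=seed)
    best_g, _ = evolve(problem, lambda ml, oc: oc.mean_progeny_index, cfg)
    cfg90 = DEConfig(pop_size=pop_size, generations=generations, seed=seed + 1)
    best_c, _ = evolve(problem, lambda ml, oc: -oc.parental_coancestry, cfg90)
    oc_g = components_cached(best_g, problem)
    oc_c = components_cached(best_c, problem)
    return Anchors(
        index_0deg=oc_g.mean_progeny_index,
        coancestry_0deg=oc_g.parental_coancestry,
        index_90deg=oc_c.mean_progeny_index,
        coancestry_90deg=oc_c.parental_coancestry,
    )


def recovery_objective(target: MatingList) -> Callable[[MatingList, ObjectiveComponents], float]:
    """Fitness = number of pairs shared with a hidden target list.

    Used to probe whether the repair decoder can reach an independently
    constructed legal solution: the maximum (the list length) is attained
    exactly when the two lists coincide as multisets of sire × dam pairs.
    """
    from collections import Counter

    want = Counter(target.pairs)

    def fitness(ml: MatingList, oc: ObjectiveComponents) -> float:
        have = Counter(ml.pairs)
        return float(sum((want & have).values()))

    return fitness
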