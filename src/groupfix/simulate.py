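"""Synthetic breeding populations for fully offline testing.

:func:`simulate` emulates a multi-farm, overlapping-generation breeding
program: each farm mates a standing team of sires to a standing herd of
dams every cycle, selects replacements by truncation on an index proxy
(true breeding value under the infinitesimal model plus observation
noise standing in for an EBV), culls for age, and applies random adult
survival and a calving rate.  After the final cycle the live animals are
emitted as selection candidates grouped per farm, with *virtual* groups
for juveniles (below first-parity age), predicted embryos from the last
mating round, and a handful of retired high-merit AI sires — together
with the full pedigree and a cross-farm permission matrix in which farms
mate within themselves, juveniles and embryos only "mate" virtually, and
AI sires reach every farm.

:func:`small_fixture` builds a deterministic three-group toy problem
(18 candidates) with a known feasible structure, small enough that the
legal space of group-combination count matrices can be enumerated by
brute force.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .candidates import Candidate, CandidateSet
from .grouping import PermissionMatrix
from .pedigree import Pedigree

__all__ = [
    "SimScenario",
    "SimulationCollapseError",
    "simulate",
    "cross_farm_permission_matrix",
    "small_fixture",
]


class SimulationCollapseError(RuntimeError):
    """A farm ran out of breeding animals under the given parameters."""


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for the synthetic breeding program.

    Defaults describe three farms each mating 25 sires to 100 dams per
    cycle, first parity at age 3, age culling after 5 (males) / 8
    (females) mating cycles, 95% adult annual survival and an 80% calving
    rate, run for 10 cycles on top of a complete initial age structure.
    ``accuracy`` scales the observation noise of the index proxy
    (correlation between the proxy and the true breeding value).
    ``juvenile_*_retention`` is the fraction of calves kept past birth —
    surplus bull calves and a small share of heifers leave immediately,
    as they would in practice.
    """

    n_farms: int = 3
    sires_per_farm: int = 25
    dams_per_farm: int = 100
    first_parity_age: int = 3
    male_culling_cycles: int = 5
    female_culling_cycles: int = 8
    adult_survival: float = 0.95
    calving_rate: float = 0.80
    n_cycles: int = 10
    accuracy: float = 0.7
    juvenile_male_retention: float = 0.5
    juvenile_female_retention: float = 0.8
    n_ai_sires: int = 3
    sire_maxuse: int = 20
    sire_minuse: int = 2
    seed: int = 0

    def __post_init__(self):
        for p in (self.adult_survival, self.calving_rate, self.accuracy):
            if not (0.0 < p <= 1.0):
                raise ValueError("probabilities must lie in (0, 1]")
        if self.first_parity_age < 1 or self.n_cycles < 1:
            raise ValueError("ages and cycle counts must be positive")


@dataclass
class _Animal:
    id: int
    sex: str  # "M"/"F"
    farm: int
    born: int  # cycle of birth (founders: negative)
    sire: int | None
    dam: int | None
    tbv: float
    ebv: float
    alive: bool = True
    retired_sire: bool = False


def _ebv(tbv: float, accuracy: float, rng: np.random.Generator) -> float:
    noise_sd = np.sqrt(max(1.0 / accuracy**2 - 1.0, 1e-12))
    return tbv + noise_sd * rng.normal()


def simulate(sc: SimScenario):
    """Run the breeding program and emit a mate-selection problem.

    Returns ``(candidates, pedigree, permission_matrix, groups)`` where
    ``groups`` maps group label → list of candidate ids.
    """
    rng = np.random.default_rng(np.random.SeedSequence(sc.seed))
    animals: list[_Animal] = []
    next_id = 1

    def new_animal(sex, farm, born, sire, dam, tbv) -> _Animal:
        nonlocal next_id
        a = _Animal(next_id, sex, farm, born, sire, dam, tbv, _ebv(tbv, sc.accuracy, rng))
        next_id += 1
        animals.append(a)
        return a

    fp = sc.first_parity_age
    male_max_age = fp + sc.male_culling_cycles - 1
    female_max_age = fp + sc.female_culling_cycles - 1

    # complete initial age structure: adults spread over mating ages,
    # juveniles sized near the steady-state cohort
    for farm in range(sc.n_farms):
        for k in range(sc.sires_per_farm):
            age0 = fp + k % sc.male_culling_cycles  # age at the first cycle
            new_animal("M", farm, 1 - age0, None, None, rng.normal())
        for k in range(sc.dams_per_farm):
            age0 = fp + k % sc.female_culling_cycles
            new_animal("F", farm, 1 - age0, None, None, rng.normal())
        cohort = sc.dams_per_farm * sc.calving_rate
        for age0 in range(1, fp):
            for _ in range(int(round(cohort * 0.5 * sc.juvenile_male_retention))):
                new_animal("M", farm, 1 - age0, None, None, rng.normal())
            for _ in range(int(round(cohort * 0.5 * sc.juvenile_female_retention))):
                new_animal("F", farm, 1 - age0, None, None, rng.normal())

    last_matings: list[tuple[int, int, int]] = []  # (sire, dam, farm)
    for cycle in range(1, sc.n_cycles + 1):
        # adult survival, then age culling
        for a in animals:
            if not a.alive:
                continue
            age = cycle - a.born
            if age >= fp and rng.random() > sc.adult_survival:
                a.alive = False
        for a in animals:
            if not a.alive:
                continue
            age = cycle - a.born
            if a.sex == "M" and age > male_max_age:
                a.alive = False
                a.retired_sire = True
            elif a.sex == "F" and age > female_max_age:
                a.alive = False

        last_matings = []
        for farm in range(sc.n_farms):
            males = [
                a
                for a in animals
                if a.alive and a.sex == "M" and a.farm == farm and fp <= cycle - a.born <= male_max_age
            ]
            females = [
                a
                for a in animals
                if a.alive and a.sex == "F" and a.farm == farm and fp <= cycle - a.born <= female_max_age
            ]
            if not males or not females:
                raise SimulationCollapseError(
                    f"farm {farm + 1} has no breeding {'males' if not males else 'females'} "
                    f"in cycle {cycle}"
                )
            males.sort(key=lambda a: -a.ebv)
            females.sort(key=lambda a: -a.ebv)
            # truncation selection: standing team of sires, standing herd of dams
            team = males[: sc.sires_per_farm]
            for a in males[sc.sires_per_farm :]:
                # surplus males leave the program at selection age
                a.alive = False
            herd = females[: sc.dams_per_farm]
            for a in females[sc.dams_per_farm :]:
                a.alive = False
            for dam in herd:
                sire = team[int(rng.integers(len(team)))]
                last_matings.append((sire.id, dam.id, farm))
                if rng.random() < sc.calving_rate:
                    sex = "M" if rng.random() < 0.5 else "F"
                    keep = (
                        sc.juvenile_male_retention
                        if sex == "M"
                        else sc.juvenile_female_retention
                    )
                    tbv = 0.5 * (sire.tbv + dam.tbv) + np.sqrt(0.5) * rng.normal()
                    calf = new_animal(sex, farm, cycle, sire.id, dam.id, tbv)
                    if rng.random() >= keep:
                        calf.alive = False

    end = sc.n_cycles + 1  # candidate snapshot is taken just before the next round
    by_id = {a.id: a for a in animals}

    # predicted embryos from the final mating round
    embryos: list[_Animal] = []
    for sire_id, dam_id, farm in last_matings:
        if rng.random() < sc.calving_rate:
            sire, dam = by_id[sire_id], by_id[dam_id]
            sex = "M" if rng.random() < 0.5 else "F"
            tbv = 0.5 * (sire.tbv + dam.tbv) + np.sqrt(0.5) * rng.normal()
            e = new_animal(sex, farm, end, sire_id, dam_id, tbv)
            embryos.append(e)

    # retired AI sires: the best males culled for age
    retired = sorted(
        (a for a in animals if a.retired_sire), key=lambda a: -a.ebv
    )[: sc.n_ai_sires]

    cands: list[Candidate] = []
    groups: dict[str, list[str]] = {}

    def add(animal: _Animal, group: str, **limits):
        cid = str(animal.id)
        cands.append(
            Candidate(id=cid, sex=animal.sex, group=group, index=animal.ebv, **limits)
        )
        groups.setdefault(group, []).append(cid)

    embryo_ids = {e.id for e in embryos}
    for a in animals:
        if a.id in embryo_ids:
            add(a, "Embryo", maxuse=1, minuse=1)
            continue
        if not a.alive:
            continue
        age = end - a.born
        if age < fp:
            add(a, "Juvenile", maxuse=2 if a.sex == "M" else 1, minuse=1)
        elif a.sex == "M" and age <= male_max_age:
            add(a, f"Farm {a.farm + 1}", maxuse=sc.sire_maxuse, minuse=sc.sire_minuse)
        elif a.sex == "F" and age <= female_max_age:
            add(a, f"Farm {a.farm + 1}", maxuse=1, minuse=1)
    for a in retired:
        add(a, "AI", maxuse=1000, minuse=1)

    ped = Pedigree(
        [
            (
                str(a.id),
                str(a.sire) if a.sire is not None else None,
                str(a.dam) if a.dam is not None else None,
            )
            for a in animals
        ]
    )
    pm = cross_farm_permission_matrix(sc.n_farms)
    return CandidateSet(cands), ped, pm, groups


def cross_farm_permission_matrix(n_farms: int = 3) -> PermissionMatrix:
    """Cross-farm permission structure with virtual groups.

    Farms mate within themselves; juvenile males may (virtually) mate any
    female group; embryos only pair with juveniles and embryos; AI sires
    reach every real female group but not embryos.  Every farm's females
    also accept their own farm's sires and virtual juvenile matings.
    """
    farm = [f"Farm {i + 1}" for i in range(n_farms)]
    male_groups = farm + ["Juvenile", "Embryo", "AI"]
    female_groups = farm + ["Juvenile", "Embryo"]
    e = np.zeros((len(male_groups), len(female_groups)), dtype=np.int64)
    for i in range(n_farms):
        e[i, i] = 1  # within-farm natural mating
        e[i, n_farms] = 1  # farm sires over juvenile females (virtual)
    e[n_farms, :] = 1  # juvenile males: all female groups (virtual)
    e[n_farms + 1, n_farms] = 1  # embryo × juvenile (virtual)
    e[n_farms + 1, n_farms + 1] = 1  # embryo × embryo (virtual)
    e[n_farms + 2, :n_farms] = 1  # AI over every farm
    e[n_farms + 2, n_farms] = 1  # AI over juveniles (virtual)
    return PermissionMatrix(
        male_groups=tuple(male_groups),
        female_groups=tuple(female_groups),
        entries=e,
    )


def small_fixture(seed: int = 0):
    """Deterministic 18-candidate, 3×3-group toy problem.

    Six males (two per group M1–M3) and twelve females (four per group
    F1–F3) descend from eight unrelated founders, so kinship varies across
    pairs.  The permission matrix::

        F1 F2 F3
     M1  1  0  0
     M2  0  1  0
     M3  0  1  1

    exercises all three action types (F1 and F3 are single-row columns,
    F2 has an optimised row and a calculated last row).  Selection
    proportions of 3/4 give 3 matings per female group (9 in total), well
    within the male capacities (maxuse 4, minuse 1).

    Returns ``(candidates, pedigree, permission_matrix, proportions)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2011]))
    founders = [(f"S{k}", None, None) for k in range(1, 5)] + [
        (f"D{k}", None, None) for k in range(1, 5)
    ]
    records = list(founders)
    cands: list[Candidate] = []
    mg = ["M1", "M1", "M2", "M2", "M3", "M3"]
    for k, g in enumerate(mg, start=1):
        sid = f"S{(k - 1) % 4 + 1}"
        did = f"D{(k - 1) % 4 + 1}"
        records.append((f"B{k}", sid, did))
        cands.append(
            Candidate(
                id=f"B{k}", sex="M", group=g, index=round(float(rng.normal()), 3),
                maxuse=4, minuse=1,
            )
        )
    fg = ["F1"] * 4 + ["F2"] * 4 + ["F3"] * 4
    for k, g in enumerate(fg, start=1):
        sid = f"S{k % 4 + 1}"
        did = f"D{(k + 1) % 4 + 1}"
        records.append((f"C{k}", sid, did))
        cands.append(
            Candidate(
                id=f"C{k}", sex="F", group=g, index=round(float(rng.normal()), 3),
                maxuse=1, minuse=1,
            )
        )
    ped = Pedigree(records)
    pm = PermissionMatrix(
        male_groups=("M1", "M2", "M3"),
        female_groups=("F1", "F2", "F3"),
        entries=np.array([[1, 0, 0], [0, 1, 0], [0, 1, 1]]),
    )
    proportions = {"F1": 0.75, "F2": 0.75, "F3": 0.75}
    return CandidateSet(cands), ped, pm, proportions
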